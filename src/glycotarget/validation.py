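"""Bioanalytical validation battery for the targeted glycopeptide assay.

Implements the study arms of a standard fit-for-purpose validation:
calibration linearity, carryover, intraday precision (as %CV of
back-calculated concentrations), matrix effect, selectivity, and limit of
detection.  Pass/fail thresholds follow the assay's stated criteria:
carryover < 5 %, %CV < 15 %, detection S/N > 3 (reference 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CARRYOVER_LIMIT_PCT",
    "CV_LIMIT_PCT",
    "SNR_THRESHOLD",
    "SNR_REFERENCE",
    "CalibrationSeries",
    "LinearityResult",
    "CarryoverResult",
    "PrecisionResult",
    "MatrixEffectResult",
    "SelectivityResult",
    "LODResult",
    "ValidationReport",
    "fit_linearity",
    "back_calculate",
    "carryover_ratio",
    "intraday_precision",
    "matrix_effect",
    "estimate_lod",
    "selectivity",
]

CARRYOVER_LIMIT_PCT = 5.0
CV_LIMIT_PCT = 15.0
SNR_THRESHOLD = 3.0
SNR_REFERENCE = 5.0


@dataclass(frozen=True)
class CalibrationSeries:
    """Replicate peak areas at each nominal concentration (ng/mL)."""

    levels: tuple[tuple[float, tuple[float, ...]], ...]

    @classmethod
    def from_dict(cls, d: dict[float, list[float]]) -> "CalibrationSeries":
        if any(c < 0 for c in d):
            raise ValueError("concentrations must be >= 0")
        return cls(tuple(sorted((float(c), tuple(map(float, a))) for c, a in d.items())))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels])

    def mean_areas(self) -> np.ndarray:
        return np.array([float(np.mean(a)) for _, a in self.levels])


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r2: float


def fit_linearity(series: CalibrationSeries, weighting: str = "none") -> LinearityResult:
    """Least squares of mean area vs nominal concentration.

    ``weighting`` in {"none", "1/x", "1/x2"}; unweighted ordinary least
    squares is the default.  Requires at least two distinct levels.
    """
    conc = series.concentrations
    area = series.mean_areas()
    if np.unique(conc).size < 2:
        raise ValueError("linearity fit needs >= 2 distinct concentration levels")
    if weighting == "none":
        fit = stats.linregress(conc, area)
        r2 = float(fit.rvalue**2) if math.isfinite(fit.rvalue) else 0.0
        return LinearityResult(float(fit.slope), float(fit.intercept), r2)
    if weighting == "1/x":
        w = np.where(conc > 0, 1.0 / np.where(conc > 0, conc, 1.0), 0.0)
    elif weighting == "1/x2":
        w = np.where(conc > 0, 1.0 / np.where(conc > 0, conc, 1.0) ** 2, 0.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    W = np.diag(w)
    X = np.column_stack([conc, np.ones_like(conc)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ area)
    pred = X @ beta
    sse = float(w @ (area - pred) ** 2)
    mean_w = float(w @ area / w.sum())
    sst = float(w @ (area - mean_w) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return LinearityResult(float(beta[0]), float(beta[1]), r2)


def back_calculate(areas: np.ndarray | list[float], fit: LinearityResult) -> np.ndarray:
    """Invert the calibration line: concentration = (area - intercept)/slope."""
    if fit.slope == 0:
        raise ValueError("cannot back-calculate with zero slope")
    return (np.asarray(areas, dtype=float) - fit.intercept) / fit.slope


@dataclass(frozen=True)
class CarryoverResult:
    ratio_pct: float
    passed: bool
    flagged: str = ""


def carryover_ratio(high_areas: list[float], blank_areas: list[float]) -> CarryoverResult:
    """Mean blank area as a percentage of mean high-sample area; pass < 5 %.

    High (e.g. 1000 ng/mL) samples and solvent blanks are injected
    alternately; residual signal in the blanks quantifies carryover.
    """
    if not high_areas or not blank_areas:
        raise ValueError("need both high-sample and blank areas")
    high = float(np.mean(high_areas))
    blank = float(np.mean(blank_areas))
    if high <= 0:
        return CarryoverResult(math.nan, False, "zero high-sample area; ratio undefined")
    ratio = blank / high * 100.0
    return CarryoverResult(ratio, ratio < CARRYOVER_LIMIT_PCT)


@dataclass(frozen=True)
class PrecisionResult:
    per_level_cv: tuple[tuple[float, float], ...]  # (concentration, %CV)
    passed: bool
    flagged: str = ""


def intraday_precision(backcalc: dict[float, list[float]]) -> PrecisionResult:
    """%CV (100 x sd/mean, ddof=1) of back-calculated concentrations per level.

    Pass iff every level's %CV < 15 %.
    """
    rows = []
    flagged = ""
    ok = True
    for conc in sorted(backcalc):
        reps = np.asarray(backcalc[conc], dtype=float)
        if reps.size < 2:
            raise ValueError(f"level {conc}: need >= 2 replicates")
        mean = float(reps.mean())
        if mean == 0:
            flagged = f"level {conc}: zero mean; %CV undefined"
            rows.append((conc, math.nan))
            ok = False
            continue
        cv = 100.0 * float(reps.std(ddof=1)) / mean
        rows.append((conc, cv))
        ok = ok and cv < CV_LIMIT_PCT
    return PrecisionResult(tuple(rows), ok, flagged)


@dataclass(frozen=True)
class MatrixEffectResult:
    ratio_pct: float
    flagged: str = ""


def matrix_effect(urine_areas: list[float], neat_areas: list[float]) -> MatrixEffectResult:
    """Mean fortified-urine area over mean fortified-neat area, as percent.

    100 % means no matrix effect; < 100 % indicates ion suppression by the
    urine matrix.
    """
    if not urine_areas or not neat_areas:
        raise ValueError("need both urine and neat areas")
    neat = float(np.mean(neat_areas))
    if neat <= 0:
        return MatrixEffectResult(math.nan, "zero neat-sample area; ratio undefined")
    return MatrixEffectResult(float(np.mean(urine_areas)) / neat * 100.0)


@dataclass(frozen=True)
class SelectivityResult:
    passed: bool
    failed_spiked: tuple[str, ...] = ()
    failed_negative: tuple[str, ...] = ()


def selectivity(
    spiked: dict[str, bool],
    negative: dict[str, bool],
) -> SelectivityResult:
    """Pass iff every spiked sample is detected and no negative sample is."""
    if not spiked or not negative:
        raise ValueError("need both spiked and negative results")
    missed = tuple(k for k, v in spiked.items() if not v)
    false_pos = tuple(k for k, v in negative.items() if v)
    return SelectivityResult(not missed and not false_pos, missed, false_pos)


@dataclass(frozen=True)
class LODResult:
    lod: float | None  # None => above max tested
    lod_reference: float | None  # lowest level meeting the reference S/N > 5
    per_level_snr: tuple[tuple[float, tuple[float, ...]], ...]
    above_max: bool = False

    def __str__(self) -> str:
        return "above max tested" if self.above_max else f"{self.lod} ng/mL"


def estimate_lod(
    snr_by_level: dict[float, list[float]],
    mode: str = "all",
) -> LODResult:
    """Lowest concentration reliably detected on a dilution ladder.

    ``mode='all'`` (default): a level passes when *every* replicate has
    S/N > 3; ``mode='mean'``: when the mean replicate S/N exceeds 3.  The
    LOD is the lowest concentration from which all higher levels also
    pass.  The analogous level for the reference S/N > 5 is reported too.
    """
    if len(snr_by_level) < 2:
        raise ValueError("need >= 2 concentration levels")
    levels = sorted(snr_by_level)

    def passes(snrs: list[float], threshold: float) -> bool:
        arr = np.asarray(snrs, dtype=float)
        if mode == "all":
            return bool(np.all(arr > threshold))
        if mode == "mean":
            return bool(arr.mean() > threshold)
        raise ValueError(f"unknown mode {mode!r}")

    def lowest_consistent(threshold: float) -> float | None:
        lod = None
        for conc in reversed(levels):
            if passes(snr_by_level[conc], threshold):
                lod = conc
            else:
                break
        return lod

    lod = lowest_consistent(SNR_THRESHOLD)
    lod_ref = lowest_consistent(SNR_REFERENCE)
    return LODResult(
        lod=lod,
        lod_reference=lod_ref,
        per_level_snr=tuple((c, tuple(snr_by_level[c])) for c in levels),
        above_max=lod is None,
    )


@dataclass
class ValidationReport:
    """All validation arms with pass flags recomputable from the numbers."""

    linearity: LinearityResult | None = None
    carryover: CarryoverResult | None = None
    precision: PrecisionResult | None = None
    matrix: MatrixEffectResult | None = None
    select: SelectivityResult | None = None
    lod: LODResult | None = None

    def as_dict(self) -> dict:
        out: dict = {}
        if self.linearity:
            out["linearity"] = {
                "slope": self.linearity.slope,
                "intercept": self.linearity.intercept,
                "r2": self.linearity.r2,
            }
        if self.carryover:
            out["carryover"] = {
                "ratio_pct": self.carryover.ratio_pct,
                "pass": self.carryover.passed,
            }
        if self.precision:
            out["precision"] = {
                "per_level_cv": dict(self.precision.per_level_cv),
                "pass": self.precision.passed,
            }
        if self.matrix:
            out["matrix_effect"] = {"ratio_pct": self.matrix.ratio_pct}
        if self.select:
            out["selectivity"] = {
                "pass": self.select.passed,
                "failed_spiked": list(self.select.failed_spiked),
                "failed_negative": list(self.select.failed_negative),
            }
        if self.lod:
            out["lod"] = {
                "estimate": self.lod.lod,
                "reference_level": self.lod.lod_reference,
                "above_max": self.lod.above_max,
            }
        return out
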