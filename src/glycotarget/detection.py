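"""Targeted detection of transitions in centroided runs.

The detection logic mirrors a t-SIM/ddMS2 assay: an extracted ion
chromatogram (XIC) of the monitored precursor isotopologue is built at ppm
tolerance, the chromatographic apex is located, signal-to-noise is
estimated against a robust background, and MS2 scans whose isolation
window covers the precursor are searched for the diagnostic oxonium
products.  A target is called detected only when both the S/N threshold
and the product-count requirement are met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentIon, TransitionEntry
from .run import Run, Spectrum

__all__ = [
    "Chromatogram",
    "DetectionPolicy",
    "ProductMatch",
    "DetectionResult",
    "extract_xic",
    "estimate_snr",
    "match_products",
    "detect_target",
]

#: robust-scale factor turning a median absolute deviation into a normal sd
MAD_SCALE = 1.4826


@dataclass
class Chromatogram:
    """Intensity vs retention time within one m/z tolerance window."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt must be strictly increasing")

    def __len__(self) -> int:
        return self.rt.size


@dataclass(frozen=True)
class DetectionPolicy:
    """Assay thresholds.  Defaults follow the validated method settings:
    10 ppm precursor tolerance, S/N threshold 3 (reference 5), ±0.01 m/z
    product tolerance, and 4 of the 5 computed oxonium/di/tri-saccharide
    products required (the published sixth product at 658.23 has ambiguous
    identity and is not required)."""

    precursor_ppm: float = 10.0
    product_tol_mz: float = 0.01
    product_tol_is_ppm: bool = False
    snr_threshold: float = 3.0
    snr_reference: float = 5.0
    min_products: int = 4
    peak_halfwidth_scans: int = 3
    area_halfwidth_min: float = 0.3


@dataclass(frozen=True)
class ProductMatch:
    expected_mz: float
    observed_mz: float
    intensity: float
    label: str

    @property
    def ppm_error(self) -> float:
        return (self.observed_mz - self.expected_mz) / self.expected_mz * 1e6


@dataclass
class DetectionResult:
    """Outcome of one targeted detection attempt."""

    transition: TransitionEntry
    detected: bool
    peak_rt: float | None
    peak_area: float
    signal_to_noise: float
    matched_products: list[ProductMatch]
    diagnostics: dict = field(default_factory=dict)


def extract_xic(
    run: Run,
    mz: float,
    ppm_tol: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> Chromatogram:
    """Per-scan summed intensity of centroids within ±ppm_tol of ``mz``."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    half = mz * ppm_tol * 1e-6
    rts, values = [], []
    for scan in run.ms1:
        if rt_window is not None and not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        sel = np.abs(scan.mz - mz) <= half
        rts.append(scan.rt)
        values.append(float(scan.intensity[sel].sum()))
    return Chromatogram(np.array(rts), np.array(values))


def estimate_snr(
    chrom: Chromatogram,
    peak_region: tuple[float, float],
) -> float:
    """Apex intensity over a robust noise level of the peak-free background.

    Noise level = median + 1.4826 x MAD of the points outside
    ``peak_region``; robust to sparse spikes.  Returns ``inf`` when the
    background is identically zero but a peak exists, and 0.0 for a flat
    all-zero chromatogram.
    """
    if len(chrom) == 0:
        raise ValueError("chromatogram is empty")
    inside = (chrom.rt >= peak_region[0]) & (chrom.rt <= peak_region[1])
    apex = float(chrom.intensity[inside].max()) if inside.any() else 0.0
    background = chrom.intensity[~inside]
    if background.size == 0:
        return math.inf if apex > 0 else 0.0
    med = float(np.median(background))
    mad = float(np.median(np.abs(background - med)))
    noise = med + MAD_SCALE * mad
    if noise == 0:
        return math.inf if apex > 0 else 0.0
    return apex / noise


def match_products(
    spectrum: Spectrum,
    expected: list[FragmentIon],
    tol: float = 0.01,
    tol_is_ppm: bool = False,
) -> list[ProductMatch]:
    """Closest-first one-to-one assignment of centroids to expected ions.

    Candidate (ion, centroid) pairs within tolerance are sorted by absolute
    m/z error (ties broken by lower expected m/z) and assigned greedily so
    each centroid and each expected ion is used at most once.
    """
    pairs = []
    for ion in expected:
        half = ion.mz * tol * 1e-6 if tol_is_ppm else tol
        for j in range(spectrum.mz.size):
            err = abs(spectrum.mz[j] - ion.mz)
            if err <= half:
                pairs.append((err, ion.mz, id(ion), j, ion))
    pairs.sort(key=lambda t: (t[0], t[1]))
    used_ions: set[int] = set()
    used_centroids: set[int] = set()
    matches = []
    for err, _, ion_id, j, ion in pairs:
        if ion_id in used_ions or j in used_centroids:
            continue
        used_ions.add(ion_id)
        used_centroids.add(j)
        matches.append(
            ProductMatch(
                expected_mz=ion.mz,
                observed_mz=float(spectrum.mz[j]),
                intensity=float(spectrum.intensity[j]),
                label=ion.label,
            )
        )
    matches.sort(key=lambda m: m.expected_mz)
    return matches


def _despike(y: np.ndarray) -> np.ndarray:
    """Replace single-scan spikes with the local 3-point median.

    A point is a spike when it exceeds twice the larger of its neighbours;
    on smooth monotone or apex data the 3-point median equals (or nearly
    equals) the point itself, so real chromatographic peaks are untouched.
    """
    if y.size < 3:
        return y
    out = y.copy()
    neighbour_max = np.maximum(y[:-2], y[2:])
    local_med = np.median(np.stack([y[:-2], y[1:-1], y[2:]]), axis=0)
    spikes = y[1:-1] > 2.0 * neighbour_max + 1e-12
    out[1:-1][spikes] = local_med[spikes]
    return out


def _peak_area(chrom: Chromatogram, apex_rt: float, halfwidth: float) -> float:
    """Background-subtracted area (intensity x minutes) around the apex.

    The trace is despiked before integration: a single-scan shot-noise
    spike is not chromatographic signal.  S/N estimation is *not*
    filtered.
    """
    inside = np.abs(chrom.rt - apex_rt) <= halfwidth
    if not inside.any():
        return 0.0
    filtered = _despike(chrom.intensity)
    background = filtered[~inside]
    baseline = float(np.median(background)) if background.size else 0.0
    if chrom.rt.size > 1:
        dt = float(np.median(np.diff(chrom.rt)))
    else:
        dt = 1.0
    net = np.clip(filtered[inside] - baseline, 0.0, None)
    return float(net.sum() * dt)


def detect_target(
    run: Run,
    transition: TransitionEntry,
    policy: DetectionPolicy = DetectionPolicy(),
) -> DetectionResult:
    """Full detection call for one transition.

    Detected iff the precursor XIC apex has S/N above
    ``policy.snr_threshold`` AND at least ``policy.min_products`` expected
    products match (within tolerance) in an MS2 scan whose isolation window
    covers the transition precursor.  Absence of MS2 coverage is reported
    in the diagnostics and forces a negative call.
    """
    diagnostics: dict = {}
    chrom = extract_xic(run, transition.precursor_mz, policy.precursor_ppm,
                        transition.rt_window)
    if len(chrom) == 0 or not np.any(chrom.intensity > 0):
        diagnostics["reason"] = "empty XIC"
        return DetectionResult(transition, False, None, 0.0, 0.0, [], diagnostics)

    apex_idx = int(np.argmax(chrom.intensity))
    apex_rt = float(chrom.rt[apex_idx])
    dt = float(np.median(np.diff(chrom.rt))) if len(chrom) > 1 else 1.0
    half = policy.peak_halfwidth_scans * dt
    snr = estimate_snr(chrom, (apex_rt - half, apex_rt + half))
    if math.isinf(snr):
        diagnostics["snr_flag"] = "all-zero background"
    # quantification centers on the despiked apex so a single-scan spike
    # elsewhere in the window cannot steal the integration region
    quant_rt = float(chrom.rt[int(np.argmax(_despike(chrom.intensity)))])
    area = _peak_area(chrom, quant_rt, policy.area_halfwidth_min)

    # MS2 confirmation: isolation window must cover the precursor
    best_matches: list[ProductMatch] = []
    n_covering = 0
    for scan in run.ms2:
        if scan.precursor_mz is None:
            continue
        width = scan.isolation_width or 2.0
        if abs(scan.precursor_mz - transition.precursor_mz) > width / 2.0:
            continue
        if not (transition.rt_window[0] <= scan.rt <= transition.rt_window[1]):
            continue
        n_covering += 1
        matches = match_products(scan, list(transition.products),
                                 policy.product_tol_mz, policy.product_tol_is_ppm)
        if len(matches) > len(best_matches):
            best_matches = matches
    diagnostics["ms2_scans_in_window"] = n_covering
    if n_covering == 0:
        diagnostics["reason"] = "no MS2 coverage"

    detected = (
        snr > policy.snr_threshold
        and len(best_matches) >= policy.min_products
        and n_covering > 0
    )
    diagnostics["snr_above_reference"] = snr > policy.snr_reference
    return DetectionResult(
        transition=transition,
        detected=detected,
        peak_rt=apex_rt,
        peak_area=area,
        signal_to_noise=snr,
        matched_products=best_matches,
        diagnostics=diagnostics,
    )
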