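"""Synthetic centroided SIM/ddMS2 runs with known ground truth.

The generator emulates the signal structure of a targeted glycopeptide
assay: MS1 SIM scans carrying the precursor isotopologue cluster under a
Gaussian elution profile, interleaved MS2 scans carrying the diagnostic
oxonium products, and a noise model (positive baseline, Gaussian scatter,
sparse spikes) tuned so that blank runs stay far below the S/N = 3
detection threshold.  Full validation-study designs (calibration series,
carryover pairs, precision levels, spiked/negative selectivity, urine/neat
matrix pairs) are simulated with an explicit ledger of injected truths so
the validation battery can be tested by parameter recovery.

What it does not emulate: real urine background complexity, retention-time
drift, detector saturation, or non-Gaussian peak shapes.  A green recovery
test therefore establishes correctness of the computations, not
instrument-level performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import (
    Glycopeptide,
    Peptide,
    parse_glycan_composition,
)
from .fragments import TransitionEntry, build_transition_list, isotope_cluster
from .run import Run, Spectrum

__all__ = [
    "NoiseModel",
    "SyntheticRunConfig",
    "StudyDesign",
    "StudyRun",
    "StudySimulation",
    "target_transition",
    "simulate_run",
    "simulate_validation_study",
]

#: Gaussian FWHM -> sigma
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def target_transition(rt_window: tuple[float, float] = (10.0, 14.0)) -> TransitionEntry:
    """The assay's target transition: HCSLNENITVPDTK_6_7_1_4, z=4, M+2.

    Precursor 1324.02 m/z with the five computed oxonium / di- /
    tri-saccharide products.
    """
    pep = Peptide(sequence="HCSLNENITVPDTK", start=32, end=45, missed_cleavages=2)
    gp = Glycopeptide(pep, parse_glycan_composition("_6_7_1_4"), site=38)
    return build_transition_list([gp], charge=4, monitored_isotopologue=2,
                                 rt_window=rt_window)[0]


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: positive baseline + Gaussian scatter + rare spikes."""

    baseline: float = 30.0
    sd: float = 10.0
    spike_rate: float = 0.005
    spike_scale: float = 10.0

    def sample(self, rng: np.random.Generator, n: int, spikes: bool = True) -> np.ndarray:
        values = np.abs(self.baseline + rng.normal(0.0, self.sd, n))
        if spikes:
            hit = rng.random(n) < self.spike_rate
            values[hit] *= self.spike_scale
        return values


@dataclass(frozen=True)
class SyntheticRunConfig:
    """Everything needed to simulate one run deterministically.

    ``response`` is the injected calibration slope: XIC peak area
    (intensity x minutes) per ng/mL.  Its default (55) places the S/N = 3
    crossing of the synthetic assay near 0.35 ng/mL, i.e. the same order
    as the real assay's sub-0.5 ng/mL limit of detection.
    """

    transition: TransitionEntry
    concentration: float  # ng/mL
    response: float = 55.0  # area units per ng/mL
    peak_rt: float = 12.0
    peak_fwhm: float = 0.2  # minutes
    rt_span: tuple[float, float] = (10.0, 14.0)
    scan_interval: float = 0.02  # minutes between MS1 scans
    ms2_every: int = 5  # one MS2 per this many MS1 scans
    ms2_response: float = 200.0  # product apex intensity per ng/mL
    #: relative apex intensities of the monitored products, in transition
    #: order (HexNAc, NeuAc, NeuAc-H2O, HexNAc+Hex, HexNAc+Hex+NeuAc)
    ms2_relative_products: tuple[float, ...] = (1.0, 0.6, 0.5, 0.8, 0.7)
    noise: NoiseModel = NoiseModel()
    ms2_noise: NoiseModel = NoiseModel(baseline=15.0, sd=5.0)
    n_noise_points: int = 10
    sim_window_halfwidth: float = 5.0  # m/z around the precursor
    centroid_floor: float = 30.0  # MS2 centroids below this are not emitted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def _elution(rt: np.ndarray | float, rt0: float, fwhm: float) -> np.ndarray | float:
    sigma = fwhm / _FWHM
    return np.exp(-0.5 * ((rt - rt0) / sigma) ** 2)


def simulate_run(config: SyntheticRunConfig) -> Run:
    """Simulate one centroided run; bitwise reproducible for a fixed seed.

    The monitored precursor isotopologue is scaled so that the
    background-subtracted XIC area equals ``concentration x response``
    (closed-form Gaussian integral); other cluster members follow the
    binomial isotopologue model.  A chemical-background centroid is placed
    at the monitored m/z in every scan so blank XICs carry realistic
    noise rather than zeros.
    """
    rng = np.random.default_rng(config.seed)
    t = config.transition
    sigma = config.peak_fwhm / _FWHM
    # amplitude such that integral(A * gaussian) = concentration * response
    amp = config.concentration * config.response / (sigma * math.sqrt(2.0 * math.pi))

    gp_mass = t.glycopeptide.mass
    cluster = isotope_cluster(gp_mass, t.charge, n_peaks=5)
    monitored_rel = cluster[t.monitored_isotopologue][1]
    cluster_mz = np.array([mz for mz, _ in cluster])
    cluster_rel = np.array([rel for _, rel in cluster]) / monitored_rel

    lo, hi = config.rt_span
    n_scans = int(round((hi - lo) / config.scan_interval)) + 1
    rts = lo + np.arange(n_scans) * config.scan_interval

    ms1: list[Spectrum] = []
    ms2: list[Spectrum] = []
    prec_mz = t.precursor_mz
    win = config.sim_window_halfwidth
    for i, rt in enumerate(rts):
        env = float(_elution(rt, config.peak_rt, config.peak_fwhm))
        # random chemical noise across the SIM window
        noise_mz = rng.uniform(prec_mz - win, prec_mz + win, config.n_noise_points)
        noise_int = config.noise.sample(rng, config.n_noise_points)
        # persistent background at the monitored m/z (slight mass jitter)
        bg_mz = prec_mz * (1.0 + rng.normal(0.0, 2e-6))
        # steady chemical background: no shot-noise spikes in this channel
        bg_int = config.noise.sample(rng, 1, spikes=False)
        mzs = [noise_mz, [bg_mz]]
        ints = [noise_int, bg_int]
        if amp > 0 and env > 1e-12:
            mzs.append(cluster_mz)
            ints.append(amp * env * cluster_rel)
        mz = np.concatenate([np.asarray(x, dtype=float) for x in mzs])
        inten = np.concatenate([np.asarray(x, dtype=float) for x in ints])
        order = np.argsort(mz)
        ms1.append(Spectrum(rt=float(rt), mz=mz[order], intensity=inten[order]))

        if i % config.ms2_every == 0:
            ms2.append(_simulate_ms2(config, rng, float(rt), env))

    return Run(ms1=ms1, ms2=ms2,
               metadata={"id": f"synthetic_seed{config.seed}",
                         "concentration": config.concentration})


def _simulate_ms2(config: SyntheticRunConfig, rng: np.random.Generator,
                  rt: float, env: float) -> Spectrum:
    t = config.transition
    n_noise = 40
    noise_mz = rng.uniform(150.0, 1400.0, n_noise)
    noise_int = config.ms2_noise.sample(rng, n_noise)
    mzs = [noise_mz]
    ints = [noise_int]
    if config.concentration > 0 and env > 1e-12:
        prod_mz = np.array([p.mz for p in t.products])
        rel = np.array(config.ms2_relative_products[: prod_mz.size])
        if rel.size < prod_mz.size:  # pad if more products than defaults
            rel = np.concatenate([rel, np.full(prod_mz.size - rel.size, 0.5)])
        signal = config.concentration * config.ms2_response * env * rel
        signal = signal + rng.normal(0.0, config.ms2_noise.sd, signal.size)
        keep = signal > config.centroid_floor
        mzs.append(prod_mz[keep])
        ints.append(signal[keep])
    mz = np.concatenate([np.asarray(x, dtype=float) for x in mzs])
    inten = np.concatenate([np.asarray(x, dtype=float) for x in ints])
    order = np.argsort(mz)
    return Spectrum(rt=rt, mz=mz[order], intensity=inten[order],
                    ms_level=2, precursor_mz=t.precursor_mz, isolation_width=2.0)


# ---------------------------------------------------------------------------
# validation-study simulation


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the synthetic validation study (mirrors the assay design:
    8-level x 7-replicate calibration, five 1000 ng/mL carryover pairs,
    3-level x 5-replicate intraday precision, five spiked + five negative
    selectivity samples, five urine/neat matrix pairs)."""

    linearity_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0)
    linearity_replicates: int = 7
    carryover_concentration: float = 1000.0
    carryover_pairs: int = 5
    carryover_fraction: float = 0.02  # injected truth
    precision_levels: tuple[float, ...] = (0.5, 50.0, 200.0)
    precision_replicates: int = 5
    selectivity_concentration: float = 10.0
    selectivity_samples: int = 5
    matrix_concentration: float = 100.0
    matrix_pairs: int = 5
    suppression: float = 0.9  # injected urine/neat response ratio
    noise_cv: float = 0.05  # proportional run-to-run response scatter


@dataclass(frozen=True)
class StudyRun:
    run_id: str
    role: str  # level | high | blank | spiked | negative | urine | neat
    nominal_concentration: float
    run: Run


@dataclass
class StudySimulation:
    runs: list[StudyRun]
    truth: dict
    design: StudyDesign


def simulate_validation_study(
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    base_config: SyntheticRunConfig | None = None,
) -> StudySimulation:
    """Simulate every arm of the validation study with a truth ledger.

    Run-to-run variability is a proportional response multiplier
    ``1 + N(0, noise_cv)``; carryover injects ``carryover_fraction`` of the
    preceding high sample's signal into each blank; matrix-arm urine runs
    are suppressed by ``suppression``.
    """
    base = base_config or SyntheticRunConfig(
        transition=target_transition(), concentration=0.0
    )
    master = np.random.default_rng(seed)
    runs: list[StudyRun] = []

    def spawn(role: str, conc: float, response_scale: float = 1.0) -> StudyRun:
        run_seed = int(master.integers(0, 2**31 - 1))
        scatter = 1.0 + master.normal(0.0, design.noise_cv)
        scatter = max(scatter, 0.0)
        cfg = replace(
            base,
            concentration=conc * scatter * response_scale if conc > 0 else
            conc,
            seed=run_seed,
        )
        idx = len(runs)
        return StudyRun(f"run{idx:03d}_{role}", role, conc, simulate_run(cfg))

    # carryover blanks carry a fraction of the preceding high's signal
    def spawn_blank_with_carryover() -> StudyRun:
        run_seed = int(master.integers(0, 2**31 - 1))
        carry = design.carryover_concentration * design.carryover_fraction
        cfg = replace(base, concentration=carry, seed=run_seed)
        idx = len(runs)
        return StudyRun(f"run{idx:03d}_blank", "blank", 0.0, simulate_run(cfg))

    for conc in design.linearity_levels:
        for _ in range(design.linearity_replicates):
            runs.append(spawn("level", conc))
    for _ in range(design.carryover_pairs):
        runs.append(spawn("high", design.carryover_concentration))
        runs.append(spawn_blank_with_carryover())
    for conc in design.precision_levels:
        for _ in range(design.precision_replicates):
            runs.append(spawn("precision", conc))
    for _ in range(design.selectivity_samples):
        runs.append(spawn("spiked", design.selectivity_concentration))
        runs.append(spawn("negative", 0.0))
    for _ in range(design.matrix_pairs):
        runs.append(spawn("urine", design.matrix_concentration,
                          response_scale=design.suppression))
        runs.append(spawn("neat", design.matrix_concentration))

    truth = {
        "response": base.response,
        "noise_cv": design.noise_cv,
        "carryover_fraction": design.carryover_fraction,
        "suppression": design.suppression,
    }
    return StudySimulation(runs=runs, truth=truth, design=design)
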