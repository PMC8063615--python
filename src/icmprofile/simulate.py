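"""Synthetic data with known ground truth.

Emulates the acquisition design of an intact-cell MALDI-TOF fertility study:
each animal contributes several ejaculates, each ejaculate is spotted twelve
times on the MALDI target and every spot is acquired three consecutive times,
giving 36 technical replicate spectra per sample.  Spectra are sums of
Gaussian peaks whose width grows linearly with m/z (linear-mode-like
resolution), a smooth exponential-decay chemical baseline, and positive-
truncated Gaussian noise; a dominant lock-mass peak is always planted in the
middle of the mass range so internal recalibration can be exercised.  Per-spot
affine mass-axis drift (ppm-scale gain plus small offset) mimics target-plate
miscalibration.  Differential peaks are scaled by their fold change in the
fertile group, so FC is fertile/subfertile throughout.

Companion generators produce Scaffold-style protein-cluster quantification
tables (negative-binomial weighted spectral counts, lognormal precursor
intensities), per-animal phenotype tables (fertility rate, mass motility,
CASA velocities) and bare feature matrices for statistical calibration runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureMatrix, PipelineError, QuantTable, Spectrum

LOCKMASS_MZ = 7983.457  # phosphoglycerate kinase proteoform, mid-range anchor

#: approximate resolving power of a linear-mode TOF in this mass range
LINEAR_MODE_RESOLUTION = 600.0

PHENOTYPE_COLUMNS = [
    "animal",
    "group",
    "fertility_rate",
    "volume_ml",
    "concentration_1e9_per_ml",
    "viability_pct",
    "mass_motility",
    "vsl_um_s",
    "vcl_um_s",
    "vap_um_s",
    "pct_motile",
    "pct_rapid",
    "pct_progressive",
]


@dataclass
class SimConfig:
    """Parameters of the spectrum simulator.

    Replicate-structure defaults (3 ejaculates, 12 spots, 3 acquisitions per
    spot, m/z 1,000-20,000) reproduce the study design they emulate; peak,
    noise and drift parameters are simulator conveniences with documented
    defaults.
    """

    n_fertile: int = 9
    n_subfertile: int = 9
    n_ejaculates: int = 3
    n_spots: int = 12
    n_acquisitions_per_spot: int = 3
    mz_range: tuple[float, float] = (1000.0, 20000.0)
    mz_step: float = 0.5
    n_base_peaks: int = 60
    n_differential: int = 5
    differential_fc: tuple[float, ...] = (2.0, 2.0, 0.5, 0.5, 1.5)
    noise_sd: float = 1.0
    baseline_scale: float = 20.0
    baseline_tau: float = 3000.0
    drift_ppm_sd: float = 150.0
    resolution: float = LINEAR_MODE_RESOLUTION
    animal_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_fertile": self.n_fertile,
            "n_subfertile": self.n_subfertile,
            "n_ejaculates": self.n_ejaculates,
            "n_spots": self.n_spots,
            "n_acquisitions_per_spot": self.n_acquisitions_per_spot,
            "n_base_peaks": self.n_base_peaks,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise PipelineError(f"{name} must be a count >= 1, got {value!r}")
        if self.n_differential < 0:
            raise PipelineError("n_differential must be >= 0")
        if self.n_differential > self.n_base_peaks:
            raise PipelineError("n_differential cannot exceed n_base_peaks")
        if len(self.differential_fc) < self.n_differential:
            raise PipelineError("differential_fc must supply one ratio per differential peak")
        if any((not math.isfinite(fc)) or fc <= 0 for fc in self.differential_fc):
            raise PipelineError("differential_fc entries must be finite and > 0")
        lo, hi = self.mz_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
            raise PipelineError("mz_range must be a finite interval with lower < upper")
        for name in ("mz_step", "noise_sd", "baseline_scale", "baseline_tau",
                     "drift_ppm_sd", "resolution", "animal_cv"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise PipelineError(f"{name} must be finite and >= 0, got {value!r}")
        if self.mz_step <= 0 or self.resolution <= 0 or self.baseline_tau <= 0:
            raise PipelineError("mz_step, resolution and baseline_tau must be > 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data for recovery testing."""

    differential_bins: list[tuple[float, float]] = field(default_factory=list)
    drift: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    lockmass_true_mz: float = LOCKMASS_MZ
    peak_mz: np.ndarray | None = None
    effects: dict = field(default_factory=dict)


def _peak_sigma(mu: np.ndarray | float, resolution: float) -> np.ndarray | float:
    # FWHM = m/R for a TOF; sigma = FWHM / 2.355
    return mu / (2.3548200450309493 * resolution)


def simulate_dataset(config: SimConfig) -> tuple[list[Spectrum], SimTruth]:
    """Simulate the full multi-animal, multi-replicate spectrum set.

    Returns one spectrum per (animal, ejaculate, spot, acquisition) plus the
    ground truth (differential peak positions and fold changes, per-spectrum
    mass-axis drift and noise level).  All randomness derives from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mz_range
    grid = np.arange(lo, hi, config.mz_step)

    # Base peak positions and amplitudes, shared by every animal.  The lock
    # mass is kept clear of random peaks so it is always the dominant
    # mid-range feature.
    margin = 5 * _peak_sigma(LOCKMASS_MZ, config.resolution)
    positions = []
    while len(positions) < config.n_base_peaks:
        cand = rng.uniform(lo + 20.0, hi - 20.0, size=config.n_base_peaks)
        positions.extend(m for m in cand if abs(m - LOCKMASS_MZ) > margin)
    positions = np.sort(np.array(positions[: config.n_base_peaks]))
    amplitudes = rng.lognormal(mean=math.log(50.0), sigma=0.8, size=config.n_base_peaks)

    diff_idx = rng.choice(config.n_base_peaks, size=config.n_differential, replace=False)
    fold_changes = np.asarray(config.differential_fc[: config.n_differential], dtype=float)

    lock_amp = 3.0 * float(amplitudes.max(initial=1.0))

    truth = SimTruth(
        differential_bins=[(float(positions[i]), float(fc)) for i, fc in zip(diff_idx, fold_changes)],
        lockmass_true_mz=LOCKMASS_MZ,
        peak_mz=positions.copy(),
    )

    animals = [("F", f"F{i + 1:02d}") for i in range(config.n_fertile)] + [
        ("SF", f"SF{i + 1:02d}") for i in range(config.n_subfertile)
    ]

    sigmas = _peak_sigma(positions, config.resolution)
    lock_sigma = _peak_sigma(LOCKMASS_MZ, config.resolution)
    baseline = config.baseline_scale * np.exp(-(grid - lo) / config.baseline_tau)

    spectra: list[Spectrum] = []
    for group, animal in animals:
        amps = amplitudes * rng.lognormal(mean=0.0, sigma=config.animal_cv, size=len(amplitudes))
        if group == "F":
            amps = amps.copy()
            amps[diff_idx] = amps[diff_idx] * fold_changes
        for ejaculate in range(config.n_ejaculates):
            for spot in range(config.n_spots):
                gain = 1.0 + rng.normal(0.0, config.drift_ppm_sd * 1e-6)
                offset = rng.normal(0.0, 0.05) if config.drift_ppm_sd > 0 else 0.0
                # peaks appear at drifted apparent positions on the fixed grid
                mu = positions * gain + offset
                mu_lock = LOCKMASS_MZ * gain + offset
                signal = baseline.copy()
                for m, a, s in zip(mu, amps, sigmas):
                    lo_i, hi_i = np.searchsorted(grid, [m - 6 * s, m + 6 * s])
                    seg = grid[lo_i:hi_i]
                    signal[lo_i:hi_i] += a * np.exp(-0.5 * ((seg - m) / s) ** 2)
                lo_i, hi_i = np.searchsorted(
                    grid, [mu_lock - 6 * lock_sigma, mu_lock + 6 * lock_sigma]
                )
                seg = grid[lo_i:hi_i]
                signal[lo_i:hi_i] += lock_amp * np.exp(
                    -0.5 * ((seg - mu_lock) / lock_sigma) ** 2
                )
                for acq in range(config.n_acquisitions_per_spot):
                    sd = config.noise_sd * rng.lognormal(0.0, 0.3) if config.noise_sd > 0 else 0.0
                    noise = np.maximum(rng.normal(0.0, sd, size=len(grid)), 0.0) if sd > 0 else 0.0
                    spec = Spectrum(
                        mz=grid,
                        intensity=signal + noise,
                        meta={
                            "animal": animal,
                            "group": group,
                            "ejaculate": ejaculate,
                            "spot": spot,
                            "acquisition": acq,
                        },
                    )
                    rid = spec.replicate_id()
                    truth.drift[rid] = (gain, offset)
                    truth.noise_sd[rid] = float(sd)
                    spectra.append(spec)
    return spectra, truth


def simulate_feature_matrix(
    n_bins: int,
    n_per_group: int,
    cv: float = 0.30,
    differential: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, SimTruth]:
    """Simulate a per-animal peak-intensity matrix directly.

    Intensities are lognormal with the requested coefficient of variation;
    ``differential`` maps bin index -> fold change applied to the fertile
    group.  Used for statistical calibration (type-I error, sensitivity)
    where full spectrum simulation would only add cost.
    """
    if n_bins < 1 or n_per_group < 1:
        raise PipelineError("n_bins and n_per_group must be >= 1")
    if cv < 0 or not math.isfinite(cv):
        raise PipelineError("cv must be finite and >= 0")
    differential = differential or {}
    if any(i < 0 or i >= n_bins for i in differential):
        raise PipelineError("differential bin index out of range")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    bins = np.sort(rng.uniform(1000.0, 20000.0, size=n_bins))
    base = rng.lognormal(mean=math.log(100.0), sigma=0.5, size=n_bins)
    effect = np.ones(n_bins)
    for i, fc in differential.items():
        effect[i] = fc
    n = 2 * n_per_group
    draws = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=(n, n_bins))
    values = draws * base
    values[:n_per_group] *= effect  # fertile animals listed first
    animals = [f"F{i + 1:02d}" for i in range(n_per_group)] + [
        f"SF{i + 1:02d}" for i in range(n_per_group)
    ]
    groups = ["F"] * n_per_group + ["SF"] * n_per_group
    meta = pd.DataFrame(
        {
            "animal": animals,
            "group": groups,
            "ejaculate": -1,
            "spot": -1,
            "acquisition": -1,
        },
        index=pd.Index(animals, name="sample"),
    )
    frame = pd.DataFrame(values, index=meta.index, columns=[f"{b:.4f}" for b in bins])
    truth = SimTruth(
        differential_bins=[(float(bins[i]), float(fc)) for i, fc in sorted(differential.items())],
        effects={int(i): float(fc) for i, fc in differential.items()},
    )
    return FeatureMatrix(values=frame, bins=bins, meta=meta), truth


def simulate_quant_table(
    n_clusters: int,
    n_per_group: int,
    n_tech: int = 3,
    effect_spec: list[float] | tuple[float, ...] = (),
    seed: int = 0,
    dispersion: float = 0.3,
    intensity_sigma: float = 0.4,
    loc_fraction: float = 0.25,
) -> tuple[QuantTable, SimTruth]:
    """Simulate a Scaffold-style protein-cluster quantification table.

    Weighted spectral counts follow a negative-binomial model
    (var = mu + dispersion * mu^2); precursor intensities are lognormal.
    ``effect_spec`` lists fold changes applied, cluster by cluster, to the
    fertile group; remaining clusters are null.  A fraction of member
    proteins carries LOC-style gene symbols to exercise cluster-representative
    selection.
    """
    if n_clusters < 1 or n_per_group < 1 or n_tech < 1:
        raise PipelineError("n_clusters, n_per_group and n_tech must be >= 1")
    if len(effect_spec) > n_clusters:
        raise PipelineError("effect_spec cannot be longer than n_clusters")
    if any((not math.isfinite(fc)) or fc <= 0 for fc in effect_spec):
        raise PipelineError("effect_spec entries must be finite and > 0")
    rng = np.random.default_rng(seed)
    animals = [f"F{i + 1:02d}" for i in range(n_per_group)] + [
        f"SF{i + 1:02d}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["F"] * n_per_group + ["SF"] * n_per_group, index=animals, name="group"
    )
    columns = pd.MultiIndex.from_product(
        [animals, range(n_tech)], names=["animal", "replicate"]
    )

    effects = {c: float(effect_spec[c]) for c in range(len(effect_spec))}
    rows, prot_meta = [], []
    nb_n = 1.0 / dispersion
    for c in range(n_clusters):
        n_members = int(rng.integers(1, 4))
        fc = effects.get(c, 1.0)
        for m in range(n_members):
            acc = f"P{c:03d}.{m}"
            is_loc = rng.uniform() < loc_fraction
            gene = f"LOC1{c:05d}{m}" if is_loc else f"GENE{c}{'ABC'[m]}"
            desc = "" if is_loc and rng.uniform() < 0.5 else f"synthetic sperm protein {c}.{m}"
            mu = rng.lognormal(math.log(20.0), 0.8)
            imu = mu * rng.lognormal(math.log(5e5 / 20.0), 0.3)
            counts_row, intens_row = [], []
            for animal in animals:
                scale = fc if groups[animal] == "F" else 1.0
                for _ in range(n_tech):
                    m_c = mu * scale
                    counts_row.append(
                        rng.negative_binomial(nb_n, nb_n / (nb_n + m_c)) if m_c > 0 else 0
                    )
                    intens_row.append(
                        rng.lognormal(math.log(imu * scale) - 0.5 * intensity_sigma**2,
                                      intensity_sigma)
                    )
            rows.append((counts_row, intens_row))
            prot_meta.append(
                {
                    "cluster": f"{c + 1}",
                    "accession": acc,
                    "gene": gene,
                    "description": desc,
                    "mw_kda": float(np.round(rng.uniform(10, 120), 1)),
                }
            )
    proteins = pd.DataFrame(prot_meta).set_index("accession")
    counts = pd.DataFrame(
        [r[0] for r in rows], index=proteins.index, columns=columns, dtype=float
    )
    intensities = pd.DataFrame(
        [r[1] for r in rows], index=proteins.index, columns=columns, dtype=float
    )
    truth = SimTruth(effects={f"{c + 1}": fc for c, fc in effects.items()})
    table = QuantTable(
        proteins=proteins, counts=counts, intensities=intensities, groups=groups
    )
    return table, truth


def simulate_phenotypes(n_fertile: int, n_subfertile: int, seed: int = 0) -> pd.DataFrame:
    """Simulate a per-animal fertility/semen phenotype table.

    Fertile animals have fertility rates in (70, 100], subfertile in [0, 40);
    mass motility is an ordinal 0-9 score with a group shift; CASA velocity
    parameters overlap between groups, as real semen parameters do.
    """
    if n_fertile < 1 or n_subfertile < 1:
        raise PipelineError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for group, n in (("F", n_fertile), ("SF", n_subfertile)):
        for i in range(n):
            if group == "F":
                fr = rng.uniform(72.0, 98.0)
                motility = np.clip(rng.normal(7.0, 1.0), 0.0, 9.0)
                vap = rng.normal(60.0, 12.0)
            else:
                fr = rng.uniform(5.0, 38.0)
                motility = np.clip(rng.normal(4.5, 1.0), 0.0, 9.0)
                vap = rng.normal(48.0, 12.0)
            vap = max(vap, 1.0)
            vcl = vap * rng.uniform(1.2, 1.8)
            vsl = vap * rng.uniform(0.6, 0.95)
            records.append(
                {
                    "animal": f"{group}{i + 1:02d}",
                    "group": group,
                    "fertility_rate": round(fr, 1),
                    "volume_ml": round(rng.uniform(0.2, 1.0), 2),
                    "concentration_1e9_per_ml": round(rng.uniform(2.0, 6.0), 2),
                    "viability_pct": round(float(np.clip(rng.normal(88, 6), 0, 100)), 1),
                    "mass_motility": round(float(motility), 1),
                    "vsl_um_s": round(vsl, 1),
                    "vcl_um_s": round(vcl, 1),
                    "vap_um_s": round(vap, 1),
                    "pct_motile": round(float(np.clip(rng.normal(82, 8), 0, 100)), 1),
                    "pct_rapid": round(float(np.clip(rng.normal(55, 12), 0, 100)), 1),
                    "pct_progressive": round(float(np.clip(rng.normal(45, 12), 0, 100)), 1),
                }
            )
    return pd.DataFrame.from_records(records, columns=PHENOTYPE_COLUMNS)
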