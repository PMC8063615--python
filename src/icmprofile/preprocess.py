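"""Spectral processing chain for intact-cell MALDI-TOF profiles.

Steps, in the order the pipeline applies them: square-root variance
stabilization, TopHat (morphological opening) baseline subtraction,
Savitzky-Golay smoothing, external calibration against a calibrant mixture,
alignment of replicate spectra on prominent peaks, internal lock-mass
recalibration, and TIC normalization.  Every step returns a new
:class:`~icmprofile.core.Spectrum` and appends a history flag; none mutates
its input.

The lock-mass correction is multiplicative (a single-point gain): TOF mass
error is predominantly gain-like, so rescaling the whole axis by
reference/observed both restores the lock peak exactly and corrects
proportional error elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

from .core import CalibrationError, Spectrum, SpectrumError
from .peaks import local_maximum_indices

#: default calibrant mixture: reference average [M+H]+ masses in Da
DEFAULT_CALIBRANTS = (
    ("Glu1-fibrinopeptide B", 1571.59),
    ("ACTH (18-39)", 2466.68),
    ("insulin", 5734.52),
    ("ubiquitin", 8565.76),
    ("cytochrome C", 12360.97),
    ("myoglobin", 16952.31),
)

LOCKMASS_REFERENCE_MZ = 7983.457


@dataclass
class CalibrantSet:
    """Named reference masses used for external (multi-point) calibration."""

    entries: tuple[tuple[str, float], ...] = DEFAULT_CALIBRANTS

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise CalibrationError("a calibrant set needs at least two entries")
        masses = [m for _, m in self.entries]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise CalibrationError("calibrant reference masses must be strictly increasing")

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for _, m in self.entries], dtype=float)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]


@dataclass
class LockMassConfig:
    """Internal single-point recalibration settings.

    The reference is the dominant mid-range proteoform (phosphoglycerate
    kinase); the search window brackets "the middle of the mass range".
    """

    reference_mz: float = LOCKMASS_REFERENCE_MZ
    search_window: tuple[float, float] = (5000.0, 12000.0)

    def __post_init__(self) -> None:
        lo, hi = self.search_window
        if not (lo < self.reference_mz < hi):
            raise CalibrationError("lock-mass reference must lie inside the search window")


def sqrt_transform(s: Spectrum) -> Spectrum:
    """Square-root each intensity (variance stabilization for count-like noise)."""
    return s.with_arrays(intensity=np.sqrt(s.intensity), step="sqrt")


def tophat_baseline(s: Spectrum, half_window: int = 75) -> tuple[np.ndarray, Spectrum]:
    """Morphological-opening (TopHat) baseline estimate and corrected spectrum.

    The baseline is a grayscale erosion followed by dilation with a flat
    structuring element of ``2 * half_window + 1`` points (windows truncated
    at the spectrum edges), which by construction never exceeds the signal;
    the corrected spectrum is the signal minus baseline, clipped at zero.
    """
    if half_window < 1:
        raise SpectrumError("half_window must be >= 1")
    size = 2 * half_window + 1
    if len(s) < size:
        raise SpectrumError(
            f"spectrum of {len(s)} points is shorter than the {size}-point TopHat window"
        )
    eroded = minimum_filter1d(s.intensity, size=size, mode="nearest")
    baseline = maximum_filter1d(eroded, size=size, mode="nearest")
    corrected = np.maximum(s.intensity - baseline, 0.0)
    return baseline, s.with_arrays(intensity=corrected, step="tophat")


def savitzky_golay(s: Spectrum, window: int = 21, order: int = 3) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing.

    ``window`` must be odd; edges are handled by fitting the boundary
    polynomial over the available points.  A window of 1 is the identity.
    """
    if window % 2 == 0:
        raise SpectrumError("Savitzky-Golay window must be odd")
    if window == 1:
        return s.with_arrays(step="savgol")
    if order >= window:
        raise SpectrumError("polynomial order must be smaller than the window")
    smoothed = savgol_filter(s.intensity, window_length=window, polyorder=order, mode="interp")
    return s.with_arrays(intensity=np.maximum(smoothed, 0.0), step="savgol")


def _apex_near(s: Spectrum, target: float, ppm: float) -> int | None:
    """Index of the tallest local maximum within +/- ppm of target, or None."""
    tol = target * ppm * 1e-6
    lo, hi = np.searchsorted(s.mz, [target - tol, target + tol])
    if hi - lo < 1:
        return None
    idx = local_maximum_indices(s.intensity, half_window=1)
    idx = idx[(idx >= lo) & (idx < hi)]
    if len(idx) == 0:
        return None
    return int(idx[np.argmax(s.intensity[idx])])


def external_calibrate(
    s: Spectrum,
    cal: CalibrantSet | None = None,
    search_ppm: float = 2000.0,
    max_error_fraction: float = 5e-4,
) -> tuple[Spectrum, dict]:
    """Affine mass-axis calibration against a calibrant mixture.

    Each calibrant is located as the tallest local maximum within
    ``+/- search_ppm`` of its reference mass; a least-squares affine map
    observed -> reference is fitted and applied to the whole axis.  The fit
    must leave every matched calibrant within ``max_error_fraction``
    (default 0.05%) of its reference, the accuracy bound the method targets.

    Returns the calibrated spectrum and a report with matched calibrants and
    relative residuals.
    """
    cal = cal or CalibrantSet()
    observed, reference, matched = [], [], []
    missing = []
    for name, ref in cal.entries:
        i = _apex_near(s, ref, search_ppm)
        if i is None:
            missing.append(name)
            continue
        observed.append(s.mz[i])
        reference.append(ref)
        matched.append(name)
    if len(observed) < 2:
        raise CalibrationError(
            f"external calibration needs >= 2 matched calibrants; missing: {missing}"
        )
    obs = np.asarray(observed)
    ref = np.asarray(reference)
    slope, intercept = np.polyfit(obs, ref, 1)
    residual = np.abs((slope * obs + intercept) - ref) / ref
    if residual.max() > max_error_fraction:
        raise CalibrationError(
            f"calibration residual {residual.max():.2e} exceeds the "
            f"{max_error_fraction:.2e} relative accuracy bound"
        )
    out = s.with_arrays(mz=slope * s.mz + intercept, step="external_cal")
    report = {
        "slope": float(slope),
        "intercept": float(intercept),
        "matched": matched,
        "missing": missing,
        "residual_rel": residual.tolist(),
    }
    return out, report


def lockmass_recalibrate(s: Spectrum, cfg: LockMassConfig | None = None) -> Spectrum:
    """Single-point internal recalibration on the mid-range lock-mass peak.

    The highest-intensity local maximum inside the search window is taken as
    the observed lock mass and the whole m/z axis is multiplied by
    reference/observed, so the lock peak apex lands exactly on the reference.
    Applying the correction twice is the identity (up to float rounding).
    """
    cfg = cfg or LockMassConfig()
    lo, hi = np.searchsorted(s.mz, cfg.search_window)
    if hi - lo < 3:
        raise CalibrationError("no data points inside the lock-mass search window")
    idx = local_maximum_indices(s.intensity, half_window=1)
    idx = idx[(idx >= lo) & (idx < hi)]
    if len(idx) == 0 or s.intensity[idx].max() <= 0:
        flagged = s.with_arrays(step="lockmass_failed")
        raise CalibrationError(
            f"no peak found in lock-mass window {cfg.search_window}; "
            f"spectrum {flagged.replicate_id()} left uncorrected"
        )
    apex = idx[np.argmax(s.intensity[idx])]
    factor = cfg.reference_mz / s.mz[apex]
    return s.with_arrays(mz=s.mz * factor, step="lockmass")


def _prominent_apexes(s: Spectrum, top_n: int) -> np.ndarray:
    """m/z of the top_n most intense local maxima (apex positions)."""
    idx = local_maximum_indices(s.intensity, half_window=5)
    if len(idx) == 0:
        return np.empty(0)
    order = np.argsort(s.intensity[idx])[::-1][:top_n]
    return np.sort(s.mz[idx[order]])


def align_prominent_peaks(
    spectra: list[Spectrum],
    top_n: int = 10,
    match_ppm: float = 2000.0,
    min_presence: float = 0.5,
) -> tuple[list[Spectrum], dict]:
    """Warp each spectrum's mass axis onto a shared prominent-peak reference.

    The reference positions are the medians of apex clusters formed by
    pooling the ``top_n`` most intense local maxima of every spectrum and
    greedily grouping them within ``match_ppm``; clusters present in at least
    ``min_presence`` of the spectra are kept.  Each spectrum gets an affine
    warp fitted by least squares to its matched (observed, reference) pairs;
    spectra with fewer than two matches are passed through unwarped and
    flagged.
    """
    if len(spectra) < 2:
        raise SpectrumError("alignment needs at least two spectra")
    per_spec = [_prominent_apexes(s, top_n) for s in spectra]
    pooled = np.sort(np.concatenate([a for a in per_spec if len(a)]))
    if len(pooled) == 0:
        raise SpectrumError("no prominent peaks found in any spectrum")
    clusters: list[list[float]] = [[pooled[0]]]
    for m in pooled[1:]:
        center = np.median(clusters[-1])
        if (m - center) / center * 1e6 > match_ppm:
            clusters.append([m])
        else:
            clusters[-1].append(m)
    refs = np.array(
        [np.median(c) for c in clusters if len(c) >= min_presence * len(spectra)]
    )
    if len(refs) < 2:
        raise SpectrumError("fewer than two shared prominent peaks across spectra")

    aligned, flagged = [], []
    for s, apexes in zip(spectra, per_spec):
        obs, tgt = [], []
        for r in refs:
            tol = r * match_ppm * 1e-6
            cand = apexes[(apexes >= r - tol) & (apexes <= r + tol)]
            if len(cand):
                obs.append(cand[np.argmin(np.abs(cand - r))])
                tgt.append(r)
        if len(obs) < 2:
            flagged.append(s.replicate_id())
            aligned.append(s.with_arrays(step="align_skipped"))
            continue
        slope, intercept = np.polyfit(np.asarray(obs), np.asarray(tgt), 1)
        aligned.append(s.with_arrays(mz=slope * s.mz + intercept, step="align"))
    return aligned, {"references": refs.tolist(), "unaligned": flagged}


def tic_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities so the total ion current sums to exactly one."""
    total = float(s.intensity.sum())
    if total <= 0:
        raise SpectrumError("cannot TIC-normalize an all-zero spectrum")
    return s.with_arrays(intensity=s.intensity / total, step="tic")


@dataclass
class PreprocessConfig:
    """Parameters of the full processing chain (all config-exposed)."""

    tophat_half_window: int = 75
    sg_window: int = 21
    sg_order: int = 3
    align_top_n: int = 10
    align_match_ppm: float = 2000.0
    lockmass: LockMassConfig = field(default_factory=LockMassConfig)
    use_lockmass: bool = True
    use_alignment: bool = True


def preprocess_chain(
    spectra: list[Spectrum], cfg: PreprocessConfig | None = None
) -> list[Spectrum]:
    """Apply the full chain: sqrt -> TopHat -> Savitzky-Golay -> alignment ->
    lock mass -> TIC normalization.

    External calibration is not part of this batch chain because it requires
    a dedicated calibrant-mixture spectrum; apply
    :func:`external_calibrate` beforehand when one is available.
    """
    cfg = cfg or PreprocessConfig()
    out = []
    for s in spectra:
        s = sqrt_transform(s)
        _, s = tophat_baseline(s, cfg.tophat_half_window)
        s = savitzky_golay(s, cfg.sg_window, cfg.sg_order)
        out.append(s)
    if cfg.use_alignment and len(out) >= 2:
        out, _ = align_prominent_peaks(out, cfg.align_top_n, cfg.align_match_ppm)
    if cfg.use_lockmass:
        out = [lockmass_recalibrate(s, cfg.lockmass) for s in out]
    return [tic_normalize(s) for s in out]
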