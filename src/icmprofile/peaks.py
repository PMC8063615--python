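"""Peak detection, cross-spectrum binning, replicate QC and precision metrics.

Peaks are strict local maxima whose intensity clears a signal-to-noise
threshold, with the noise scale estimated robustly per spectrum by the median
absolute deviation (MAD).  Detected peaks from many spectra are pooled into a
samples x m/z-bins feature matrix; technical replicates are filtered by
pairwise Pearson correlation over bins, merged by averaging, and intra-/
inter-assay precision is summarized as percent coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .core import FeatureMatrix, PipelineError, QCReport, Spectrum, SpectrumError

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma for Gaussian noise


@dataclass(frozen=True)
class Peak:
    """A detected peak: apex m/z (Da), intensity and signal-to-noise ratio."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.snr < 0:
            raise PipelineError("peak intensity and SNR must be >= 0")


def local_maximum_indices(intensity: np.ndarray, half_window: int = 20) -> np.ndarray:
    """Indices of strict local maxima within +/- half_window points.

    A point qualifies only if it is strictly greater than every other point
    of its window (plateau tops are not peaks); windows are truncated at the
    edges.
    """
    x = np.asarray(intensity, dtype=float)
    size = 2 * half_window + 1
    wmax = maximum_filter1d(x, size=size, mode="nearest")
    candidates = np.flatnonzero(x == wmax)
    keep = []
    n = len(x)
    for i in candidates:
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        window = x[lo:hi]
        if np.count_nonzero(window == x[i]) == 1:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def estimate_noise_mad(s: Spectrum) -> float:
    """Robust per-spectrum noise scale: 1.4826 x MAD of the intensities."""
    if len(s) < 3:
        raise SpectrumError("noise estimation needs at least three points")
    med = np.median(s.intensity)
    return float(MAD_SCALE * np.median(np.abs(s.intensity - med)))


def detect_peaks(
    s: Spectrum, snr_min: float = 2.0, half_window: int = 20
) -> list[Peak]:
    """Detect strict local maxima with signal-to-noise >= ``snr_min``.

    Noise is the MAD estimate of the (baseline-corrected) spectrum.  Returned
    peaks are sorted by m/z.
    """
    if snr_min <= 0:
        raise PipelineError("snr_min must be > 0")
    noise = estimate_noise_mad(s)
    idx = local_maximum_indices(s.intensity, half_window=half_window)
    peaks = []
    for i in idx:
        inten = float(s.intensity[i])
        snr = inten / noise if noise > 0 else np.inf
        if inten > 0 and snr >= snr_min:
            peaks.append(Peak(mz=float(s.mz[i]), intensity=inten, snr=float(snr)))
    return peaks


def bin_peaks(
    peaklists: list[list[Peak]],
    tolerance_ppm: float = 500.0,
    metas: list[dict] | None = None,
) -> FeatureMatrix:
    """Cluster peaks across spectra into m/z bins and tabulate intensities.

    Pooled peaks are sorted by m/z and greedily clustered: a new bin starts
    whenever the gap to the current bin's intensity-weighted mean m/z exceeds
    ``tolerance_ppm``.  Matrix entries are peak intensities (the most intense
    peak if a spectrum contributes several to one bin) and 0 where a spectrum
    has no peak in a bin; the bin representative is the intensity-weighted
    mean m/z.
    """
    if tolerance_ppm <= 0:
        raise PipelineError("tolerance_ppm must be > 0")
    if len(peaklists) == 0:
        raise PipelineError("at least one peak list is required")
    if metas is not None and len(metas) != len(peaklists):
        raise PipelineError("one metadata record per peak list required")

    pooled = [
        (p.mz, p.intensity, spec_i)
        for spec_i, plist in enumerate(peaklists)
        for p in plist
    ]
    pooled.sort(key=lambda t: t[0])

    bin_members: list[list[tuple[float, float, int]]] = []
    wsum = msum = 0.0
    for mz, inten, spec_i in pooled:
        weight = inten if inten > 0 else 1e-12
        if bin_members:
            center = msum / wsum
            if (mz - center) / center * 1e6 > tolerance_ppm:
                bin_members.append([])
                wsum = msum = 0.0
        else:
            bin_members.append([])
        bin_members[-1].append((mz, inten, spec_i))
        wsum += weight
        msum += weight * mz
    if not bin_members:
        bin_members = []

    reps, columns = [], []
    n_spec = len(peaklists)
    values = np.zeros((n_spec, len(bin_members)))
    for b, members in enumerate(bin_members):
        weights = np.array([max(i, 1e-12) for _, i, _ in members])
        mzs = np.array([m for m, _, _ in members])
        reps.append(float(np.sum(weights * mzs) / np.sum(weights)))
        for m, inten, spec_i in members:
            values[spec_i, b] = max(values[spec_i, b], inten)
    order = np.argsort(reps)
    reps = np.asarray(reps)[order]
    values = values[:, order]
    columns = [f"{r:.10g}" for r in reps]

    if metas is None:
        metas = [{} for _ in peaklists]
    rows = []
    for i, meta in enumerate(metas):
        rows.append(
            {
                "animal": meta.get("animal", f"spec{i}"),
                "group": meta.get("group", "unknown"),
                "ejaculate": meta.get("ejaculate", 0),
                "spot": meta.get("spot", 0),
                "acquisition": meta.get("acquisition", 0),
            }
        )
    meta_df = pd.DataFrame(rows)
    index = pd.Index(
        [
            f"{r['animal']}.e{r['ejaculate']}.s{r['spot']}.a{r['acquisition']}"
            for r in rows
        ],
        name="sample",
    )
    meta_df.index = index
    frame = pd.DataFrame(values, index=index, columns=columns)
    return FeatureMatrix(values=frame, bins=reps, meta=meta_df)


def feature_matrix_from_spectra(
    spectra: list[Spectrum],
    snr_min: float = 2.0,
    half_window: int = 20,
    tolerance_ppm: float = 500.0,
) -> FeatureMatrix:
    """Detect peaks in each spectrum and bin them into a feature matrix."""
    peaklists = [detect_peaks(s, snr_min=snr_min, half_window=half_window) for s in spectra]
    return bin_peaks(peaklists, tolerance_ppm=tolerance_ppm, metas=[s.meta for s in spectra])


def _sample_key(meta: pd.DataFrame) -> pd.Series:
    return meta["animal"].astype(str) + ".e" + meta["ejaculate"].astype(str)


def filter_replicates_by_correlation(
    m: FeatureMatrix,
    threshold_min: float = 0.40,
    threshold_max: float = 0.90,
    step: float = 0.05,
    min_keep_fraction: float = 0.5,
    aggregate: str = "median",
) -> tuple[FeatureMatrix, QCReport]:
    """Discard technical replicates poorly correlated with their sample mates.

    Within each sample (animal x ejaculate), Pearson correlations are
    computed pairwise between replicate bin vectors.  Candidate thresholds
    run from ``threshold_min`` to ``threshold_max`` in ``step`` increments; a
    replicate survives threshold tau when its median (or mean) correlation
    with same-sample replicates is >= tau.  The selected tau is the largest
    for which at least ``min_keep_fraction`` of all replicates survive and
    every sample retains at least one replicate.
    """
    if aggregate not in ("median", "mean"):
        raise PipelineError("aggregate must be 'median' or 'mean'")
    samples = _sample_key(m.meta)
    agg_fn = np.median if aggregate == "median" else np.mean

    scores = pd.Series(index=m.values.index, dtype=float)
    for _, idx in m.values.groupby(samples).groups.items():
        if len(idx) < 2:
            raise PipelineError(
                f"sample of replicate {idx[0]} has fewer than two technical replicates"
            )
        block = m.values.loc[idx].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(block)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, np.nan)
        scores.loc[idx] = [agg_fn(row[~np.isnan(row)]) for row in corr]

    thresholds = np.round(
        np.arange(threshold_min, threshold_max + step / 2, step), 10
    )
    chosen = None
    for tau in thresholds[::-1]:
        retained = scores >= tau
        per_sample_ok = retained.groupby(samples).any().all()
        if retained.mean() >= min_keep_fraction and per_sample_ok:
            chosen = float(tau)
            break
    if chosen is None:
        retained = scores >= thresholds[0]
        dead = retained.groupby(samples).any()
        bad = sorted(dead.index[~dead]) or ["<global fraction below min_keep_fraction>"]
        raise PipelineError(
            f"all replicates discarded at minimum threshold {thresholds[0]:.2f} "
            f"for sample(s): {bad}"
        )
    retained = scores >= chosen
    report = QCReport(
        threshold=chosen,
        retained=retained,
        correlations=pd.DataFrame({"score": scores, "retained": retained}),
    )
    return m.subset_rows(retained.to_numpy()), report


def merge_replicates(m: FeatureMatrix, level: str = "sample") -> FeatureMatrix:
    """Average replicate rows into per-sample or per-animal rows.

    ``level='sample'`` collapses technical replicates (spot x acquisition)
    into one row per animal x ejaculate ("total average spectrum for each
    sample"); ``level='animal'`` collapses ejaculate rows into one row per
    animal.
    """
    if level not in ("sample", "animal"):
        raise PipelineError("level must be 'sample' or 'animal'")
    if m.n_samples == 0:
        raise PipelineError("cannot merge an empty matrix")
    if level == "sample":
        keys = _sample_key(m.meta)
        keep = ["animal", "group", "ejaculate"]
    else:
        keys = m.meta["animal"].astype(str)
        keep = ["animal", "group"]
    grouped = m.values.groupby(keys, sort=True).mean()
    meta = m.meta.groupby(keys, sort=True).first()[keep]
    for col in ("ejaculate", "spot", "acquisition"):
        if col not in meta:
            meta[col] = -1
    meta["spot"] = -1
    meta["acquisition"] = -1
    grouped.index.name = "sample"
    meta.index.name = "sample"
    return FeatureMatrix(values=grouped, bins=m.bins.copy(), meta=meta)


def compute_cv(m: FeatureMatrix, level: str = "intra") -> QCReport:
    """Percent coefficient of variation per bin.

    ``level='intra'``: CV across technical replicates within each ejaculate,
    averaged over ejaculates.  ``level='inter'``: per-ejaculate means are
    computed first, then CV across ejaculates within each animal, averaged
    over animals.  CV% = 100 x sample SD / mean; bins whose mean is zero in a
    unit are excluded there and reported.
    """
    if level == "intra":
        values, meta = m.values, m.meta
        keys = _sample_key(meta)
    elif level == "inter":
        merged = merge_replicates(m, level="sample")
        values, meta = merged.values, merged.meta
        keys = meta["animal"].astype(str)
    else:
        raise PipelineError("level must be 'intra' or 'inter'")

    per_unit = []
    n_excluded = 0
    for _, idx in values.groupby(keys).groups.items():
        block = values.loc[idx]
        if len(block) < 2:
            raise PipelineError("CV needs >= 2 observations per unit")
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        cv = 100.0 * sd / mean
        n_excluded += int((mean == 0).sum())
        per_unit.append(cv.where(mean > 0))
    cv_per_bin = pd.concat(per_unit, axis=1).mean(axis=1)
    excluded = cv_per_bin.index[cv_per_bin.isna()].tolist()
    return QCReport(
        cv_per_bin=cv_per_bin,
        cv_mean=float(cv_per_bin.mean(skipna=True)),
        excluded_bins=excluded,
        notes=[f"{n_excluded} unit-level zero-mean bins excluded"],
    )
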