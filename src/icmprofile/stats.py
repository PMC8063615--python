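"""Differential abundance statistics and the fertility/semen phenotype layer.

The intact-cell branch compares fertile (F) and subfertile (SF) groups per
m/z bin with a two-sided Mann-Whitney test and gates candidate peaks on
p < 0.05 together with a fold change (F/SF group-mean ratio) <= 0.66 or
>= 1.5; PCA and volcano coordinates support the descriptive views.  No
multiple-testing correction is applied by default (per-feature p-values are
reported as-is); a Benjamini-Hochberg adjustment is available but off by
default.

Phenotype operations classify animals by fertility rate (> 70% fertile,
< 40% subfertile, in between excluded), classify sperm motility from CASA
velocities, and compare semen parameters between groups with Mann-Whitney
tests at p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FeatureMatrix, PipelineError

P_CUT = 0.05
FC_LOW = 0.66
FC_HIGH = 1.5

#: exact Mann-Whitney enumeration is used up to this group size (no ties)
EXACT_N_MAX = 12


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney p-value for a location difference.

    Exact by enumeration of the rank-sum null distribution when both groups
    have <= 12 observations and the pooled data are tie-free; otherwise the
    mid-rank, tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise PipelineError("Mann-Whitney needs at least two values per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) <= EXACT_N_MAX and len(y) <= EXACT_N_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):  # fully tied data under the asymptotic path
        return 1.0
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fold_change(x, y) -> float:
    """Group-mean ratio mean(x)/mean(y) with the table conventions:
    0/positive -> 0.0, positive/0 -> +inf, 0/0 -> 1.0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise PipelineError("fold change expects non-negative abundances")
    mx, my = float(np.mean(x)), float(np.mean(y))
    if my == 0.0:
        return 1.0 if mx == 0.0 else float("inf")
    return mx / my


@dataclass(frozen=True)
class DifferentialPeakResult:
    bin_mz: float
    p: float
    fc: float
    label: str  # ns | significant | significant_fc


def classify_result(
    p: float, fc: float, p_cut: float = P_CUT, fc_low: float = FC_LOW, fc_high: float = FC_HIGH
) -> str:
    if p < p_cut and (fc <= fc_low or fc >= fc_high):
        return "significant_fc"
    if p < p_cut:
        return "significant"
    return "ns"


def differential_peaks(
    m: FeatureMatrix,
    p_cut: float = P_CUT,
    fc_low: float = FC_LOW,
    fc_high: float = FC_HIGH,
    bh_correct: bool = False,
) -> list[DifferentialPeakResult]:
    """Per-bin Mann-Whitney + fold-change gates on a per-animal matrix.

    Rows must carry F/SF group labels; fold change is F over SF.
    """
    groups = m.groups()
    f_mask = (groups == "F").to_numpy()
    sf_mask = (groups == "SF").to_numpy()
    if f_mask.sum() < 2 or sf_mask.sum() < 2:
        raise PipelineError("differential testing needs >= 2 animals per group")
    values = m.values.to_numpy()
    ps, fcs = [], []
    for j in range(values.shape[1]):
        x = values[f_mask, j]
        y = values[sf_mask, j]
        ps.append(mann_whitney(x, y))
        fcs.append(fold_change(x, y))
    ps = np.asarray(ps)
    if bh_correct and len(ps):
        order = np.argsort(ps)
        ranked = ps[order] * len(ps) / (np.arange(len(ps)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(ps)
        out[order] = np.minimum(adj, 1.0)
        ps = out
    return [
        DifferentialPeakResult(
            bin_mz=float(b), p=float(p), fc=float(fc),
            label=classify_result(p, fc, p_cut, fc_low, fc_high),
        )
        for b, p, fc in zip(m.bins, ps, fcs)
    ]


def volcano_classify(results: list[DifferentialPeakResult]) -> pd.DataFrame:
    """Volcano-plot coordinates (log2 FC, -log10 p) and class labels."""
    with np.errstate(divide="ignore"):
        frame = pd.DataFrame(
            {
                "bin_mz": [r.bin_mz for r in results],
                "p": [r.p for r in results],
                "fc": [r.fc for r in results],
                "log2_fc": [np.log2(r.fc) if r.fc > 0 else -np.inf for r in results],
                "neg_log10_p": [-np.log10(r.p) for r in results],
                "label": [r.label for r in results],
            }
        )
    return frame


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_pct: np.ndarray  # per component, descending


def pca(m: FeatureMatrix, scale: str = "center") -> PCAResult:
    """Principal component analysis by SVD of the centered matrix.

    ``scale='center'`` (default) centers columns; ``'standardize'`` also
    divides by the column SD.  Components are indexed from 1 and signed so
    the largest-magnitude loading of each component is positive.
    """
    if scale not in ("center", "standardize"):
        raise PipelineError("scale must be 'center' or 'standardize'")
    X = m.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise PipelineError("PCA needs at least 2 samples and 2 features")
    X = X - X.mean(axis=0, keepdims=True)
    if scale == "standardize":
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    total_var = float((X**2).sum())
    if total_var == 0:
        raise PipelineError("zero-variance matrix")
    u, sv, vt = np.linalg.svd(X, full_matrices=False)
    k = len(sv)
    for c in range(k):  # sign convention: dominant loading positive
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * sv, index=m.values.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=m.values.columns, columns=comp)
    variance_pct = 100.0 * sv**2 / (sv**2).sum()
    return PCAResult(scores=scores, loadings=loadings, variance_pct=variance_pct)


# --------------------------------------------------------------------------
# phenotype layer

FR_FERTILE = 70.0
FR_SUBFERTILE = 40.0
VAP_MOTILE = 5.0
VAP_RAPID = 50.0


def classify_fertility(fr: float) -> str:
    """Fertility-rate classification: > 70% fertile, < 40% subfertile,
    otherwise intermediate (excluded from group comparisons)."""
    if not (0.0 <= fr <= 100.0):
        raise PipelineError(f"fertility rate {fr!r} outside [0, 100]")
    if fr > FR_FERTILE:
        return "fertile"
    if fr < FR_SUBFERTILE:
        return "subfertile"
    return "intermediate"


def classify_motility(vap: float, vsl: float = 0.0) -> dict:
    """CASA motility flags from the average-path velocity (strict thresholds).

    The progressive flag follows the printed VAP > 50 um/s rule, which
    duplicates the rapid class; this redundancy is flagged in the output so
    downstream users can substitute a straightness-based rule.
    """
    if vap < 0 or vsl < 0:
        raise PipelineError("velocities must be >= 0")
    motile = vap > VAP_MOTILE
    rapid = vap > VAP_RAPID
    return {
        "motile": motile,
        "rapid": rapid,
        "progressive": rapid,
        "progressive_rule": "vap>50 (duplicates 'rapid'; likely a reporting slip)",
    }


def compare_phenotypes(
    table: pd.DataFrame, group_col: str = "group", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-parameter Mann-Whitney comparison between F and SF animals.

    Returns one row per numeric phenotype with group means, the two-sided
    p-value and a significance flag at ``alpha``; constant parameters get
    p = 1 and a note.  No multiplicity correction is applied.
    """
    groups = table[group_col]
    f = table[groups == "F"]
    sf = table[groups == "SF"]
    if len(f) < 2 or len(sf) < 2:
        raise PipelineError("phenotype comparison needs >= 2 animals per group")
    rows = []
    for col in table.columns:
        if col in (group_col, "animal") or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        x = f[col].to_numpy(dtype=float)
        y = sf[col].to_numpy(dtype=float)
        constant = np.all(np.concatenate([x, y]) == x[0])
        p = 1.0 if constant else mann_whitney(x, y)
        rows.append(
            {
                "parameter": col,
                "mean_F": float(np.mean(x)),
                "mean_SF": float(np.mean(y)),
                "p": p,
                "significant": bool(p <= alpha) and not constant,
                "note": "constant across animals" if constant else "",
            }
        )
    return pd.DataFrame(rows)
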