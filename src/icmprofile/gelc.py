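"""Label-free GeLC-MS/MS differential quantification rules.

Consumes already-quantified protein-cluster tables (weighted spectral counts
and average precursor intensities per technical replicate) and applies the
decision rules of the bottom-up branch:

* spectral counting (SC): replicate columns are normalized so every column
  total equals the across-replicate mean total ("normalized weighted
  spectra", NWS); per-animal values are the means over technical replicates;
* average precursor intensity (API): per-animal means of the intensity
  columns (optionally column-normalized the same way);
* a two-sided t-test (Welch by default) per protein on per-animal values; a
  protein is differentially abundant (DAP) when p < 0.05, the F/SF fold
  change is <= 0.71 or >= 1.4 and — for SC only — the larger group-mean NWS
  is >= 5;
* one annotated significant member (gene symbol present, LOC-style entries
  excluded when alternatives exist) is drawn per cluster to represent it;
  when the representative is significant under both methods the SC
  statistics are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PipelineError, QuantTable
from .stats import fold_change

GELC_P_CUT = 0.05
GELC_FC_LOW = 0.71
GELC_FC_HIGH = 1.4
NWS_FLOOR = 5.0


def nws_normalize(q: QuantTable) -> QuantTable:
    """Scale each replicate's weighted counts to the mean column total.

    After normalization every column sums to the across-replicate mean of
    the original totals, preserving within-column proportions.
    """
    totals = q.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise PipelineError(f"replicate column(s) with zero total count: {bad}")
    target = float(totals.mean())
    scaled = q.counts * (target / totals)
    return QuantTable(
        proteins=q.proteins.copy(),
        counts=scaled,
        intensities=q.intensities.copy(),
        groups=q.groups.copy(),
    )


def _ttest(x: np.ndarray, y: np.ndarray, welch: bool = True) -> tuple[float, bool]:
    """Two-sided t-test p-value; degenerate (all-identical) data -> p=1, flagged."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]) or (np.ptp(x) == 0 and np.ptp(y) == 0):
        return 1.0, True
    res = sps.ttest_ind(x, y, equal_var=not welch)
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 1.0, True
    return p, False


def gelc_differential(
    q: QuantTable,
    method: str = "SC",
    p_cut: float = GELC_P_CUT,
    fc_low: float = GELC_FC_LOW,
    fc_high: float = GELC_FC_HIGH,
    nws_floor: float = NWS_FLOOR,
    welch: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-protein differential test under SC (counts) or API (intensities).

    Returns one row per member protein with per-animal group means, p, the
    F/SF fold change, individual pass flags and the overall DAP call.
    """
    if method not in ("SC", "API"):
        raise PipelineError("method must be 'SC' or 'API'")
    if method == "SC" and normalize:
        q = nws_normalize(q)
    per_animal = q.per_animal_means("counts" if method == "SC" else "intensities")
    groups = q.groups
    f_animals = [a for a in per_animal.columns if groups[a] == "F"]
    sf_animals = [a for a in per_animal.columns if groups[a] == "SF"]
    if len(f_animals) < 2 or len(sf_animals) < 2:
        raise PipelineError("gelc_differential needs >= 2 animals per group")

    rows = []
    for acc, vals in per_animal.iterrows():
        x = vals[f_animals].to_numpy(dtype=float)
        y = vals[sf_animals].to_numpy(dtype=float)
        p, degenerate = _ttest(x, y, welch=welch)
        fc = fold_change(x, y)
        pass_p = p < p_cut
        pass_fc = fc <= fc_low or fc >= fc_high
        pass_nws = max(np.mean(x), np.mean(y)) >= nws_floor if method == "SC" else True
        rows.append(
            {
                "accession": acc,
                "cluster": q.proteins.loc[acc, "cluster"],
                "gene": q.proteins.loc[acc, "gene"],
                "description": q.proteins.loc[acc, "description"],
                "method": method,
                "mean_F": float(np.mean(x)),
                "mean_SF": float(np.mean(y)),
                "p": p,
                "fc": fc,
                "pass_p": pass_p,
                "pass_fc": pass_fc,
                "pass_nws": pass_nws,
                "degenerate": degenerate,
                "is_dap": bool(pass_p and pass_fc and pass_nws),
            }
        )
    return pd.DataFrame(rows).set_index("accession")


def _is_loc_like(gene: str) -> bool:
    gene = (gene or "").strip()
    return gene == "" or gene.upper().startswith("LOC")


@dataclass
class ClusterRepresentative:
    cluster: str
    accession: str
    gene: str
    method: str
    p: float
    fc: float
    in_unique_gene_list: bool


def select_representatives(
    sc_results: pd.DataFrame,
    api_results: pd.DataFrame,
    seed: int = 0,
) -> list[ClusterRepresentative]:
    """Pick one significant member protein to represent each cluster.

    Candidates are the cluster members significant under at least one
    method; members with a proper gene symbol and a description are
    preferred (LOC-style/unannotated members are used only when no
    alternative exists, and such clusters are excluded from the unique-gene
    list).  One candidate is drawn uniformly with the seeded generator; if
    the chosen member is significant under both methods its SC statistics
    are reported.
    """
    rng = np.random.default_rng(seed)
    sc_dap = sc_results[sc_results["is_dap"]]
    api_dap = api_results[api_results["is_dap"]]
    significant = sorted(set(sc_dap.index) | set(api_dap.index))
    by_cluster: dict[str, list[str]] = {}
    for acc in significant:
        cluster = str(
            (sc_results if acc in sc_results.index else api_results).loc[acc, "cluster"]
        )
        by_cluster.setdefault(cluster, []).append(acc)

    reps = []
    for cluster in sorted(by_cluster, key=str):
        members = sorted(by_cluster[cluster])
        annotated = [
            a
            for a in members
            if not _is_loc_like(str(sc_results.loc[a, "gene"]))
            and str(sc_results.loc[a, "description"]).strip() not in ("", "nan")
        ]
        pool = annotated if annotated else members
        choice = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
        in_sc = choice in sc_dap.index
        in_api = choice in api_dap.index
        source = sc_results if (in_sc or (in_sc and in_api)) else api_results
        method = "SC" if in_sc else "API"
        reps.append(
            ClusterRepresentative(
                cluster=cluster,
                accession=choice,
                gene=str(source.loc[choice, "gene"]),
                method=method,
                p=float(source.loc[choice, "p"]),
                fc=float(source.loc[choice, "fc"]),
                in_unique_gene_list=bool(annotated),
            )
        )
    return reps


def dap_summary(sc_results: pd.DataFrame, api_results: pd.DataFrame) -> dict:
    """Counts of DAP clusters under SC, API, both, and in total."""
    sc = set(sc_results.index[sc_results["is_dap"]])
    api = set(api_results.index[api_results["is_dap"]])
    return {
        "n_dap_sc": len(sc),
        "n_dap_api": len(api),
        "n_dap_shared": len(sc & api),
        "n_dap_total": len(sc | api),
    }
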