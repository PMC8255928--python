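"""FPKM computation, sample-level QC and differential-expression calling.

DE thresholds follow the source study's screen: fold change >= 2 (in
either direction) and p < 0.05. The per-gene test is a Welch t on
log2(FPKM + 1); a count-model dispersion fit is out of scope and the test
is an argument so it can be swapped. All QC (sample correlation, PCA,
hierarchical clustering) operates on log2(FPKM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

PSEUDOCOUNT = 1.0  # FPKM added before ratios and logs


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p: float
    direction: str  # up / down / ns
    mean_case: float
    mean_control: float


def fpkm(fragments: float, exonic_length: int, total_mapped: int) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if exonic_length <= 0 or total_mapped <= 0:
        raise ValueError("exonic_length and total_mapped must be positive")
    return fragments * 1e9 / (exonic_length * total_mapped)


def de_test(
    mat: ExpressionMatrix,
    alpha: float = 0.05,
    fc: float = 2.0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch t on log2(x+1) with a two-sided fold-change screen.

    Fold change is (mean_case + 1) / (mean_control + 1) on the raw scale;
    a gene is ``up`` when the ratio >= fc with p < alpha and case above
    control, ``down`` symmetric (ratio <= 1/fc), else ``ns``. With
    ``adjust=True`` the screen uses Benjamini-Hochberg adjusted p-values.
    """
    case = mat.samples_in("case")
    ctrl = mat.samples_in("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group")
    logx = mat.log2p1()
    a = logx[case].to_numpy()
    b = logx[ctrl].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    mean_case = mat.values[case].mean(axis=1).to_numpy()
    mean_ctrl = mat.values[ctrl].mean(axis=1).to_numpy()
    ratio = (mean_case + PSEUDOCOUNT) / (mean_ctrl + PSEUDOCOUNT)
    log2fc_vals = np.log2(ratio)
    # zero variance in both groups: identical values -> p=1; exact shift -> p=0
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    p_screen = stats.false_discovery_control(p, method="bh") if adjust else p
    direction = np.full(len(p), "ns", dtype=object)
    passed = p_screen < alpha
    direction[passed & (ratio >= fc)] = "up"
    direction[passed & (ratio <= 1.0 / fc)] = "down"
    return pd.DataFrame(
        {
            "gene_id": mat.gene_ids,
            "log2fc": log2fc_vals,
            "p": p,
            "p_adj": p_screen if adjust else p,
            "direction": direction,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
        }
    ).set_index("gene_id", drop=False)


def de_gene_ids(de_table: pd.DataFrame) -> list[str]:
    return list(de_table.loc[de_table["direction"] != "ns", "gene_id"])


def sample_correlation(mat: ExpressionMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlation of log2(x+1) across genes."""
    logx = mat.log2p1()
    if logx.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    r = np.corrcoef(logx.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=mat.sample_ids, columns=mat.sample_ids)


def pca_scores(mat: ExpressionMatrix, k: int = 2) -> pd.DataFrame:
    """Sample scores of the first k principal components.

    SVD of the gene-centered log2(x+1) matrix; components ordered by
    decreasing singular value. Sign convention: within each component the
    largest-magnitude gene loading is made positive, so scores are
    deterministic.
    """
    logx = mat.log2p1().to_numpy()
    n_genes, n_samples = logx.shape
    if k > min(n_genes, n_samples):
        raise ValueError("k exceeds matrix rank bound")
    centered = logx - logx.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for j in range(len(s)):
        i_max = np.argmax(np.abs(u[:, j]))
        if u[i_max, j] < 0:
            u[:, j] *= -1.0
            vt[j, :] *= -1.0
    scores = (vt[:k, :].T * s[:k])
    return pd.DataFrame(
        scores, index=mat.sample_ids, columns=[f"PC{j+1}" for j in range(k)]
    )


def hclust_average(items: pd.DataFrame) -> np.ndarray:
    """Average-linkage agglomeration on 1 - Pearson r distance.

    ``items``: observations in columns (e.g. samples) over features in
    rows. Returns the scipy linkage matrix; merge heights are
    non-decreasing and ties resolve deterministically by the condensed
    distance order (smallest indices first).
    """
    if items.shape[1] < 2:
        raise ValueError("need >= 2 items")
    r = np.corrcoef(items.to_numpy(), rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return linkage(squareform(d, checks=False), method="average")


__all__ = [
    "DEResult",
    "PSEUDOCOUNT",
    "de_gene_ids",
    "de_test",
    "fpkm",
    "hclust_average",
    "pca_scores",
    "sample_correlation",
]
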