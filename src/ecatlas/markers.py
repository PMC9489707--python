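"""Per-cluster marker discovery by pairwise differential expression with
rank-product combination, plus condition (tumor vs peri-tumoral) DE.

Every cluster is compared against every other cluster separately; genes are
ranked within each pairwise comparison by log2 fold change (rank 1 = most
upregulated) and the per-pair ranks are combined multiplicatively. The
combined score is the sum of log ranks, which orders genes identically to
the rank product while staying in floating-point range.

The per-gene test is an ordinary two-sample linear-model t (optionally with
the patient as an additive covariate); moderated-variance shrinkage is
deliberately not applied — the rank-product combination across all pairwise
contrasts, not the per-pair p-value, drives the marker ordering, and the
choice is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

_LFC_EPS = 1e-9


@dataclass
class PairwiseDEResult:
    """DE of ``target`` vs ``reference`` cluster.

    ``log2fc`` is the log2 ratio of depth-normalized mean expression
    (target over reference, pseudocount 1e-9), so a planted k-fold marker
    recovers log2(k) without the low-count compression a difference of
    log1p means would introduce; the ratio form keeps exact antisymmetry
    under pair swap.
    """

    target: object
    reference: object
    table: pd.DataFrame  # index gene; columns log2fc, p_value, adj_p
    test: str = "two-sample linear-model t (no moderation)"


@dataclass
class MarkerTable:
    """Per-cluster rank-product marker ranking."""

    tables: dict = field(default_factory=dict)  # cluster -> DataFrame

    def top_n(self, cluster, n: int) -> list[str]:
        tab = self.tables[cluster]
        return list(tab.sort_values("final_rank").index[:n])


def _dense(nm: ad.AnnData) -> np.ndarray:
    return nm.X.toarray() if sparse.issparse(nm.X) else np.asarray(nm.X)


def _linear_means(nm: ad.AnnData, mask: np.ndarray) -> np.ndarray:
    """Mean depth-normalized (linear-scale) expression over masked cells."""
    return np.expm1(_dense(nm)[mask]).mean(axis=0)


def _group_t_test(
    Y: np.ndarray, group: np.ndarray, covariate: np.ndarray | None
) -> np.ndarray:
    """Vectorized per-gene t-test of the group coefficient in an OLS fit.

    Without a covariate this is exactly the equal-variance two-sample t.
    With one, the covariate enters as additive dummy columns.
    """
    n = Y.shape[0]
    cols = [np.ones(n), group.astype(float)]
    if covariate is not None:
        levels = pd.unique(covariate)
        for lv in levels[1:]:  # first level absorbed by the intercept
            cols.append((covariate == lv).astype(float))
    X = np.column_stack(cols)
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    if df <= 0:
        return np.ones(Y.shape[1])
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
    t = beta[1] / se
    return 2.0 * stats.t.sf(np.abs(t), df)


def pairwise_de(
    nm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    covariate: str | None = None,
    min_cells: int = 3,
) -> list[PairwiseDEResult]:
    """DE for every ordered cluster pair; BH adjustment within each pair.

    Clusters with fewer than ``min_cells`` cells are excluded with a warning.
    ``covariate`` names an ``obs`` column (e.g. ``"patient"``) used as an
    additive covariate in the per-gene linear model.
    """
    labels = np.asarray(labels)
    clusters = [c for c in pd.unique(labels)]
    sizes = {c: int((labels == c).sum()) for c in clusters}
    small = [c for c in clusters if sizes[c] < min_cells]
    if small:
        import warnings

        warnings.warn(f"excluding clusters with <{min_cells} cells: {small}")
        clusters = [c for c in clusters if c not in small]
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters with enough cells")

    logY = _dense(nm)
    linY = np.expm1(logY)
    cov_all = nm.obs[covariate].to_numpy() if covariate else None

    results = []
    lin_means = {c: linY[labels == c].mean(axis=0) for c in clusters}
    for tgt in clusters:
        for ref in clusters:
            if tgt == ref:
                continue
            mask = (labels == tgt) | (labels == ref)
            p = _group_t_test(
                logY[mask],
                (labels[mask] == tgt),
                cov_all[mask] if cov_all is not None else None,
            )
            lfc = np.log2(lin_means[tgt] + _LFC_EPS) - np.log2(
                lin_means[ref] + _LFC_EPS
            )
            adj = multipletests(p, method="fdr_bh")[1]
            tab = pd.DataFrame(
                {"log2fc": lfc, "p_value": p, "adj_p": adj},
                index=nm.var_names.copy(),
            )
            results.append(PairwiseDEResult(target=tgt, reference=ref, table=tab))
    return results


def rank_by_logfc(pair: PairwiseDEResult) -> pd.Series:
    """Rank genes within one pairwise comparison: rank 1 = largest log2FC;
    ties broken by smaller p-value, then lexicographic gene id."""
    tab = pair.table
    genes = tab.index.to_numpy()
    order = np.lexsort(
        (genes, tab["p_value"].to_numpy(), -tab["log2fc"].to_numpy())
    )
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(1, len(genes) + 1)
    return pd.Series(ranks, index=tab.index, name=f"rank_{pair.target}_vs_{pair.reference}")


def rank_product_markers(pairs: list[PairwiseDEResult]) -> pd.DataFrame:
    """Combine per-pair ranks for one target cluster into a final marker list.

    The combined score is the sum of log ranks over all (target, reference)
    pairs — monotone-equivalent to the rank product. Ties in the combined
    score break by larger mean log2FC, then gene id. ``uniquely_up`` flags
    genes with positive log2FC in every pairwise comparison.
    """
    targets = {p.target for p in pairs}
    if len(targets) != 1:
        raise ValueError("all pairwise results must share one target cluster")
    universes = {tuple(p.table.index) for p in pairs}
    if len(universes) != 1:
        raise ValueError("mismatched gene universes across pairwise results")
    genes = pairs[0].table.index
    rank_mat = np.column_stack([rank_by_logfc(p).to_numpy() for p in pairs])
    lfc_mat = np.column_stack([p.table["log2fc"].to_numpy() for p in pairs])
    score = np.log(rank_mat).sum(axis=1)
    mean_lfc = lfc_mat.mean(axis=1)
    order = np.lexsort((genes.to_numpy(), -mean_lfc, score))
    final = np.empty(len(genes), dtype=int)
    final[order] = np.arange(1, len(genes) + 1)
    return pd.DataFrame(
        {
            "combined_score": score,
            "final_rank": final,
            "mean_log2fc": mean_lfc,
            "uniquely_up": (lfc_mat > 0).all(axis=1),
        },
        index=genes.copy(),
    )


def compute_markers(
    nm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    covariate: str | None = None,
) -> MarkerTable:
    """All pairwise comparisons + rank-product combination for every cluster."""
    pairs = pairwise_de(nm, labels, covariate=covariate)
    mt = MarkerTable()
    for tgt in {p.target for p in pairs}:
        mt.tables[tgt] = rank_product_markers([p for p in pairs if p.target == tgt])
    return mt


def top_n_markers(mt: MarkerTable, n: int) -> dict:
    """The ``n`` best-final-rank genes per cluster."""
    return {c: mt.top_n(c, n) for c in mt.tables}


def condition_de(
    nm: ad.AnnData,
    condition: pd.Series | np.ndarray,
    alpha: float = 0.05,
    positive_condition: str = "peritumor",
) -> pd.DataFrame:
    """Tumor vs peri-tumoral DE with BH control.

    Returns genes with BH-adjusted p < ``alpha``; log2FC is positive when the
    gene is higher in ``positive_condition`` (peritumor-positive convention).
    """
    condition = np.asarray(condition)
    levels = pd.unique(condition)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(levels)}")
    if positive_condition not in levels:
        raise ValueError(f"{positive_condition!r} absent from condition labels")
    other = [lv for lv in levels if lv != positive_condition][0]
    logY = _dense(nm)
    p = _group_t_test(logY, condition == positive_condition, None)
    pos_mean = np.expm1(logY[condition == positive_condition]).mean(axis=0)
    neg_mean = np.expm1(logY[condition == other]).mean(axis=0)
    lfc = np.log2(pos_mean + _LFC_EPS) - np.log2(neg_mean + _LFC_EPS)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": lfc, "p_value": p, "adj_p": adj}, index=nm.var_names.copy()
    )
    out.attrs["sign_convention"] = f"log2fc > 0 means higher in {positive_condition}"
    return out[out["adj_p"] < alpha].sort_values("adj_p")
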