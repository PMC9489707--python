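"""Permutation-based receptor-ligand interaction testing between cluster
pairs, with endothelial-specificity and venous-consensus filters.

A ligand (or receptor) partner counts as expressed in a cluster when each of
its component genes is detected in at least a threshold fraction (default
0.25) of the cluster's cells; multi-subunit partners aggregate by the
minimum over components, for both the expression fraction and the
cluster-level mean. The interaction mean of a (pair, source, target) row is
the average of the ligand-side and receptor-side cluster expressions. The
null distribution comes from shuffling cluster labels over all cells
(default 500 iterations) and the p-value uses the add-one correction
p = (1 + #{null >= observed}) / (iterations + 1), so p is never zero.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .io import read_lr_database
from .markers import PairwiseDEResult


def bundled_lr_database() -> pd.DataFrame:
    """The minimal bundled ligand-receptor pair table (well-known EC-immune
    axes such as GAS6-MERTK/AXL, VEGFA-FLT1/KDR/NRP1, SELE-SELPLG)."""
    with importlib.resources.as_file(
        importlib.resources.files("ecatlas.data") / "lr_pairs.tsv"
    ) as path:
        return read_lr_database(path)


def _components(field_value: str) -> list[str]:
    return [g for g in str(field_value).split("|") if g]


def _parse_db(db: pd.DataFrame, var_names) -> list[dict]:
    """Resolve component gene names to column indices; skip pairs with
    missing genes (warning)."""
    known = {g: i for i, g in enumerate(var_names)}
    parsed = []
    for _, row in db.iterrows():
        lig = _components(row["ligand_components"])
        rec = _components(row["receptor_components"])
        missing = [g for g in lig + rec if g not in known]
        if missing:
            warnings.warn(
                f"pair {row['pair_id']!r} skipped: genes absent from matrix {missing}"
            )
            continue
        parsed.append(
            {
                "pair_id": row["pair_id"],
                "lig_idx": np.array([known[g] for g in lig]),
                "rec_idx": np.array([known[g] for g in rec]),
            }
        )
    return parsed


@dataclass
class InteractionTest:
    """Per (pair, source, target): expression flag, interaction mean, p."""

    table: pd.DataFrame
    iterations: int | None = None
    min_expr_frac: float = 0.25


def _cluster_stats(
    X_log: np.ndarray, detected: np.ndarray, labels: np.ndarray, clusters: list
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster x gene mean log-normalized expression and detection fraction."""
    means = np.empty((len(clusters), X_log.shape[1]))
    fracs = np.empty_like(means)
    for i, c in enumerate(clusters):
        mask = labels == c
        means[i] = X_log[mask].mean(axis=0)
        fracs[i] = detected[mask].mean(axis=0)
    return means, fracs


def interaction_means(
    nm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    db: pd.DataFrame,
    min_expr_frac: float = 0.25,
) -> InteractionTest:
    """Observed interaction means for every ordered cluster pair and LR pair.

    Rows whose ligand or receptor partner fails the expression-fraction
    threshold in its cluster get ``expressed=False`` and no mean.
    """
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels), key=str)
    X_log = nm.X.toarray() if sparse.issparse(nm.X) else np.asarray(nm.X)
    counts = nm.layers.get("counts")
    if counts is not None:
        detected = np.asarray(
            (counts > 0).toarray() if sparse.issparse(counts) else counts > 0
        )
    else:
        detected = X_log > 0
    parsed = _parse_db(db, nm.var_names)
    means, fracs = _cluster_stats(X_log, detected, labels, clusters)

    rows = []
    for p in parsed:
        lig_mean = means[:, p["lig_idx"]].min(axis=1)
        rec_mean = means[:, p["rec_idx"]].min(axis=1)
        lig_expr = fracs[:, p["lig_idx"]].min(axis=1) >= min_expr_frac
        rec_expr = fracs[:, p["rec_idx"]].min(axis=1) >= min_expr_frac
        for si, src in enumerate(clusters):
            for ti, tgt in enumerate(clusters):
                expressed = bool(lig_expr[si] and rec_expr[ti])
                rows.append(
                    {
                        "pair_id": p["pair_id"],
                        "source": src,
                        "target": tgt,
                        "expressed": expressed,
                        "mean": 0.5 * (lig_mean[si] + rec_mean[ti])
                        if expressed
                        else np.nan,
                    }
                )
    return InteractionTest(table=pd.DataFrame(rows), min_expr_frac=min_expr_frac)


def permutation_test(
    nm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    db: pd.DataFrame,
    iterations: int = 500,
    seed: int = 0,
    min_expr_frac: float = 0.25,
) -> InteractionTest:
    """Label-shuffling permutation p-values for all expressed interactions."""
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels), key=str)
    cindex = {c: i for i, c in enumerate(clusters)}
    obs = interaction_means(nm, labels, db, min_expr_frac=min_expr_frac)
    tab = obs.table.copy()
    parsed = _parse_db(db, nm.var_names)
    X_log = nm.X.toarray() if sparse.issparse(nm.X) else np.asarray(nm.X)

    # only genes appearing in some pair need null means
    used = np.unique(np.concatenate([np.r_[p["lig_idx"], p["rec_idx"]] for p in parsed]))
    remap = {g: i for i, g in enumerate(used)}
    Xu = X_log[:, used]
    onehot = np.zeros((len(clusters), len(labels)))
    sizes = np.array([(labels == c).sum() for c in clusters], dtype=float)

    src_i = tab["source"].map(cindex).to_numpy()
    tgt_i = tab["target"].map(cindex).to_numpy()
    pair_lig = {p["pair_id"]: np.array([remap[g] for g in p["lig_idx"]]) for p in parsed}
    pair_rec = {p["pair_id"]: np.array([remap[g] for g in p["rec_idx"]]) for p in parsed}
    lig_cols = tab["pair_id"].map(pair_lig)
    rec_cols = tab["pair_id"].map(pair_rec)

    obs_mean = tab["mean"].to_numpy()
    exceed = np.zeros(len(tab))
    rng = np.random.default_rng(seed)
    perm = np.arange(len(labels))
    for _ in range(iterations):
        rng.shuffle(perm)
        plabels = labels[perm]
        onehot[:] = 0.0
        for i, c in enumerate(clusters):
            onehot[i, plabels == c] = 1.0
        cmeans = (onehot @ Xu) / sizes[:, None]
        lig_null = np.array(
            [cmeans[si, cols].min() for si, cols in zip(src_i, lig_cols)]
        )
        rec_null = np.array(
            [cmeans[ti, cols].min() for ti, cols in zip(tgt_i, rec_cols)]
        )
        null_mean = 0.5 * (lig_null + rec_null)
        exceed += null_mean >= obs_mean
    p = (1.0 + exceed) / (iterations + 1.0)
    tab["p"] = np.where(tab["expressed"], p, np.nan)
    return InteractionTest(table=tab, iterations=iterations, min_expr_frac=min_expr_frac)


def min_pairwise_lfc(pairs: list[PairwiseDEResult]) -> pd.DataFrame:
    """genes x clusters table of each gene's minimum log2FC of a cluster
    against every other cluster (the 'enriched vs all other EC subclusters'
    statistic)."""
    targets = sorted({p.target for p in pairs}, key=str)
    out = {}
    for tgt in targets:
        mats = [p.table["log2fc"] for p in pairs if p.target == tgt]
        out[tgt] = pd.concat(mats, axis=1).min(axis=1)
    return pd.DataFrame(out)


@dataclass
class FilteredInteractions:
    """Interaction rows with exclusion/specificity flags and, when a venous
    subcluster set is supplied, the venous consensus table."""

    table: pd.DataFrame
    venous: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def apply_specificity_filters(
    it: InteractionTest,
    ec_lfc: pd.DataFrame,
    ec_clusters: set,
    cluster_sizes: dict,
    db: pd.DataFrame,
    venous_set: set | None = None,
    min_cells: int = 100,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
) -> FilteredInteractions:
    """Specificity and consensus filtering of permutation-tested interactions.

    Flags are computed independently, so the outcome does not depend on
    application order: EC-self rows (both clusters endothelial) are excluded;
    rows involving any cluster below ``min_cells`` cells are excluded; the
    EC-side genes must be enriched at log2FC >= ``lfc_min`` against all other
    EC subclusters (``ec_lfc`` is the genes x EC-clusters minimum pairwise
    log2FC table from :func:`min_pairwise_lfc`). With a ``venous_set`` of
    exactly 4 venous subclusters, each (LR pair, partner cluster, direction)
    is kept in the venous analysis only when significant in at least 3 of
    the 4 venous subclusters; its reported mean is the average over the 4.
    """
    if venous_set is not None and len(venous_set) != 4:
        raise ValueError("the venous consensus rule is defined for exactly 4 subclusters")
    parsed = {
        row["pair_id"]: (
            _components(row["ligand_components"]),
            _components(row["receptor_components"]),
        )
        for _, row in db.iterrows()
    }
    tab = it.table.copy()
    src_ec = tab["source"].isin(ec_clusters)
    tgt_ec = tab["target"].isin(ec_clusters)
    tab["excluded_self"] = src_ec & tgt_ec
    small = {c for c, n in cluster_sizes.items() if n < min_cells}
    tab["excluded_small_cluster"] = tab["source"].isin(small) | tab["target"].isin(small)

    def ec_side_ok(row) -> bool:
        lig, rec = parsed[row["pair_id"]]
        checks = []
        if row["source"] in ec_clusters:
            checks += [(g, row["source"]) for g in lig]
        if row["target"] in ec_clusters:
            checks += [(g, row["target"]) for g in rec]
        if not checks:
            return True  # no EC side: specificity rule does not apply
        for g, c in checks:
            if g not in ec_lfc.index or c not in ec_lfc.columns:
                return False
            if ec_lfc.loc[g, c] < lfc_min:
                return False
        return True

    tab["ec_specific"] = tab.apply(ec_side_ok, axis=1)
    tab["significant"] = tab["p"] < alpha
    tab["kept"] = (
        tab["significant"]
        & tab["ec_specific"]
        & ~tab["excluded_self"]
        & ~tab["excluded_small_cluster"]
    )

    venous = None
    if venous_set is not None:
        rows = []
        base = tab[~tab["excluded_self"] & ~tab["excluded_small_cluster"]]
        for direction, ec_col, partner_col in (
            ("venous_ligand", "source", "target"),
            ("venous_receptor", "target", "source"),
        ):
            sub = base[base[ec_col].isin(venous_set)]
            for (pair, partner), grp in sub.groupby(["pair_id", partner_col]):
                n_sig = int(grp["significant"].sum())
                rows.append(
                    {
                        "pair_id": pair,
                        "partner": partner,
                        "direction": direction,
                        "n_venous_tested": len(grp),
                        "n_venous_significant": n_sig,
                        "mean_over_venous": grp["mean"].mean(),
                        "venous_consensus": n_sig >= 3,
                    }
                )
        venous = pd.DataFrame(rows)
    return FilteredInteractions(
        table=tab,
        venous=venous,
        params={"min_cells": min_cells, "lfc_min": lfc_min, "alpha": alpha},
    )
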