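"""End-to-end orchestration of the atlas stages from a config mapping.

Each runner consumes a plain dict (typically loaded from YAML), writes its
artifacts under ``outdir`` and returns a machine-readable report embedding
the seed, a hash of the config and the versions of the numerical libraries
of record. Defaults follow the atlas parameterization: gene QC 10 cells /
0.003 row mean, cell QC 300 genes / 2 SD / 10% mito, 1000 bootstraps,
projection threshold 0.5, top-25 markers, 500 permutation iterations,
expression threshold 0.25, specificity log2FC 0.25, regression span 0.2,
pseudotime k=3 with 8 principal components.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import cohort as ch
from . import interactome as ia
from . import io as eio
from . import markers as mk
from . import qc
from . import syndata as sd
from . import taxonomy as tx
from . import trajectory as tj


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _report_base(cfg: dict) -> dict:
    import importlib.metadata

    import scipy

    return {
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed", 0),
        "versions": {
            "ecatlas": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "anndata": importlib.metadata.version("anndata"),
            "scanpy": importlib.metadata.version("scanpy"),
        },
    }


def _load_or_simulate(cfg: dict):
    if cfg.get("input"):
        adata, truth = eio.read_count_matrix(cfg["input"]), None
    else:
        sim = sd.SimConfig(seed=cfg.get("seed", 0), **cfg.get("sim", {}))
        adata, truth = sd.simulate_counts(sim)
    return adata, truth


def run_atlas(cfg: dict) -> dict:
    """QC -> normalize -> cluster -> markers -> tree -> composition."""
    outdir = Path(cfg.get("outdir", "atlas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = _report_base(cfg)
    seed = cfg.get("seed", 0)
    stage = "load"
    try:
        adata, _ = _load_or_simulate(cfg)
        report["n_cells_raw"], report["n_genes_raw"] = adata.shape

        stage = "qc"
        thr = qc.QCThresholds(**cfg.get("qc", {}))
        adata = qc.filter_genes(adata, thr)
        adata, qcrep = qc.filter_cells(adata, thr)
        qcrep.to_csv(outdir / "qc_report.tsv", sep="\t")
        report["n_cells_qc"], report["n_genes_qc"] = adata.shape

        stage = "normalize"
        nm = qc.normalize_scale(adata)

        stage = "cluster"
        k = cfg.get("clustering", {}).get("k", 12)
        labels = tx.cluster_cells(nm, k=k, seed=seed)
        labels.to_csv(outdir / "clusters.tsv", sep="\t")
        report["n_clusters"] = int(labels.nunique())

        stage = "markers"
        mt = mk.compute_markers(nm, labels)
        long = pd.concat(
            [tab.assign(cluster=c) for c, tab in mt.tables.items()]
        ).rename_axis("gene")
        long.to_csv(outdir / "markers.tsv", sep="\t")
        top_n = cfg.get("markers", {}).get("top_n", 25)
        report["top_n_markers"] = top_n

        stage = "tree"
        cent = tx.build_centroids(nm, labels)
        boot = cfg.get("bootstrap", {})
        tree = tx.multiscale_bootstrap(
            cent.profile, n_boot=boot.get("n_boot", 1000), seed=seed
        )
        (outdir / "tree.nwk").write_text(tree.to_newick())
        report["n_supported_branches"] = int(
            (tree.branches["au"] >= boot.get("au_cutoff", 0.4)).sum()
        )

        stage = "composition"
        ct = ab.composition(labels, nm.obs["patient"], nm.obs["condition"])
        ct.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        tests = ab.paired_condition_test(ct)
        tests.to_csv(outdir / "composition_tests.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_congruency(cfg: dict) -> dict:
    """Projection + Jaccard + PCA + shared top-50 between two datasets."""
    outdir = Path(cfg.get("outdir", "congruency_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = _report_base(cfg)
    seed = cfg.get("seed", 0)
    stage = "load"
    try:
        datasets = []
        for key in ("dataset_a", "dataset_b"):
            sub = dict(cfg.get(key, {}))
            sub.setdefault("seed", seed if key == "dataset_a" else seed + 1)
            adata, _ = _load_or_simulate(sub)
            thr = qc.QCThresholds(**cfg.get("qc", {}))
            adata = qc.filter_genes(adata, thr)
            adata, _ = qc.filter_cells(adata, thr)
            nm = qc.normalize_scale(adata)
            k = sub.get("clustering", {}).get("k", cfg.get("clustering", {}).get("k", 5))
            labels = tx.cluster_cells(nm, k=k, seed=seed)
            mt = mk.compute_markers(nm, labels)
            datasets.append((nm, labels, mt))
        (nm_a, lab_a, mt_a), (nm_b, lab_b, mt_b) = datasets

        stage = "projection"
        top_n = cfg.get("markers", {}).get("top_n", 25)
        feats = sorted({g for c in mt_b.tables for g in mt_b.top_n(c, top_n)})
        cent_b = tx.build_centroids(nm_b, lab_b, features=[f for f in feats if f in nm_b.var_names])
        proj = tx.project_cells(nm_a, cent_b, threshold=cfg.get("projection", {}).get("threshold", 0.5))
        pd.DataFrame(
            {"assigned": proj.assignments, "similarity": proj.similarity}
        ).to_csv(outdir / "projection.tsv", sep="\t")
        report["assigned_fraction"] = float(
            (proj.assignments != "unassigned").mean()
        )

        stage = "jaccard"
        n50 = cfg.get("markers", {}).get("jaccard_top_n", 50)
        sets_a = {f"A{c}": set(mt_a.top_n(c, n50)) for c in mt_a.tables}
        sets_b = {f"B{c}": set(mt_b.top_n(c, n50)) for c in mt_b.tables}
        pooled = {**sets_a, **sets_b}
        jm = tx.jaccard_matrix(pooled, pooled)
        jm.to_csv(outdir / "jaccard.tsv", sep="\t")
        coords, evr = tx.jaccard_pca(jm)
        coords.to_csv(outdir / "jaccard_pca.tsv", sep="\t")
        report["pca_explained_variance"] = [float(v) for v in evr]

        stage = "shared_top_n"
        shared = []
        for ca in mt_a.tables:
            for cb in mt_b.tables:
                cnt, _ = tx.shared_top_n(mt_a, mt_b, ca, cb, n=n50)
                shared.append({"cluster_a": ca, "cluster_b": cb, "shared": cnt})
        pd.DataFrame(shared).to_csv(outdir / "shared_top50.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_interactome(cfg: dict) -> dict:
    outdir = Path(cfg.get("outdir", "interactome_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = _report_base(cfg)
    seed = cfg.get("seed", 0)
    stage = "load"
    try:
        adata, truth = _load_or_simulate(cfg)
        nm = qc.normalize_scale(adata)
        labels = (
            truth.true_labels
            if truth is not None
            else nm.obs["true_cluster"]
        )
        db = (
            eio.read_lr_database(cfg["lr_database"])
            if cfg.get("lr_database")
            else ia.bundled_lr_database()
        )
        stage = "permutation"
        it = ia.permutation_test(
            nm, labels, db,
            iterations=cfg.get("interactome", {}).get("iterations", 500),
            seed=seed,
        )
        it.table.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        report["n_tested"] = int(it.table["expressed"].sum())
        report["n_significant"] = int((it.table["p"] < 0.05).sum())
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_cohort(cfg: dict) -> dict:
    outdir = Path(cfg.get("outdir", "cohort_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = _report_base(cfg)
    seed = cfg.get("seed", 0)
    stage = "load"
    try:
        if cfg.get("cohort_table"):
            df = eio.read_cohort(cfg["cohort_table"])
        else:
            c = cfg.get("cohort", {})
            df = sd.simulate_cohort(
                n_treated=c.get("n_treated", 358),
                n_control=c.get("n_control", 4290),
                hr_bc=c.get("hr_bc", 0.7),
                hr_competing=c.get("hr_competing", 1.0),
                max_follow_up=c.get("max_follow_up", 14.0),
                seed=seed,
            )
        stage = "cif"
        cif_by_group = {}
        for g, sub in df.groupby("group"):
            est = ch.cumulative_incidence(sub, event_of_interest=1)
            cif_by_group[g] = est
            pd.DataFrame({"time": est.times, "cif": est.cif}).to_csv(
                outdir / f"cif_{g}.tsv", sep="\t", index=False
            )
        stage = "logrank"
        chi2, p = ch.logrank(df)
        report["logrank_chi2"] = chi2
        report["logrank_p"] = p
        stage = "km"
        km = ch.km_summaries(df)
        km.to_csv(outdir / "km.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
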