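"""Synthetic single-cell count matrices and survival cohorts with planted structure.

Every generator here plants a known truth (cluster labels, marker sets, a
latent arterio-venous-style gradient, ligand-receptor co-expression, cause
specific hazards) so that each downstream stage of the atlas pipeline can be
validated against ground truth rather than eyeballed.

Counts follow the standard scRNA-seq negative-binomial convention
Var = mu + mu^2 / dispersion, realised as a gamma-Poisson mixture so that
non-integer dispersions are supported and the Poisson limit is available by
passing ``nb_dispersion=inf``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "LRPlant",
    "simulate_counts",
    "simulate_trajectory",
    "simulate_interactome",
    "simulate_cohort",
    "simulate_registry",
]


@dataclass
class SimConfig:
    """Configuration of the planted-cluster count generator.

    Defaults emulate the statistical structure of an EC-enriched breast
    atlas: ~12 subclusters with distinct marker programs of ~20 genes at a
    strong (8-fold) enrichment, 9 patients contributing tumor and matched
    peri-tumoral cells, moderate overdispersion and log-normal library-size
    variation.
    """

    n_genes: int = 2000
    n_clusters: int = 12
    n_cells_per_cluster: list[int] | None = None
    n_patients: int = 9
    marker_genes_per_cluster: int = 20
    marker_fold_change: float = 8.0
    baseline_mean: float = 0.5
    nb_dispersion: float = 2.0
    library_size_log_sd: float = 0.35
    mito_gene_fraction: float = 0.05
    doublet_rate: float = 0.0
    #: cluster -> (share of tumor cells, share of peri-tumoral cells);
    #: each condition's shares over clusters must sum to 1.
    condition_enrichment: dict[int, tuple[float, float]] | None = None
    #: log-sd of an optional per-patient multiplier on all gene means.
    patient_effect_log_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_cluster is None:
            self.n_cells_per_cluster = [200] * self.n_clusters
        if len(self.n_cells_per_cluster) != self.n_clusters:
            raise ValueError("n_cells_per_cluster length must equal n_clusters")
        for name in ("n_genes", "n_clusters", "n_patients", "marker_genes_per_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(n <= 0 for n in self.n_cells_per_cluster):
            raise ValueError("all cluster sizes must be > 0")
        for name in ("marker_fold_change", "baseline_mean", "nb_dispersion",
                     "library_size_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("mito_gene_fraction", "doublet_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.marker_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError(
                "marker_genes_per_cluster x n_clusters exceeds n_genes; "
                "planted marker sets must be disjoint"
            )
        if self.condition_enrichment is not None:
            t = sum(v[0] for v in self.condition_enrichment.values())
            p = sum(v[1] for v in self.condition_enrichment.values())
            if not (math.isclose(t, 1.0, abs_tol=1e-9) and math.isclose(p, 1.0, abs_tol=1e-9)):
                raise ValueError("condition_enrichment shares must sum to 1 per condition")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class LRPlant:
    """A planted ligand-receptor co-expression: the ligand gene is boosted in
    the source cluster and the receptor gene in the target cluster."""

    ligand: str
    receptor: str
    source_cluster: int
    target_cluster: int
    fold: float = 10.0


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for downstream validation."""

    true_labels: pd.Series
    planted_markers: dict[int, set[str]] = field(default_factory=dict)
    true_pseudotime: pd.Series | None = None
    planted_lr_pairs: list[LRPlant] = field(default_factory=list)
    is_doublet: pd.Series | None = None
    cohort_truth: tuple[float, float] | None = None


def _gene_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_mito = int(round(cfg.mito_gene_fraction * cfg.n_genes))
    names = [f"G{i:04d}" for i in range(cfg.n_genes)]
    is_mito = np.zeros(cfg.n_genes, dtype=bool)
    # mito genes are placed at the tail so marker indices (head) never collide
    if n_mito:
        is_mito[-n_mito:] = True
        for j in range(cfg.n_genes - n_mito, cfg.n_genes):
            names[j] = f"MT-{names[j]}"
    return pd.DataFrame({"symbol": names, "is_mito": is_mito}).set_index(
        pd.Index(names, name="gene")
    )


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + mu^2/dispersion; Poisson when inf."""
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _assign_meta(cfg: SimConfig, labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = labels.size
    patients = np.array([f"P{rng.integers(cfg.n_patients) + 1}" for _ in range(n)])
    if cfg.condition_enrichment is None:
        p_tumor = np.full(n, 0.5)
    else:
        shares = {c: v for c, v in cfg.condition_enrichment.items()}
        p_tumor = np.array(
            [shares[c][0] / (shares[c][0] + shares[c][1]) for c in labels]
        )
    condition = np.where(rng.random(n) < p_tumor, "tumor", "peritumor")
    return pd.DataFrame(
        {
            "patient": patients,
            "condition": condition,
            "fraction": "enriched-EC",
            "true_cluster": labels,
        },
        index=pd.Index([f"CELL{i:05d}" for i in range(n)], name="barcode"),
    )


def _finish_adata(
    counts: np.ndarray, genes: pd.DataFrame, obs: pd.DataFrame
) -> ad.AnnData:
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)), obs=obs, var=genes.copy()
    )
    return adata


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a planted-cluster UMI matrix (cells x genes, sparse ``.X``).

    Gene means are ``baseline_mean`` times the marker fold change when the
    gene belongs to the cell's cluster program, times a log-normal cell
    library factor (unit mean). Doublets are formed post hoc by adding a
    second random cell's counts and are flagged in the truth so the QC
    doublet rule's sensitivity is measurable.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_frame(cfg, rng)

    labels = np.repeat(np.arange(cfg.n_clusters), cfg.n_cells_per_cluster)
    n_cells = labels.size

    planted: dict[int, set[str]] = {}
    mean_per_cluster = np.full((cfg.n_clusters, cfg.n_genes), cfg.baseline_mean)
    for c in range(cfg.n_clusters):
        idx = np.arange(
            c * cfg.marker_genes_per_cluster, (c + 1) * cfg.marker_genes_per_cluster
        )
        mean_per_cluster[c, idx] *= cfg.marker_fold_change
        planted[c] = set(genes.index[idx])

    lib = rng.lognormal(
        mean=-0.5 * cfg.library_size_log_sd**2, sigma=cfg.library_size_log_sd, size=n_cells
    )
    obs = _assign_meta(cfg, labels, rng)
    if cfg.patient_effect_log_sd > 0:
        pats = sorted(obs["patient"].unique())
        eff = {
            p: rng.lognormal(-0.5 * cfg.patient_effect_log_sd**2, cfg.patient_effect_log_sd)
            for p in pats
        }
        lib = lib * obs["patient"].map(eff).to_numpy()

    mu = mean_per_cluster[labels] * lib[:, None]
    counts = _sample_nb(rng, mu, cfg.nb_dispersion)

    n_doub = int(round(cfg.doublet_rate * n_cells))
    is_doublet = np.zeros(n_cells, dtype=bool)
    if n_doub:
        targets = rng.choice(n_cells, size=n_doub, replace=False)
        partners = rng.integers(0, n_cells, size=n_doub)
        counts[targets] += counts[partners]
        is_doublet[targets] = True

    adata = _finish_adata(counts, genes, obs)
    adata.obs["is_doublet"] = is_doublet
    truth = SyntheticTruth(
        true_labels=pd.Series(labels, index=adata.obs_names, name="true_cluster"),
        planted_markers=planted,
        is_doublet=pd.Series(is_doublet, index=adata.obs_names, name="is_doublet"),
    )
    return adata, truth


def simulate_trajectory(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Cells along a 1-D gradient blending >=3 ordered expression programs.

    Each cell draws a latent position t ~ U(0,1); program weights are
    triangular bumps centred at equispaced positions with half-width equal to
    the inter-program spacing, so only the flanking programs are active at
    any t (emulating an artery -> capillary -> vein marker gradient). The
    cell label is the argmax-weight program.
    """
    cfg = config
    if cfg.n_clusters < 3:
        raise ValueError("trajectory simulation needs >= 3 ordered programs")
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_frame(cfg, rng)

    n_cells = int(np.sum(cfg.n_cells_per_cluster))
    t = rng.uniform(0.0, 1.0, size=n_cells)
    P = cfg.n_clusters
    centers = np.linspace(0.0, 1.0, P)
    width = 1.0 / (P - 1)
    w = np.clip(1.0 - np.abs(t[:, None] - centers[None, :]) / width, 0.0, None)

    planted: dict[int, set[str]] = {}
    mu = np.full((n_cells, cfg.n_genes), cfg.baseline_mean)
    for c in range(P):
        idx = np.arange(
            c * cfg.marker_genes_per_cluster, (c + 1) * cfg.marker_genes_per_cluster
        )
        mu[:, idx] *= 1.0 + (cfg.marker_fold_change - 1.0) * w[:, c][:, None]
        planted[c] = set(genes.index[idx])

    labels = np.argmax(w, axis=1)
    lib = rng.lognormal(
        -0.5 * cfg.library_size_log_sd**2, cfg.library_size_log_sd, size=n_cells
    )
    counts = _sample_nb(rng, mu * lib[:, None], cfg.nb_dispersion)

    obs = _assign_meta(cfg, labels, rng)
    adata = _finish_adata(counts, genes, obs)
    adata.obs["true_t"] = t
    truth = SyntheticTruth(
        true_labels=pd.Series(labels, index=adata.obs_names, name="true_cluster"),
        planted_markers=planted,
        true_pseudotime=pd.Series(t, index=adata.obs_names, name="true_t"),
    )
    return adata, truth


def simulate_interactome(
    config: SimConfig, planted: list[LRPlant]
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Counts with planted ligand-receptor co-expression across cluster pairs.

    The base matrix comes from :func:`simulate_counts`'s generative model;
    each plant multiplies the ligand gene's mean in the source cluster and
    the receptor gene's mean in the target cluster by ``plant.fold``. All
    other ligand/receptor genes stay at baseline everywhere.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_frame(cfg, rng)
    name_to_idx = {g: i for i, g in enumerate(genes.index)}

    labels = np.repeat(np.arange(cfg.n_clusters), cfg.n_cells_per_cluster)
    n_cells = labels.size
    mean_per_cluster = np.full((cfg.n_clusters, cfg.n_genes), cfg.baseline_mean)
    for plant in planted:
        for clus in (plant.source_cluster, plant.target_cluster):
            if not 0 <= clus < cfg.n_clusters:
                raise ValueError(f"plant references unknown cluster {clus}")
        for gene in (plant.ligand, plant.receptor):
            if gene not in name_to_idx:
                raise ValueError(f"plant references unknown gene {gene!r}")
        mean_per_cluster[plant.source_cluster, name_to_idx[plant.ligand]] *= plant.fold
        mean_per_cluster[plant.target_cluster, name_to_idx[plant.receptor]] *= plant.fold

    lib = rng.lognormal(
        -0.5 * cfg.library_size_log_sd**2, cfg.library_size_log_sd, size=n_cells
    )
    counts = _sample_nb(rng, mean_per_cluster[labels] * lib[:, None], cfg.nb_dispersion)
    obs = _assign_meta(cfg, labels, rng)
    adata = _finish_adata(counts, genes, obs)
    truth = SyntheticTruth(
        true_labels=pd.Series(labels, index=adata.obs_names, name="true_cluster"),
        planted_lr_pairs=list(planted),
    )
    return adata, truth


_STAGE_PROBS = {"I": 0.50, "II": 0.35, "III": 0.15}
_GRADE_PROBS = {1: 0.25, 2: 0.50, 3: 0.25}
_HR_PROBS = {"double_positive": 0.7, "single_positive": 0.3}


def simulate_cohort(
    n_treated: int,
    n_control: int,
    hr_bc: float,
    hr_competing: float,
    max_follow_up: float = 14.0,
    seed: int = 0,
    baseline_hazard_bc: float = 0.02,
    baseline_hazard_competing: float = 0.015,
) -> pd.DataFrame:
    """Two-arm cohort with exponential cause-specific hazards and a competing
    event (death of other causes), administratively censored at
    ``max_follow_up`` years.

    The treated arm's breast-cancer-specific hazard is multiplied by
    ``hr_bc`` and its competing hazard by ``hr_competing``. Covariates
    (age ~ N(60,10), BMI ~ N(26,4), categorical stage/grade) are recorded so
    matching can be exercised. Events: 0 censored, 1 BC-specific, 2 competing.
    """
    if baseline_hazard_bc <= 0 or baseline_hazard_competing <= 0:
        raise ValueError("baseline hazards must be positive")
    if hr_bc <= 0 or hr_competing <= 0:
        raise ValueError("hazard ratios must be positive")
    if max_follow_up < 0:
        raise ValueError("max_follow_up must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_treated + n_control
    treated = np.r_[np.ones(n_treated, dtype=bool), np.zeros(n_control, dtype=bool)]
    lam_bc = baseline_hazard_bc * np.where(treated, hr_bc, 1.0)
    lam_cmp = baseline_hazard_competing * np.where(treated, hr_competing, 1.0)
    t_bc = rng.exponential(1.0 / lam_bc)
    t_cmp = rng.exponential(1.0 / lam_cmp)
    t_event = np.minimum(t_bc, t_cmp)
    time = np.minimum(t_event, max_follow_up)
    event = np.where(
        t_event >= max_follow_up, 0, np.where(t_bc <= t_cmp, 1, 2)
    )
    df = pd.DataFrame(
        {
            "patient_id": [f"PT{i:05d}" for i in range(n)],
            "group": np.where(treated, "metformin", "control"),
            "time_years": time,
            "event": event.astype(int),
            "age": rng.normal(60.0, 10.0, n),
            "bmi": rng.normal(26.0, 4.0, n),
            "stage": rng.choice(list(_STAGE_PROBS), p=list(_STAGE_PROBS.values()), size=n),
            "grade": rng.choice(list(_GRADE_PROBS), p=list(_GRADE_PROBS.values()), size=n),
        }
    )
    df.attrs["cohort_truth"] = (hr_bc, hr_competing)
    return df


def simulate_registry(
    n_total: int = 4924,
    n_missing_metadata: int = 265,
    n_early_discontinuers: int = 11,
    n_treated: int = 358,
    min_follow_up: float = 8.0,
    max_follow_up: float = 14.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A raw hospital-registry-style table, before inclusion/exposure rules.

    Emulates the screening stage of a retrospective cohort: ``n_total``
    eligible patients, of whom ``n_missing_metadata`` lack a critical
    covariate, ``n_treated`` have continuous drug exposure longer than one
    year, and ``n_early_discontinuers`` started but stopped within a year.
    Exposure is stored as semicolon-separated ``start-stop`` intervals in
    years since diagnosis. Feed the result to :func:`ecatlas.cohort.assign_groups`.
    """
    if n_missing_metadata + n_early_discontinuers + n_treated > n_total:
        raise ValueError("subgroup counts exceed n_total")
    rng = np.random.default_rng(seed)
    n = n_total
    age = rng.normal(60.0, 10.0, n)
    bmi = rng.normal(26.0, 4.0, n)
    stage = rng.choice(list(_STAGE_PROBS), p=list(_STAGE_PROBS.values()), size=n)
    grade = rng.choice(list(_GRADE_PROBS), p=list(_GRADE_PROBS.values()), size=n)
    hr_status = rng.choice(list(_HR_PROBS), p=list(_HR_PROBS.values()), size=n)
    follow = rng.uniform(min_follow_up, max_follow_up, n)

    exposure = np.array([""] * n, dtype=object)
    # treated: one continuous interval strictly longer than 1 year
    for i in range(n_treated):
        start = rng.uniform(0.0, 2.0)
        length = rng.uniform(1.5, 6.0)
        exposure[i] = f"{start:.3f}-{start + length:.3f}"
    # early discontinuers: exposure but never a continuous year
    for i in range(n_treated, n_treated + n_early_discontinuers):
        start = rng.uniform(0.0, 2.0)
        length = rng.uniform(0.1, 0.9)
        exposure[i] = f"{start:.3f}-{start + length:.3f}"
    # metadata-missing patients drawn from the untreated remainder
    missing_idx = rng.choice(
        np.arange(n_treated + n_early_discontinuers, n),
        size=n_missing_metadata,
        replace=False,
    )
    age[missing_idx] = np.nan

    deaths = rng.random(n) < 0.25
    relapse = rng.random(n) < 0.15
    event = np.where(deaths, np.where(rng.random(n) < 0.5, 1, 2), 0)
    cause_known = np.where(deaths, rng.random(n) > 0.2, True)

    df = pd.DataFrame(
        {
            "patient_id": [f"PT{i:05d}" for i in range(n)],
            "time_years": follow,
            "event": event.astype(int),
            "relapse_observed": relapse,
            "cause_known": cause_known,
            "exposure": exposure,
            "age": age,
            "bmi": bmi,
            "stage": stage,
            "grade": grade,
            "hr_status": hr_status,
        }
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
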