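"""Cluster-level taxonomy tools: clustering interface, centroid profiles,
bootstrap-supported dendrograms, cross-dataset projection and Jaccard
congruency.

The dendrogram uses Euclidean distance with complete linkage over cluster
centroid profiles. Branch confidence follows the multiscale bootstrap: gene
(feature) columns are resampled with replacement at a range of sample-size
scales, the per-branch presence frequency is recorded at each scale, and the
scale dependence of the probit-transformed frequencies is extrapolated to
yield the approximately unbiased (AU) p-value; the plain bootstrap
probability (BP) is the presence frequency at scale 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


# ---------------------------------------------------------------- clustering

def cluster_cells(
    nm: ad.AnnData,
    k: int,
    n_pcs: int = 20,
    seed: int = 0,
    backend=None,
) -> pd.Series:
    """Label cells by a pluggable community-detection step.

    ``backend`` may be any callable ``(pca_coords, seed) -> labels``; the
    shipped default is a deterministic k-means on the first ``n_pcs``
    principal components of the scaled layer, which is reproducible under a
    fixed seed and adequate for well-separated planted clusters.
    """
    if k > nm.n_obs:
        raise ValueError(f"k={k} exceeds number of cells {nm.n_obs}")
    X = nm.layers["scaled"] if "scaled" in nm.layers else (
        nm.X.toarray() if sparse.issparse(nm.X) else np.asarray(nm.X)
    )
    n_pcs = min(n_pcs, min(X.shape) - 1) or 1
    coords = PCA(n_components=n_pcs, random_state=seed).fit_transform(np.asarray(X))
    if backend is not None:
        labels = np.asarray(backend(coords, seed))
    else:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(coords)
    return pd.Series(labels, index=nm.obs_names, name="cluster")


# ----------------------------------------------------------------- centroids

@dataclass
class ClusterCentroids:
    """clusters x features matrix of mean normalized log expression."""

    profile: pd.DataFrame  # index cluster, columns features
    source: str = ""

    @property
    def clusters(self) -> list:
        return list(self.profile.index)

    @property
    def features(self) -> list[str]:
        return list(self.profile.columns)


def build_centroids(
    nm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    features: list[str] | None = None,
    source: str = "",
    statistic: str = "mean",
) -> ClusterCentroids:
    """Per-cluster mean (or median) of normalized log expression, restricted
    to ``features`` (default: all genes)."""
    labels = np.asarray(labels)
    if features is None:
        features = list(nm.var_names)
    missing = [f for f in features if f not in nm.var_names]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    sub = nm[:, features]
    X = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X)
    agg = np.mean if statistic == "mean" else np.median
    rows = {}
    for c in pd.unique(labels):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"cluster {c} is empty")
        rows[c] = agg(X[mask], axis=0)
    profile = pd.DataFrame.from_dict(rows, orient="index", columns=features)
    return ClusterCentroids(profile=profile.sort_index(), source=source)


# ---------------------------------------------------------------- projection

@dataclass
class ProjectionResult:
    assignments: pd.Series  # per cell: cluster label or "unassigned"
    similarity: pd.Series  # cosine similarity index in [-1, 1]
    threshold: float


def _row_standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - mu) / sd


def _row_normalize(M: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(M, axis=1, keepdims=True)
    nrm = np.where(nrm == 0, 1.0, nrm)
    return M / nrm


def project_cells(
    query: ad.AnnData,
    ref: ClusterCentroids,
    threshold: float = 0.5,
    min_shared_features: int = 10,
) -> ProjectionResult:
    """Assign query cells to reference cluster centroids.

    For each cell, cosine similarity, Pearson and Spearman correlation to
    every centroid are computed on the shared feature set; the cell is
    assigned to the cosine argmax when at least two of the three measures
    agree on that cluster and its cosine similarity reaches ``threshold``,
    otherwise it is left "unassigned". The reported similarity index is the
    cosine to the assigned centroid (max cosine when unassigned).
    """
    shared = [f for f in ref.features if f in query.var_names]
    if len(shared) < min_shared_features:
        raise ValueError(
            f"only {len(shared)} shared features between query and reference "
            f"(need >= {min_shared_features})"
        )
    sub = query[:, shared]
    Q = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    C = ref.profile[shared].to_numpy(dtype=float)
    clusters = np.asarray(ref.clusters, dtype=object)

    cos = _row_normalize(Q) @ _row_normalize(C).T
    n_feat = len(shared)
    pear = (_row_standardize(Q) @ _row_standardize(C).T) / n_feat
    rank_q = stats.rankdata(Q, axis=1)
    rank_c = stats.rankdata(C, axis=1)
    spear = (_row_standardize(rank_q) @ _row_standardize(rank_c).T) / n_feat

    arg = np.column_stack([m.argmax(axis=1) for m in (cos, pear, spear)])
    cos_arg = arg[:, 0]
    votes = (arg == cos_arg[:, None]).sum(axis=1)
    cos_best = cos[np.arange(len(cos_arg)), cos_arg]
    assigned = (votes >= 2) & (cos_best >= threshold)

    labels = np.where(assigned, clusters[cos_arg], "unassigned")
    sim = cos_best  # cosine to assigned cluster, or max cosine when unassigned
    return ProjectionResult(
        assignments=pd.Series(labels, index=query.obs_names, name="assigned"),
        similarity=pd.Series(sim, index=query.obs_names, name="similarity"),
        threshold=threshold,
    )


# -------------------------------------------------------- hierarchical trees

def hierarchical_tree(cent: ClusterCentroids) -> np.ndarray:
    """Complete-linkage tree on Euclidean distances between centroid rows."""
    if len(cent.clusters) < 2:
        raise ValueError("need >= 2 clusters to build a tree")
    return hierarchy.linkage(cent.profile.to_numpy(), method="complete")


def _branch_sets(Z: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Leaf sets of internal nodes (singleton leaves excluded; the root is
    kept and trivially earns AU = BP = 1)."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for i, (a, b, _, _) in enumerate(Z):
        node = members[int(a)] | members[int(b)]
        members[n_leaves + i] = node
        out.append(node)
    return out


@dataclass
class SupportTree:
    linkage: np.ndarray
    labels: list
    branches: pd.DataFrame = field(default_factory=pd.DataFrame)
    # branches: index branch id; columns clusters (frozenset), au, bp, flagged

    def to_newick(self) -> str:
        """Newick string with AU/BP per internal branch as comments."""
        support = {row["clusters"]: (row["au"], row["bp"]) for _, row in self.branches.iterrows()}
        n = len(self.labels)
        sets = {i: frozenset([i]) for i in range(n)}

        def render(node_id: int) -> str:
            if node_id < n:
                return str(self.labels[node_id])
            a, b, dist, _ = self.linkage[node_id - n]
            sets[node_id] = sets[int(a)] | sets[int(b)]
            inner = f"{render(int(a))},{render(int(b))}"
            key = sets[node_id]
            if key in support:
                au, bp = support[key]
                return f"({inner})[&&AU={au:.3f},BP={bp:.3f}]"
            return f"({inner})"

        # populate sets bottom-up first
        for i, (a, b, _, _) in enumerate(self.linkage):
            sets[n + i] = sets[int(a)] | sets[int(b)]
        return render(n + len(self.linkage) - 1) + ";"

    def supported_branches(self, au_cutoff: float = 0.4) -> pd.DataFrame:
        """Branches meeting the AU confidence cutoff (default 0.4)."""
        return self.branches[self.branches["au"] >= au_cutoff]


def multiscale_bootstrap(
    profile: pd.DataFrame,
    n_boot: int = 1000,
    scales: np.ndarray | None = None,
    seed: int = 0,
) -> SupportTree:
    """AU and BP branch support for the complete-linkage tree over ``profile``.

    For each scale r the features (columns) are resampled with replacement to
    ceil(r * n_features) columns, ``n_boot`` times, and the tree is rebuilt;
    the per-branch presence frequency BP_r is probit-transformed and fitted
    against sqrt(r) by weighted least squares, z(r) = v*sqrt(r) + c/sqrt(r);
    AU = 1 - Phi(v - c). BP is the plain frequency at r = 1. Branches present
    in every resample at every scale get AU = BP = 1 without fitting; a
    branch never observed at any scale gets AU = 0 and is flagged.
    """
    if profile.shape[1] < 10:
        raise ValueError("need >= 10 features for bootstrap support")
    if scales is None:
        scales = np.linspace(0.5, 1.4, 10)
    scales = np.asarray(scales, dtype=float)
    if not np.any(np.isclose(scales, 1.0)):
        scales = np.sort(np.append(scales, 1.0))
    rng = np.random.default_rng(seed)

    M = profile.to_numpy(dtype=float)
    n_leaves, n_feat = M.shape
    Z_obs = hierarchy.linkage(M, method="complete")
    observed = _branch_sets(Z_obs, n_leaves)

    counts = np.zeros((len(observed), len(scales)))
    for si, r in enumerate(scales):
        m = max(1, math.ceil(r * n_feat))
        for _ in range(n_boot):
            cols = rng.integers(0, n_feat, size=m)
            Zb = hierarchy.linkage(M[:, cols], method="complete")
            present = set(_branch_sets(Zb, n_leaves))
            for bi, br in enumerate(observed):
                if br in present:
                    counts[bi, si] += 1

    freq = counts / n_boot
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    rows = []
    for bi, br in enumerate(observed):
        bp = freq[bi, r1]
        flagged = False
        if np.all(freq[bi] == 1.0):
            au = 1.0
        elif np.all(freq[bi] == 0.0):
            au, flagged = 0.0, True
        else:
            # probit-transformed frequencies; clamp to keep z finite
            f = np.clip(freq[bi], 0.5 / n_boot, 1.0 - 0.5 / n_boot)
            z = stats.norm.ppf(1.0 - f)
            X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
            # delta-method weights for the probit of a binomial frequency
            w = n_boot * stats.norm.pdf(z) ** 2 / (f * (1.0 - f))
            W = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
            v, c = coef
            au = float(1.0 - stats.norm.cdf(v - c))
        rows.append(
            {"clusters": frozenset(profile.index[i] for i in br), "au": au,
             "bp": float(bp), "flagged": flagged}
        )
    branches = pd.DataFrame(rows)
    return SupportTree(linkage=Z_obs, labels=list(profile.index), branches=branches)


# ----------------------------------------------------------------- congruency

def jaccard_matrix(
    sets_a: dict, sets_b: dict
) -> pd.DataFrame:
    """Pairwise Jaccard coefficients |A∩B| / |A∪B| between marker gene sets.

    Empty sets yield a coefficient of 0 with a warning.
    """
    for name, sets in (("sets_a", sets_a), ("sets_b", sets_b)):
        for k, s in sets.items():
            if len(s) == 0:
                warnings.warn(f"empty gene set {k!r} in {name}; Jaccard defined as 0")
    out = pd.DataFrame(index=list(sets_a), columns=list(sets_b), dtype=float)
    for ka, a in sets_a.items():
        a = set(a)
        for kb, b in sets_b.items():
            b = set(b)
            union = len(a | b)
            out.loc[ka, kb] = len(a & b) / union if union else 0.0
    return out


def jaccard_pca(jm: pd.DataFrame, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA embedding of the rows of a square symmetric Jaccard matrix.

    Rows are treated as feature vectors and centered; returns the first
    ``n_components`` coordinates per cluster and the explained-variance
    shares.
    """
    if jm.shape[0] != jm.shape[1]:
        raise ValueError("Jaccard matrix must be square over pooled clusters")
    if jm.shape[0] < 4:
        raise ValueError("need >= 4 clusters for a 3-D embedding")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(jm.to_numpy(dtype=float))
    cols = [f"PC{i+1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=jm.index, columns=cols), pca.explained_variance_ratio_


def shared_top_n(
    mt_a, mt_b, cluster_a, cluster_b, n: int = 50
) -> tuple[int, list[str]]:
    """Count and list genes ranking in the top-n marker lists of both clusters."""
    top_a = set(mt_a.top_n(cluster_a, n))
    top_b = set(mt_b.top_n(cluster_b, n))
    shared = sorted(top_a & top_b)
    return len(shared), shared
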