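"""Clustering and anatomical-network characterization of chosen regions.

Chosen regions are clustered on their activity profiles (counts across
animals, z-scored per region) with Ward.D2 agglomerative clustering on
the Euclidean distance matrix, visualized with non-metric MDS (Kruskal
stress-1), and tested for above-chance anatomical connectivity against a
row-shuffled connectome null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .core import AtlasTree, ConnectivityMatrix, CountMatrix, FosmapError, ValidationError

__all__ = [
    "ClusterAssignment",
    "ConnectivityTestResult",
    "activity_profiles",
    "ward_cluster",
    "nmds_embed",
    "resolve_connectivity_roi",
    "cluster_connectivity_test",
]


@dataclass
class ClusterAssignment:
    roi_ids: list[str]
    labels: dict[str, int]
    #: scipy-format linkage record: rows (idx_a, idx_b, height, size)
    linkage: np.ndarray
    k: int
    mds_coords: dict[str, tuple[float, float]] | None = None
    mds_stress: float | None = None


@dataclass
class ConnectivityTestResult:
    observed_density: float
    null_densities: np.ndarray
    p_value: float
    clusters_used: list[int]
    roi_mapping: dict[str, str]
    excluded: list[tuple[int, str]] = field(default_factory=list)


def activity_profiles(
    counts: CountMatrix, chosen: list[str], scale: bool = True
) -> pd.DataFrame:
    """ROI x animal activity profiles, optionally z-scored per ROI.

    Scaling uses the sample standard deviation (ddof=1, the R ``scale()``
    convention), so a two-animal profile [1, 3] becomes [-0.707, 0.707].
    """
    missing = [r for r in chosen if r not in counts.df.columns]
    if missing:
        raise ValidationError(f"chosen ROIs not in count matrix: {missing}")
    prof = counts.df[chosen].T.astype(float)
    if scale:
        sd = prof.std(axis=1, ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValidationError(
                f"zero-variance ROI(s) cannot be scaled: {list(zero.index)}"
            )
        prof = prof.sub(prof.mean(axis=1), axis=0).div(sd, axis=0)
    return prof


def ward_cluster(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Ward.D2 hierarchical clustering of region profiles, cut into k groups.

    Operates on the Euclidean distance matrix between region profiles with
    the Ward.D2 update

        d(i u j, l) = sqrt[((n_i+n_l) d_il^2 + (n_j+n_l) d_jl^2
                            - n_l d_ij^2) / (n_i+n_j+n_l)],

    i.e. scipy's ``linkage(method="ward")``, which coincides with R's
    ``hclust(method="ward.D2")`` on a Euclidean distance matrix. The tree
    is cut below the k-1 highest merges.
    """
    n = profiles.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in 1..{n}, got {k}")
    X = profiles.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    lab = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        roi_ids=list(profiles.index),
        labels=dict(zip(profiles.index, map(int, lab))),
        linkage=Z,
        k=k,
    )


def nmds_embed(
    distance: np.ndarray, seed: int = 0, n_restarts: int = 4
) -> tuple[np.ndarray, float]:
    """Non-metric 2-D MDS embedding (Kruskal stress-1), best of restarts.

    Returns (coords centered at the origin, stress-1). Requires n >= 3.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if D.shape[0] < 3:
        raise ValidationError("need at least 3 points for an MDS embedding")
    import inspect

    kwargs = dict(
        n_components=2,
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    sig = inspect.signature(MDS).parameters
    if "metric_mds" in sig:  # sklearn >= 1.9 parameter names
        kwargs.update(metric_mds=False, metric="precomputed")
        if "init" in sig:
            kwargs.update(init="random")
    else:
        kwargs.update(metric=False, dissimilarity="precomputed")
    mds = MDS(**kwargs)
    coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    return coords, float(mds.stress_)


def resolve_connectivity_roi(roi: str, tree: AtlasTree, available: set[str]) -> str:
    """Map a region onto the connectome: itself, or the next inclusive region.

    If the region is absent from the connectivity matrix, walk up the
    atlas and use the nearest ancestor that is available (e.g. BST data
    standing in for a BST subnucleus).
    """
    if roi not in tree:
        raise FosmapError(f"ROI {roi!r} not in atlas")
    if roi in available:
        return roi
    for anc in tree.ancestors(roi):
        if anc in available:
            return anc
    lineage = [roi, *tree.ancestors(roi)]
    raise FosmapError(
        f"no connectivity data for {roi!r} or any ancestor (lineage: {lineage})"
    )


def _mean_cluster_density(
    dens: np.ndarray, members: list[list[int]]
) -> float:
    """Unweighted mean over clusters of the mean ordered-pair density."""
    cluster_means = []
    for idx in members:
        vals = []
        for i in idx:
            for j in idx:
                if i == j:
                    continue
                v = dens[i, j]
                if not np.isnan(v):
                    vals.append(v)
        # a permutation can relocate the NaN sentinel onto every pair of a
        # small cluster; such a cluster carries no information for that draw
        if vals:
            cluster_means.append(float(np.mean(vals)))
    return float(np.mean(cluster_means)) if cluster_means else np.nan


def cluster_connectivity_test(
    conn: ConnectivityMatrix,
    assignment: ClusterAssignment,
    tree: AtlasTree,
    n_perm: int = 10_000,
    seed: int = 0,
    exclude_clusters: list[int] | None = None,
    strict: bool = False,
) -> ConnectivityTestResult:
    """Permutation test: are clusters denser than a row-shuffled connectome?

    The observed statistic is the unweighted mean, over non-excluded
    clusters, of the mean normalized connection density across ordered
    member pairs (diagonal and self-pairs arising from a shared mapping
    excluded). The null shuffles the *row* labels of the mapped submatrix
    (columns fixed, preserving the asymmetric origin -> target semantics);
    p uses the plus-one rule. Clusters with fewer than 2 mappable members
    are excluded with a warning (or raise when ``strict``).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    exclude = set(exclude_clusters or [])
    avail = set(conn.origin_ids) & set(conn.target_ids)
    mapping: dict[str, str] = {}
    for roi in assignment.roi_ids:
        mapping[roi] = resolve_connectivity_roi(roi, tree, avail)

    ids = sorted({mapping[r] for r in assignment.roi_ids})
    pos = {rid: i for i, rid in enumerate(ids)}
    dens = conn.df.loc[ids, ids].to_numpy(dtype=float)
    np.fill_diagonal(dens, np.nan)

    members: list[list[int]] = []
    clusters_used: list[int] = []
    excluded: list[tuple[int, str]] = []
    for c in sorted(set(assignment.labels.values())):
        if c in exclude:
            excluded.append((c, "excluded by request"))
            continue
        rois = [r for r in assignment.roi_ids if assignment.labels[r] == c]
        idx = [pos[mapping[r]] for r in rois]
        # self-pairs from shared mapping contribute nothing; need >= 2 distinct targets
        if len(set(idx)) < 2:
            msg = f"cluster {c} has fewer than 2 mappable members"
            if strict:
                raise FosmapError(msg)
            import warnings

            warnings.warn(msg, UserWarning, stacklevel=2)
            excluded.append((c, "fewer than 2 mappable members"))
            continue
        members.append(idx)
        clusters_used.append(c)
    if not members:
        raise FosmapError("no cluster has >= 2 mappable members")

    observed = _mean_cluster_density(dens, members)
    rng = np.random.default_rng(seed)
    m = len(ids)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(m)
        null[b] = _mean_cluster_density(dens[perm, :], members)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ConnectivityTestResult(
        observed_density=observed,
        null_densities=null,
        p_value=float(p),
        clusters_used=clusters_used,
        roi_mapping=mapping,
        excluded=excluded,
    )
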