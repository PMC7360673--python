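"""Group statistics: per-source t-tests with cluster-based permutation
correction, and per-RSN t-tests.

The cluster-based permutation test (CBPT) controls the family-wise error of
the per-source comparisons: sources whose two-sided t-test falls below the
cluster-forming alpha are grouped into spatially contiguous clusters (per
t-sign), each cluster is scored by its summed t ("cluster mass", the
T-statsum), and the observed masses are referred to the Monte-Carlo null of
the maximum |mass| under random relabelings of the subjects that preserve
the group sizes. Monte-Carlo p-values use the (1 + k) / (N + 1) estimator,
which never returns 0; an exhaustive mode enumerates every distinct
relabeling for small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .source_space import Adjacency

__all__ = [
    "TMap",
    "ProtoCluster",
    "ClusterResult",
    "CBPTConfig",
    "RSNTestResult",
    "pointwise_t",
    "find_clusters",
    "cluster_permutation_test",
    "rsn_group_test",
    "restrict_adjacency",
]


@dataclass
class TMap:
    """Per-source two-sample t statistics.

    Positive t means group 1's mean exceeds group 2's (by convention the
    robust group is passed first, so a frailty deficit appears positive).
    """

    t: np.ndarray
    n1: int
    n2: int
    df: float
    seed: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t-map contains non-finite values")


@dataclass
class ProtoCluster:
    """A connected suprathreshold component before permutation scoring."""

    indices: np.ndarray
    mass: float
    sign: str  # "positive" | "negative"


@dataclass
class ClusterResult:
    """A cluster with its Monte-Carlo corrected p-value."""

    indices: np.ndarray
    mass: float
    sign: str
    p_value: float
    n_permutations: int


@dataclass
class CBPTConfig:
    """Configuration of the cluster-based permutation test."""

    cluster_forming_alpha: float = 0.05
    n_permutations: int = 5000
    rng_seed: int | None = None
    t_variant: str = "pooled"  # or "welch"
    max_stat: str = "both_signs"  # or "per_sign"
    exhaustive: bool = False
    allow_few_relabelings: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.cluster_forming_alpha < 1:
            raise ValueError("cluster_forming_alpha must be in (0, 1)")
        if not self.exhaustive and self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError("t_variant must be 'pooled' or 'welch'")
        if self.max_stat not in ("both_signs", "per_sign"):
            raise ValueError("max_stat must be 'both_signs' or 'per_sign'")


@dataclass
class RSNTestResult:
    """Uncorrected two-sample t-test of one network's mean FC."""

    network: str
    band: str
    mean1: float
    mean2: float
    t: float
    p: float
    n1: int
    n2: int


def _group_masks(groups, group_order: tuple[str, str] | None):
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if group_order is None:
        if len(labels) != 2:
            raise ValueError("need exactly two group labels")
        group_order = (labels[0], labels[1])
    m1 = groups == group_order[0]
    m2 = groups == group_order[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("both groups need at least two subjects")
    if m1.sum() + m2.sum() != len(groups):
        raise ValueError("groups contain labels outside group_order")
    return m1, m2, group_order


def _t_stat(x1: np.ndarray, x2: np.ndarray, variant: str) -> tuple[np.ndarray, float | np.ndarray]:
    """Vectorised two-sample t over the last-but-one axis (subjects)."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:  # welch
        denom = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(np.isfinite(t), t, 0.0), df


def pointwise_t(
    values: np.ndarray,
    groups,
    group_order: tuple[str, str] | None = None,
    variant: str = "pooled",
    seed: str = "",
    band: str = "",
) -> TMap:
    """Independent-samples t-test at every source.

    ``values`` is ``(subjects, sources)``; ``groups`` the per-subject label.
    Sources with zero variance in both groups get t = 0 with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    m1, m2, _ = _group_masks(groups, group_order)
    x1, x2 = values[m1], values[m2]
    zero_var = (x1.var(axis=0) == 0) & (x2.var(axis=0) == 0)
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} source(s) have zero variance in both groups; t set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    t, df = _t_stat(x1, x2, variant)
    df_scalar = float(np.mean(df)) if variant == "welch" else float(df)
    return TMap(t=t, n1=int(m1.sum()), n2=int(m2.sum()), df=df_scalar, seed=seed, band=band)


def restrict_adjacency(adjacency: Adjacency | sparse.spmatrix, keep) -> sparse.csr_matrix:
    """Adjacency over a subset of sources, reindexed to the subset's order.

    Used to carry grid adjacency onto a seed-FC vector, whose entries live
    on the non-seed sources only.
    """
    keep = np.asarray(keep, dtype=np.intp)
    mat = adjacency.to_sparse() if isinstance(adjacency, Adjacency) else adjacency.tocsr()
    return mat[np.ix_(keep, keep)].tocsr()


def _as_sparse(adjacency) -> sparse.csr_matrix:
    if isinstance(adjacency, Adjacency):
        return adjacency.to_sparse()
    return sparse.csr_matrix(adjacency)


def _clusters_from_t(
    t: np.ndarray, t_crit: float, adj: sparse.csr_matrix
) -> list[ProtoCluster]:
    out: list[ProtoCluster] = []
    for sign, mask in (("positive", t > t_crit), ("negative", t < -t_crit)):
        nodes = np.flatnonzero(mask)
        if nodes.size == 0:
            continue
        sub = adj[np.ix_(nodes, nodes)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = nodes[labels == c]
            out.append(
                ProtoCluster(
                    indices=members, mass=float(t[members].sum()), sign=sign
                )
            )
    return out


def find_clusters(
    tmap: TMap, adjacency, alpha: float = 0.05
) -> list[ProtoCluster]:
    """Spatially contiguous clusters of suprathreshold sources, per t-sign.

    A source enters a cluster when its two-sided p is below ``alpha``; the
    cluster mass is the exact sum of its members' t-values.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    adj = _as_sparse(adjacency)
    if adj.shape[0] != len(tmap.t):
        raise ValueError("adjacency does not cover the t-map's sources")
    t_crit = float(stats.t.isf(alpha / 2.0, tmap.df))
    return _clusters_from_t(tmap.t, t_crit, adj)


def _relabelings(n_total: int, n1: int, rng: np.random.Generator, config: CBPTConfig):
    """Yield boolean group-1 masks for permutations (observed labeling first
    in exhaustive mode, where every distinct relabeling appears once)."""
    from math import comb

    n_distinct = comb(n_total, n1)
    if n_distinct < 100 and not (config.exhaustive or config.allow_few_relabelings):
        raise ValueError(
            f"only {n_distinct} distinct relabelings exist; too few for a "
            "Monte-Carlo null (use exhaustive=True for small samples)"
        )
    if config.exhaustive:
        for comb_idx in combinations(range(n_total), n1):
            m = np.zeros(n_total, dtype=bool)
            m[list(comb_idx)] = True
            yield m
    else:
        for _ in range(config.n_permutations):
            m = np.zeros(n_total, dtype=bool)
            m[rng.choice(n_total, size=n1, replace=False)] = True
            yield m


def cluster_permutation_test(
    values: np.ndarray,
    groups,
    adjacency,
    config: CBPTConfig | None = None,
    group_order: tuple[str, str] | None = None,
    seed: str = "",
    band: str = "",
) -> list[ClusterResult]:
    """Cluster-based Monte-Carlo permutation test on per-source group means.

    Observed clusters come from :func:`find_clusters`; the null is the
    distribution over group-size-preserving relabelings of the maximum
    |cluster mass| (over both signs by default, per sign optionally). Each
    observed cluster's p is ``(1 + #{null >= |mass|}) / (N + 1)`` in
    Monte-Carlo mode, or the exact proportion over all distinct relabelings
    in exhaustive mode. Results are sorted by p.
    """
    config = config or CBPTConfig()
    values = np.asarray(values, dtype=np.float64)
    m1, m2, order = _group_masks(groups, group_order)
    reorder = np.concatenate([np.flatnonzero(m1), np.flatnonzero(m2)])
    x = values[reorder]
    n1 = int(m1.sum())
    n_total = x.shape[0]

    adj = _as_sparse(adjacency)
    if adj.shape[0] != values.shape[1]:
        raise ValueError("adjacency does not cover the sources")

    t_obs, df = _t_stat(x[:n1], x[n1:], config.t_variant)
    df_scalar = float(np.mean(df)) if config.t_variant == "welch" else float(df)
    t_crit = float(stats.t.isf(config.cluster_forming_alpha / 2.0, df_scalar))
    observed = _clusters_from_t(t_obs, t_crit, adj)

    rng = np.random.default_rng(config.rng_seed)
    per_sign = config.max_stat == "per_sign"
    null_max: list[float] = []
    null_max_neg: list[float] = []
    for mask in _relabelings(n_total, n1, rng, config):
        t_p, _ = _t_stat(x[mask], x[~mask], config.t_variant)
        clusters = _clusters_from_t(t_p, t_crit, adj)
        if per_sign:
            pos = [c.mass for c in clusters if c.sign == "positive"]
            neg = [abs(c.mass) for c in clusters if c.sign == "negative"]
            null_max.append(max(pos, default=0.0))
            null_max_neg.append(max(neg, default=0.0))
        else:
            null_max.append(max((abs(c.mass) for c in clusters), default=0.0))
    null_arr = np.asarray(null_max)
    null_neg_arr = np.asarray(null_max_neg) if per_sign else None
    n_perm = len(null_arr)

    results = []
    for c in observed:
        ref = null_arr
        if per_sign and c.sign == "negative":
            ref = null_neg_arr
        k = int((ref >= abs(c.mass) - 1e-12).sum())
        if config.exhaustive:
            p = k / n_perm  # observed labeling is included, so k >= 1
        else:
            p = (1 + k) / (n_perm + 1)
        results.append(
            ClusterResult(
                indices=c.indices,
                mass=c.mass,
                sign=c.sign,
                p_value=float(p),
                n_permutations=n_perm,
            )
        )
    results.sort(key=lambda r: (r.p_value, -abs(r.mass)))
    return results


def rsn_group_test(
    rsn_values: np.ndarray,
    groups,
    network: str = "",
    band: str = "",
    group_order: tuple[str, str] | None = None,
    variant: str = "pooled",
) -> RSNTestResult:
    """Two-sided independent-samples t-test of one RSN's mean FC.

    Uncorrected across networks and bands, mirroring how intra-network
    comparisons are conventionally reported.
    """
    rsn_values = np.asarray(rsn_values, dtype=np.float64)
    m1, m2, order = _group_masks(groups, group_order)
    x1, x2 = rsn_values[m1], rsn_values[m2]
    t, df = _t_stat(x1[:, None], x2[:, None], variant)
    t = float(t[0])
    df = float(df if np.isscalar(df) else df[0])
    p = float(2.0 * stats.t.sf(abs(t), df))
    return RSNTestResult(
        network=network,
        band=band,
        mean1=float(x1.mean()),
        mean2=float(x2.mean()),
        t=t,
        p=p,
        n1=len(x1),
        n2=len(x2),
    )
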