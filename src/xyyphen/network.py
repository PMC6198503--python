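"""Bootstrap consensus feature-network analysis of phenotype variables.

The pipeline that turns a participant-by-variable table into phenotypic
modules:

1. pairwise Pearson correlations (pairwise-complete over missing data);
2. a one-shot filter removing variables whose scaled mean correlation with
   the rest falls below a threshold (default -2);
3. B bootstrap draws of participants (with replacement); per draw, the
   correlation matrix is re-estimated, the number of clusters k is chosen
   by the gap statistic, and the variables are cut into k clusters by
   average-linkage hierarchical clustering on distance d = 1 - r;
4. a consensus (co-clustering) matrix: the proportion of draws in which
   each variable pair shared a cluster;
5. module detection on the weighted consensus graph by the consensus of L
   Louvain runs at resolution gamma (association-matrix reclustering
   iterated to convergence), with gamma selectable from the mean nodal
   versatility curve;
6. export as GraphML / edge list / node table with seeded force-directed
   coordinates.

Randomness is governed by one master seed; per-draw sub-seeds are derived
counter-style (``SeedSequence([seed, draw])``) so changing B leaves earlier
draws untouched and draws may be evaluated in any order.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CorrelationMatrix",
    "FilterReport",
    "BootstrapPartitionSet",
    "ConsensusMatrix",
    "ModulePartition",
    "pairwise_correlations",
    "filter_variables",
    "gap_statistic_k",
    "cluster_variables",
    "bootstrap_cocluster",
    "louvain_consensus",
    "versatility_curve",
    "export_network",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Variable x variable Pearson correlations with per-pair effective n.

    ``undefined`` lists variables whose correlations could not be computed
    (constant or all-missing columns); their rows/columns are NaN.
    """

    r: pd.DataFrame
    n_eff: pd.DataFrame
    undefined: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = self.r.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("correlation matrix must be square")
        mask = ~np.isnan(a)
        if not np.allclose(np.where(mask & mask.T, a, 0.0),
                           np.where(mask & mask.T, a.T, 0.0), atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        finite = a[np.isfinite(a)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("correlations outside [-1, 1]")

    @property
    def variables(self) -> list[str]:
        return list(self.r.index)

    def defined(self) -> "CorrelationMatrix":
        keep = [v for v in self.variables if v not in self.undefined]
        return CorrelationMatrix(self.r.loc[keep, keep], self.n_eff.loc[keep, keep], ())


def pairwise_correlations(data: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations.

    Pairs with fewer than ``min_n`` joint observations, and variables that
    are constant over their observed values, yield NaN and are flagged.
    """
    if data.shape[1] < 2:
        raise ValueError("need at least two variables")
    x = data.astype(float)
    undefined = tuple(
        c for c in x.columns
        if x[c].notna().sum() < min_n or np.nanstd(x[c].to_numpy(), ddof=0) == 0
    )
    r = x.corr(method="pearson", min_periods=min_n)
    notna = x.notna().to_numpy().astype(float)
    n_eff = pd.DataFrame(notna.T @ notna, index=x.columns, columns=x.columns).astype(int)
    for c in undefined:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
    np.fill_diagonal(r.to_numpy(), 1.0)
    for c in undefined:
        r.loc[c, c] = np.nan
    return CorrelationMatrix(r, n_eff, undefined)


@dataclass(frozen=True)
class FilterReport:
    """Scaled-mean-correlation filter outcome.

    ``m`` is each variable's mean off-diagonal correlation, ``z`` its
    standardization over variables; variables with z < tau are removed,
    once (the filter is not iterated).
    """

    table: pd.DataFrame  # columns: variable, mean_r, scaled, removed
    tau: float

    @property
    def removed(self) -> list[str]:
        return list(self.table.loc[self.table["removed"], "variable"])

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[~self.table["removed"], "variable"])


def filter_variables(corr: CorrelationMatrix, tau: float = -2.0) -> FilterReport:
    """Remove variables whose scaled mean correlation falls below ``tau``.

    Applied once on the full-sample correlation matrix.  A zero spread of
    the mean correlations (all equal) removes nothing, with a warning.
    """
    cm = corr.defined()
    names = cm.variables
    if len(names) < 3:
        raise ValueError("need at least three variables with defined correlations")
    a = cm.r.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, np.nan)
    m = np.nanmean(a, axis=1)
    sd = np.std(m, ddof=1)
    if sd == 0:
        warnings.warn("all mean correlations equal: nothing removed", stacklevel=2)
        z = np.zeros_like(m)
        removed = np.zeros(len(names), dtype=bool)
    else:
        z = (m - m.mean()) / sd
        removed = z < tau
    table = pd.DataFrame(
        {"variable": names, "mean_r": m, "scaled": z, "removed": removed}
    )
    # variables with undefined correlations cannot be scored; carry them as removed
    for v in corr.undefined:
        table = pd.concat(
            [table, pd.DataFrame([{"variable": v, "mean_r": np.nan, "scaled": np.nan, "removed": True}])],
            ignore_index=True,
        )
    return FilterReport(table, tau)


def _within_dispersion(d2: np.ndarray, labels: np.ndarray) -> float:
    """W_k: sum over clusters of (sum of pairwise squared distances)
    divided by twice the cluster size."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size > 1:
            w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return w


def _dispersion_curve(d2: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """log W_k for each column of ``cuts`` (labels per k), vectorized."""
    p = d2.shape[0]
    out = np.empty(cuts.shape[1])
    for j in range(cuts.shape[1]):
        col = cuts[:, j]
        k = int(col.max()) + 1
        m = np.zeros((p, k))
        m[np.arange(p), col] = 1.0
        sums = np.einsum("ik,ij,jk->k", m, d2, m)
        sizes = m.sum(axis=0)
        out[j] = np.log(max(float((sums / (2.0 * sizes)).sum()), 1e-300))
    return out


def _cut_all(zl: np.ndarray, p: int, k_max: int) -> np.ndarray:
    """Labels (p x k_max, columns k = 1..k_max, 0-based labels) for every
    cut of an agglomerative tree, by replaying the merge sequence."""
    cur = np.arange(2 * p - 1)[:p].copy()
    snapshots: dict[int, np.ndarray] = {}
    if p <= k_max:
        snapshots[p] = cur.copy()
    for t in range(p - 1):
        i, j = int(zl[t, 0]), int(zl[t, 1])
        cur[(cur == i) | (cur == j)] = p + t
        k = p - t - 1
        if 1 <= k <= k_max:
            snapshots[k] = cur.copy()
    out = np.empty((p, k_max), dtype=int)
    for k in range(1, k_max + 1):
        _, inv = np.unique(snapshots[k], return_inverse=True)
        out[:, k - 1] = inv
    return out


def _corr_distance(r: np.ndarray, use_abs: bool) -> np.ndarray:
    d = 1.0 - (np.abs(r) if use_abs else r)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def _gap_select(
    r: np.ndarray,
    k_max: int,
    n_ref: int,
    rng: np.random.Generator,
    method: str,
    use_abs: bool,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Fast gap-statistic core on a defined correlation matrix.

    Returns (selected k, gap curve, s curve).  Observed partitions cut the
    d = 1 - r average-linkage tree; dispersion is squared Euclidean between
    correlation profiles; reference profiles are uniform over each
    coordinate's observed range, clustered on Euclidean distance.
    """
    p = r.shape[0]
    k_max = max(1, min(k_max, p))
    ks = list(range(1, k_max + 1))
    zl_obs = linkage(squareform(_corr_distance(r, use_abs), checks=False), method=method)
    cuts_obs = _cut_all(zl_obs, p, k_max)
    d2_obs = squareform(pdist(r, metric="sqeuclidean"), checks=False)
    log_w_obs = _dispersion_curve(d2_obs, cuts_obs)

    lo, hi = r.min(axis=0), r.max(axis=0)
    log_w_ref = np.empty((n_ref, k_max))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=r.shape)
        dr = pdist(ref, metric="euclidean")
        zl = linkage(dr, method=method)
        cuts = _cut_all(zl, p, k_max)
        log_w_ref[b] = _dispersion_curve(squareform(dr**2, checks=False), cuts)

    gap = log_w_ref.mean(axis=0) - log_w_obs
    s = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / n_ref)
    selected = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            selected = k
            break
    return selected, gap, s


def cluster_variables(corr: CorrelationMatrix, k: int, method: str = "average",
                      use_abs: bool = False) -> pd.Series:
    """Cut an average-linkage tree on distance d = 1 - r into k clusters.

    With ``use_abs`` the distance is 1 - |r| instead.  Variables with
    undefined correlations are excluded (callers track them per draw).
    """
    cm = corr.defined()
    names = cm.variables
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(names))
    r = cm.r.to_numpy(dtype=float)
    d = 1.0 - (np.abs(r) if use_abs else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    if len(names) == 1 or k == 1:
        return pd.Series(np.ones(len(names), dtype=int), index=names)
    zl = linkage(squareform(d, checks=False), method=method)
    labels = fcluster(zl, t=k, criterion="maxclust")
    return pd.Series(labels, index=names)


def gap_statistic_k(
    corr: CorrelationMatrix,
    k_max: int = 8,
    n_ref: int = 50,
    seed: int = 0,
    method: str = "average",
    use_abs: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Select the number of clusters by the gap statistic.

    Each variable is represented by its correlation profile (its row of the
    correlation matrix).  Observed partitions come from the same
    hierarchical cut used downstream (d = 1 - r, average linkage); the
    reference distribution draws profiles uniformly over each coordinate's
    observed range and clusters them by average linkage on Euclidean
    distance.  Dispersion W_k uses squared Euclidean distance between
    profiles on both sides.  The selected k is the smallest with
    Gap(k) >= Gap(k+1) - s(k+1); the full curve is returned.
    """
    cm = corr.defined()
    names = cm.variables
    p = len(names)
    if p < 2:
        return 1, pd.DataFrame({"k": [1], "gap": [0.0], "s": [0.0]})
    if n_ref < 10:
        raise ValueError("n_ref must be >= 10")
    if k_max > p:
        warnings.warn(f"k_max {k_max} exceeds variable count {p}; clipped", stacklevel=2)
    rng = np.random.default_rng(seed)
    selected, gap, s = _gap_select(
        cm.r.to_numpy(dtype=float), k_max, n_ref, rng, method, use_abs
    )
    curve = pd.DataFrame({"k": np.arange(1, gap.size + 1), "gap": gap, "s": s})
    return int(selected), curve


@dataclass
class BootstrapPartitionSet:
    """Per-draw partitions from the bootstrap: selected k, variable labels
    (NaN where a variable was undefined in that draw), and the resampled
    participant indices for audit."""

    partitions: pd.DataFrame  # draws x variables, cluster labels
    selected_k: np.ndarray
    resample_indices: np.ndarray  # draws x n participants
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.partitions)


@dataclass(frozen=True)
class ConsensusMatrix:
    """Co-clustering proportions: fraction of (valid) draws in which each
    variable pair shared a cluster."""

    c: pd.DataFrame
    n_valid: pd.DataFrame  # per-pair count of draws where both were defined
    n_draws: int

    def __post_init__(self) -> None:
        a = self.c.to_numpy(dtype=float)
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("consensus matrix must be symmetric")
        if np.nanmin(a) < -1e-12 or np.nanmax(a) > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("consensus diagonal must be 1")

    @property
    def variables(self) -> list[str]:
        return list(self.c.index)


def bootstrap_cocluster(
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    k_max: int = 8,
    n_ref: int = 50,
    method: str = "average",
    use_abs: bool = False,
    min_n: int = 3,
) -> tuple[BootstrapPartitionSet, ConsensusMatrix]:
    """Bootstrap co-clustering of variables.

    Per draw: resample participants with replacement, recompute pairwise
    correlations, pick k by the gap statistic, cut the hierarchy.  The
    consensus entry (i, j) is the fraction of draws (among those where both
    variables were defined) clustering i with j.  Sub-seeds are derived per
    draw from the master seed, so results do not depend on execution order
    and extending B preserves earlier draws.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    names = list(data.columns)
    p = len(names)
    n = len(data)
    co = np.zeros((p, p))
    valid = np.zeros((p, p))
    part_rows = np.full((n_boot, p), np.nan)
    ks = np.zeros(n_boot, dtype=int)
    indices = np.empty((n_boot, n), dtype=int)
    x = data.to_numpy(dtype=float)
    any_missing = bool(np.isnan(x).any())
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        idx = rng.integers(0, n, n)
        indices[b] = idx
        sample = x[idx]
        if any_missing:
            corr = pairwise_correlations(pd.DataFrame(sample, columns=names), min_n=min_n)
            defined_mask = np.array([v not in corr.undefined for v in names])
            r = corr.r.to_numpy(dtype=float)[np.ix_(defined_mask, defined_mask)]
            # pairs with too few joint observations: treat as uncorrelated
            r = np.where(np.isnan(r), 0.0, r)
            np.fill_diagonal(r, 1.0)
        else:
            with np.errstate(invalid="ignore"):
                sds = sample.std(axis=0, ddof=0)
            defined_mask = sds > 0
            r = np.corrcoef(sample[:, defined_mask], rowvar=False)
        col_idx = np.flatnonzero(defined_mask)
        if col_idx.size < 2:
            ks[b] = 0
            continue
        k, _, _ = _gap_select(r, k_max, n_ref, rng, method, use_abs)
        zl = linkage(
            squareform(_corr_distance(r, use_abs), checks=False), method=method
        )
        kk = min(k, col_idx.size)
        lab = _cut_all(zl, col_idx.size, kk)[:, kk - 1] + 1
        ks[b] = k
        part_rows[b, col_idx] = lab
        same = (lab[:, None] == lab[None, :]).astype(float)
        co[np.ix_(col_idx, col_idx)] += same
        valid[np.ix_(col_idx, col_idx)] += 1.0
    with np.errstate(invalid="ignore"):
        c = np.where(valid > 0, co / np.where(valid > 0, valid, 1), np.nan)
    np.fill_diagonal(c, 1.0)
    consensus = ConsensusMatrix(
        pd.DataFrame(c, index=names, columns=names),
        pd.DataFrame(valid.astype(int), index=names, columns=names),
        n_boot,
    )
    partitions = pd.DataFrame(part_rows, columns=names)
    return BootstrapPartitionSet(partitions, ks, indices, seed), consensus


@dataclass
class ModulePartition:
    """Final module assignment with stability diagnostics."""

    labels: pd.Series  # variable -> module id (contiguous from 1)
    gamma: float
    n_runs: int
    versatility: pd.Series  # per-variable assignment inconsistency in [0,1]
    strength: pd.Series  # mean off-diagonal correlation per variable (node size)
    modularity: float
    n_consensus_iterations: int = 1

    def __post_init__(self) -> None:
        labs = sorted(self.labels.unique())
        if labs != list(range(1, len(labs) + 1)):
            raise ValueError("module labels must be contiguous from 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        v = self.versatility.to_numpy(dtype=float)
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("versatility must lie in [0, 1]")

    @property
    def n_modules(self) -> int:
        return int(self.labels.nunique())


def _louvain_runs(w: np.ndarray, gamma: float, n_runs: int, seed: int) -> np.ndarray:
    """Memberships (runs x nodes) from repeated seeded Louvain runs on a
    weighted adjacency (diagonal ignored)."""
    p = w.shape[0]
    a = w.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    a = np.where(np.isnan(a), 0.0, a)
    g = ig.Graph.Weighted_Adjacency(a.tolist(), mode="undirected", attr="weight", loops=False)
    if g.ecount() == 0:
        # no edges: every node its own community in every run
        return np.tile(np.arange(p), (n_runs, 1))
    weights = g.es["weight"]
    out = np.empty((n_runs, p), dtype=int)
    ss = np.random.SeedSequence([seed, 1_000_003])
    sub = ss.generate_state(n_runs)
    for i in range(n_runs):
        random.seed(int(sub[i]))
        out[i] = g.community_multilevel(weights=weights, resolution=gamma).membership
    return out


def _association(memberships: np.ndarray) -> np.ndarray:
    """Fraction of runs co-assigning each node pair."""
    L = memberships.shape[0]
    co = np.zeros((memberships.shape[1],) * 2)
    for row in memberships:
        co += row[:, None] == row[None, :]
    return co / L


def _versatility_from_memberships(memberships: np.ndarray) -> np.ndarray:
    """Nodal assignment inconsistency across runs.

    For a node i and a pair of runs, agreement on partner j means the two
    runs concur on whether i and j share a module.  Versatility(i) is one
    minus the mean agreement over all partners and run pairs; 0 when every
    run assigns i identically, approaching 1 under maximal instability.
    """
    L, p = memberships.shape
    if L < 2 or p < 2:
        return np.zeros(p)
    co = np.zeros((p, p))
    for row in memberships:
        co += row[:, None] == row[None, :]
    agree = (co * (co - 1) + (L - co) * (L - co - 1)) / (L * (L - 1))
    np.fill_diagonal(agree, np.nan)
    return 1.0 - np.nanmean(agree, axis=1)


def louvain_consensus(
    consensus: ConsensusMatrix,
    gamma: float = 1.2,
    n_runs: int = 1000,
    seed: int = 0,
    max_iter: int = 20,
    corr: CorrelationMatrix | None = None,
) -> ModulePartition:
    """Consensus of repeated Louvain runs on the weighted consensus graph.

    L seeded Louvain runs are performed at resolution ``gamma``; if they
    disagree, the run-association matrix (pairwise co-assignment fraction)
    is itself reclustered by another round of L runs, iterating until all
    runs agree (the standard consensus-clustering scheme).  Versatility is
    computed from the first-round runs on the original consensus matrix.
    Node ``strength`` (the plot's node-size rule: mean pairwise correlation
    of a variable with all others) is taken from ``corr`` when supplied,
    otherwise from the consensus weights.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    names = consensus.variables
    w = consensus.c.to_numpy(dtype=float)
    if len(names) == 0:
        raise ValueError("empty consensus matrix")
    memberships = _louvain_runs(w, gamma, n_runs, seed)
    versatility = _versatility_from_memberships(memberships)
    n_iter = 1
    current = memberships
    while n_iter < max_iter and not (current == current[0]).all():
        assoc = _association(current)
        current = _louvain_runs(assoc, gamma, n_runs, seed + n_iter)
        n_iter += 1
    final = current[0]
    # relabel contiguously from 1, ordered by first appearance
    _, labels = np.unique(final, return_inverse=True)
    order = {}
    relabeled = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        relabeled[i] = order[lab]
    if relabeled.max() == len(names) and len(names) > 1:
        warnings.warn("every node is a singleton module at this gamma", stacklevel=2)

    a = w.copy()
    np.fill_diagonal(a, 0.0)
    g = ig.Graph.Weighted_Adjacency(np.where(np.isnan(a), 0, a).tolist(),
                                    mode="undirected", attr="weight", loops=False)
    if g.ecount() > 0:
        q = g.modularity(list(relabeled - 1), weights=g.es["weight"], resolution=gamma)
    else:
        q = float("nan")
    if corr is not None:
        sm = corr.r.loc[names, names].to_numpy(dtype=float).copy()
    else:
        sm = w.copy()
    np.fill_diagonal(sm, np.nan)
    strength = np.nanmean(sm, axis=1)
    return ModulePartition(
        labels=pd.Series(relabeled, index=names),
        gamma=gamma,
        n_runs=n_runs,
        versatility=pd.Series(np.clip(versatility, 0.0, 1.0), index=names),
        strength=pd.Series(strength, index=names),
        modularity=float(q),
        n_consensus_iterations=n_iter,
    )


def versatility_curve(
    consensus: ConsensusMatrix,
    gamma_grid: np.ndarray | None = None,
    n_runs: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Mean nodal versatility as a function of the Louvain resolution.

    For each gamma, L runs are performed and the global mean versatility
    recorded.  gamma* is the first interior local minimum of the curve
    (ties resolved toward the smallest gamma); a perfectly flat curve
    returns the grid midpoint with a warning.
    """
    if gamma_grid is None:
        gamma_grid = np.round(np.arange(0.5, 2.0 + 1e-9, 0.05), 10)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size < 3:
        raise ValueError("gamma grid needs at least 3 points")
    if not np.all(np.diff(gamma_grid) > 0):
        raise ValueError("gamma grid must be strictly increasing")
    w = consensus.c.to_numpy(dtype=float)
    mean_v = np.empty(gamma_grid.size)
    n_mods = np.empty(gamma_grid.size, dtype=int)
    for i, gam in enumerate(gamma_grid):
        memberships = _louvain_runs(w, float(gam), n_runs, seed + 7919 * i)
        mean_v[i] = float(np.mean(_versatility_from_memberships(memberships)))
        n_mods[i] = int(np.median([np.unique(m).size for m in memberships]))
    curve = pd.DataFrame({"gamma": gamma_grid, "mean_versatility": mean_v,
                          "median_n_modules": n_mods})
    if np.ptp(mean_v) == 0:
        warnings.warn("flat versatility curve; returning grid midpoint", stacklevel=2)
        return curve, float(gamma_grid[gamma_grid.size // 2])
    gamma_star = None
    for i in range(1, gamma_grid.size - 1):
        if mean_v[i] <= mean_v[i - 1] and mean_v[i] <= mean_v[i + 1]:
            gamma_star = float(gamma_grid[i])
            break
    if gamma_star is None:
        # monotone curve: take the end with the smaller versatility
        gamma_star = float(gamma_grid[int(np.argmin(mean_v))])
    return curve, gamma_star


def export_network(
    consensus: ConsensusMatrix,
    partition: ModulePartition,
    out_dir,
    edge_threshold: float = 0.0,
    layout_seed: int = 0,
    layout: bool = True,
):
    """Write the consensus network: GraphML, a weighted edge list (TSV),
    and a node table (module, versatility, strength), with seeded
    Fruchterman-Reingold coordinates embedded when ``layout`` is set.
    Returns the ``networkx`` graph."""
    import networkx as nx
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = consensus.variables
    g = nx.Graph()
    for v in names:
        g.add_node(
            v,
            module=int(partition.labels[v]),
            versatility=float(partition.versatility[v]),
            strength=float(partition.strength[v]),
        )
    c = consensus.c.to_numpy(dtype=float)
    for i, vi in enumerate(names):
        for j in range(i + 1, len(names)):
            wij = c[i, j]
            if np.isfinite(wij) and wij > edge_threshold:
                g.add_edge(vi, names[j], weight=round(float(wij), 9))
    if layout and g.number_of_nodes() > 0:
        pos = nx.spring_layout(g, seed=layout_seed, weight="weight")
        for v, (x, y) in pos.items():
            g.nodes[v]["x"] = round(float(x), 9)
            g.nodes[v]["y"] = round(float(y), 9)
    nx.write_graphml(g, out_dir / "network.graphml")
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in sorted(g.edges(data=True))],
        columns=["var_i", "var_j", "consensus"],
    )
    edges.to_csv(out_dir / "edges.tsv", sep="\t", index=False, float_format="%.9g")
    nodes = pd.DataFrame(
        {
            "variable": names,
            "module": [int(partition.labels[v]) for v in names],
            "versatility": [float(partition.versatility[v]) for v in names],
            "strength": [float(partition.strength[v]) for v in names],
        }
    )
    nodes.to_csv(out_dir / "nodes.csv", index=False, float_format="%.9g")
    return g
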