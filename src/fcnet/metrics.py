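"""Graph-topology metrics on binary networks.

Global measures (clustering coefficient Cp, characteristic path length Lp,
global/local efficiency), nodal measures (degree, nodal efficiency,
betweenness centrality), normalization of Cp and Lp against ensembles of
degree-preserving rewired null graphs (gamma, lambda, and the small-world
scalar sigma = gamma/lambda), and AUC summarization of metric-versus-sparsity
curves.

All functions take a dense binary adjacency matrix (symmetric, zero
diagonal).  Distances are unweighted shortest-path hop counts; unreachable
pairs have infinite distance, which efficiency-type metrics map to zero and
Lp handles by averaging over reachable pairs only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: Default size of the degree-preserving null ensemble.
DEFAULT_N_RANDOM = 100
#: Swap-attempt budget per null as a multiple of the edge count.
DEFAULT_SWAP_FACTOR = 10


# ---------------------------------------------------------------------------
# jit-compiled graph kernels (pure-python / scipy fallbacks below)
# ---------------------------------------------------------------------------

def _dense_to_csr_arrays(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(indptr, indices) adjacency-list arrays from a dense 0/1 matrix."""
    rows, cols = np.nonzero(a)
    n = a.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=n), out=indptr[1:])
    return indptr, cols.astype(np.int64)


def _bfs_all_pairs_py(indptr, indices, n):
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0.0
        queue = np.empty(n, dtype=np.int64)
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            v = queue[head]
            head += 1
            dv = dist[s, v]
            for ptr in range(indptr[v], indptr[v + 1]):
                w = indices[ptr]
                if dist[s, w] == np.inf:
                    dist[s, w] = dv + 1.0
                    queue[tail] = w
                    tail += 1
    return dist


def _brandes_py(indptr, indices, n):
    bc = np.zeros(n)
    sigma = np.zeros(n)
    dist = np.zeros(n, dtype=np.int64)
    delta = np.zeros(n)
    order = np.zeros(n, dtype=np.int64)
    for s in range(n):
        sigma[:] = 0.0
        sigma[s] = 1.0
        dist[:] = -1
        dist[s] = 0
        delta[:] = 0.0
        head, tail = 0, 1
        order[0] = s
        while head < tail:
            v = order[head]
            head += 1
            dv = dist[v]
            for ptr in range(indptr[v], indptr[v + 1]):
                w = indices[ptr]
                if dist[w] < 0:
                    dist[w] = dv + 1
                    order[tail] = w
                    tail += 1
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
        for i in range(tail - 1, -1, -1):
            v = order[i]
            for ptr in range(indptr[v], indptr[v + 1]):
                w = indices[ptr]
                if dist[w] == dist[v] + 1:
                    delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
        delta[s] = 0.0
        bc += delta
    return bc / 2.0


def _local_efficiency_py(a, indptr, indices, n):
    total = 0.0
    sub_dist = np.empty(n)
    queue = np.empty(n, dtype=np.int64)
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k < 2:
            continue
        nbrs = indices[indptr[i]:indptr[i + 1]]
        inv_sum = 0.0
        for si in range(k):
            s = nbrs[si]
            sub_dist[:k] = np.inf
            sub_dist[si] = 0.0
            queue[0] = si
            head, tail = 0, 1
            while head < tail:
                vi = queue[head]
                head += 1
                v = nbrs[vi]
                dv = sub_dist[vi]
                for wi in range(k):
                    if a[v, nbrs[wi]] and sub_dist[wi] == np.inf:
                        sub_dist[wi] = dv + 1.0
                        queue[tail] = wi
                        tail += 1
            for wi in range(k):
                if wi != si and sub_dist[wi] != np.inf:
                    inv_sum += 1.0 / sub_dist[wi]
        total += inv_sum / (k * (k - 1.0))
    return total / n


if _HAVE_NUMBA:
    _bfs_all_pairs = njit(cache=True)(_bfs_all_pairs_py)
    _brandes = njit(cache=True)(_brandes_py)
    _local_efficiency_kernel = njit(cache=True)(_local_efficiency_py)
else:  # pragma: no cover
    _bfs_all_pairs = _bfs_all_pairs_py
    _brandes = _brandes_py
    _local_efficiency_kernel = _local_efficiency_py


# ---------------------------------------------------------------------------
# distances and global metrics
# ---------------------------------------------------------------------------

def all_pairs_shortest_paths(adjacency: np.ndarray) -> np.ndarray:
    """Unweighted shortest-path distance matrix (np.inf if unreachable)."""
    a = np.asarray(adjacency)
    if _HAVE_NUMBA:
        indptr, indices = _dense_to_csr_arrays(a)
        return _bfs_all_pairs(indptr, indices, a.shape[0])
    return _csgraph_shortest_path(  # pragma: no cover
        csr_matrix(a), method="D", directed=False, unweighted=True
    )


def clustering(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cp.

    A node's coefficient is the fraction of its neighbour pairs that are
    themselves connected, ``2*t_i / (k_i*(k_i-1))`` with ``t_i`` the number
    of triangles through node i; nodes of degree < 2 contribute 0.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    triangles2 = ((a @ a) * a).sum(axis=1)  # = diag(A^3) = 2*t_i
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles2 / denom, 0.0)
    return c, float(c.mean())


def path_length(distances: np.ndarray) -> tuple[float, int]:
    """Characteristic path length Lp over reachable ordered pairs.

    Returns ``(Lp, n_unreachable_pairs)`` where the count is over ordered
    off-diagonal pairs.  On connected graphs the count is 0 and Lp is the
    usual mean shortest-path length.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    n_unreachable = int((~finite).sum())
    if not finite.any():
        raise ValueError("no reachable pairs: graph has no edges")
    if n_unreachable:
        logger.debug("Lp over %d reachable of %d pairs", finite.sum(), vals.size)
    return float(vals[finite].mean()), n_unreachable


def global_efficiency(distances: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    a = np.ascontiguousarray(adjacency, dtype=np.uint8)
    indptr, indices = _dense_to_csr_arrays(a)
    return float(_local_efficiency_kernel(a, indptr, indices, a.shape[0]))


# ---------------------------------------------------------------------------
# nodal metrics
# ---------------------------------------------------------------------------

def nodal_degree(adjacency: np.ndarray) -> np.ndarray:
    """Degree of every node (row sums)."""
    return np.asarray(adjacency).sum(axis=1).astype(np.int64)


def nodal_efficiency(distances: np.ndarray) -> np.ndarray:
    """Inverse harmonic mean of each node's distances to all others.

    ``E_nodal,i = (1/(n-1)) * sum_{j != i} 1/d_ij`` — finite on disconnected
    graphs (unreachable pairs contribute 0), which is why it is preferred
    over path length for nodal comparisons.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness(adjacency: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Betweenness centrality via Brandes' accumulation.

    For every node pair (s, t) the fraction of shortest s-t paths passing
    through node i is accumulated; endpoints are excluded.  Returned
    unnormalized by default (each unordered pair contributes at most 1);
    ``normalized=True`` divides by ``(n-1)(n-2)/2``.
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    indptr, indices = _dense_to_csr_arrays(a)
    bc = _brandes(indptr, indices, n)
    if normalized and n > 2:
        bc = bc / ((n - 1) * (n - 2) / 2.0)
    return bc


# ---------------------------------------------------------------------------
# degree-preserving null models
# ---------------------------------------------------------------------------

def _swap_kernel_py(adj, u, v, idx, flip):
    n_attempts = idx.shape[0]
    m = u.shape[0]
    for t in range(n_attempts):
        e1 = idx[t, 0] % m
        e2 = idx[t, 1] % m
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if flip[t]:
            c, d = d, c
        # propose a-b, c-d -> a-d, c-b
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        u[e1], v[e1] = a, d
        u[e2], v[e2] = c, b


if _HAVE_NUMBA:
    _swap_kernel = njit(cache=True)(_swap_kernel_py)
else:  # pragma: no cover
    _swap_kernel = _swap_kernel_py


def rewire_null(
    adjacency: np.ndarray,
    n_swaps_factor: int = DEFAULT_SWAP_FACTOR,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Degree-preserving randomization by Markov-chain double-edge swaps.

    Repeatedly picks two edges (a-b, c-d) and rewires them to (a-d, c-b),
    rejecting proposals that would create self-loops or multi-edges, so the
    degree sequence is conserved exactly.  The attempt budget is
    ``n_swaps_factor`` times the edge count.  Graphs admitting no valid swap
    (e.g. a triangle) are returned as a copy with a warning.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(adjacency, dtype=np.uint8).copy()
    iu, ju = np.triu_indices(a.shape[0], k=1)
    on = a[iu, ju] > 0
    u = iu[on].astype(np.int64).copy()
    v = ju[on].astype(np.int64).copy()
    m = u.size
    if m < 2:
        warnings.warn("graph has < 2 edges; returning a copy", stacklevel=2)
        return a
    budget = int(n_swaps_factor * m)
    idx = rng.integers(0, m, size=(budget, 2))
    flip = rng.integers(0, 2, size=budget).astype(np.bool_)
    before = a.copy()
    _swap_kernel(a, u, v, idx, flip)
    if np.array_equal(before, a):
        warnings.warn("no valid double-edge swap found; null equals input",
                      stacklevel=2)
    return a


def null_ensemble(
    adjacency: np.ndarray,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int | np.random.SeedSequence | None = None,
    n_swaps_factor: int = DEFAULT_SWAP_FACTOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Cp and Lp for ``n_random`` degree-preserving nulls.

    Returns ``(cp_null, lp_null)`` arrays of length ``n_random``.  Child
    seeds are spawned deterministically from ``seed`` so a fixed seed
    reproduces the ensemble bit-exactly.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = seq.spawn(n_random)
    cp = np.empty(n_random)
    lp = np.empty(n_random)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny graphs may admit no swap
        for i, child in enumerate(children):
            null = rewire_null(adjacency, n_swaps_factor, seed=child)
            _, cp[i] = clustering(null)
            lp[i], _ = path_length(all_pairs_shortest_paths(null))
    return cp, lp


def small_world_indices(
    adjacency: np.ndarray,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int | np.random.SeedSequence | None = None,
    n_swaps_factor: int = DEFAULT_SWAP_FACTOR,
) -> tuple[float, float, float]:
    """Normalized small-world indices (gamma, lambda, sigma).

    gamma = Cp / mean(Cp of nulls), lambda = Lp / mean(Lp of nulls),
    sigma = gamma / lambda.  A small-world network has gamma > 1 with
    lambda close to 1, hence sigma > 1.
    """
    _, cp = clustering(adjacency)
    lp, _ = path_length(all_pairs_shortest_paths(adjacency))
    cp_null, lp_null = null_ensemble(adjacency, n_random, seed, n_swaps_factor)
    c_rand = float(cp_null.mean())
    l_rand = float(lp_null.mean())
    if c_rand <= 0:
        raise ValueError("degenerate null ensemble: mean null clustering is 0")
    gamma = cp / c_rand
    lam = lp / l_rand
    return gamma, lam, gamma / lam


# ---------------------------------------------------------------------------
# curves over the sparsity grid and AUC
# ---------------------------------------------------------------------------

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eglo", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


def auc(values: np.ndarray, grid: np.ndarray) -> float:
    """Area under a metric-versus-sparsity curve by the trapezoidal rule.

    A single-point grid has zero width, hence AUC 0.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values and grid differ in length")
    if grid.size < 2:
        return 0.0
    return float(np.trapezoid(values, grid))


@dataclass
class SubjectMetrics:
    """All metrics for one subject across the sparsity grid.

    ``global_curves`` maps metric name -> array over the grid;
    ``nodal_curves`` maps metric name -> (n_nodes, n_grid) array;
    ``*_auc`` hold the corresponding trapezoidal AUC scalars.
    """

    grid: np.ndarray
    global_curves: dict[str, np.ndarray]
    nodal_curves: dict[str, np.ndarray]
    global_auc: dict[str, float]
    nodal_auc: dict[str, np.ndarray]


def metric_curves(
    conn,
    grid: np.ndarray,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int | np.random.SeedSequence | None = None,
    compute_betweenness: bool = True,
    n_swaps_factor: int = DEFAULT_SWAP_FACTOR,
) -> SubjectMetrics:
    """Evaluate every global and nodal metric at every grid sparsity.

    ``conn`` is a :class:`~fcnet.datatypes.ConnectivityMatrix`.  Null-model
    seeds are spawned per threshold from ``seed`` so results are
    reproducible and independent of evaluation order.
    """
    from .netcon import binarize_at_sparsity  # local import: avoid cycle

    grid = np.asarray(grid, dtype=float)
    seq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    n_nodes = conn.n_nodes
    g_curves = {name: np.empty(grid.size) for name in GLOBAL_METRIC_NAMES}
    nodal_names = list(NODAL_METRIC_NAMES) if compute_betweenness \
        else [n for n in NODAL_METRIC_NAMES if n != "betweenness"]
    n_curves = {name: np.empty((n_nodes, grid.size)) for name in nodal_names}

    for ti, t in enumerate(grid):
        net = binarize_at_sparsity(conn, float(t))
        a = net.adjacency
        dist = all_pairs_shortest_paths(a)
        _, cp = clustering(a)
        lp, _ = path_length(dist)
        g_curves["Cp"][ti] = cp
        g_curves["Lp"][ti] = lp
        g_curves["Eglo"][ti] = global_efficiency(dist)
        g_curves["Eloc"][ti] = local_efficiency(a)
        gamma, lam, sig = small_world_indices(
            a, n_random=n_random,
            seed=np.random.SeedSequence(entropy=seq.entropy, spawn_key=(ti,)),
            n_swaps_factor=n_swaps_factor,
        )
        g_curves["gamma"][ti] = gamma
        g_curves["lambda"][ti] = lam
        g_curves["sigma"][ti] = sig
        n_curves["degree"][:, ti] = nodal_degree(a)
        n_curves["nodal_efficiency"][:, ti] = nodal_efficiency(dist)
        if compute_betweenness:
            n_curves["betweenness"][:, ti] = betweenness(a)

    g_auc = {name: auc(vals, grid) for name, vals in g_curves.items()}
    n_auc = {
        name: np.array([auc(vals[i], grid) for i in range(n_nodes)])
        for name, vals in n_curves.items()
    }
    return SubjectMetrics(
        grid=grid, global_curves=g_curves, nodal_curves=n_curves,
        global_auc=g_auc, nodal_auc=n_auc,
    )
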