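"""Functional-network construction.

Per-subject Pearson correlation matrices over ROI time series, Fisher r-to-z
transformation, sparsity-based binarization, and data-driven selection of the
sparsity threshold range.

Sparsity T is the fraction of retained edges out of the n(n-1)/2 possible
undirected edges, so networks compared across subjects or groups have
identical wiring cost.  Binarization keeps the round(T*n(n-1)/2) largest
strictly positive z-values; negative correlations are never turned into
edges by default.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import BinaryNetwork, ConnectivityMatrix, ROITimeSeries

logger = logging.getLogger(__name__)

#: Default sparsity grid (inclusive) used throughout the analysis.
DEFAULT_GRID = (0.11, 0.30, 0.01)
#: Mean-degree criterion factor: min T must give mean degree > factor*log(N).
DEFAULT_DEGREE_FACTOR = 2.0
#: Small-worldness floor for the max-T criterion.
DEFAULT_SIGMA_FLOOR = 1.1
#: Correlations are clipped to +/- this value before atanh.
DEFAULT_CLIP = 1.0 - 1e-6


def sparsity_grid(
    t_min: float = DEFAULT_GRID[0],
    t_max: float = DEFAULT_GRID[1],
    step: float = DEFAULT_GRID[2],
) -> np.ndarray:
    """Inclusive arithmetic grid of sparsity values."""
    if not 0 < t_min <= t_max < 1:
        raise ValueError("need 0 < t_min <= t_max < 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((t_max - t_min) / step)) + 1
    grid = t_min + step * np.arange(n)
    return np.round(grid, 10)


def correlation_matrix(ts: ROITimeSeries) -> np.ndarray:
    """Pearson correlations between all ROI pairs.

    Raises if any ROI has zero variance (its correlation is undefined),
    naming the offending region.
    """
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.roi_labels[i] for i in bad[:5])
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(ts.data)
    # numerical guard: corrcoef can stray a hair outside [-1, 1]
    return np.clip(r, -1.0, 1.0)


def fisher_z(
    r: np.ndarray,
    roi_labels: tuple[str, ...] | None = None,
    clip: float = DEFAULT_CLIP,
) -> ConnectivityMatrix:
    """Fisher r-to-z transform, z = atanh(r), with the diagonal zeroed.

    ``r`` is clipped to (-clip, clip) first so duplicated signals (r = 1)
    map to a large finite z instead of infinity.
    """
    if not 0 < clip < 1:
        raise ValueError("clip must lie in (0, 1)")
    r = np.asarray(r, dtype=float)
    z = np.arctanh(np.clip(r, -clip, clip))
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, 0.0)
    if roi_labels is None:
        roi_labels = tuple(f"ROI{i + 1}" for i in range(z.shape[0])) \
            if z.shape[0] != 90 else None
    if roi_labels is None:
        return ConnectivityMatrix(z=z)
    return ConnectivityMatrix(z=z, roi_labels=roi_labels)


def edge_budget(n_nodes: int, sparsity: float) -> int:
    """Number of edges a sparsity value prescribes: round(T * n(n-1)/2)."""
    return int(round(sparsity * n_nodes * (n_nodes - 1) / 2))


def binarize_at_sparsity(
    conn: ConnectivityMatrix, sparsity: float, use_absolute: bool = False
) -> BinaryNetwork:
    """Threshold a z-matrix into a binary graph at a given sparsity.

    The ``round(T*n(n-1)/2)`` largest strictly positive upper-triangle
    z-values become edges (``use_absolute=True`` ranks by |z| instead).
    Ties are broken by lexicographic (i, j) order for determinism.  If fewer
    eligible values exist than the budget, all of them become edges and a
    warning is logged.
    """
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    n = conn.n_nodes
    budget = edge_budget(n, sparsity)
    iu, ju = np.triu_indices(n, k=1)
    vals = conn.z[iu, ju]
    score = np.abs(vals) if use_absolute else vals
    eligible = score > 0.0
    # sort eligible entries by descending score, ties by (i, j) ascending
    order = np.lexsort((ju, iu, -score))
    order = order[eligible[order]]
    if order.size < budget:
        logger.warning(
            "only %d positive edges available for budget %d at T=%.3f",
            order.size, budget, sparsity,
        )
    chosen = order[:budget]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[chosen], ju[chosen]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=sparsity,
                         roi_labels=conn.roi_labels)


def select_threshold_range(
    conns: list[ConnectivityMatrix],
    grid: np.ndarray | None = None,
    degree_factor: float = DEFAULT_DEGREE_FACTOR,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    n_random: int = 100,
    seed: int | None = None,
    log_base: str = "natural",
) -> np.ndarray:
    """Select the admissible sparsity grid for a cohort.

    Two criteria, applied to every subject at every candidate T:

    1. minimum T — the mean nodal degree ``T*(N-1)`` must exceed
       ``degree_factor * log(N)`` (natural log by default);
    2. maximum T — the small-worldness scalar sigma, computed against
       ``n_random`` degree-preserving nulls, must exceed ``sigma_floor``.

    Returns the sub-grid satisfying both for all subjects; raises with
    per-criterion diagnostics if it is empty.
    """
    from .metrics import small_world_indices  # local import: avoid cycle

    if not conns:
        raise ValueError("need at least one subject")
    if grid is None:
        grid = sparsity_grid()
    n = conns[0].n_nodes
    log_n = np.log(n) if log_base == "natural" else np.log10(n)
    min_mean_degree = degree_factor * log_n

    # criterion 1 is purely combinatorial: mean degree = 2*E/N = T*(N-1)
    mean_degree = grid * (n - 1)
    ok_low = mean_degree > min_mean_degree

    # criterion 2 requires sigma for every subject at every threshold
    rng_seq = np.random.SeedSequence(seed)
    ok_high = np.ones(grid.size, dtype=bool)
    for si, conn in enumerate(conns):
        for ti, t in enumerate(grid):
            if not ok_high[ti]:
                continue
            net = binarize_at_sparsity(conn, float(t))
            sub_seed = np.random.SeedSequence(
                entropy=rng_seq.entropy, spawn_key=(si, ti)
            )
            gamma, lam, sig = small_world_indices(
                net.adjacency, n_random=n_random, seed=sub_seed
            )
            if sig <= sigma_floor:
                ok_high[ti] = False

    admissible = ok_low & ok_high
    if not admissible.any():
        raise ValueError(
            "no admissible sparsity: degree criterion admits "
            f"{ok_low.sum()}/{grid.size} grid values, sigma criterion "
            f"{ok_high.sum()}/{grid.size}; their intersection is empty"
        )
    lo = int(np.flatnonzero(admissible).min())
    hi = int(np.flatnonzero(admissible).max())
    return grid[lo:hi + 1]


def min_sparsity_for_degree(
    n_nodes: int,
    grid: np.ndarray | None = None,
    degree_factor: float = DEFAULT_DEGREE_FACTOR,
    log_base: str = "natural",
) -> float:
    """Smallest grid sparsity whose mean degree exceeds factor*log(N)."""
    if grid is None:
        grid = sparsity_grid()
    log_n = np.log(n_nodes) if log_base == "natural" else np.log10(n_nodes)
    ok = grid * (n_nodes - 1) > degree_factor * log_n
    if not ok.any():
        raise ValueError("no grid sparsity satisfies the degree criterion")
    return float(grid[np.flatnonzero(ok).min()])
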