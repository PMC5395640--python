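"""Synthetic resting-state cohort generator.

Builds complete multi-subject datasets — ROI time series, head-motion
traces, nuisance confounds, and a clinical cohort table — whose statistical
structure matches what the downstream graph analysis assumes: signals are
band-limited multivariate Gaussians whose covariance encodes a weighted
small-world (rewired ring lattice) 90-node network; one group carries
planted, severity-coupled alterations at named AAL regions; clinical scores
are monotonically linked to the planted effect so correlation analyses have
a recoverable ground truth.

Two groups mirror the target study design: IS (insomnia symptoms, n=30,
three-item sleep-subscale score >= 1) and NIS (no symptoms, n=62, score 0),
240 volumes at TR = 2 s, fluctuations confined to 0.01-0.1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aal import AAL90_LABELS, N_AAL90
from .datatypes import MotionTrace, ROITimeSeries
from .preprocess import DEFAULT_BAND, bandpass

#: Planted-effect loci (1-based AAL indices) with their direction, following
#: the regions where the analysis is expected to localize group differences:
#: weakened left/right inferior frontal gyrus; strengthened right olfactory,
#: right fusiform, right putamen, right pallidum.
DEFAULT_WEAKEN_NODES = (12, 13)     # Frontal_Inf_Oper_R, Frontal_Inf_Tri_L
DEFAULT_STRENGTHEN_NODES = (22, 56, 74, 76)  # Olfactory_R, Fusiform_R, Putamen_R, Pallidum_R

DEFAULT_WEIGHT_RANGE = (0.3, 0.7)


@dataclass
class GroundTruthNetwork:
    """Weighted undirected network generating the synthetic signals.

    ``weights`` is symmetric and nonnegative with a zero diagonal; the
    topology is a Watts-Strogatz-style rewired ring lattice (neighbour
    count ``k``, rewiring probability ``p``), which sits in the small-world
    regime for p in (0, 0.3) and k >= 4.
    """

    weights: np.ndarray
    k: int
    p: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(np.diag(w), 0.0):
            raise ValueError("weight diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def weighted_degree(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class EffectSpec:
    """A planted group effect: scale all edges incident to target nodes.

    ``target_nodes`` are 1-based AAL indices; ``effect_size`` is the
    multiplicative factor applied to incident edge weights (0.6 = 40%
    weakening); ``direction`` is a readable tag consistent with the factor.
    """

    target_nodes: tuple[int, ...]
    effect_size: float
    direction: str = "weaken"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.direction not in ("weaken", "strengthen"):
            raise ValueError("direction must be 'weaken' or 'strengthen'")
        self.target_nodes = tuple(int(t) for t in self.target_nodes)


def make_ground_truth(
    n_nodes: int = N_AAL90,
    k: int = 10,
    p: float = 0.1,
    seed: int | np.random.SeedSequence | None = None,
    weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE,
    max_retries: int = 20,
) -> GroundTruthNetwork:
    """Connected weighted rewired ring lattice.

    Starts from a ring lattice where every node connects to its ``k``
    nearest neighbours, rewires each edge with probability ``p`` (rejecting
    self-loops and duplicates), and draws edge weights uniformly from
    ``weight_range``.  A disconnected rewiring outcome is retried with a
    fresh child seed up to ``max_retries`` times.
    """
    import networkx as nx

    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    if k % 2 != 0 or not 0 < k < n_nodes:
        raise ValueError("k must be even and in (0, n_nodes)")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    seq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    for child in seq.spawn(max_retries):
        rng = np.random.default_rng(child)
        g = nx.watts_strogatz_graph(
            n_nodes, k, p, seed=int(rng.integers(2**31))
        )
        if nx.is_connected(g):
            break
    else:
        raise RuntimeError(
            f"no connected rewiring in {max_retries} attempts "
            f"(n={n_nodes}, k={k}, p={p})"
        )
    w = np.zeros((n_nodes, n_nodes))
    edges = np.array(sorted(g.edges()))
    vals = rng.uniform(*weight_range, size=len(edges))
    w[edges[:, 0], edges[:, 1]] = vals
    w[edges[:, 1], edges[:, 0]] = vals
    return GroundTruthNetwork(weights=w, k=k, p=p)


def apply_effect(
    net: GroundTruthNetwork, spec: EffectSpec
) -> GroundTruthNetwork:
    """Scale every edge weight incident to the spec's target nodes.

    Non-incident weights are untouched.  Edges between two target nodes are
    scaled once (not squared).
    """
    n = net.n_nodes
    idx0 = [t - 1 for t in spec.target_nodes]
    if any(i < 0 or i >= n for i in idx0):
        raise ValueError(f"target nodes out of range [1, {n}]")
    w = net.weights.copy()
    mask = np.zeros((n, n), dtype=bool)
    mask[idx0, :] = True
    mask[:, idx0] = True
    np.fill_diagonal(mask, False)
    w[mask] = w[mask] * spec.effect_size
    return GroundTruthNetwork(weights=w, k=net.k, p=net.p)


def network_to_covariance(
    net: GroundTruthNetwork, diag_load: float | None = None
) -> np.ndarray:
    """Symmetric positive-definite covariance from the weight matrix.

    Covariance = weights + load * I.  With ``diag_load=None`` the loading is
    ``|lambda_min(weights)| + 0.5``, which guarantees positive definiteness
    with a minimum eigenvalue of 0.5 and keeps implied correlations
    proportional to edge weights (monotone in the edge weight, since all
    variances are equal).  Positive definiteness is certified by a Cholesky
    factorization before returning.
    """
    w = net.weights
    if diag_load is None:
        lam_min = float(np.linalg.eigvalsh(w)[0])
        diag_load = abs(lam_min) + 0.5
    cov = w + diag_load * np.eye(net.n_nodes)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        lam_min = float(np.linalg.eigvalsh(cov)[0])
        raise ValueError(
            f"covariance not positive definite (min eigenvalue {lam_min:.3g}); "
            "increase diag_load"
        ) from None
    return cov


def implied_correlation(net: GroundTruthNetwork,
                        diag_load: float | None = None) -> np.ndarray:
    """Population correlation matrix implied by the covariance construction."""
    cov = network_to_covariance(net, diag_load)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def simulate_timeseries(
    cov: np.ndarray,
    n_volumes: int = 240,
    tr_seconds: float = 2.0,
    band: tuple[float, float] | None = DEFAULT_BAND,
    seed: int | np.random.SeedSequence | None = None,
    roi_labels: tuple[str, ...] | None = None,
) -> ROITimeSeries:
    """Band-limited multivariate Gaussian ROI signals.

    Draws ``n_volumes`` i.i.d. samples from N(0, cov) via a Cholesky factor,
    then band-pass filters every row with the same zero-phase filter the
    preprocessing stage uses.  Applying one filter to all rows leaves
    between-row correlations untouched in expectation, so the sample
    correlation matrix converges to the population correlation implied by
    ``cov`` as ``n_volumes`` grows.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if n_volumes < 50:
        raise ValueError("need at least 50 volumes")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("covariance must be positive definite") from None
    rng = np.random.default_rng(seed)
    data = chol @ rng.standard_normal((n, n_volumes))
    if roi_labels is None:
        roi_labels = AAL90_LABELS if n == N_AAL90 \
            else tuple(f"ROI{i + 1}" for i in range(n))
    ts = ROITimeSeries(data=data, tr=tr_seconds, roi_labels=roi_labels)
    if band is not None:
        ts = bandpass(ts, band[0], band[1])
    return ts


def simulate_motion(
    n_volumes: int = 240,
    spike_prob: float = 0.02,
    spike_mag: float = 1.0,
    walk_sd: float = 0.01,
    seed: int | np.random.SeedSequence | None = None,
) -> MotionTrace:
    """Smooth random-walk head motion with occasional single-frame spikes.

    Each of the six rigid-body parameters performs an independent Gaussian
    random walk with per-frame step SD ``walk_sd`` (mm or degrees).  With
    probability ``spike_prob`` a frame receives an additional transient
    offset of ``spike_mag`` in one randomly chosen parameter — the signature
    of a brief head jerk, which the FD/scrubbing stage should flag.
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, walk_sd, size=(n_volumes, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    spikes = np.flatnonzero(rng.random(n_volumes - 1) < spike_prob) + 1
    for t in spikes:
        j = int(rng.integers(6))
        params[t, j] += spike_mag
    return MotionTrace(translations=params[:, :3], rotations=params[:, 3:])


@dataclass
class CohortConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    Defaults encode the emulated study: 30 IS vs 62 NIS subjects, 240
    volumes at TR = 2 s, a 90-node k=10/p=0.1 rewired-lattice ground truth,
    a 40% weakening at the inferior frontal nodes and a matching
    strengthening at the striatal/fusiform/olfactory nodes, both scaled per
    subject by insomnia severity (``coupling_slope`` = fractional effect per
    unit score relative to the base effect at the IS mean score of 1.7).
    """

    n_is: int = 30
    n_nis: int = 62
    n_nodes: int = N_AAL90
    k: int = 10
    p: float = 0.1
    n_volumes: int = 240
    tr_seconds: float = 2.0
    band: tuple[float, float] = DEFAULT_BAND
    weaken: EffectSpec = field(default_factory=lambda: EffectSpec(
        DEFAULT_WEAKEN_NODES, 0.6, "weaken"))
    strengthen: EffectSpec = field(default_factory=lambda: EffectSpec(
        DEFAULT_STRENGTHEN_NODES, 1.4, "strengthen"))
    coupling_slope: float = 1.0
    mean_is_score: float = 1.7
    spike_prob: float = 0.02
    spike_mag: float = 1.0
    walk_sd: float = 0.01
    n_confounds: int = 2

    def __post_init__(self) -> None:
        if self.n_is < 2 or self.n_nis < 2:
            raise ValueError("group sizes must be >= 2 (statistics undefined)")


@dataclass
class SubjectData:
    """Raw per-subject inputs as the pipeline expects them."""

    subject_id: str
    timeseries: ROITimeSeries
    motion: MotionTrace
    confounds: np.ndarray  # (n_volumes, n_confounds), e.g. mean WM/CSF


@dataclass
class SyntheticCohort:
    """A generated cohort: clinical table, per-subject data, provenance."""

    cohort: "pandas.DataFrame"  # noqa: F821 - forward name for doc purposes
    subjects: list[SubjectData]
    truth: GroundTruthNetwork
    config: CohortConfig
    seed: int | None


def _draw_insomnia_items(rng: np.random.Generator) -> np.ndarray:
    """Three 0-2 sleep items (DIS, DMS, EMA) conditioned on total >= 1."""
    while True:
        items = rng.binomial(2, 0.28, size=3)
        if items.sum() >= 1:
            return items


def _severity_multiplier(base: float, score: float, slope: float,
                         mean_score: float) -> float:
    """Per-subject effect factor, monotone in the insomnia score.

    A subject at the mean IS score gets exactly the base factor; higher
    scores move the factor further from 1 along the same direction.
    Clipped to stay nonnegative.
    """
    factor = 1.0 + (base - 1.0) * slope * score / mean_score
    return max(factor, 0.05)


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a full two-group cohort with planted, severity-coupled effects.

    NIS subjects' signals are drawn from the unmodified ground-truth
    network and have insomnia score 0.  Each IS subject draws a three-item
    insomnia score (total >= 1), and their network carries the weakening /
    strengthening effects scaled by that score, so that larger scores
    co-occur with stronger topological alteration — the monotone coupling
    the correlation analyses are meant to recover.  Demographics and
    clinical scores are drawn to match the emulated study's group summary
    statistics; the total HAMD/HAMA scores are the adjusted (non-sleep)
    scores plus a sleep-related part, so adjusted <= total by construction.
    """
    import pandas as pd

    if config is None:
        config = CohortConfig()
    root = np.random.SeedSequence(seed)
    net_seq, clin_seq, subj_seq = root.spawn(3)
    truth = make_ground_truth(config.n_nodes, config.k, config.p, seed=net_seq)
    rng = np.random.default_rng(clin_seq)

    rows = []
    subjects: list[SubjectData] = []
    n_total = config.n_is + config.n_nis
    subj_children = subj_seq.spawn(n_total)

    for i in range(n_total):
        is_group = i < config.n_is
        sid = f"sub-{i + 1:03d}"
        if is_group:
            items = _draw_insomnia_items(rng)
            score = int(items.sum())
            age = rng.normal(38.00, 11.85)
            edu = rng.normal(14.07, 3.34)
            male = rng.random() < 15 / 30
            adj_hamd = max(0, round(rng.normal(1.23, 1.31)))
            adj_hama = max(0, round(rng.normal(1.97, 2.00)))
        else:
            items = np.zeros(3, dtype=int)
            score = 0
            age = rng.normal(37.47, 11.95)
            edu = rng.normal(15.42, 2.95)
            male = rng.random() < 26 / 62
            adj_hamd = max(0, round(rng.normal(0.19, 0.51)))
            adj_hama = max(0, round(rng.normal(0.32, 0.79)))
        hamd = adj_hamd + score
        hama = adj_hama + min(2, round(0.7 * score))

        # severity-coupled subject network
        net_i = truth
        if is_group:
            weak = EffectSpec(
                config.weaken.target_nodes,
                _severity_multiplier(config.weaken.effect_size, score,
                                     config.coupling_slope,
                                     config.mean_is_score),
                "weaken",
            )
            strong = EffectSpec(
                config.strengthen.target_nodes,
                _severity_multiplier(config.strengthen.effect_size, score,
                                     config.coupling_slope,
                                     config.mean_is_score),
                "strengthen",
            )
            net_i = apply_effect(apply_effect(truth, weak), strong)
        cov = network_to_covariance(net_i)

        child = subj_children[i]
        ts_seq, mot_seq, conf_seq = child.spawn(3)
        ts = simulate_timeseries(
            cov, config.n_volumes, config.tr_seconds, config.band, seed=ts_seq
        )
        motion = simulate_motion(
            config.n_volumes, config.spike_prob, config.spike_mag,
            config.walk_sd, seed=mot_seq,
        )
        conf_rng = np.random.default_rng(conf_seq)
        confounds = conf_rng.standard_normal(
            (config.n_volumes, config.n_confounds)
        )

        rows.append({
            "subject_id": sid,
            "group": "IS" if is_group else "NIS",
            "age": round(float(np.clip(age, 18, 70)), 1),
            "gender": int(male),
            "education": round(float(np.clip(edu, 6, 22)), 1),
            "HAMD": int(hamd),
            "HAMA": int(hama),
            "adj_HAMD": int(adj_hamd),
            "adj_HAMA": int(adj_hama),
            "DIS": int(items[0]),
            "DMS": int(items[1]),
            "EMA": int(items[2]),
            "insomnia_score": score,
        })
        subjects.append(SubjectData(
            subject_id=sid, timeseries=ts, motion=motion, confounds=confounds
        ))

    cohort = pd.DataFrame(rows)
    return SyntheticCohort(
        cohort=cohort, subjects=subjects, truth=truth,
        config=config, seed=seed,
    )
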