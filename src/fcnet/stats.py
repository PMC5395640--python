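"""Group-level inference on network metrics.

Demographic comparisons (Welch t from raw data or printed summaries,
Pearson chi-square for 2x2 tables), per-threshold two-sample tests on
global metrics, covariate-adjusted nonparametric permutation tests on nodal
AUC values, and partial correlations between nodal AUCs and clinical
scores, with the 1/N-nodes false-positive threshold used for nodal
correlation results.

Covariate adjustment everywhere follows regress-out-then-analyse: metric
values (and scores, for correlations) are replaced by their least-squares
residuals on [intercept, covariates] computed across all subjects, after
which group labels are permuted or the Pearson correlation is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# classic tests
# ---------------------------------------------------------------------------

def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's two-sample t-test from group summary statistics.

    Returns ``(t, df, p_two_tailed)`` with the Welch-Satterthwaite degrees
    of freedom.  This is the test that reproduces published demographic
    t-values from printed mean +/- SD rows.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("SDs must be nonnegative and not both zero")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's t-test from raw samples; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table.

    Table layout: rows are groups, columns are categories — ``[[a, b],
    [c, d]]``.  Raises if any margin is zero (expected counts undefined).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def nodal_threshold(n_nodes: int) -> float:
    """False-positive significance cutoff for nodal tests: 1 / n_nodes."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    return 1.0 / n_nodes


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def residualize(
    values: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """Least-squares residuals of ``values`` on [intercept, covariates].

    With no covariates this is mean-centering.  Collinear covariate columns
    are dropped (the fit is unchanged); raises if there are too few
    observations for the design.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size")
                              and covariates.size == 0):
        return y - y.mean(axis=0)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariates not aligned with values")
    design = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(design)
    if n <= rank:
        raise ValueError(
            f"too few observations (n={n}) for {rank} design columns"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


# ---------------------------------------------------------------------------
# per-threshold global tests
# ---------------------------------------------------------------------------

def per_threshold_global_tests(
    curves: dict[str, np.ndarray],
    groups: np.ndarray,
    grid: np.ndarray,
) -> "pandas.DataFrame":  # noqa: F821
    """Welch t-test per (global metric, sparsity), uncorrected.

    ``curves`` maps metric name to an (n_subjects, n_grid) array; ``groups``
    is a boolean or {0,1} array marking the first group (IS).  Returns one
    row per metric-threshold cell with group means +/- SD, t, df and p; the
    ``correction`` column is the literal string "uncorrected".
    """
    import pandas as pd

    groups = np.asarray(groups).astype(bool)
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []
    for name, mat in curves.items():
        mat = np.asarray(mat, dtype=float)
        if not np.all(np.isfinite(mat)):
            bad = np.flatnonzero(~np.isfinite(mat).all(axis=1))
            raise ValueError(
                f"missing {name} values for subject rows {bad.tolist()}"
            )
        for ti, t_val in enumerate(grid):
            x = mat[groups, ti]
            y = mat[~groups, ti]
            if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
                t, df, p = 0.0, float(x.size + y.size - 2), 1.0
            else:
                t, df, p = welch_t(x, y)
            rows.append({
                "metric": name, "sparsity": float(t_val),
                "mean_g1": x.mean(), "sd_g1": x.std(ddof=1),
                "mean_g2": y.mean(), "sd_g2": y.std(ddof=1),
                "t": t, "df": df, "p": p, "correction": "uncorrected",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation inference on AUCs
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Covariate-adjusted two-group permutation test on one AUC measure."""

    observed: float          # adjusted group contrast (g1 - g2 direction),
                             # studentized unless statistic='mean_diff'
    p: float                 # two-tailed, (+1)/(n+1) estimator
    n_permutations: int
    null_mean: float
    null_sd: float
    null_q025: float
    null_q975: float
    seed: int | None = None


def permutation_test_auc(
    auc_values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
    statistic: str = "t",
) -> PermutationResult:
    """Nonparametric group test on per-subject AUC values.

    Both the AUCs and the group indicator are residualized on the
    covariates across all subjects (Frisch-Waugh partialling, as in
    Freedman-Lane permutation schemes); the statistic is the
    covariate-adjusted group difference — the partial regression slope of
    the residualized AUC on the residualized indicator, which reduces
    exactly to the plain difference of group means when there are no
    covariates (``statistic='t'`` divides the slope by its OLS standard
    error).  The null distribution comes from ``n_perm`` random
    relabelings preserving the observed group sizes, each relabeling
    residualized the same way, so the test stays calibrated even when
    covariates correlate with the true group label.  The two-tailed
    p-value is ``(#{|null| >= |obs|} + 1) / (n_perm + 1)``, which can
    never be exactly zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in ("mean_diff", "t"):
        raise ValueError(f"unknown statistic {statistic!r}")
    groups = np.asarray(groups).astype(bool)
    n = groups.size
    y = residualize(np.asarray(auc_values, dtype=float), covariates)
    if np.allclose(y.std(), 0):
        import warnings

        warnings.warn("constant AUC across subjects; p = 1", stacklevel=2)
        return PermutationResult(0.0, 1.0, n_perm, 0.0, 0.0, 0.0, 0.0)

    # residual-forming matrix of [intercept, covariates]; applying it to a
    # label vector gives the covariate-orthogonal part of that contrast
    if covariates is None or (hasattr(covariates, "size")
                              and np.asarray(covariates).size == 0):
        design = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        design = np.column_stack([np.ones(n), c if c.ndim > 1 else c[:, None]])
    q_mat, _ = np.linalg.qr(design)
    n_model = design.shape[1] + 1  # covariate columns + group term

    def stat(g: np.ndarray) -> float:
        gf = g.astype(float)
        g_res = gf - q_mat @ (q_mat.T @ gf)
        denom = g_res @ g_res
        if denom <= 1e-12:
            return 0.0
        slope = (g_res @ y) / denom
        if statistic == "mean_diff":
            return float(slope)
        rss = max(y @ y - slope**2 * denom, 0.0)
        se = np.sqrt(rss / max(n - n_model, 1) / denom)
        if se == 0.0:  # perfect separation: infinitely strong evidence
            return float(np.sign(slope) * np.inf) if slope != 0 else 0.0
        return float(slope / se)

    observed = stat(groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(n)
    g_perm = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        perm = rng.permutation(idx)
        g_perm[:] = False
        g_perm[perm[: groups.sum()]] = True
        null[i] = stat(g_perm)
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed, p=float(p), n_permutations=n_perm,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
        null_q025=float(np.quantile(null, 0.025)),
        null_q975=float(np.quantile(null, 0.975)),
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Partial (or plain) Pearson correlation between an AUC and a score."""

    r: float
    p: float
    df: int
    n_covariates: int
    significant_nodal: bool  # against the 1/N-nodes cutoff


def partial_correlation_with_score(
    auc_values: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    n_nodes_for_threshold: int | None = None,
) -> CorrelationResult:
    """Pearson correlation of residualized AUCs with residualized scores.

    Both variables are residualized on the same covariate design; the
    p-value uses the t transform with df = n - q - 2 (q = number of
    covariate columns).  If ``n_nodes_for_threshold`` is given, the result
    is flagged against the 1/N false-positive cutoff.
    """
    x = residualize(np.asarray(auc_values, dtype=float), covariates)
    y = residualize(np.asarray(scores, dtype=float), covariates)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("zero-variance residuals; correlation undefined")
    n = x.size
    q = 0
    if covariates is not None and np.asarray(covariates).size:
        c = np.asarray(covariates)
        q = 1 if c.ndim == 1 else c.shape[1]
    df = n - q - 2
    if df < 1:
        raise ValueError("not enough observations for the partial correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    sig = False
    if n_nodes_for_threshold is not None:
        sig = p < nodal_threshold(n_nodes_for_threshold)
    return CorrelationResult(r=r, p=p, df=df, n_covariates=q,
                             significant_nodal=sig)


def between_region_correlation(
    auc_a: np.ndarray,
    auc_b: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Pearson r between two regions' nodal AUC vectors, per group.

    Returns ``{group_label: (r, p)}``; with ``groups=None`` a single entry
    ``"all"`` is returned.  Groups with fewer than 4 subjects raise.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("region AUC vectors differ in length")
    if groups is None:
        groups = np.array(["all"] * a.size)
    groups = np.asarray(groups)
    out: dict[str, tuple[float, float]] = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        m = groups == g
        if m.sum() < 4:
            raise ValueError(f"group {g!r} too small (n={int(m.sum())} < 4)")
        r, p = sps.pearsonr(a[m], b[m])
        out[str(g)] = (float(r), float(p))
    return out


# ---------------------------------------------------------------------------
# demographics table
# ---------------------------------------------------------------------------

def demographics_table(cohort: "pandas.DataFrame") -> "pandas.DataFrame":  # noqa: F821
    """Group comparison of demographic and clinical variables.

    Continuous variables get Welch t-tests; gender gets the Pearson
    chi-square.  Mirrors the usual "Table 1" layout: one row per measure
    with per-group mean +/- SD (or male/female counts), the statistic and p.
    """
    import pandas as pd

    is_mask = (cohort["group"] == "IS").to_numpy()
    rows = []
    continuous = [
        ("Age (years)", "age"),
        ("Education level (years)", "education"),
        ("HAMD score", "HAMD"),
        ("Adjusted HAMD score", "adj_HAMD"),
        ("HAMA score", "HAMA"),
        ("Adjusted HAMA score", "adj_HAMA"),
        ("Insomnia score", "insomnia_score"),
    ]
    for label, col in continuous:
        x = cohort.loc[is_mask, col].to_numpy(dtype=float)
        y = cohort.loc[~is_mask, col].to_numpy(dtype=float)
        t, df, p = welch_t(x, y)
        rows.append({
            "measure": label,
            "IS": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
            "NIS": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
            "statistic": round(t, 3), "p": p, "test": "welch_t",
        })
    male_is = int((cohort.loc[is_mask, "gender"] == 1).sum())
    male_nis = int((cohort.loc[~is_mask, "gender"] == 1).sum())
    n_is, n_nis = int(is_mask.sum()), int((~is_mask).sum())
    chi2, p = chi_square_2x2(
        male_is, n_is - male_is, male_nis, n_nis - male_nis
    )
    rows.insert(1, {
        "measure": "Gender (male/female)",
        "IS": f"{male_is}/{n_is - male_is}",
        "NIS": f"{male_nis}/{n_nis - male_nis}",
        "statistic": round(chi2, 3), "p": p, "test": "chi_square",
    })
    return pd.DataFrame(rows)
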