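"""Study-level model and results objects.

:class:`ConnectomeStudy` bundles a multi-subject resting-state dataset (ROI
time series, motion traces, confounds, clinical table) with the analysis
configuration; ``fit()`` runs the full pipeline — temporal preprocessing and
motion QC, connectivity estimation, sparsity-thresholded graph metrics with
degree-preserving null normalization, AUC summarization — and performs the
group statistics, returning a :class:`ConnectomeResults` carrying every
table plus ``summary()``.

Randomness (null ensembles, permutations) is governed by a single seed
passed to ``fit``; identical data + config + seed reproduce results
bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as gm
from . import netcon, preprocess, stats
from .datatypes import ExclusionReport, ROITimeSeries
from .synth import SubjectData, SyntheticCohort

logger = logging.getLogger(__name__)

#: Covariates controlled for in nodal permutation tests and correlations.
DEFAULT_COVARIATES = ("age", "gender", "education", "adj_HAMA", "adj_HAMD")


class ConnectomeStudy:
    """Two-group functional-connectome topology study.

    Parameters
    ----------
    subjects : list of SubjectData
        Raw per-subject inputs (ROI time series, motion, confounds).
    cohort : DataFrame
        One row per subject with ``subject_id``, ``group`` ("IS"/"NIS"),
        covariate columns and ``insomnia_score``.
    preprocessed : bool
        If True, the time series are taken as already cleaned and the
        temporal preprocessing stage is skipped.
    """

    def __init__(
        self,
        subjects: list[SubjectData],
        cohort: pd.DataFrame,
        preprocessed: bool = False,
    ) -> None:
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        missing = set(ids) - set(cohort["subject_id"])
        if missing:
            raise ValueError(f"subjects missing from cohort table: {missing}")
        self.subjects = subjects
        self.cohort = (
            cohort.set_index("subject_id").loc[ids].reset_index()
        )
        self.preprocessed = preprocessed

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort,
                    preprocessed: bool = False) -> "ConnectomeStudy":
        """Build a study directly from a :func:`fcnet.synth.simulate_cohort`."""
        return cls(cohort.subjects, cohort.cohort, preprocessed=preprocessed)

    @classmethod
    def from_directory(cls, path, preprocessed: bool = False
                       ) -> "ConnectomeStudy":
        """Load a study from the on-disk layout written by the simulator."""
        from .io import read_cohort_dir

        subjects, cohort = read_cohort_dir(path)
        return cls(subjects, cohort, preprocessed=preprocessed)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        grid: np.ndarray | None = None,
        n_random: int = gm.DEFAULT_N_RANDOM,
        n_perm: int = 5000,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        seed: int | None = None,
        compute_betweenness: bool = True,
        preprocess_options: dict | None = None,
    ) -> "ConnectomeResults":
        """Run preprocessing, network construction, metrics and statistics.

        ``grid`` defaults to the 0.11–0.30 sparsity range in steps of 0.01;
        ``n_random`` degree-preserving nulls normalize Cp and Lp at every
        threshold; ``n_perm`` label permutations drive the nodal AUC tests.
        """
        if grid is None:
            grid = netcon.sparsity_grid()
        grid = np.asarray(grid, dtype=float)
        root = np.random.SeedSequence(seed)
        pp_opts = dict(preprocess_options or {})

        # -- stage 1: temporal preprocessing + QC --------------------------
        cleaned: list[tuple[str, ROITimeSeries]] = []
        reports: list[ExclusionReport] = []
        for subj in self.subjects:
            if self.preprocessed:
                ts = subj.timeseries
                rep = ExclusionReport(
                    subject_id=subj.subject_id, kept_fraction=1.0,
                    max_translation_mm=0.0, max_rotation_deg=0.0, reasons=(),
                )
            else:
                ts, rep = preprocess.run_subject(
                    subj.subject_id, subj.timeseries, subj.motion,
                    subj.confounds, **pp_opts,
                )
            reports.append(rep)
            if not rep.excluded:
                cleaned.append((subj.subject_id, ts))
        kept_ids = [sid for sid, _ in cleaned]
        if len(kept_ids) < 4:
            raise ValueError(
                f"only {len(kept_ids)} subjects survive QC; too few to analyse"
            )
        cohort = self.cohort[self.cohort["subject_id"].isin(kept_ids)]
        cohort = cohort.set_index("subject_id").loc[kept_ids].reset_index()
        groups = (cohort["group"] == "IS").to_numpy()
        logger.info("fit: %d/%d subjects after QC (%d IS, %d NIS)",
                    len(kept_ids), len(self.subjects),
                    int(groups.sum()), int((~groups).sum()))

        # -- stage 2: connectivity + metric curves -------------------------
        roi_labels = cleaned[0][1].roi_labels
        subject_metrics: list[gm.SubjectMetrics] = []
        for si, (sid, ts) in enumerate(cleaned):
            conn = netcon.fisher_z(netcon.correlation_matrix(ts),
                                   roi_labels=ts.roi_labels)
            sm = gm.metric_curves(
                conn, grid, n_random=n_random,
                seed=np.random.SeedSequence(entropy=root.entropy,
                                            spawn_key=(0, si)),
                compute_betweenness=compute_betweenness,
            )
            subject_metrics.append(sm)

        global_curves = {
            name: np.vstack([sm.global_curves[name]
                             for sm in subject_metrics])
            for name in gm.GLOBAL_METRIC_NAMES
        }
        nodal_aucs = {
            name: np.vstack([sm.nodal_auc[name][None, :]
                             for sm in subject_metrics])
            for name in subject_metrics[0].nodal_auc
        }

        # -- stage 3: statistics -------------------------------------------
        cov_mat = cohort.loc[:, list(covariates)].to_numpy(dtype=float) \
            if covariates else None
        table1 = stats.demographics_table(cohort)
        global_tests = stats.per_threshold_global_tests(
            global_curves, groups, grid
        )

        n_nodes = len(roi_labels)
        perm_rows = []
        corr_rows = []
        scores = cohort["insomnia_score"].to_numpy(dtype=float)
        p_cut = stats.nodal_threshold(n_nodes)
        for mi, (mname, aucs) in enumerate(sorted(nodal_aucs.items())):
            for node in range(n_nodes):
                pr = stats.permutation_test_auc(
                    aucs[:, node], groups, cov_mat, n_perm=n_perm,
                    seed=np.random.SeedSequence(entropy=root.entropy,
                                                spawn_key=(1, mi, node)),
                )
                x, y = aucs[groups, node], aucs[~groups, node]
                perm_rows.append({
                    "node": node + 1, "region": roi_labels[node],
                    "metric": mname,
                    "mean_IS": x.mean(), "sd_IS": x.std(ddof=1),
                    "mean_NIS": y.mean(), "sd_NIS": y.std(ddof=1),
                    "observed_diff": pr.observed, "p": pr.p,
                    "significant": pr.p < 0.05,
                })
                cr = stats.partial_correlation_with_score(
                    aucs[:, node], scores, cov_mat,
                    n_nodes_for_threshold=n_nodes,
                )
                corr_rows.append({
                    "node": node + 1, "region": roi_labels[node],
                    "metric": mname, "r": cr.r, "p": cr.p,
                    "significant_unc": cr.p < 0.05,
                    "significant_1overN": cr.significant_nodal,
                })
        nodal_permutation = pd.DataFrame(perm_rows)
        score_correlations = pd.DataFrame(corr_rows)

        return ConnectomeResults(
            model=self,
            grid=grid,
            cohort=cohort,
            groups=groups,
            roi_labels=roi_labels,
            exclusions=reports,
            subject_metrics=subject_metrics,
            global_curves=global_curves,
            nodal_aucs=nodal_aucs,
            table1=table1,
            global_tests=global_tests,
            nodal_permutation=nodal_permutation,
            score_correlations=score_correlations,
            metadata={
                "seed": seed, "n_random": n_random, "n_perm": n_perm,
                "covariates": list(covariates),
                "grid": [float(t) for t in grid],
                "nodal_p_cutoff": p_cut,
                "n_subjects_in": len(self.subjects),
                "n_subjects_kept": len(kept_ids),
            },
        )


@dataclass
class ConnectomeResults:
    """Fitted results: per-subject metric curves, AUCs and group tables.

    Tables
    ------
    table1 : demographics/clinical group comparison.
    global_tests : Welch t per global metric per sparsity (uncorrected).
    nodal_permutation : covariate-adjusted permutation test per nodal
        metric per region.
    score_correlations : partial correlation of each nodal AUC with the
        insomnia score, flagged at 0.05 and at the 1/N cutoff.
    """

    model: ConnectomeStudy
    grid: np.ndarray
    cohort: pd.DataFrame
    groups: np.ndarray
    roi_labels: tuple[str, ...]
    exclusions: list[ExclusionReport]
    subject_metrics: list[gm.SubjectMetrics]
    global_curves: dict[str, np.ndarray]
    nodal_aucs: dict[str, np.ndarray]
    table1: pd.DataFrame
    global_tests: pd.DataFrame
    nodal_permutation: pd.DataFrame
    score_correlations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    # -- convenience -------------------------------------------------------

    def sigma_range(self) -> tuple[float, float]:
        """(min, max) small-worldness over all subjects and thresholds."""
        s = self.global_curves["sigma"]
        return float(s.min()), float(s.max())

    def significant_nodes(self, metric: str, table: str = "permutation"
                          ) -> pd.DataFrame:
        """Rows flagged significant for one nodal metric."""
        if table == "permutation":
            t = self.nodal_permutation
            return t[(t["metric"] == metric) & t["significant"]]
        t = self.score_correlations
        return t[(t["metric"] == metric) & t["significant_unc"]]

    def between_region_correlation(
        self, region_a: str, region_b: str, metric: str = "degree",
        per_group: bool = True,
    ) -> dict[str, tuple[float, float]]:
        """Pearson r between two regions' nodal AUC vectors (per group)."""
        labels = list(self.roi_labels)
        ia, ib = labels.index(region_a), labels.index(region_b)
        aucs = self.nodal_aucs[metric]
        grp = np.where(self.groups, "IS", "NIS") if per_group else None
        return stats.between_region_correlation(aucs[:, ia], aucs[:, ib], grp)

    def summary(self) -> str:
        """Human-readable run summary in the spirit of a model results table."""
        md = self.metadata
        n_is = int(self.groups.sum())
        n_nis = int((~self.groups).sum())
        smin, smax = self.sigma_range()
        n_exc = sum(r.excluded for r in self.exclusions)
        lines = [
            "Functional connectome topology study",
            "=" * 52,
            f"Subjects analysed: {len(self.groups)} "
            f"({n_is} IS, {n_nis} NIS); excluded by QC: {n_exc}",
            f"Sparsity grid: {self.grid[0]:.2f}-{self.grid[-1]:.2f} "
            f"({self.grid.size} thresholds)",
            f"Null ensembles: {md.get('n_random')} per threshold; "
            f"permutations: {md.get('n_perm')}; seed: {md.get('seed')}",
            f"Covariates: {', '.join(md.get('covariates', []))}",
            f"Small-worldness sigma range: [{smin:.3f}, {smax:.3f}]"
            + ("  (> 1.1: small-world regime)" if smin > 1.1 else ""),
            "",
            "Global per-threshold tests (uncorrected p < 0.05): "
            f"{int((self.global_tests['p'] < 0.05).sum())} of "
            f"{len(self.global_tests)} cells",
            "Nodal permutation tests (p < 0.05):",
        ]
        for metric in sorted(self.nodal_aucs):
            sig = self.significant_nodes(metric)
            regions = ", ".join(
                f"{r.region}({'IS<NIS' if r.observed_diff < 0 else 'IS>NIS'})"
                for r in sig.itertuples()
            ) or "none"
            lines.append(f"  {metric:18s}: {regions}")
        cut = md.get("nodal_p_cutoff", 1 / len(self.roi_labels))
        sig_corr = self.score_correlations[
            self.score_correlations["significant_unc"]
        ]
        lines.append("Score correlations (p < 0.05; * p < "
                     f"{cut:.3f} [1/N]):")
        if len(sig_corr) == 0:
            lines.append("  none")
        for row in sig_corr.itertuples():
            star = "*" if row.significant_1overN else ""
            lines.append(
                f"  {row.metric:18s} {row.region:22s} "
                f"r={row.r:+.3f} p={row.p:.4f}{star}"
            )
        return "\n".join(lines)

    def save_tables(self, outdir) -> None:
        """Write all result tables and a JSON run-metadata sidecar."""
        from .io import save_results_tables

        save_results_tables(self, outdir)

    def plot_global_curves(self, path=None):
        """Plot group-mean global metric curves over the sparsity grid."""
        from .plotting import plot_global_curves

        return plot_global_curves(self, path=path)
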