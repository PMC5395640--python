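# Methods

`fcnet` implements a complete graph-theoretical analysis of resting-state
functional brain networks for a two-group cohort design, together with a
synthetic-cohort generator that provides ground truth for every stage.
This note documents the model, the procedure, the numerical choices, and
what the synthetic validation does and does not establish.

## The analysis

### Nodes, edges, and sparsity thresholding

The brain is parcellated into N = 90 anatomically defined regions (AAL-90,
45 per hemisphere; odd 1-based indices left, even right). Each region
contributes one time series; the network edge candidates are the Pearson
correlations between all region pairs, Fisher-transformed (z = atanh r,
with r clipped to ±(1−10⁻⁶) so duplicated signals stay finite).

Instead of a correlation cutoff, networks are binarized at a *sparsity* T:
the round(T·N(N−1)/2) largest strictly positive z-values become edges, so
every subject's network has the same wiring cost and group comparisons are
not confounded by overall correlation level. Ties are broken by
lexicographic (i, j) order so the pipeline is deterministic under
permutation. Negative correlations are never turned into edges by default
(an |z| ranking is available as an option).

A whole grid of sparsities, T = 0.11 to 0.30 in steps of 0.01 (20
thresholds), is analysed. The lower bound is the smallest grid value at
which the mean degree T·(N−1) exceeds 2·ln N (≈ 9.0 for N = 90, giving
T > 0.101, hence 0.11 on the grid); the upper bound requires the
small-worldness scalar σ to exceed 1.1 for every subject. The log is the
natural log; base 10 is exposed as a config option.

### Graph metrics

On each binary network the package computes:

* global — clustering coefficient Cp (mean over nodes of the fraction of
  connected neighbour pairs), characteristic path length Lp (mean
  shortest-path length over *reachable* ordered pairs; the unreachable
  count is reported), global efficiency E_glo (mean 1/d with 1/∞ = 0),
  local efficiency E_loc (mean over nodes of the global efficiency of each
  neighbour-induced subgraph);
* nodal — degree Deg_i, nodal efficiency E_nodal,i (inverse harmonic mean
  of node i's distances; robust to disconnection), and betweenness
  centrality BC_i (Brandes accumulation counting shortest-path
  multiplicities; endpoints excluded; unnormalized by default).

Cp and Lp are normalized against degree-preserving null networks: γ =
Cp/C_random, λ = Lp/L_random, and the small-world scalar σ = γ/λ. The
null ensemble (100 networks per subject per threshold by default) is built
by Markov-chain double-edge swaps — pick two edges (a–b, c–d), rewire to
(a–d, c–b), reject self-loops and multi-edges — with an attempt budget of
10× the edge count. The degree sequence is conserved exactly. Null seeds
are spawned deterministically from (subject index, threshold index, master
seed), so ensembles are bit-reproducible and independent of evaluation
order. A graph admitting no valid swap (e.g. a triangle) is returned
unchanged with a warning.

Every metric's curve over the sparsity grid is summarized by its area
under the curve (trapezoidal rule over the 0.19-wide grid; a constant
curve c integrates to 0.19·c). AUCs are the threshold-independent
quantities all group statistics operate on.

### Temporal preprocessing and motion quality control

The pipeline covers the temporal half of resting-state preprocessing (the
spatial half — realignment, normalisation — happens upstream; motion
parameters arrive as inputs). Fixed order, each stage logged:

1. discard the first k = 10 volumes (magnetisation equilibrium);
2. per-region linear detrend;
3. nuisance regression on [intercept, 6 motion parameters, supplied
   confound columns (e.g. mean WM/CSF signals)], dropping collinear
   columns with a warning;
4. band-pass 0.01–0.1 Hz (zero-phase forward–backward Butterworth of
   order 2, i.e. effective order 4; an FFT mask is config-selectable; the
   contract is ≥ 0.9 amplitude at mid-band and ≤ 0.1 at twice the upper
   edge for ~230-sample series);
5. motion scrubbing.

Framewise displacement is FD_t = Σ|Δ translations| + Σ|Δ rotations
converted to arc length at r = 50 mm| with backward differences and
FD₁ = 0. Volumes with FD > 0.3 mm are removed (threshold configurable;
0.5 mm is another value in circulation). Only the flagged frame is
removed — no 1-back/2-forward augmentation, no interpolation. A subject is
excluded when fewer than 50% of volumes survive scrubbing or when any
parameter exceeds ±2 mm / ±2°.

Detrending and nuisance regression precede filtering; scrubbing is last.
This ordering is a documented package decision (it affects results and is
therefore logged), not a universal convention.

### Group statistics

* **Demographics** (Table-1 style): Welch's t (unequal variances) for
  continuous measures — chosen because it reproduces published t-values
  from printed mean ± SD rows — and Pearson's χ² without continuity
  correction for the 2×2 gender table.
* **Global metrics**: one Welch t per (metric, threshold) cell, explicitly
  labelled *uncorrected*; 7 metrics × 20 thresholds = 140 tests.
* **Nodal AUCs**: nonparametric permutation tests (5 000 relabelings by
  default) controlling for age, gender (0/1), education, adjusted HAMA and
  adjusted HAMD. The statistic is the *studentized covariate-adjusted
  group contrast*: both the AUC and the (re)permuted group indicator are
  residualized on the covariates (Frisch–Waugh partialling, as in
  Freedman–Lane schemes) and the partial slope is divided by its OLS
  standard error. Studentizing and re-residualizing the label vector for
  every permutation keeps the test calibrated even when covariates
  correlate with the true group label (the adjusted clinical scores do, by
  design); residualizing only the outcome and permuting labels with a raw
  mean difference is measurably conservative in that regime (simulated
  type-I ≈ 0.02 at nominal 0.05), and the unstudentized partial slope is
  anti-conservative (≈ 0.08). With no covariates the statistic reduces to
  the plain difference of group means. Two-tailed p uses the
  (#exceedances + 1)/(n_perm + 1) estimator, never exactly zero.
* **Clinical correlations**: Pearson correlation between residualized
  nodal AUC and residualized insomnia score (same covariates), p from the
  t transform with df = n − q − 2; nodal results are additionally flagged
  at the 1/N = 1/90 ≈ 0.011 false-positive cutoff.
* **Between-region coupling**: per-group Pearson r between two regions'
  nodal-AUC vectors.

A single master seed drives every stochastic component (simulation, null
ensembles, permutations) through spawned `SeedSequence` children; identical
data + config + seed give byte-identical output tables.

## The synthetic-cohort generator

The generator emulates the data structure the analysis assumes, with a
known ground truth:

* **Topology**: a connected Watts–Strogatz ring lattice on 90 nodes
  (k = 10 neighbours, rewiring p = 0.1 — comfortably inside the
  small-world regime), edge weights uniform on [0.3, 0.7]. Disconnected
  rewirings are retried with fresh child seeds.
* **Covariance**: C = W + (|λ_min(W)| + 0.5)·I, certified
  positive-definite by Cholesky. All variances are equal, so implied
  correlations are proportional to edge weights (monotone by
  construction); with the defaults the strongest implied correlations are
  ≈ 0.25.
* **Signals**: 240 volumes at TR = 2 s per subject, drawn i.i.d. from
  N(0, C) and band-limited to 0.01–0.1 Hz with the same zero-phase filter
  the preprocessing stage uses (one filter implementation in the package).
  Filtering all rows identically leaves cross-correlations unbiased, so
  sample correlations converge to the implied correlations as the series
  lengthens.
* **Motion**: six independent Gaussian random walks (step SD 0.01
  mm/degree) with occasional single-frame spikes (probability 0.02,
  magnitude 1 mm) — the signature the FD/scrubbing stage must catch.
* **Cohort**: 30 IS vs 62 NIS subjects by default. Insomnia score = sum of
  three 0–2 items (each Binomial(2, 0.28), conditioned ≥ 1 for IS; 0 for
  NIS), giving an IS mean near 1.7. Demographics are drawn to match the
  emulated study's group summaries; HAMD = adjusted HAMD + insomnia score
  and similarly for HAMA, so adjusted ≤ total holds by construction and the
  adjusted scores are *group-correlated*, as in the real cohort.
* **Planted effects**: edge weights incident to target AAL nodes are
  scaled (default: weaken nodes 12, 13 — right IFG pars opercularis, left
  IFG pars triangularis — by 0.6; strengthen nodes 22, 56, 74, 76 by 1.4).
  Each IS subject's factor is modulated by severity: factor(score) =
  1 + (base − 1)·slope·score/1.7, so a subject at the IS mean score gets
  exactly the base factor and higher scores get stronger alterations —
  the monotone coupling the correlation analyses recover. Slope 0 switches
  the effect off entirely (null cohorts).

### What the generator does not emulate

Gaussian, stationary, band-limited signals with equal variances: no
hemodynamic response, no scanner drifts or physiological noise spectra, no
spatial voxel structure (region series are generated directly), no
heavy-tailed motion. Passing tests therefore demonstrate that the
*pipeline* recovers what it assumes — planted topology, planted group
effects, calibrated inference — not that real fMRI data satisfy those
assumptions.

### Statistical power at the default settings

With 230 retained volumes band-limited to 0.01–0.1 Hz the effective number
of independent samples is ≈ 80, so the sampling SD of a single correlation
is ≈ 0.11 — the same order as the implied edge correlations (≤ 0.25).
A 40% weakening of one node's edges consequently shifts that node's
degree-AUC by ≈ 0.6 units against a between-subject SD of ≈ 0.95
(d ≈ 0.6), and covariate adjustment with group-correlated clinical scores
absorbs part of the remaining effect. At n = 30 vs 62 the
covariate-adjusted permutation test then detects the weakening in roughly
a third of replicates; the *direction* of the effect (IS < NIS) and the
negative AUC-versus-score partial correlation are recovered in ≈ 95–100%
and ≈ 90% of replicates respectively. This is a property of the stated
study conditions, mirrored by the marginal p-values such designs produce
in practice; the acceptance suite reports these rates honestly rather than
inflating the generator's correlation ceiling to make detection easy.

## Numerical choices

* Graph kernels (all-pairs BFS, Brandes betweenness, neighbour-subgraph
  efficiency, the edge-swap loop) are numba-jitted with equivalent
  pure-Python fallbacks; tests compare all of them against independent
  brute-force oracles (Floyd–Warshall, explicit path enumeration) and
  against networkx as a third opinion.
* Lp on disconnected graphs averages over reachable pairs (and reports the
  unreachable count); nodal efficiency is the disconnection-robust nodal
  quantity.
* Degenerate inputs fail loudly and specifically: zero-variance ROI series
  name the region, non-SPD covariances report the minimal eigenvalue,
  empty admissible threshold ranges report both criteria, scrubbing that
  removes every volume raises.
* Problem sizes in the shipped test-suite and acceptance script (10
  subjects × 20 thresholds × 100 nulls for the small-world audit; 50
  replicate cohorts for parameter recovery; 500 replicates × 1 000
  permutations for the type-I audit) were chosen to make each property
  measurable with comfortable margins at interactive runtimes.

## Known limitations

* The σ normalization uses mean Cp/Lp over nulls, not distributional
  calibration; σ > 1.1 is a convention, not a test.
* The permutation and correlation analyses assume exchangeability after
  linear covariate adjustment; nonlinear confounding is out of scope.
* Voxel-level ingestion (`roi_average`) assumes a label image aligned with
  the data grid; no registration is performed.
* The 10×edges swap budget randomizes graphs of the densities used here
  (clustering reaches the density-matched random level) but is a
  convention; exact uniform sampling of the degree-sequence graph space is
  not attempted.
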