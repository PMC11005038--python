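# Methods

This note documents the models implemented in `cholepk`, the defaults
they ship with, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Toxicokinetic steady-state model

The QIVIVE stage assumes first-order kinetics in a single well-mixed
compartment under constant oral input. At steady state the plasma
concentration per unit dose rate is

    Css = F · BW / (24 · (CLh + CLr))        [mg/L per mg/kg/day]

with hepatic clearance by the well-stirred liver model and renal
clearance by glomerular filtration of unbound drug:

    CLint,whole = Clint · hepatocellularity · liver mass · 60/10^6  [L/h]
    CLh = Q · fub · CLint,whole / (Q + fub · CLint,whole)
    CLr = fub · GFR

Defaults describe a reference human and are configurable on
`PhysiologyConfig`; every dose-matrix output records them in metadata.

| parameter          | default | unit                  |
|--------------------|---------|-----------------------|
| body weight        | 70      | kg                    |
| liver blood flow Q | 90      | L/h                   |
| GFR                | 6.7     | L/h                   |
| hepatocellularity  | 110     | 10^6 cells/g liver    |
| liver mass         | 1820    | g                     |
| bioavailability F  | 1.0     | —                     |
| Css percentile     | 0.90    | —                     |
| variability CV     | 0.3     | — (lognormal, fub & Clint) |
| MC draws           | 1000    | —                     |

Assumptions worth keeping in mind: distribution is instantaneous (no
peripheral compartment), absorption is complete and unmodelled (oral and
intravenous routes share the expression with F = 1), metabolism is
linear (no saturation), and the only elimination routes are hepatic
metabolism and glomerular filtration (no biliary or active renal
secretion). These are the standard simplifications of high-throughput
reverse dosimetry; the model is deliberately transparent rather than a
full PBPK description.

The 90th percentile is computed by Monte-Carlo sampling of fub and
Clint from mean-preserving lognormals with the configured coefficient of
variation (fub truncated at 1), taking the order statistic with 1-based
index ceil(p·n) of the sorted Css draws. What the percentile ranges over
(population variability, parameter uncertainty, or both) is explicit
configuration here, not an assumption buried in a library. With zero
variability the percentile degenerates exactly to the analytic point
estimate.

Reverse dosimetry inverts the exposure model:
IEOD50 = IC50[mg/L] / Css-per-unit-dose. It is strictly increasing in
IC50 and strictly decreasing in Css. Compounds whose *minimum* IEOD50
across transporters exceeds 10 000 mg/kg/day are removed as
physiologically implausible; the minimum is used because it is the
quantity the OR rule consumes, and the boundary value itself is kept
(strictly-greater removal).

## Transporter QSARs

Each transporter's regressor is selected among XGBoost, random forest,
k-NN and SVM by grid search with 5-fold CV on mean absolute error, on
Morgan fingerprints (radius 2, 2048 bits, feature invariants).
Replicated measurements enter the training set as separate rows, so
well-replicated compounds carry more weight; the experimental mean per
(compound, transporter) overrides the model prediction in the final
activity matrix, with per-cell provenance recorded. Fold splitting is by
data row by default; splitting by unique compound is available via the
grouping utilities when leakage between replicates is a concern.

The grid search is implemented explicitly (sorted parameter grid, fixed
shuffled K-fold, first-occurrence tie-break) so selection is exactly
reproducible; the shipped default grids are small on purpose (≤ 8
points per family) and include both linear and radial SVM kernels. The
SVR grid also offers an epsilon of 0.01 alongside the 0.1 default: an
insensitive tube of 0.1 log units is on the order of assay precision
and can bias fits on clean data. Family tie-breaks follow the fixed
order XGB < RF < KNN/NB < SVM. Every stochastic fit receives a seed
derived from the global seed and its context (transporter, family) via
a stable hash.

Classifiers (the direct QSAR baselines) use the same machinery with ROC
AUC as the selection metric, Multinomial Naive Bayes on fingerprint
blocks and Gaussian Naive Bayes on physicochemical blocks. No class
rebalancing is applied by default.

## Decision rules

`PkRuleMetamodel` calls a compound cholestatic when its therapeutic
dose exceeds n times the IEOD50 of any transporter — the logical OR,
equivalently TD > n · min_t IEOD50_t. The safety factor n is tuned over
25 log-spaced values in [0.1, 100] to maximize the arithmetic mean of
sensitivity and specificity (Youden's J and MCC are selectable); ties
take the smallest n, the conservative choice. The continuous score is
the signed log-dose margin log10(TD) − log10(n · min_t IEOD50_t), so
ranking metrics can be computed from margins; a strict binary mode
computes AUC from predicted labels instead (the two-point ROC, equal to
(S+SP)/2). An alternative reading that compares TD against the highest
IEOD50 across transporters is available as `mode="highest"`; OR is the
default because it is the conservative aggregation and consistent with
the 90th-percentile Css choice. Inside any CV harness, n is re-tuned on
each training fold.

`NoPkRuleMetamodel` is parameter-free: positive when any transporter
IC50 ≤ 300 μM (inclusive bound). Its predictions are invariant to
whatever labels `fit` receives.

## Cross-validation regimes and metrics

Three schemes share one fold format: repeated random k-fold (default
20 × 5), similarity-cluster CV (average-linkage agglomerative
clustering of fingerprints under Jaccard distance, cut at five
clusters, each fold testing one cluster), and ATC-group CV over the
five most represented level-2 therapeutic classes (J01, N05, L01, C01,
N02), each fold testing one class. A compound carrying several of the
listed codes is assigned to the smallest group, which preserves balance;
compounds carrying none are excluded. Average linkage was chosen as the
standard compromise between chaining (single) and cluster-size bias
(complete); the linkage is configurable.

Metrics are sensitivity, specificity, accuracy, MCC and ROC AUC
(midrank tie handling). On degenerate folds (single-class truth) the
undefined metrics are reported as missing and excluded from means, with
the exclusion count logged — zero-filling would bias scheme comparisons
in which some folds test a nearly single-class cluster.

Similarity diagnostics report, per group pair, the mean Tanimoto
similarity of each compound's three most similar compounds in the
target group (self excluded within-group), averaged over the group.

Statistical utilities: per-descriptor two-sample t-tests of the
Lipinski variables between classes, and fixed-effects two-way ANOVA
(type II) of pIC50/pIEOD50 on transporter and class, with the
interaction optional and refused when a factor cell is empty.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
at desk scale:

- **Fingerprints** come from five disjoint cluster bit-templates (60
  bits each, 2% bit noise) plus 32 *activity bits* sampled
  independently of cluster membership. Transporter pIC50 is a linear
  function of a per-transporter subset of the activity bits plus
  Gaussian assay noise (default sd 0.3). Keeping the
  structure–activity signal orthogonal to cluster identity is what
  makes the structure-independence experiment meaningful: transporter
  QSARs can generalize across clusters, while labels tied to cluster
  membership cannot be predicted for an unseen cluster.
- **Measurements**: each (compound, transporter) pair is measured with
  probability 0.4; measured pairs carry a second replicate with
  probability 0.3.
- **Toxicokinetics**: lognormal fub (median 0.1), Clint (median 10
  μL/min/10^6 cells) and molecular weight (median 350 g/mol).
- **Doses and labels**: the therapeutic dose is placed at
  TD = n*·min IEOD50·10^u with u = ±(0.1 + |N(0, 1)|), the sign drawn
  Bernoulli at the configured prevalence (default 0.27, matching a
  curated cholestasis collection). Labels therefore equal the
  generating dose rule exactly before optional flip noise, and the
  0.1 log-margin guarantees a nonempty perfect-separation interval
  around n*, so a noise-free fit can reach training balanced accuracy
  1.0 with a finite n-grid. `label_mode="structure"` instead ties
  labels to membership of designated clusters.
- **Ground truth** dose matrices use the deterministic point Css, so
  the generating rule is exactly recoverable when Monte-Carlo
  variability is switched off.

What the generator does **not** emulate: real transporter SAR
(activities are linear in designated bits), correlated inhibition
across transporters, assay heterogeneity between sources, realistic
ATC-label correlations beyond a cluster association, or the true
cholestasis label-generating process. Passing tests therefore
demonstrate that the pipeline recovers the structures it assumes — not
that those structures hold for real pharmaceuticals.

## Experiment sizes and configurations

The test suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to exercise every code path with stable statistics: 420
compounds for the main evaluation run (mirroring the scale of a curated
cholestasis dataset), 500 for parameter recovery, 300 for the
structure-dependence comparison, and SVM/KNN model families for the
per-transporter regressors in scripted runs (linear SVR is the
best-suited family for the generator's linear signal; the full
four-family search remains the library default).

The parameter-recovery experiment uses a balanced label prevalence
(0.5) and deterministic Css. The balance is a property of the
experiment, not the default data: under symmetric 10% label flips the
achievable sensitivity of any predictor that recovers the true rule is
capped at 0.9p/(0.9p + 0.1(1−p)) for prevalence p — about 0.77 at
p = 0.27 and 0.90 at p = 0.5 — so only a balanced design can separate
"fails to recover the rule" from "hits the noise ceiling".

## Known limitations

- The steady-state model omits absorption kinetics, transporter-mediated
  disposition and nonlinearity; IEOD50s inherit those simplifications.
- The 300 μM threshold of the no-TK rule and the 10 000 mg/kg/day
  plausibility cutoff are fixed conventions, not fitted quantities.
- Curation neutralizes charges and strips salts but does not
  standardize tautomers or stereochemistry (preserved as given).
- Hyperparameter grids are intentionally small; for real data they
  should be widened per family.
- The estimator contract of the metamodels is minimal (fit / predict /
  decision_function); probability calibration is out of scope.
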