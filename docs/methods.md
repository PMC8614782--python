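# Methods

## The modelling problem

The target is the natural logarithm of the singlet-oxygen quenching rate
ratio, `y = ln(k_q / k_ref)`, with α-tocopherol as the reference
(`k_ref`); for compounds reported directly as a SOAC ratio,
`y = ln(SOAC)`. Both routes are equivalent by definition and the package
enforces their consistency to 1e-12. The log transform puts the
multiplicative spread of quenching rates (several orders of magnitude
between weak phenols and carotenoids) on an additive scale.

The regime of interest is small-n/large-p: roughly 74 compounds against
~200 candidate descriptors plus 2048 fingerprint bits. Every design
choice below follows from that regime — aggressive collinearity pruning,
simple fixed hyperparameters, leave-one-out validation, and consensus
rather than single-model importance.

## Featurization

Two feature sets are built per compound and modelled **separately**:

* **Descriptors**: five quantum quantities — HOMO and LUMO energies (eV),
  their gap (eV), heat of formation (kcal/mol), dipole moment (Debye) —
  plus the full RDKit 2-D descriptor list (~210 scalars: topological
  indices such as BalabanJ, partitioned-surface-area terms such as
  SlogP_VSA* and PEOE_VSA*, counts, EState indices, …). The candidate
  list is deliberately the complete toolkit list; the selection stage is
  responsible for shrinking it.
* **Morgan fingerprints**: hashed circular substructures, default radius
  2 and 2048 bits. Radius 2 captures atom environments up to two bonds
  out — large enough to flag conjugated fragments, small enough that bit
  semantics stay interpretable. Both parameters are configurable.

Descriptor computation is a backend contract with three implementations:

* `stub` — pseudo-descriptors drawn from an RNG keyed by a hash of the
  **canonical** SMILES. Deterministic, engine-free, schema-identical to
  the toolkit backend; all tests run on it. Values land in plausible
  ranges (HOMO in [-10, -5] eV, LUMO above HOMO, etc.) but carry no
  chemistry.
* `toolkit` — RDKit 2-D descriptors computed on the canonicalized
  molecule; quantum fields delegated to a quantum sub-backend (the stub
  unless an engine is attached). Canonicalization makes the output
  invariant to atom ordering in the input SMILES.
* `quantum` — the toolkit backend with a subprocess adapter around a
  semiempirical engine (MOPAC, PM7 keywords): embed a 3-D conformer
  (ETKDG + MMFF), write the input deck, parse HOMO/LUMO, final heat of
  formation and the dipole SUM row from the output listing. If the
  executable is absent a `CapabilityError` names it — never silent
  zeros. Conformer generation is deliberately simple (single ETKDG
  embed); an exhaustive force-field conformer search is out of scope,
  and PM7 values are in any case version- and geometry-sensitive.

A compound failing any featurizer is dropped from **both** tables and
logged in a rejection report; with n this small, imputation would be
worse than honest removal. When a row carries both a SOAC value and a
rate constant, SOAC wins (it is the curated quantity; the rate route
requires the configured `k_ref`).

## Feature selection

Unsupervised, descriptors only, three stages in order: drop
zero-variance columns; drop value-identical duplicates (survivor = first
in name order); then **greedy correlation pruning** — while any pair has
|Pearson r| ≥ threshold, take the pair attaining the maximum (ties:
lexicographically smallest pair) and delete the member that is redundant
with more of the table: more partners at |r| ≥ threshold, then larger
mean |r| against all other features, then the later name. The
correlation matrix is fully recomputed after every deletion (p is a few
hundred at most; auditability beats micro-optimisation, and the test
suite checks the sequence against a brute-force re-enumeration).

Pearson correlation is computed on raw, unstandardized values, and the
threshold (default 0.95) is mandatory in every config: an implicit
cutoff would make runs irreproducible from their config alone.

Selection is fitted on the **full** dataset before the train/test split.
This mirrors reporting a single dataset-level descriptor count, and is a
mild form of leakage (the test rows influence which features survive).
It is documented rather than "fixed" because the selection is
unsupervised — it never sees y — so the leakage does not touch the
target. Fingerprint bits bypass pruning entirely.

The output carries its own certificate: max pairwise |r| of the kept set
is below the threshold, and re-running selection on its output is the
identity.

## Evaluation protocol

* **Split**: n_test = 8 when n = 74 (66 train / 8 test), otherwise the
  same held-out fraction (round(n·8/74), at least 1); random states
  default to 0, 10 and 100. Partitions are asserted disjoint and
  exhaustive on every run.
* **Metrics**: test R² (baseline = test-set mean; negative values are
  preserved — they drive the consensus eligibility filter), test RMSE,
  and RMSE_LOO. Each LOOCV fold holds out one sample, so the per-fold
  RMSE is that sample's absolute error and RMSE_LOO equals the mean
  absolute leave-one-out error; this is a documented consequence of
  defining the score as the average of per-fold RMSEs. LOOCV runs on the
  training partition only, so it is comparable with test RMSE as an
  overfitting diagnostic; the held-out 8 are never touched.
* **Algorithms**: XGBoost, LightGBM, CatBoost, random forest, AdaBoost
  (depth-3 stumps), LASSO and a small MLP (64×32), the last two inside a
  StandardScaler pipeline — descriptors span wildly different scales and
  neither L1 shrinkage nor gradient descent is scale-invariant. LASSO
  importance is therefore |coefficient| on the standardized scale.
  Tree ensembles use each library's native importance (impurity/gain);
  the type is whatever the library ships and is recorded with the run's
  hyperparameters.
* **Hyperparameters**: fixed, documented defaults per algorithm
  (`soacml.suite.DEFAULT_HYPERPARAMETERS`), overridable per run and
  embedded in every report. Notable small-n adjustments: LightGBM
  `min_child_samples=5` (the library default of 20 effectively disables
  splitting at n_train = 66) and modest ensemble sizes (300 trees). No
  hyperparameter search is performed: the reproducible object is the
  protocol, not the tuning.
* **Missing libraries**: CatBoost (and a MOPAC executable) may be
  absent; the adapter raises a `CapabilityError`, the grid records the
  skip and continues. The MLP is an optional baseline and never enters
  the importance analysis.

## Consensus importance

Raw importances are not comparable across algorithms, so the consensus
uses ranks. For each **eligible** run — importance-capable algorithm
with test R² ≥ 0 (R² = NaN, possible only for constant test targets, is
ineligible) — the ten highest-importance features get scores 10…1;
ties are broken stably by feature name so the statistic is a pure
function of its inputs; zero-importance features are never scored, even
when fewer than ten features are positive (a score should witness
signal). Scores are summed across eligible runs — all
algorithm × feature-set × random-state combinations, with the
descriptor-set and fingerprint-set consensuses also reported separately
(their importances live on different supports) alongside a combined
view.

Useful invariants, all asserted in the test suite: a model with ≥ 10
positive-importance features contributes exactly 55 points; every
consensus score is bounded by 10 × (number of eligible models); adding
an eligible model never decreases any feature's score.

## Synthetic data

The generator emulates the statistical shape of the real problem, not
its chemistry: descriptor columns are multivariate normal with
equicorrelated blocks (ρ per block; a Gaussian copula with Gaussian
marginals is exactly a multivariate normal, so blocks are sampled via a
Cholesky factor), fingerprint bits are i.i.d. Bernoulli and independent
of descriptors, and y is a sparse linear combination of named features
plus Gaussian noise. One RNG stream per operation is derived from
(seed, operation tag), so feature and target generation are
independently reproducible and adding operations never shifts existing
draws.

The reference study conditions (`make_recovery_spec`) are: 74 samples;
60 descriptors, the first 20 in four ρ = 0.8 blocks of five; 2048
fingerprint bits at 5% density; five planted unit coefficients placed in
distinct blocks or independent columns (signal variance exactly 5);
noise σ = √(5·0.2/0.8) ≈ 1.118, making the planted linear model's
population R² exactly 0.8. The recovery experiment runs the full
pipeline over 20 replicates and asks whether ≥ 4 of the 5 planted
descriptors reach the descriptor-consensus top-10 in ≥ 80% of them, with
LOOCV disabled (it affects neither eligibility nor importances).

What passing on synthetic data does **not** show: real descriptors are
not Gaussian, real fingerprints are structured and correlated with
descriptors (both reflect the same molecule), and real
structure–activity relations are not linear. The synthetic suite
validates the machinery — selection, protocol, consensus arithmetic,
signal recovery under collinearity — not chemical validity.

## Numerical and degenerate-input choices

* Correlation matrices are symmetrized (`max(r, rᵀ)`) before argmax
  scans; floating-point asymmetry in the underlying BLAS calls can
  otherwise hide the maximal pair.
* Pearson r is undefined for constant columns; `correlation_prune`
  refuses tables containing them and points to `drop_zero_variance`.
* Constant test targets make R² undefined: reported as NaN with a
  warning, RMSE still returned; NaN is ineligible for the consensus.
* An empty eligible set yields a warned-but-valid empty consensus, not
  an exception (a batch run over many configs should not die on one bad
  grid).
* Duplicate detection compares exact byte patterns of the float columns,
  not approximate equality — "duplicate content" means duplicate.

## Problem sizes used in the shipped experiments

The packaged tests run the grid at n = 24–30 with 30-tree ensembles, the
oracle-equivalence suites at p ≤ 8 × 100 random tables and 3 × 5 × 100
consensus instances, and the recovery experiment at the full reference
conditions (74 × 60 + 2048, 20 replicates, ~12 s each on one CPU).
These sizes were chosen so the whole suite completes in a few minutes
while still exercising every code path at the study's native scale where
it matters (the recovery experiment).

## Known limitations

* The quantum backend's values depend on the engine version and the
  single-conformer geometry; no attempt is made to reproduce any
  specific published descriptor table.
* Impurity/gain importances are biased toward high-cardinality features
  and split credit arbitrarily among correlated ones; the consensus
  mitigates instability across models but inherits both biases —
  block-mates of a truly informative descriptor routinely absorb part of
  its score (visible in the worked example).
* The consensus score is an indicator of predictive reliance, not of
  causality or mechanism.
* LOOCV at n = 66 is expensive for the MLP and boosted ensembles;
  `compute_loocv=False` is provided for exploratory runs.
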