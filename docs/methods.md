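# Methods

## Model

A probability tree over a fixed, expert-chosen feature order is a chain of
splits: all nodes at depth *k* branch on feature *k*, every root-to-leaf
path assigns one value to every feature, and the probability of a path is
the product of its transition probabilities. Transition probabilities are
the raw empirical conditional frequencies of the training records — no
smoothing or pseudo-counts are applied, so fully determined branches carry
probability exactly 1 and leaf class fractions are exact ratios of record
counts. Value combinations never observed in training are not stored as
zero-probability branches; they are simply absent, and queries that
condition on them raise an explicit unsupported-query signal rather than
silently returning 0. Children of a node are ordered by the sorted values
of their statements; this is a convention of this implementation (any fixed
order would do) chosen so that serialization, DOT export and tie-breaking
are deterministic.

Only binary targets are supported, and records with missing values in any
used column are rejected at induction time; incompleteness at prediction
time is handled by the traversal itself (below). Continuous features enter
the tree only after discretization at their crisp cuts: the tree structure
and its probabilities are identical for crisp and fuzzy prediction, the two
differ purely in how a patient is matched against branches.

## Fuzzy traversal

Each fuzzy variable is a linguistic variable: a binary partition of a
numeric universe into piecewise-linear fuzzy sets (ramps; trapezoids are
expressible through knots). Degrees are clamped to the boundary memberships
outside the knot range. At a fuzzy split, the patient's raw value yields
one degree per branch; degrees are renormalized to sum to 1 before use as
traversal weights (complementary binary partitions already sum to 1
everywhere, so renormalization only matters for user-supplied
non-complementary sets, and for branches missing from the tree). The
prediction recursion is:

1. at a leaf, return the requested class's fraction of the leaf counts;
2. with no statements left, return the conditional class probability given
   the path so far (equivalently, the theta-weighted aggregate of the
   subtree's leaves);
3. a matching child is entered with its renormalized membership weight
   (weight 1 for a crisp match), summing over all weighted branches;
4. a stated value with no matching child (a combination absent from
   training) falls back to the theta-weighted average over the children;
5. a variable the patient says nothing about is averaged uniformly with
   weight 1/|children|.

Cases (4) and (5) deliberately differ: an unseen *value* is replaced by the
population's conditional distribution (theta weights), whereas an *unknown*
variable is treated as maximally uninformative (uniform weights). When a
patient's full combination is unrepresented, the longest represented subset
of their statements is found by maximizing, over all root-to-leaf paths,
the number of satisfied statements (scanned in feature order — since the
tree fixes the variable order, only order-respecting subsequences
correspond to paths; ties break toward the first path in child order). The
dropped variables are then handled by rule (5), so the result remains a
proper probability. The classification threshold is inclusive
(positive iff P ≥ threshold, default 0.50) and adjustable.

Crisp prediction replaces every ramp by a step at the declared cut — the
high-side term takes membership 1 for values at or above the cut, its
complement below — so the crisp tree is literally the fuzzy algorithm with
all memberships in {0, 1}, and the crisp-limit identity is tested as a
property rather than assumed.

One ambiguity is worth recording: on the demonstration fixture the
membership-weighted expansion (0.427) selects the class-1 leaves, while the
crisp traversal of the same patient returns probability 1 for class 0. The
package reports both class probabilities for every prediction and anchors
its tests to 0.427 as the value of the weighted expansion, without taking a
position on which clinical label that expansion names.

## Counterfactual (scenario) queries

Scenario queries substitute statements (interventions) and/or mark
variables unknown (removals), then re-traverse the same tree; factual and
scenario probabilities are returned side by side. This is observational
re-conditioning, not structural counterfactual inference: there is no
abduction over exogenous noise, and no causal identification is claimed.
With a crisp evidence set, substitution is exactly direct conditioning on
the edited statements.

## Evaluation protocol

The data are split once into stratified train/test partitions (delegated to
scikit-learn's stratified splitter; proportions per class are exact to one
record). Each bootstrap replicate resamples the *training* partition with
replacement, refits the tree, and scores the fixed test partition at the
chosen threshold; accuracy, specificity, sensitivity and precision are
reported in percent with mean point estimates and 2.5/97.5-percentile 95%
CIs across replicates. Resampling only the training partition against a
fixed test set is the simplest protocol consistent with splitting before
bootstrapping; it is a documented choice, not the only defensible one.
Replicates missing a class are skipped and counted; replicate metrics with
zero denominators are excluded from that metric's aggregation and logged.
All randomness derives from one seed through counter-based substreams
(`default_rng([seed, replicate])`), so reports are exactly reproducible.
Benchmark models (logistic regression, decision trees, ...) plug in through
the same two-method interface via a thin scikit-learn adapter; they are
harness features, not re-implementations.

## Synthetic data

No clinical data ship with the package; everything is generated.

* The **demo fixture** is built by inducing the tree from 4 000 constructed
  records so that its constants are exact: leaf positive-class fractions
  0, 0, 0.667 (667/1000) and 0.5, with the crisp covariates forming a
  single chain. The default fuzzy sets are the ramps *50Plus* (age 40→50
  years) and *Large Nodule* (10→20 mm); each ramp reaches full membership
  exactly at its crisp cut (age 50, 20 mm), so membership at 48 years and
  18 mm is 0.8 and the crisp and fuzzy views agree at the cut.
* The **cohort generators** emulate the two case-study schemas: thyroid
  (5-level cytology class, gender, thyroiditis, struma, continuous age and
  nodule size → 5·2⁵ = 160 possible realizations; default n = 401,
  prevalence 0.08, consistent with the 5–10% malignancy rate of thyroid
  nodules) and CKD (4-level GFR stage, diabetes, and six fuzzy labs/age →
  4·2⁷ = 512 realizations; default n = 2 599, invented two-year progression
  prevalence 0.20). Features are drawn independently from declared
  marginals (normals clipped to the universe, or uniforms); the outcome is
  Bernoulli with per-stratum probabilities, rescaled so the expected
  positive fraction equals the configured prevalence (the rescaling factor
  is analytic for tabulated rules, realized-mean for callable rules). All
  marginals and risk tables are invented: the generators reproduce the
  schemas, realization sparsity and prevalence regime of the case studies,
  **not** their joint distributions, so passing tests demonstrate
  correctness of the algorithms and recovery of known generating rules —
  they say nothing about clinical performance on real cohorts.
* Because features are independent by construction, every conditional
  transition probability equals the corresponding marginal, which is what
  the parameter-recovery tests compare against (within 0.02 on 50 000
  records, on branches with at least 2 000 supporting records).
* `smooth_risk_cohort` draws outcomes from a risk that ramps smoothly
  through the classification threshold inside the fuzzy transition region;
  it is the setting where membership-weighted traversal should recover
  borderline positives that a crisp dichotomy misses, and the fuzzy-vs-crisp
  sensitivity comparison is asserted only as a tendency averaged over 20
  seeds.

## Numerical choices and problem sizes

Probability normalization is checked to 1e-9. Exactness-sensitive
comparisons in tests use absolute tolerances of 1e-10–1e-12 (pure float
arithmetic over products and sums). The traversal recursion depth equals
the feature count (≤ 10 in all shipped schemas). Oracle-equivalence
properties run on 100 random full-factorial fixtures of up to 6 features
(so that every branch exists and the enumeration oracle has a closed form);
parameter recovery uses one 50 000-record cohort; bootstrap tests use tens
to hundreds of replicates on cohorts of 150–4 000 records. These sizes were
chosen to make every probabilistic assertion statistically comfortable
while keeping the whole suite under a minute of compute.

## Known limitations

* Binary targets only; no automatic feature selection or ordering; tree
  structure is the fixed-order chain of the declared features.
* Membership functions are piecewise linear; no Gaussian/sigmoidal families
  and no fuzzy rule inference (Mamdani/Sugeno) — fuzzy sets act purely as
  traversal weights.
* Scenario queries are re-conditioning, not causal effect estimation.
* CKD fuzzy definitions are schema templates with placeholder knots; real
  applications must supply clinically grounded universes, knots and cuts.
* No probability calibration or ROC-based threshold optimization.
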