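# fptree — fuzzy probability trees for interpretable clinical prediction

`fptree` implements **fuzzy probability trees (FPTs)**: discrete probability
trees induced from tabular patient records, extended with fuzzy linguistic
variables so that a prediction traverses *every* compatible branch, weighted
by the patient's membership degrees, instead of forcing borderline values
through a crisp cut. It is aimed at biostatisticians and clinical-modelling
researchers who need an inherently interpretable classifier over modest
tabular cohorts — the reference settings are thyroid-nodule malignancy
classification and two-year progression of chronic kidney disease to
end-stage renal disease.

## The model

A probability tree over an expert-chosen feature order
$X_1, \dots, X_d$ branches at depth $k$ on the values of $X_k$. Each node
$n = (w, \mathcal{S}, \mathcal{C})$ carries a statement
"$X_k$ IS $v$" and an ordered set of transitions $(\theta, m)$, where
$\theta_{w,m} = P(S_m \mid S_w)$ is the empirical conditional relative
frequency of the child's statement given the path to the parent. A *total
realization* is a root-to-leaf path with probability
$\prod \theta$; leaves store per-class record counts for the binary target.
Events are Boolean propositions ($\neg, \wedge, \vee$) over statements,
with probability equal to the summed probability of the realizations they
select.

A **fuzzy** probability tree declares some numeric features as linguistic
variables. A term $\tilde{A}$ (e.g. *Large Nodule*) is a fuzzy set over the
feature's universe of discourse $U$ with a piecewise-linear membership
function $\mu_{\tilde{A}}: U \to [0,1]$. At prediction time a raw value $u$
is mapped to one degree per branch; the degrees, renormalized to sum to 1,
replace the single crisp branch choice:

$$P(\text{class} \mid \text{patient}) \;=\; \sum_{\text{paths}}
\Big(\prod_{\text{fuzzy splits}} \mu \Big)
\Big(\prod_{\text{remaining splits}} \theta \text{ or } \tfrac{1}{|C|}\Big)
\cdot \frac{\#\text{class at leaf}}{\#\text{leaf}}$$

Unseen values fall back to theta-weighted averages over the children,
unknown variables to uniform averages, and patients not represented in the
training data to the longest represented subset of their conditions. The
classification rule is an inclusive cut-off: positive iff
$P(\text{positive}) \geq 0.50$ by default. Crisp probability-tree
prediction is the special case in which every ramp is a step function at
its cut.

The package also provides event algebra, what-if scenario queries
(substitute or remove conditions and re-traverse), a bootstrap evaluation
harness (stratified split, resampling with replacement, accuracy /
specificity / sensitivity / precision with 95% percentile CIs), synthetic
cohort generators with analytically known conditionals, JSON model
serialization, GraphViz DOT export, and a CLI.

## Worked example

The demonstration fixture encodes a small thyroid subtree (all records are
TIR3B cytology, female, no thyroiditis, no struma) with leaf class
fractions 0 / 0 / 0.667 / 0.5 over the four age × nodule-size branches, and
a demonstration patient aged 48 with an 18 mm nodule. *50Plus* ramps from
age 40 to 50 and *Large Nodule* from 10 mm to 20 mm, so the patient has
membership 0.8 in both:

```python
from fptree import make_demo_fixture, predict, crisp_predict, branch_weights

demo = make_demo_fixture()
print(branch_weights(demo.fuzzy_config["Age"], 48))
# {'50Plus': 0.8, 'Under50': 0.19999999999999996}

fuzzy = predict(demo.tree, demo.fuzzy_config, demo.patient)
crisp = crisp_predict(demo.tree, demo.fuzzy_config, demo.crisp_cuts, demo.patient)
print(f"FPT: P+ = {fuzzy.prob_positive:.5f}, P- = {fuzzy.prob_negative:.5f}")
print(f"PT : P+ = {crisp.prob_positive:.5f}, P- = {crisp.prob_negative:.5f}")
```

prints

```
FPT: P+ = 0.42672, P- = 0.57328
PT : P+ = 0.00000, P- = 1.00000
```

The crisp tree sends age 48 down the under-50 branch and the 18 mm nodule
down the small-nodule branch, reaching a purely benign leaf (probability
1). The fuzzy traversal instead expands

```
0.2·(0.2·1·0 + 0.8·1·0) + 0.8·(0.2·0.333·0 + 0.2·0.667·1 + 0.8·0.5·0 + 0.8·0.5·1)
  = 0.427
```

— the weighted positive-class value 0.42672, reflecting that this patient
is nearly 50 with a nearly large nodule. Both class probabilities are
reported; the labels follow the 0.50 cut-off.

## Command line

```bash
fptree simulate --cohort thyroid --n 401 --seed 1 --out cohort.csv
fptree build --data cohort.csv --config config.yaml --out model.json
fptree predict --model model.json --config config.yaml --patients patients.csv
fptree evaluate --data cohort.csv --config config.yaml --bootstraps 250 --seed 7
fptree counterfactual --model model.json --config config.yaml \
    --patient patient.csv --set Treatment=Yes --unset Struma
fptree export-dot --model model.json --out tree.dot
```

A model config (YAML or JSON) declares the feature order, the binary
target, per-variable types, and for each fuzzy variable its universe, term
knots and crisp cut; `fptree.demo_model_config()` shows the full shape.

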