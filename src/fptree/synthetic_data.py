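"""Synthetic fixtures and cohorts with known generating rules.

Two kinds of data back the test and demonstration surface of the package:

* :func:`make_demo_fixture` — a small hand-checkable tree over the thyroid
  schema (5-level cytology class, binary covariates, fuzzy age and nodule
  size) whose transition probabilities and leaf class fractions are simple
  printed constants, together with the demonstration patient (TIR3B,
  female, age 48, no thyroiditis, no struma, 18 mm nodule) and the default
  ramp membership functions.

* :func:`generate_cohort` — schema-faithful cohorts for the thyroid-nodule
  and chronic-kidney-disease case studies.  Features are drawn
  independently from declared marginals; the binary outcome is drawn from
  per-stratum probabilities, so every conditional probability of the
  generator is known analytically and parameter recovery can be tested.
  All marginal distributions and risk tables here are invented, schema
  stand-ins for the private clinical cohorts — they emulate the structure
  of those data sets, not their joint distributions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_tree import FPTError, ProbabilityTree, Statement, build_tree
from .fuzzy import FuzzySet, LinguisticVariable
from .prediction import FuzzyConfig, PatientRecord

logger = logging.getLogger("fptree")


# ---------------------------------------------------------------------------
# Demo fixture
# ---------------------------------------------------------------------------

@dataclass
class DemoFixture:
    """The worked-example tree, patient and fuzzy configuration."""

    tree: ProbabilityTree
    patient: PatientRecord
    fuzzy_config: FuzzyConfig
    crisp_cuts: dict[str, float]
    records: pd.DataFrame


def demo_fuzzy_config() -> FuzzyConfig:
    """Default linguistic variables of the thyroid demonstration.

    '50Plus' ramps linearly from 0 at age 40 to 1 at age 50 (so age 48 has
    degree 0.8) and 'Large Nodule' ramps from 0 at 10 mm to 1 at 20 mm (so
    an 18 mm nodule has degree 0.8); each crisp cut coincides with the
    point where its ramp reaches full membership.
    """
    age = LinguisticVariable(
        name="Age",
        universe=(0.0, 120.0),
        unit="years",
        sets=[
            FuzzySet("50Plus", [(40.0, 0.0), (50.0, 1.0)]),
            FuzzySet("Under50", [(40.0, 1.0), (50.0, 0.0)]),
        ],
    )
    nodule = LinguisticVariable(
        name="NoduleDimensions",
        universe=(0.0, 60.0),
        unit="mm",
        sets=[
            FuzzySet("Large Nodule", [(10.0, 0.0), (20.0, 1.0)]),
            FuzzySet("Small Nodule", [(10.0, 1.0), (20.0, 0.0)]),
        ],
    )
    return {"Age": age, "NoduleDimensions": nodule}


DEMO_CRISP_CUTS = {"Age": 50.0, "NoduleDimensions": 20.0}

DEMO_FEATURE_ORDER = [
    "Class", "Gender", "Age", "Thyroiditis", "Struma", "NoduleDimensions",
]


def make_demo_fixture() -> DemoFixture:
    """Build the demonstration subtree with its printed constants.

    The records realize exactly the worked-example probabilities: under the
    'Under50' age branch both nodule leaves are purely benign (class
    fraction 1 for the negative class), while under '50Plus' the small- and
    large-nodule leaves have positive-class fractions 0.667 and 0.5.  The
    crisp covariates (cytology class TIR3B, female, no thyroiditis, no
    struma) form a single chain, as in the subtree relevant to the
    demonstration patient.
    """
    blocks = [
        # (age term, nodule term, n_benign, n_malignant)
        ("Under50", "Small Nodule", 1000, 0),
        ("Under50", "Large Nodule", 1000, 0),
        ("50Plus", "Small Nodule", 333, 667),
        ("50Plus", "Large Nodule", 500, 500),
    ]
    rows = []
    for age_term, nodule_term, n_benign, n_malignant in blocks:
        for outcome, count in (("0", n_benign), ("1", n_malignant)):
            rows.extend(
                {
                    "Class": "TIR3B",
                    "Gender": "Female",
                    "Age": age_term,
                    "Thyroiditis": "No",
                    "Struma": "No",
                    "NoduleDimensions": nodule_term,
                    "Malignant": outcome,
                }
                for _ in range(count)
            )
    records = pd.DataFrame(rows)
    tree = build_tree(records, DEMO_FEATURE_ORDER, target="Malignant")
    patient = PatientRecord(
        statements=[
            Statement("Class", "TIR3B"),
            Statement("Gender", "Female"),
            Statement("Thyroiditis", "No"),
            Statement("Struma", "No"),
        ],
        raw_values={"Age": 48.0, "NoduleDimensions": 18.0},
    )
    return DemoFixture(
        tree=tree,
        patient=patient,
        fuzzy_config=demo_fuzzy_config(),
        crisp_cuts=dict(DEMO_CRISP_CUTS),
        records=records,
    )


# ---------------------------------------------------------------------------
# Cohort generators
# ---------------------------------------------------------------------------

@dataclass
class CategoricalFeature:
    name: str
    values: list[str]
    probs: list[float]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs):
            raise FPTError(f"feature {self.name!r}: values/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise FPTError(f"feature {self.name!r}: probabilities must sum to 1")


@dataclass
class ContinuousFeature:
    """A numeric feature with a binary linguistic partition.

    The 'high' term ramps linearly from 0 at ``ramp_low`` to 1 at
    ``ramp_high``; the crisp cut dichotomizes at ``cut`` (high iff value >=
    cut).  Values are drawn from a normal (mean, sd) or uniform
    distribution and clipped to the universe.
    """

    name: str
    mean: float
    sd: float
    universe: tuple[float, float]
    cut: float
    high_term: str
    low_term: str
    ramp_low: float
    ramp_high: float
    unit: str = ""
    dist: str = "normal"

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < self.cut <= hi:
            raise FPTError(f"feature {self.name!r}: cut outside universe")

    def linguistic(self) -> LinguisticVariable:
        high = FuzzySet(self.high_term, [(self.ramp_low, 0.0), (self.ramp_high, 1.0)])
        return LinguisticVariable(
            name=self.name,
            universe=self.universe,
            sets=[high, high.complement(self.low_term)],
            unit=self.unit,
        )

    def prob_high(self) -> float:
        """Analytic probability that the crisp term is the high one."""
        lo, hi = self.universe
        if self.dist == "normal":
            return float(norm.sf(self.cut, loc=self.mean, scale=self.sd))
        if self.dist == "uniform":
            return (hi - self.cut) / (hi - lo)
        raise FPTError(f"unknown distribution {self.dist!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.universe
        if self.dist == "normal":
            values = rng.normal(self.mean, self.sd, size=n)
        else:
            values = rng.uniform(lo, hi, size=n)
        return np.clip(values, lo, hi)


GeneratingRule = Mapping[tuple, float] | Callable[[pd.DataFrame], np.ndarray]


@dataclass
class CohortSpec:
    """Schema, marginals, outcome rule and size of a synthetic cohort.

    ``generating_rule`` is either a mapping from tuples of (crisp) values
    of ``strata_features`` to positive-class probabilities, or a callable
    returning one probability weight per record.  With ``prevalence`` set,
    the rule is rescaled so the expected positive fraction equals the
    prevalence; with ``prevalence=None`` the rule's values are used as
    absolute probabilities.
    """

    name: str
    features: list[CategoricalFeature | ContinuousFeature]
    strata_features: list[str]
    generating_rule: GeneratingRule
    prevalence: float | None
    n: int
    seed: int = 0
    target: str = "Outcome"

    def __post_init__(self) -> None:
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise FPTError(f"prevalence {self.prevalence} outside (0, 1)")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise FPTError(f"duplicate feature names in cohort {self.name!r}")
        for s in self.strata_features:
            if s not in names:
                raise FPTError(f"stratum feature {s!r} not in schema")
        if isinstance(self.generating_rule, Mapping):
            for key, p in self.generating_rule.items():
                if not 0.0 <= p <= 1.0:
                    raise FPTError(f"stratum {key}: probability {p} outside [0,1]")

    # -- schema views -------------------------------------------------------

    @property
    def feature_order(self) -> list[str]:
        return [f.name for f in self.features]

    def continuous(self) -> list[ContinuousFeature]:
        return [f for f in self.features if isinstance(f, ContinuousFeature)]

    def fuzzy_config(self) -> FuzzyConfig:
        return {f.name: f.linguistic() for f in self.continuous()}

    def crisp_cuts(self) -> dict[str, float]:
        return {f.name: f.cut for f in self.continuous()}

    def n_realizations(self) -> int:
        """Number of possible total realizations (value combinations)."""
        out = 1
        for f in self.features:
            out *= len(f.values) if isinstance(f, CategoricalFeature) else 2
        return out

    # -- analytic generator quantities --------------------------------------

    def marginal(self, feature: str, value: str) -> float:
        """Analytic marginal probability of a crisp feature value."""
        for f in self.features:
            if f.name != feature:
                continue
            if isinstance(f, CategoricalFeature):
                if value not in f.values:
                    raise FPTError(f"{value!r} not a level of {feature!r}")
                return f.probs[f.values.index(value)]
            if value == f.high_term:
                return f.prob_high()
            if value == f.low_term:
                return 1.0 - f.prob_high()
            raise FPTError(f"{value!r} not a term of {feature!r}")
        raise FPTError(f"unknown feature {feature!r}")

    def _stratum_levels(self) -> list[list[str]]:
        levels = []
        for name in self.strata_features:
            f = next(f for f in self.features if f.name == name)
            if isinstance(f, CategoricalFeature):
                levels.append(list(f.values))
            else:
                levels.append([f.low_term, f.high_term])
        return levels

    def expected_rule(self) -> float:
        """E[generating_rule] under the independent feature marginals."""
        if not isinstance(self.generating_rule, Mapping):
            raise FPTError("expected_rule requires a per-stratum rule mapping")
        total = 0.0
        for combo in itertools.product(*self._stratum_levels()):
            p_stratum = math.prod(
                self.marginal(f, v) for f, v in zip(self.strata_features, combo)
            )
            total += p_stratum * self.generating_rule[tuple(combo)]
        return total

    def stratum_table(self) -> pd.DataFrame:
        """Analytic stratum probabilities and positive-class probabilities."""
        if not isinstance(self.generating_rule, Mapping):
            raise FPTError("stratum_table requires a per-stratum rule mapping")
        scale = 1.0
        if self.prevalence is not None:
            scale = self.prevalence / self.expected_rule()
        rows = []
        for combo in itertools.product(*self._stratum_levels()):
            p_stratum = math.prod(
                self.marginal(f, v) for f, v in zip(self.strata_features, combo)
            )
            p_pos = min(1.0, self.generating_rule[tuple(combo)] * scale)
            rows.append(
                dict(zip(self.strata_features, combo))
                | {"p_stratum": p_stratum, "p_positive": p_pos}
            )
        return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort: independent features, outcome per generating rule.

    Fully reproducible from the seed (``seed`` overrides ``spec.seed``).
    Continuous columns keep their raw numeric values; discretization to
    linguistic terms happens at model-fitting time.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    data: dict[str, np.ndarray] = {}
    for f in spec.features:
        if isinstance(f, CategoricalFeature):
            data[f.name] = rng.choice(f.values, size=n, p=f.probs)
        else:
            data[f.name] = f.draw(rng, n)
    df = pd.DataFrame(data)

    if isinstance(spec.generating_rule, Mapping):
        crisp = df.copy()
        for f in spec.continuous():
            crisp[f.name] = np.where(
                df[f.name] >= f.cut, f.high_term, f.low_term
            )
        keys = list(zip(*(crisp[s] for s in spec.strata_features)))
        weights = np.array([spec.generating_rule[k] for k in keys], dtype=float)
        scale = 1.0 if spec.prevalence is None \
            else spec.prevalence / spec.expected_rule()
    else:
        weights = np.asarray(spec.generating_rule(df), dtype=float)
        scale = 1.0 if spec.prevalence is None \
            else spec.prevalence / weights.mean()

    p = weights * scale
    if (p > 1.0).any():
        logger.warning(
            "cohort %s: %d stratum probabilities clipped to 1",
            spec.name, int((p > 1.0).sum()),
        )
        p = np.clip(p, 0.0, 1.0)
    df[spec.target] = (rng.random(n) < p).astype(int)
    return df


# ---------------------------------------------------------------------------
# Shipped cohort schemas (invented marginals and risk tables)
# ---------------------------------------------------------------------------

def thyroid_cohort(n: int = 401, prevalence: float | None = 0.08,
                   seed: int = 0) -> CohortSpec:
    """Thyroid-nodule-like cohort: 5-level cytology class, binary
    covariates, continuous age (years) and nodule size (mm).

    The default size mirrors the case study's 401 records, giving the same
    realization sparsity (401 / 160 ~ 2.5 records per possible path); the
    default prevalence 0.08 reflects that roughly 5-10% of thyroid nodules
    are malignant.  Risk rises with the cytology class and with a large
    nodule.
    """
    features = [
        CategoricalFeature("Class", ["TIR2", "TIR3A", "TIR3B", "TIR4", "TIR5"],
                           [0.40, 0.15, 0.15, 0.20, 0.10]),
        CategoricalFeature("Gender", ["Female", "Male"], [0.80, 0.20]),
        ContinuousFeature("Age", mean=52.0, sd=15.0, universe=(18.0, 95.0),
                          cut=50.0, high_term="50Plus", low_term="Under50",
                          ramp_low=40.0, ramp_high=50.0, unit="years"),
        CategoricalFeature("Thyroiditis", ["No", "Yes"], [0.85, 0.15]),
        CategoricalFeature("Struma", ["No", "Yes"], [0.80, 0.20]),
        ContinuousFeature("NoduleDimensions", mean=16.0, sd=8.0,
                          universe=(1.0, 60.0), cut=20.0,
                          high_term="Large Nodule", low_term="Small Nodule",
                          ramp_low=10.0, ramp_high=20.0, unit="mm"),
    ]
    rule = {}
    base = {"TIR2": 0.02, "TIR3A": 0.05, "TIR3B": 0.15, "TIR4": 0.50,
            "TIR5": 0.85}
    bump = {"TIR2": 0.04, "TIR3A": 0.08, "TIR3B": 0.25, "TIR4": 0.65,
            "TIR5": 0.95}
    for cls in base:
        rule[(cls, "Small Nodule")] = base[cls]
        rule[(cls, "Large Nodule")] = bump[cls]
    return CohortSpec(
        name="thyroid",
        features=features,
        strata_features=["Class", "NoduleDimensions"],
        generating_rule=rule,
        prevalence=prevalence,
        n=n,
        seed=seed,
        target="Malignant",
    )


def ckd_cohort(n: int = 2599, prevalence: float | None = 0.20,
               seed: int = 0) -> CohortSpec:
    """CKD-like cohort: GFR stage plus binary/fuzzy labs, 2-year
    end-stage-renal-disease outcome.

    One 4-level feature and seven binaries give 4 * 2^7 = 512 possible
    realizations; the default 2599 records match the case study's cohort
    size (~5 records per realization).  The 0.20 two-year progression
    prevalence and all risk numbers are invented placeholders.  Progression
    risk rises with GFR stage and proteinuria.
    """
    features = [
        CategoricalFeature("GFRStage", ["G2", "G3a", "G3b", "G4"],
                           [0.20, 0.30, 0.30, 0.20]),
        CategoricalFeature("Diabetes", ["No", "Yes"], [0.65, 0.35]),
        ContinuousFeature("Age", mean=65.0, sd=12.0, universe=(18.0, 95.0),
                          cut=50.0, high_term="50Plus", low_term="Under50",
                          ramp_low=40.0, ramp_high=50.0, unit="years"),
        ContinuousFeature("SerumCreatinine", mean=1.8, sd=0.8,
                          universe=(0.4, 8.0), cut=2.0,
                          high_term="HighCreatinine", low_term="NormalCreatinine",
                          ramp_low=1.5, ramp_high=2.0, unit="mg/dL"),
        ContinuousFeature("Hemoglobin", mean=11.5, sd=1.8,
                          universe=(6.0, 18.0), cut=11.0,
                          high_term="NotAnemic", low_term="Anemic",
                          ramp_low=10.0, ramp_high=11.0, unit="g/dL"),
        ContinuousFeature("Proteinuria", mean=1.2, sd=0.9,
                          universe=(0.0, 10.0), cut=1.0,
                          high_term="HighProteinuria", low_term="LowProteinuria",
                          ramp_low=0.5, ramp_high=1.0, unit="g/day"),
        ContinuousFeature("Phosphate", mean=4.0, sd=0.9,
                          universe=(1.0, 9.0), cut=4.5,
                          high_term="HighPhosphate", low_term="NormalPhosphate",
                          ramp_low=4.0, ramp_high=4.5, unit="mg/dL"),
        ContinuousFeature("Potassium", mean=4.6, sd=0.6,
                          universe=(2.5, 8.0), cut=5.0,
                          high_term="Hyperkalemia", low_term="NormalKalemia",
                          ramp_low=4.5, ramp_high=5.0, unit="mmol/L"),
    ]
    rule = {}
    low = {"G2": 0.02, "G3a": 0.05, "G3b": 0.12, "G4": 0.30}
    high = {"G2": 0.08, "G3a": 0.15, "G3b": 0.30, "G4": 0.55}
    for stage in low:
        rule[(stage, "LowProteinuria")] = low[stage]
        rule[(stage, "HighProteinuria")] = high[stage]
    return CohortSpec(
        name="ckd",
        features=features,
        strata_features=["GFRStage", "Proteinuria"],
        generating_rule=rule,
        prevalence=prevalence,
        n=n,
        seed=seed,
        target="ESRD2y",
    )


def smooth_risk_cohort(n: int = 600, seed: int = 0) -> CohortSpec:
    """A cohort whose outcome probability is a smooth ramp in one
    continuous feature — the setting where fuzzy traversal should recover
    borderline cases that a crisp cut misclassifies.

    True risk ramps from 0.35 below x=40 to 0.80 above x=60, crossing the
    classification threshold inside the fuzzy transition region, so the
    membership-weighted prediction tracks the true risk where the crisp
    dichotomy cannot.
    """
    features = [
        ContinuousFeature("Biomarker", mean=50.0, sd=12.0,
                          universe=(20.0, 80.0), cut=50.0,
                          high_term="High", low_term="Low",
                          ramp_low=40.0, ramp_high=60.0, unit="au"),
        CategoricalFeature("Comorbidity", ["No", "Yes"], [0.7, 0.3]),
    ]

    def rule(df: pd.DataFrame) -> np.ndarray:
        x = df["Biomarker"].to_numpy(dtype=float)
        ramp = np.clip((x - 40.0) / 20.0, 0.0, 1.0)
        return 0.35 + 0.45 * ramp

    return CohortSpec(
        name="smooth",
        features=features,
        strata_features=["Biomarker"],
        generating_rule=rule,
        prevalence=None,
        n=n,
        seed=seed,
        target="Event",
    )
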