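"""What-if scenario queries over a fitted tree.

A scenario takes a patient's factual evidence and re-evaluates the class
probability after substituting some statements (interventions, e.g. "what
if this patient had taken RASI medication?") and/or treating some variables
as unknown (removals, handled by uniform branch weighting).

Semantics: scenario queries are condition substitution followed by
re-traversal of the same tree — observational re-conditioning.  They are
not structural counterfactuals with explicit exogenous noise (no
abduction–action–prediction step); the factual and scenario probabilities
are returned side by side for exactly that comparative reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .core_tree import FPTError, ProbabilityTree, Statement
from .prediction import FuzzyConfig, PatientRecord, fuzzy_predict


@dataclass
class Scenario:
    """Factual evidence plus the edits defining the alternate world."""

    evidence: PatientRecord
    interventions: list[Statement] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = {s.variable for s in self.interventions} & set(self.removed)
        if overlap:
            raise FPTError(
                f"variables {sorted(overlap)} are both intervened on and removed"
            )


class ScenarioResult(NamedTuple):
    factual: float
    scenario: float


def _apply(scenario: Scenario) -> PatientRecord:
    """Evidence with interventions substituted and removals dropped."""
    replaced = {s.variable: s for s in scenario.interventions}
    removed = set(scenario.removed)
    statements = [
        replaced.pop(s.variable, s)
        for s in scenario.evidence.statements
        if s.variable not in removed
    ]
    raw = {
        k: v for k, v in scenario.evidence.raw_values.items()
        if k not in removed and k not in replaced
    }
    for s in replaced.values():  # interventions on previously unknown variables
        statements.append(s)
    return PatientRecord(statements=statements, raw_values=raw,
                         outcome=scenario.evidence.outcome)


def counterfactual_query(
    tree: ProbabilityTree,
    fuzzy_config: FuzzyConfig | None,
    scenario: Scenario,
    cls: object,
) -> ScenarioResult:
    """(factual, scenario) probability of class ``cls``.

    The factual probability is the fuzzy prediction on the evidence as
    given; the scenario probability re-traverses the tree with the
    interventions substituted and the removed variables treated as unknown.
    """
    fuzzy_config = fuzzy_config or {}
    for s in scenario.interventions:
        if s.variable not in tree.feature_order:
            raise FPTError(
                f"intervention on variable {s.variable!r} absent from the tree"
            )
    for name in scenario.removed:
        if name not in tree.feature_order:
            raise FPTError(f"removed variable {name!r} absent from the tree")

    factual = _patient_probability(tree, fuzzy_config, scenario.evidence, cls)
    altered = _patient_probability(tree, fuzzy_config, _apply(scenario), cls)
    return ScenarioResult(factual=factual, scenario=altered)


def _patient_probability(
    tree: ProbabilityTree,
    fuzzy_config: FuzzyConfig,
    patient: PatientRecord,
    cls: object,
) -> float:
    from .prediction import _assemble_statements

    statements = _assemble_statements(tree, fuzzy_config, patient)
    return fuzzy_predict(tree, tree.root, statements, cls, fuzzy_config)


def intervene(patient: PatientRecord, **edits) -> Scenario:
    """Shorthand: ``intervene(patient, Treatment='RASI', Age=None)`` builds a
    Scenario substituting keyword values and removing keys given None."""
    interventions = [
        Statement(k, str(v)) for k, v in edits.items() if v is not None
    ]
    removed = [k for k, v in edits.items() if v is None]
    return Scenario(evidence=patient, interventions=interventions, removed=removed)
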