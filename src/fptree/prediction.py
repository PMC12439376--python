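"""Fuzzy and crisp prediction over probability trees.

Crisp probability-tree prediction follows the single root-to-leaf path
selected by a patient's discrete statements and returns the class fraction
at the reached leaf.  Fuzzy prediction generalizes this: at a split on a
linguistic variable, the patient's raw value is converted to a membership
degree per branch and the prediction is the membership-weighted average of
the branch predictions, so all compatible paths contribute.

The recursion mirrors the traversal contract case by case:

(i)   at a leaf, return the requested class's fraction of the leaf counts;
(ii)  with no statements left, return the conditional class probability
      given the path so far (the count-weighted aggregate of the subtree);
(iii) if the next statement's variable is the children's variable and a
      value (or fuzzy raw value) matches, weight the matching children by
      their renormalized membership degrees (1 for a crisp match) and
      recurse;
(iv)  if the variable matches but the stated value has no child (a
      combination absent from the training data), take the theta-weighted
      average over all children;
(v)   if the patient carries no statement for the children's variable,
      average the children uniformly with weight 1/|children|.

Classification applies an inclusive cut-off: the positive class is
predicted when its probability is >= the threshold (default 0.50).
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field

from .core_tree import (
    FPTError,
    Node,
    ProbabilityTree,
    Statement,
    UnsupportedQueryError,
    _check_class,
)
from .fuzzy import LinguisticVariable, branch_weights, crisp_variant

logger = logging.getLogger("fptree")

DEFAULT_THRESHOLD = 0.50

FuzzyConfig = dict[str, LinguisticVariable]


@dataclass
class PatientRecord:
    """A patient: discrete statements plus raw values for fuzzy variables."""

    statements: list[Statement] = field(default_factory=list)
    raw_values: dict[str, float] = field(default_factory=dict)
    outcome: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.statements:
            if s.variable in seen:
                raise FPTError(f"duplicate statement for {s.variable!r}")
            seen.add(s.variable)


@dataclass
class PredictionResult:
    """Both class probabilities, the thresholded label, and the support
    (number of training records that contributed to the estimate)."""

    prob_positive: float
    prob_negative: float
    label: str
    threshold: float
    support: int


def _is_raw(value: object) -> bool:
    return isinstance(value, numbers.Number) and not isinstance(value, bool)


def _children_variable(node: Node) -> str:
    return node.children[0].statements[0].variable


def _subtree_fraction(node: Node, cls: str) -> tuple[float, int]:
    total = node.total_count()
    if total == 0:  # cannot occur on induced trees; defensive
        raise UnsupportedQueryError("subtree has zero training support")
    return node.class_count(cls) / total, total


def _traverse(
    node: Node,
    statements: list[Statement],
    cls: str,
    fuzzy_config: FuzzyConfig,
    order: dict[str, int] | None = None,
) -> tuple[float, int]:
    """Recursive core of fuzzy prediction; returns (probability, support)."""
    if node.is_leaf:  # case (i)
        total = sum(node.class_counts.values())
        return node.class_counts.get(cls, 0) / total, total
    if not statements:  # case (ii)
        return _subtree_fraction(node, cls)

    var = _children_variable(node)
    head = statements[0]
    if order and head.variable != var and \
            order.get(head.variable, -1) < order.get(var, -1):
        # statement about a variable above this subtree: nothing to match
        return _traverse(node, statements[1:], cls, fuzzy_config, order)
    if head.variable != var:
        # case (v): the patient asserts nothing about this split's variable.
        rest = statements
        prob = 0.0
        support = 0
        weight = 1.0 / len(node.children)
        for child in node.children:
            p, s = _traverse(child, rest, cls, fuzzy_config, order)
            prob += weight * p
            support += s
        return prob, support

    rest = statements[1:]
    by_value = {child.statements[0].value: child for child in node.children}

    if var in fuzzy_config and _is_raw(head.value):
        # case (iii), fuzzy: weight all branches by membership degree.
        weights = branch_weights(fuzzy_config[var], float(head.value))
        present = {t: w for t, w in weights.items() if t in by_value and w > 0.0}
        total_w = sum(present.values())
        if total_w > 0.0:
            prob = 0.0
            support = 0
            for term, w in present.items():
                p, s = _traverse(by_value[term], rest, cls, fuzzy_config, order)
                prob += (w / total_w) * p
                support += s
            return prob, support
        # every positively-weighted term is an unseen branch: fall through
        # to the theta-weighted average of case (iv).
    elif head.value in by_value:
        # case (iii), crisp: follow the matching child with weight 1.
        return _traverse(by_value[head.value], rest, cls, fuzzy_config, order)

    # case (iv): variable present, value unseen in training.
    prob = 0.0
    support = 0
    for theta, child in node.transitions:
        p, s = _traverse(child, rest, cls, fuzzy_config, order)
        prob += theta * p
        support += s
    return prob, support


def fuzzy_predict(
    tree: ProbabilityTree,
    node: Node,
    statements: list[Statement],
    cls: object,
    fuzzy_config: FuzzyConfig | None = None,
) -> float:
    """Probability that a patient described by ``statements`` belongs to
    class ``cls``, traversing the (sub)tree rooted at ``node``.

    Statements must be ordered compatibly with the tree's feature order
    from ``node`` downward; fuzzy variables carry their raw numeric value.
    """
    cls = _check_class(tree, cls)
    if tree.node_by_id(node.id) is not node:
        raise FPTError(f"node {node.id} does not belong to this tree")
    ordered = _align(tree, statements, start_var=None)
    order = {v: i for i, v in enumerate(tree.feature_order)}
    prob, _ = _traverse(node, ordered, cls, fuzzy_config or {}, order)
    return prob


def _align(
    tree: ProbabilityTree,
    statements: list[Statement],
    start_var: str | None,
) -> list[Statement]:
    """Sort statements into feature order; reject unknown variables."""
    index = {v: i for i, v in enumerate(tree.feature_order)}
    for s in statements:
        if s.variable not in index:
            raise FPTError(f"statement on unknown variable {s.variable!r}")
    return sorted(statements, key=lambda s: index[s.variable])


def find_existing_conditions(
    tree: ProbabilityTree,
    statements: list[Statement],
) -> list[Statement]:
    """Longest subset of the statements supported by some path in the tree.

    Scanned in feature order, this returns the largest set of the patient's
    conditions that is represented in the training data, enabling
    prediction from the most similar observed profiles when the full
    combination never occurs.  Ties break toward the first path in the
    tree's deterministic child order.  An empty list is a valid result.
    """
    ordered = _align(tree, statements, None)
    want = {s.variable: str(s.value) for s in ordered}

    def best(node: Node) -> tuple[int, list[Statement]]:
        matched = [
            s for s in node.statements
            if want.get(s.variable) == str(s.value)
        ]
        if node.is_leaf:
            return len(matched), matched
        top_score = -1
        top_list: list[Statement] = []
        for _, child in node.transitions:
            score, kept = best(child)
            if score > top_score:
                top_score, top_list = score, kept
        return len(matched) + top_score, matched + top_list

    _, kept = best(tree.root)
    return kept


def predict(
    tree: ProbabilityTree,
    fuzzy_config: FuzzyConfig | None,
    patient: PatientRecord,
    threshold: float = DEFAULT_THRESHOLD,
    positive_label: str | None = None,
) -> PredictionResult:
    """Classify a patient with the fuzzy prediction algorithm.

    Raw values of fuzzy variables are fuzzified into branch weights; the
    positive-class probability is the membership- and theta-weighted
    aggregate over all compatible paths, and the label applies the
    inclusive threshold rule (positive iff P(positive) >= threshold).

    If the patient's conditions are not represented at all, the class prior
    is returned with a logged warning.
    """
    fuzzy_config = fuzzy_config or {}
    positive = _positive_label(tree, positive_label)
    statements = _assemble_statements(tree, fuzzy_config, patient)
    order = {v: i for i, v in enumerate(tree.feature_order)}
    try:
        prob, support = _traverse(
            tree.root, statements, positive, fuzzy_config, order
        )
    except UnsupportedQueryError:
        crisp_only = [s for s in statements if not _is_raw(s.value)]
        kept = find_existing_conditions(tree, crisp_only)
        if not kept:
            logger.warning(
                "no represented conditions for patient; returning class prior"
            )
        # Dropped variables are simply absent from the statement list, so
        # the traversal handles them by uniform child weighting (case v).
        fuzzy_stmts = [s for s in statements if _is_raw(s.value)]
        retry = _align(tree, kept + fuzzy_stmts, None)
        prob, support = _traverse(tree.root, retry, positive, fuzzy_config, order)

    prob_positive = prob
    prob_negative = 1.0 - prob_positive
    negative = next(c for c in tree.class_labels if c != positive) \
        if len(tree.class_labels) > 1 else positive
    label = positive if prob_positive >= threshold else negative
    return PredictionResult(
        prob_positive=prob_positive,
        prob_negative=prob_negative,
        label=label,
        threshold=threshold,
        support=support,
    )


def crisp_predict(
    tree: ProbabilityTree,
    fuzzy_config: FuzzyConfig | None,
    crisp_cuts: dict[str, float],
    patient: PatientRecord,
    threshold: float = DEFAULT_THRESHOLD,
    positive_label: str | None = None,
) -> PredictionResult:
    """Traditional (crisp) probability-tree prediction.

    Every linguistic variable's ramps are replaced by step functions at the
    declared cut, so exactly one branch per split receives weight 1 and the
    traversal follows a single path; this is fuzzy prediction in its crisp
    limit.
    """
    fuzzy_config = fuzzy_config or {}
    step_config = {
        name: crisp_variant(var, crisp_cuts[name])
        for name, var in fuzzy_config.items()
    }
    return predict(tree, step_config, patient, threshold, positive_label)


# ---------------------------------------------------------------------------
# helpers shared with evaluation / CLI
# ---------------------------------------------------------------------------

def _positive_label(tree: ProbabilityTree, positive_label: str | None) -> str:
    if positive_label is None:
        return tree.class_labels[-1]
    return _check_class(tree, positive_label)


def _assemble_statements(
    tree: ProbabilityTree,
    fuzzy_config: FuzzyConfig,
    patient: PatientRecord,
) -> list[Statement]:
    """Merge discrete statements and fuzzy raw values in feature order."""
    stated = {s.variable: s for s in patient.statements}
    out: list[Statement] = []
    for var in tree.feature_order:
        if var in patient.raw_values and var in fuzzy_config:
            out.append(Statement(var, float(patient.raw_values[var])))
        elif var in stated:
            out.append(stated[var])
    return out


def patient_from_row(
    row,
    feature_order: list[str],
    fuzzy_config: FuzzyConfig,
    target: str | None = None,
) -> PatientRecord:
    """Build a PatientRecord from a tabular row (a mapping or pandas Series).

    Fuzzy variables become raw values; everything else becomes a discrete
    statement.  Missing (NaN) entries are skipped: unknown variables are
    handled by uniform branch weighting at prediction time.
    """
    import pandas as pd

    statements: list[Statement] = []
    raw: dict[str, float] = {}
    for var in feature_order:
        if var not in row:
            continue
        value = row[var]
        if pd.isna(value):
            continue
        if var in fuzzy_config:
            raw[var] = float(value)
        else:
            statements.append(Statement(var, str(value)))
    outcome = None
    if target is not None and target in row and not pd.isna(row[target]):
        outcome = str(row[target])
    return PatientRecord(statements=statements, raw_values=raw, outcome=outcome)
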