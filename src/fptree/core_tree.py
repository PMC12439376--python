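"""Discrete probability trees induced from tabular records.

A probability tree (PT) is a rooted tree in which every node carries a
statement of the form ``variable IS value`` and every arc carries a
transition probability theta.  Here the tree is a fixed-order chain over a
declared list of features: all nodes at depth ``d`` branch on
``feature_order[d]``, and every root-to-leaf path (a *total realization*)
assigns a value to every feature.  The probability of a realization is the
product of the thetas along its path, and an *event* is a Boolean
proposition over statements that selects a set of realizations.

Transition probabilities are the raw empirical conditional frequencies of
the training records: theta on the arc into a child equals the fraction of
records at the parent that take that branch.  Branches never taken by any
training record are simply absent, so every stored leaf is supported by at
least one record and carries the per-class record counts used for
prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

THETA_TOL = 1e-9


class FPTError(Exception):
    """Base error for invalid trees, queries, or configurations."""


class UnsupportedQueryError(FPTError):
    """A query conditions on a feature combination with zero training support.

    Callers should fall back to the longest represented subset of their
    conditions (see ``prediction.find_existing_conditions``).
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Statement:
    """An assertion ``variable IS value`` — the atom of paths and patients.

    ``value`` is normally the string label of a category, binary level or
    linguistic term; prediction code may also carry a raw numeric value for
    a fuzzy variable, which is resolved to branch weights at traversal time.
    """

    variable: str
    value: object

    def __repr__(self) -> str:  # compact: ('Age' IS '50Plus')
        return f"({self.variable!r} IS {self.value!r})"


@dataclass
class Node:
    """Tree node: identifier, own statements, and weighted child arcs.

    ``statements`` holds the statement(s) asserted by reaching this node
    (empty at the root).  ``transitions`` is the ordered list of
    ``(theta, child)`` arcs; children are ordered by the sorted values of
    their statements so that serialization and traversal are deterministic.
    ``class_counts`` is present exactly at leaves and maps each class label
    to the number of training records ending in the leaf.
    """

    id: int
    statements: list[Statement] = field(default_factory=list)
    transitions: list[tuple[float, "Node"]] = field(default_factory=list)
    class_counts: dict[str, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.class_counts is not None

    @property
    def children(self) -> list["Node"]:
        return [child for _, child in self.transitions]

    def total_count(self) -> int:
        """Number of training records under this node."""
        if self.is_leaf:
            return sum(self.class_counts.values())
        return sum(child.total_count() for child in self.children)

    def class_count(self, cls: str) -> int:
        if self.is_leaf:
            return self.class_counts.get(cls, 0)
        return sum(child.class_count(cls) for child in self.children)


@dataclass
class ProbabilityTree:
    """A complete probability tree over a fixed feature order."""

    root: Node
    feature_order: list[str]
    target: str
    record_count: int
    class_labels: list[str]

    def nodes(self) -> Iterator[Node]:
        """Preorder iteration over all nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def node_by_id(self, node_id: int) -> Node:
        for node in self.nodes():
            if node.id == node_id:
                return node
        raise FPTError(f"no node with id {node_id} in tree")

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.nodes() if n.is_leaf)

    def validate(self) -> None:
        """Check structural invariants; raise FPTError on violation."""
        for node in self.nodes():
            if node.is_leaf:
                if node.transitions:
                    raise FPTError(f"leaf node {node.id} has transitions")
                if sum(node.class_counts.values()) < 1:
                    raise FPTError(f"leaf node {node.id} has zero support")
            else:
                total = sum(theta for theta, _ in node.transitions)
                if abs(total - 1.0) > THETA_TOL:
                    raise FPTError(
                        f"thetas at node {node.id} sum to {total}, not 1"
                    )
                for theta, _ in node.transitions:
                    if not 0.0 <= theta <= 1.0:
                        raise FPTError(f"theta {theta} outside [0,1]")
        depth = len(self.feature_order)
        total_prob = 0.0
        total_records = 0
        for realization in realizations(self):
            if len(realization.path) != depth:
                raise FPTError("leaf depth differs from feature count")
            total_prob += realization.probability
            total_records += sum(realization.leaf.class_counts.values())
        if abs(total_prob - 1.0) > THETA_TOL:
            raise FPTError(f"realization probabilities sum to {total_prob}")
        if total_records != self.record_count:
            raise FPTError(
                f"leaf counts total {total_records} != record_count "
                f"{self.record_count}"
            )


@dataclass
class Realization:
    """A root-to-leaf path with its product-of-thetas probability."""

    path: list[Statement]
    probability: float
    leaf: Node

    def assignment(self) -> dict[str, object]:
        return {s.variable: s.value for s in self.path}


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

class EventExpression:
    """Boolean proposition over statements, evaluable on a realization.

    Supports operator syntax: ``Atom('X', 'a') & ~Atom('Y', '1')``.
    """

    def evaluate(self, assignment: Mapping[str, object]) -> bool:
        raise NotImplementedError

    def variables(self) -> set[str]:
        raise NotImplementedError

    def __and__(self, other: "EventExpression") -> "EventExpression":
        return And(self, other)

    def __or__(self, other: "EventExpression") -> "EventExpression":
        return Or(self, other)

    def __invert__(self) -> "EventExpression":
        return Not(self)


@dataclass(frozen=True)
class Atom(EventExpression):
    variable: str
    value: object

    def evaluate(self, assignment: Mapping[str, object]) -> bool:
        return assignment.get(self.variable) == self.value

    def variables(self) -> set[str]:
        return {self.variable}


@dataclass(frozen=True)
class Not(EventExpression):
    operand: EventExpression

    def evaluate(self, assignment: Mapping[str, object]) -> bool:
        return not self.operand.evaluate(assignment)

    def variables(self) -> set[str]:
        return self.operand.variables()


@dataclass(frozen=True)
class And(EventExpression):
    left: EventExpression
    right: EventExpression

    def evaluate(self, assignment: Mapping[str, object]) -> bool:
        return self.left.evaluate(assignment) and self.right.evaluate(assignment)

    def variables(self) -> set[str]:
        return self.left.variables() | self.right.variables()


@dataclass(frozen=True)
class Or(EventExpression):
    left: EventExpression
    right: EventExpression

    def evaluate(self, assignment: Mapping[str, object]) -> bool:
        return self.left.evaluate(assignment) or self.right.evaluate(assignment)

    def variables(self) -> set[str]:
        return self.left.variables() | self.right.variables()


# ---------------------------------------------------------------------------
# Induction
# ---------------------------------------------------------------------------

def build_tree(
    records: pd.DataFrame,
    feature_order: Iterable[str],
    target: str,
) -> ProbabilityTree:
    """Induce a probability tree from tabular records.

    The tree branches on the features in ``feature_order`` (expert-chosen;
    no automatic ordering).  Every theta is the empirical conditional
    relative frequency of the child's statement given the parent path, and
    each leaf stores per-class record counts for the binary ``target``.

    Records with missing values in any used column are rejected: only
    complete profiles enter the model.

    Raises
    ------
    FPTError
        On an empty table, unknown feature or target name, missing values,
        or a target with more than two levels.
    """
    feature_order = list(feature_order)
    if len(records) == 0:
        raise FPTError("cannot build a tree from an empty record set")
    for name in feature_order + [target]:
        if name not in records.columns:
            raise FPTError(f"column {name!r} not present in records")
    used = records[feature_order + [target]]
    if used.isna().any().any():
        bad = [c for c in used.columns if used[c].isna().any()]
        raise FPTError(f"missing values in columns {bad}; only complete "
                       "records may be used")

    # Statement values and class labels are compared as strings throughout.
    data = used.astype(str)
    class_labels = sorted(data[target].unique())
    if len(class_labels) > 2:
        raise FPTError(
            f"target {target!r} has {len(class_labels)} levels; the model "
            "supports binary targets only"
        )

    counter = iter(range(10**9))

    def grow(subset: pd.DataFrame, depth: int, stmts: list[Statement]) -> Node:
        node = Node(id=next(counter), statements=stmts)
        if depth == len(feature_order):
            counts = subset[target].value_counts()
            node.class_counts = {
                label: int(counts.get(label, 0)) for label in class_labels
            }
            return node
        feature = feature_order[depth]
        n_here = len(subset)
        for value, group in sorted(subset.groupby(feature, observed=True)):
            theta = len(group) / n_here
            child = grow(group, depth + 1, [Statement(feature, value)])
            node.transitions.append((theta, child))
        return node

    tree = ProbabilityTree(
        root=grow(data, 0, []),
        feature_order=feature_order,
        target=target,
        record_count=len(data),
        class_labels=class_labels,
    )
    return tree


def realizations(tree: ProbabilityTree) -> list[Realization]:
    """Enumerate all total realizations (root-to-leaf paths) with
    probabilities equal to the product of the thetas along each path."""
    out: list[Realization] = []

    def walk(node: Node, prob: float, path: list[Statement]) -> None:
        path = path + node.statements
        if node.is_leaf:
            out.append(Realization(path=path, probability=prob, leaf=node))
            return
        for theta, child in node.transitions:
            walk(child, prob * theta, path)

    walk(tree.root, 1.0, [])
    return out


# ---------------------------------------------------------------------------
# Probability queries
# ---------------------------------------------------------------------------

def _check_conditions(tree: ProbabilityTree, conditions: Iterable[Statement]) -> list[Statement]:
    conditions = list(conditions)
    for cond in conditions:
        if cond.variable not in tree.feature_order:
            raise FPTError(f"unknown variable {cond.variable!r} in conditions")
    return conditions


def _check_class(tree: ProbabilityTree, cls: object) -> str:
    cls = str(cls)
    if cls not in tree.class_labels:
        raise FPTError(
            f"unknown class label {cls!r}; tree classes are {tree.class_labels}"
        )
    return cls


def conditional_probability(
    tree: ProbabilityTree,
    conditions: Iterable[Statement],
    cls: object,
) -> float:
    """P(target = cls | all conditions hold), from leaf class counts.

    Aggregates the class counts of every leaf whose realization satisfies
    all conditions, which is identical to filter-and-count over the raw
    training rows.  With no conditions this is the marginal class prior.

    Raises
    ------
    UnsupportedQueryError
        If no training record satisfies the conditions (the caller should
        fall back via ``prediction.find_existing_conditions``).
    """
    conditions = _check_conditions(tree, conditions)
    cls = _check_class(tree, cls)
    want = {c.variable: str(c.value) for c in conditions}
    n_cls = 0
    n_all = 0
    for realization in realizations(tree):
        assignment = realization.assignment()
        if all(assignment.get(v) == val for v, val in want.items()):
            n_cls += realization.leaf.class_counts.get(cls, 0)
            n_all += sum(realization.leaf.class_counts.values())
    if n_all == 0:
        raise UnsupportedQueryError(
            f"no training record satisfies conditions {conditions}"
        )
    return n_cls / n_all


def event_probability(tree: ProbabilityTree, event: EventExpression) -> float:
    """Probability of an event: the summed probability of all total
    realizations on which the proposition evaluates true."""
    unknown = event.variables() - set(tree.feature_order)
    if unknown:
        raise FPTError(f"event references unknown variables {sorted(unknown)}")
    return sum(
        r.probability for r in realizations(tree) if event.evaluate(r.assignment())
    )


# ---------------------------------------------------------------------------
# Serialization and visualization
# ---------------------------------------------------------------------------

def _node_to_dict(node: Node) -> dict:
    d: dict = {
        "id": node.id,
        "statements": [[s.variable, s.value] for s in node.statements],
    }
    if node.is_leaf:
        d["class_counts"] = dict(node.class_counts)
    else:
        d["transitions"] = [
            {"theta": theta, "child": _node_to_dict(child)}
            for theta, child in node.transitions
        ]
    return d


def _node_from_dict(d: dict) -> Node:
    node = Node(
        id=int(d["id"]),
        statements=[Statement(v, val) for v, val in d["statements"]],
    )
    if "class_counts" in d:
        node.class_counts = {str(k): int(v) for k, v in d["class_counts"].items()}
    else:
        node.transitions = [
            (float(t["theta"]), _node_from_dict(t["child"]))
            for t in d["transitions"]
        ]
    return node


def tree_to_dict(tree: ProbabilityTree) -> dict:
    return {
        "feature_order": list(tree.feature_order),
        "target": tree.target,
        "record_count": tree.record_count,
        "class_labels": list(tree.class_labels),
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> ProbabilityTree:
    return ProbabilityTree(
        root=_node_from_dict(d["root"]),
        feature_order=list(d["feature_order"]),
        target=str(d["target"]),
        record_count=int(d["record_count"]),
        class_labels=[str(c) for c in d["class_labels"]],
    )


def tree_to_json(tree: ProbabilityTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=1)


def tree_from_json(text: str) -> ProbabilityTree:
    return tree_from_dict(json.loads(text))


def to_dot(tree: ProbabilityTree) -> str:
    """GraphViz DOT rendering: one graph node per tree node, edge labels
    are the transition probabilities to three decimals."""
    lines = ["digraph fpt {", '  node [shape=box, fontname="Helvetica"];']
    for node in tree.nodes():
        if node.statements:
            label = ", ".join(f"{s.variable} = {s.value}" for s in node.statements)
        else:
            label = "root"
        if node.is_leaf:
            counts = ", ".join(f"{k}: {v}" for k, v in sorted(node.class_counts.items()))
            label += f"\\n[{counts}]"
        lines.append(f'  n{node.id} [label="{label}"];')
    for node in tree.nodes():
        for theta, child in node.transitions:
            lines.append(f'  n{node.id} -> n{child.id} [label="{theta:.3f}"];')
    lines.append("}")
    return "\n".join(lines)
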