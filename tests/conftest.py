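"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's recursive traversal: they work
by exhaustive row filtering or path enumeration, so agreement with them is
a genuine cross-check of the tree algorithms.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fptree import (
    FuzzySet,
    LinguisticVariable,
    Statement,
    branch_weights,
    build_tree,
    make_demo_fixture,
    realizations,
)


@pytest.fixture
def demo():
    return make_demo_fixture()


@pytest.fixture
def ten_rows() -> pd.DataFrame:
    """Ten records over two binary features with hand-countable frequencies."""
    return pd.DataFrame(
        {
            "A": ["0", "0", "0", "0", "1", "1", "1", "1", "1", "1"],
            "B": ["0", "0", "1", "1", "0", "0", "0", "1", "1", "1"],
            "Y": ["0", "1", "0", "0", "1", "1", "0", "1", "0", "1"],
        }
    )


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def filter_count_probability(records: pd.DataFrame, conditions, cls, target) -> float | None:
    """P(target=cls | conditions) by direct row filtering; None if no match."""
    df = records.astype(str)
    mask = pd.Series(True, index=df.index)
    for cond in conditions:
        mask &= df[cond.variable] == str(cond.value)
    sub = df[mask]
    if len(sub) == 0:
        return None
    return float((sub[target] == str(cls)).mean())


def enumerate_event_probability(tree, event) -> float:
    """Event probability by explicit path enumeration and evaluation."""
    return sum(
        r.probability for r in realizations(tree) if event.evaluate(r.assignment())
    )


def enumerate_fuzzy_prediction(tree, fuzzy_config, statements, cls) -> float:
    """Weighted path-enumeration oracle for fuzzy prediction.

    For every root-to-leaf path, multiply one factor per feature:
    renormalized membership weight for a fuzzy raw value, an exact-match
    indicator for a stated crisp value, the transition theta for features
    after the last statement, and 1/#children for features skipped between
    statements.  The prediction is the weighted sum of leaf class
    fractions.  Valid on full-combination trees (every branch present).
    """
    stated = {}
    for s in statements:
        stated[s.variable] = s.value
    order = tree.feature_order
    stated_idx = [i for i, v in enumerate(order) if v in stated]
    last_stated = max(stated_idx) if stated_idx else -1

    # per-variable child counts and thetas, read off the tree by prefix
    def factors(path_stmts, leaf):
        node = tree.root
        product = 1.0
        for depth, stmt in enumerate(path_stmts):
            var = order[depth]
            children = {c.statements[0].value: (theta, c)
                        for theta, c in node.transitions}
            theta, child = children[stmt.value]
            if var in stated:
                value = stated[var]
                if isinstance(value, (int, float)) and var in fuzzy_config:
                    weights = branch_weights(fuzzy_config[var], float(value))
                    present = {t: w for t, w in weights.items()
                               if t in children and w > 0}
                    total = sum(present.values())
                    product *= present.get(stmt.value, 0.0) / total
                else:
                    product *= 1.0 if stmt.value == str(value) else 0.0
            elif depth > last_stated:
                product *= theta
            else:
                product *= 1.0 / len(children)
            node = child
        return product

    total = 0.0
    for r in realizations(tree):
        counts = r.leaf.class_counts
        frac = counts.get(str(cls), 0) / sum(counts.values())
        total += factors(r.path, r.leaf) * frac
    return total


# ---------------------------------------------------------------------------
# Random fixture generators (full factorial, so every branch is present)
# ---------------------------------------------------------------------------

def random_full_table(rng: np.random.Generator, n_features: int | None = None,
                      fuzzy_vars: int = 0):
    """A random full-factorial table plus fuzzy config for ``fuzzy_vars``
    of the features (those features get the fixed terms Lo/Hi)."""
    if n_features is None:
        n_features = int(rng.integers(2, 5))
    n_features = max(n_features, fuzzy_vars)
    names = [f"F{i}" for i in range(n_features)]
    levels = {}
    fuzzy_config = {}
    for i, name in enumerate(names):
        if i < fuzzy_vars:
            levels[name] = ["Hi", "Lo"]
            lo = float(rng.uniform(0, 40))
            hi = lo + float(rng.uniform(5, 30))
            high = FuzzySet("Hi", [(lo, 0.0), (hi, 1.0)])
            fuzzy_config[name] = LinguisticVariable(
                name=name, universe=(lo - 10, hi + 10),
                sets=[high, high.complement("Lo")],
            )
        else:
            k = int(rng.integers(2, 4))
            levels[name] = [f"v{j}" for j in range(k)]
    rows = []
    for combo in itertools.product(*(levels[n] for n in names)):
        for _ in range(int(rng.integers(1, 4))):
            rows.append(dict(zip(names, combo)) | {"Y": str(rng.integers(0, 2))})
    records = pd.DataFrame(rows)
    if records["Y"].nunique() < 2:  # force both classes to exist
        records.loc[records.index[0], "Y"] = "0"
        records.loc[records.index[1], "Y"] = "1"
    tree = build_tree(records, names, "Y")
    return records, tree, fuzzy_config, levels


def random_patient(rng: np.random.Generator, tree, fuzzy_config, levels,
                   p_skip: float = 0.3):
    """Random statements: raw values for fuzzy variables, existing levels
    for crisp ones; each variable independently skipped with ``p_skip``."""
    statements = []
    for var in tree.feature_order:
        if rng.random() < p_skip:
            continue
        if var in fuzzy_config:
            lo, hi = fuzzy_config[var].universe
            statements.append(Statement(var, float(rng.uniform(lo, hi))))
        else:
            statements.append(Statement(var, str(rng.choice(levels[var]))))
    return statements


def assert_close(a: float, b: float, tol: float = 1e-12) -> None:
    assert math.isfinite(a) and math.isfinite(b)
    assert abs(a - b) <= tol, f"{a} != {b}"
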