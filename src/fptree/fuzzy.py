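"""Fuzzy sets and linguistic variables used as traversal weights.

A linguistic variable replaces a numeric feature (age in years, nodule size
in mm, creatinine in mg/dL, ...) by a small set of linguistic terms, each a
fuzzy set over the feature's universe of discourse.  Membership functions
are piecewise linear, defined by an ordered list of (value, membership)
knots, constant at the boundary memberships outside the knot range.  During
fuzzy tree traversal, a patient's raw value is mapped to one membership
degree per term; the degrees, renormalized to sum to one, weight the
corresponding tree branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_tree import FPTError, THETA_TOL


@dataclass
class FuzzySet:
    """A linguistic term with a piecewise-linear membership function."""

    name: str
    knots: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.knots:
            raise FPTError(f"fuzzy set {self.name!r} declares no knots")
        xs = [x for x, _ in self.knots]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise FPTError(
                f"fuzzy set {self.name!r}: knot values must be strictly increasing"
            )
        if any(not 0.0 <= mu <= 1.0 for _, mu in self.knots):
            raise FPTError(
                f"fuzzy set {self.name!r}: knot memberships must lie in [0, 1]"
            )

    def membership(self, value: float) -> float:
        """Degree of membership of ``value``: linear interpolation between
        the bracketing knots, clamped to the boundary memberships outside
        the knot range."""
        if not np.isfinite(value):
            raise FPTError(f"membership of non-finite value {value!r}")
        xs = np.array([x for x, _ in self.knots], dtype=float)
        ys = np.array([mu for _, mu in self.knots], dtype=float)
        return float(np.interp(float(value), xs, ys))

    @property
    def rising(self) -> bool:
        """True if the term denotes the high side of its universe."""
        return self.knots[-1][1] >= self.knots[0][1]

    def complement(self, name: str | None = None) -> "FuzzySet":
        """The term with membership 1 - mu at every knot."""
        return FuzzySet(
            name=name or f"Not {self.name}",
            knots=[(x, 1.0 - mu) for x, mu in self.knots],
        )


@dataclass
class CrispCut(FuzzySet):
    """A step membership function: the crisp limit of a ramp.

    A rising cut has membership 1 exactly for values >= ``cut``; a falling
    cut has membership 1 for values < ``cut``.  Used by crisp probability
    tree prediction so that it is literally fuzzy prediction with all
    memberships in {0, 1}.
    """

    cut: float = 0.0
    step_rising: bool = True

    def membership(self, value: float) -> float:
        if not np.isfinite(value):
            raise FPTError(f"membership of non-finite value {value!r}")
        above = float(value) >= self.cut
        return 1.0 if above == self.step_rising else 0.0

    @property
    def rising(self) -> bool:
        return self.step_rising


@dataclass
class LinguisticVariable:
    """A numeric feature partitioned into linguistic terms.

    ``sets`` holds one fuzzy set per tree branch value; in both clinical
    case studies the partition is binary and the two memberships sum to one
    at every point of the universe.
    """

    name: str
    universe: tuple[float, float]
    sets: list[FuzzySet] = field(default_factory=list)
    unit: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise FPTError(
                f"variable {self.name!r}: universe ({lo}, {hi}) is empty"
            )
        if len(self.sets) == 1:
            # Binary partition declared by one term: complement the other.
            self.sets = [self.sets[0], self.sets[0].complement()]
        if len(self.sets) < 2:
            raise FPTError(f"variable {self.name!r} needs at least 2 fuzzy sets")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise FPTError(f"variable {self.name!r}: duplicate set names {names}")

    def term_names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get_set(self, term: str) -> FuzzySet:
        for s in self.sets:
            if s.name == term:
                return s
        raise FPTError(f"variable {self.name!r} has no term {term!r}")


def membership(fuzzy_set: FuzzySet, value: float) -> float:
    """Functional alias for :meth:`FuzzySet.membership`."""
    return fuzzy_set.membership(value)


def branch_weights(var: LinguisticVariable, value: float) -> dict[str, float]:
    """Map a raw value to one weight per linguistic term.

    Degrees are renormalized to sum to one before use as traversal
    weights (for the binary partitions of the case studies they already
    do).  A value with zero degree in every set is outside the variable's
    support and is an error.
    """
    degrees = {s.name: s.membership(value) for s in var.sets}
    total = sum(degrees.values())
    if total <= 0.0:
        raise FPTError(
            f"value {value} of {var.name!r} has zero membership in every set"
        )
    if abs(total - 1.0) > THETA_TOL:
        degrees = {k: v / total for k, v in degrees.items()}
    return degrees


# ---------------------------------------------------------------------------
# Crisp discretization (the traditional-PT view of the same variables)
# ---------------------------------------------------------------------------

def crisp_variant(var: LinguisticVariable, cut: float) -> LinguisticVariable:
    """Replace every term's ramp by a step at ``cut``.

    The step orientation follows each ramp's direction, so e.g. a rising
    'Large Nodule' term becomes "dimension >= cut" and its complement the
    strict converse; the two crisp terms still partition the universe.
    """
    sets = [
        CrispCut(name=s.name, knots=s.knots, cut=cut, step_rising=s.rising)
        for s in var.sets
    ]
    return LinguisticVariable(
        name=var.name, universe=var.universe, sets=sets, unit=var.unit
    )


def crisp_term(var: LinguisticVariable, cut: float, value: float) -> str:
    """The single linguistic term selected by the crisp cut."""
    for s in crisp_variant(var, cut).sets:
        if s.membership(value) == 1.0:
            return s.name
    raise FPTError(f"no crisp term for value {value} of {var.name!r}")


def discretize(
    records: pd.DataFrame,
    fuzzy_config: dict[str, LinguisticVariable],
    cuts: dict[str, float],
) -> pd.DataFrame:
    """Replace each fuzzy variable's numeric column by crisp term labels.

    This is how continuous features enter tree induction: the tree itself
    stores only discrete statements, and the fuzziness acts purely at
    prediction time.
    """
    out = records.copy()
    for name, var in fuzzy_config.items():
        if name not in out.columns:
            continue
        if name not in cuts:
            raise FPTError(f"no crisp cut declared for fuzzy variable {name!r}")
        out[name] = [crisp_term(var, cuts[name], v) for v in out[name]]
    return out


def binary_partition(
    name: str,
    universe: tuple[float, float],
    term: str,
    low: float,
    high: float,
    complement_name: str | None = None,
    unit: str = "",
    rising: bool = True,
) -> LinguisticVariable:
    """Convenience constructor for the two-term ramps of the case studies.

    A rising partition ramps ``term`` from membership 0 at ``low`` to 1 at
    ``high`` (a falling one is the mirror image); the complementary term is
    generated automatically so the pair sums to one everywhere.
    """
    knots = [(low, 0.0), (high, 1.0)] if rising else [(low, 1.0), (high, 0.0)]
    main = FuzzySet(name=term, knots=knots)
    sets = [main, main.complement(complement_name)]
    return LinguisticVariable(name=name, universe=universe, sets=sets, unit=unit)
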