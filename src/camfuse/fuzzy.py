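"""A small Mamdani fuzzy-inference engine.

The engine follows the classical Mamdani configuration: AND between rule
antecedents is the minimum, a fired rule clips (min-implication) its
consequent fuzzy set at the rule's activation, clipped sets aggregate by
pointwise maximum, and the crisp output is the centroid of the aggregated
membership over the output universe.  A negated antecedent ("Not X")
contributes the standard complement 1 - mu_X.  All rules carry weight one.

Membership shapes are triangular, Gaussian (exp(-(x-m)^2 / (2 s^2))) and
trapezoidal.  Crisp inputs outside a variable's universe are clamped to the
nearest bound and a warning is logged: in the intended application the
inputs are bounding-box coordinates, which can legitimately leave the frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import NoRuleFiredError

__all__ = [
    "MembershipFunction",
    "Triangular",
    "Gaussian",
    "Trapezoidal",
    "LinguisticVariable",
    "Antecedent",
    "FuzzyRule",
    "RuleBase",
    "AggregatedOutput",
    "membership_degree",
    "evaluate_rule",
    "aggregate",
    "defuzzify_centroid",
]

logger = logging.getLogger(__name__)


class MembershipFunction:
    """Base class; subclasses validate their parameters at construction."""

    def degree(self, x):
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: Mapping) -> "MembershipFunction":
        shape = d["shape"]
        if shape == "triangular":
            return Triangular(d["a"], d["b"], d["c"])
        if shape == "gaussian":
            return Gaussian(d["mean"], d["sigma"])
        if shape == "trapezoidal":
            return Trapezoidal(d["a"], d["b"], d["c"], d["d"])
        raise ValueError(f"unknown membership shape {shape!r}")


@dataclass(frozen=True)
class Triangular(MembershipFunction):
    """Triangle with feet at a and c and peak (degree 1) at b; a <= b <= c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.a <= self.b <= self.c:
            raise ValueError(f"triangular requires a <= b <= c, got {(self.a, self.b, self.c)}")
        if self.a == self.c:
            raise ValueError("triangular membership must have nonzero support")

    def degree(self, x):
        x = np.asarray(x, dtype=float)
        left = (x - self.a) / (self.b - self.a) if self.b > self.a else (x >= self.b) * 1.0
        right = (self.c - x) / (self.c - self.b) if self.c > self.b else (x <= self.b) * 1.0
        return np.clip(np.minimum(left, right), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"shape": "triangular", "a": self.a, "b": self.b, "c": self.c}


@dataclass(frozen=True)
class Gaussian(MembershipFunction):
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"gaussian sigma must be positive, got {self.sigma}")

    def degree(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.sigma
        return np.exp(-0.5 * z * z)

    def to_dict(self) -> dict:
        return {"shape": "gaussian", "mean": self.mean, "sigma": self.sigma}


@dataclass(frozen=True)
class Trapezoidal(MembershipFunction):
    """Flat top (degree 1) between b and c, feet at a and d; a <= b <= c <= d."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.a <= self.b <= self.c <= self.d:
            raise ValueError(
                f"trapezoidal requires a <= b <= c <= d, got {(self.a, self.b, self.c, self.d)}"
            )
        if self.a == self.d:
            raise ValueError("trapezoidal membership must have nonzero support")

    def degree(self, x):
        x = np.asarray(x, dtype=float)
        left = (x - self.a) / (self.b - self.a) if self.b > self.a else (x >= self.b) * 1.0
        right = (self.d - x) / (self.d - self.c) if self.d > self.c else (x <= self.c) * 1.0
        return np.clip(np.minimum(left, right), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"shape": "trapezoidal", "a": self.a, "b": self.b, "c": self.c, "d": self.d}


def membership_degree(mf: MembershipFunction, x) -> float:
    """Degree of membership of a scalar crisp value, in [0, 1]."""
    return float(mf.degree(x))


@dataclass(frozen=True)
class LinguisticVariable:
    """A named quantity partitioned into labeled fuzzy sets over a closed universe."""

    name: str
    universe: tuple[float, float]
    sets: Mapping[str, MembershipFunction]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"universe must satisfy lo < hi, got {self.universe}")
        if len(self.sets) == 0:
            raise ValueError(f"variable {self.name!r} has no fuzzy sets")

    def clamp(self, x: float) -> float:
        lo, hi = self.universe
        if x < lo or x > hi:
            logger.warning(
                "input %.6g for %r outside universe [%g, %g]; clamped", x, self.name, lo, hi
            )
            return min(max(x, lo), hi)
        return x

    def degrees(self, x: float) -> dict[str, float]:
        xc = self.clamp(float(x))
        return {label: float(mf.degree(xc)) for label, mf in self.sets.items()}


@dataclass(frozen=True)
class Antecedent:
    variable: str
    label: str
    negated: bool = False

    def describe(self) -> str:
        op = "is Not" if self.negated else "is"
        return f"({self.variable} {op} {self.label})"


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedents AND'ed> THEN <output is consequent>; weight fixed at 1."""

    name: str
    antecedents: tuple[Antecedent, ...]
    consequent: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.antecedents) == 0:
            raise ValueError(f"rule {self.name!r} needs at least one antecedent")
        if self.weight != 1.0:
            raise ValueError("all rules carry weight one")


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[FuzzyRule, ...]
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable

    def __post_init__(self) -> None:
        by_name = {v.name: v for v in self.inputs}
        for rule in self.rules:
            for ant in rule.antecedents:
                if ant.variable not in by_name:
                    raise ValueError(f"rule {rule.name!r} references unknown variable {ant.variable!r}")
                if ant.label not in by_name[ant.variable].sets:
                    raise ValueError(
                        f"rule {rule.name!r} references unknown set {ant.label!r} "
                        f"of variable {ant.variable!r}"
                    )
            if rule.consequent not in self.output.sets:
                raise ValueError(
                    f"rule {rule.name!r} consequent {rule.consequent!r} is not an output set"
                )

    @property
    def input_by_name(self) -> dict[str, LinguisticVariable]:
        return {v.name: v for v in self.inputs}


def evaluate_rule(
    rule: FuzzyRule, inputs: Mapping[str, float], rulebase: RuleBase
) -> float:
    """Activation of one rule: min over antecedent degrees (complement if negated)."""
    variables = rulebase.input_by_name
    degrees = []
    for ant in rule.antecedents:
        if ant.variable not in inputs:
            raise KeyError(
                f"rule {rule.name!r} needs a crisp value for variable {ant.variable!r}"
            )
        var = variables[ant.variable]
        mu = float(var.sets[ant.label].degree(var.clamp(float(inputs[ant.variable]))))
        degrees.append(1.0 - mu if ant.negated else mu)
    return min(degrees)


@dataclass(frozen=True)
class AggregatedOutput:
    """The union of clipped consequent sets, evaluable over the output universe."""

    universe: tuple[float, float]
    evaluate: Callable[[np.ndarray], np.ndarray]
    activations: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, x):
        return self.evaluate(np.asarray(x, dtype=float))


def aggregate(rulebase: RuleBase, inputs: Mapping[str, float]) -> AggregatedOutput:
    """Fire every rule, clip its consequent at the activation, take pointwise max.

    Rules with zero activation contribute nothing; if no rule fires at all
    the returned aggregate is identically zero (detected by the defuzzifier).
    """
    activations: dict[str, float] = {}
    clipped: list[tuple[float, MembershipFunction]] = []
    for rule in rulebase.rules:
        act = evaluate_rule(rule, inputs, rulebase)
        activations[rule.name] = act
        if act > 0.0:
            clipped.append((act, rulebase.output.sets[rule.consequent]))

    def evaluate(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(x, dtype=float))
        for act, mf in clipped:
            out = np.maximum(out, np.minimum(mf.degree(x), act))
        return out

    return AggregatedOutput(universe=rulebase.output.universe, evaluate=evaluate,
                            activations=activations)


def defuzzify_centroid(aggregated: AggregatedOutput, resolution: float = 0.1) -> float:
    """Centroid (center of mass) of the aggregated membership.

    Approximates integral(x mu(x)) / integral(mu(x)) by trapezoidal quadrature on a
    uniform grid of spacing ``resolution`` spanning the output universe.
    Raises :class:`NoRuleFiredError` for an identically-zero aggregate so the
    caller can decide on a fallback.
    """
    lo, hi = aggregated.universe
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = max(int(round((hi - lo) / resolution)), 1) + 1
    grid = np.linspace(lo, hi, n)
    mu = aggregated(grid)
    total = np.trapezoid(mu, grid)
    if total <= 0.0:
        raise NoRuleFiredError("aggregated membership is identically zero")
    return float(np.trapezoid(grid * mu, grid) / total)
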