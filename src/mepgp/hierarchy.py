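"""Weighted indicator hierarchies.

Composite environmental indices are organised as a three-level weighted
tree: policy objectives split into issue categories, which split into
indicators.  Each node carries a weight relative to its siblings; the
composite weight of an indicator is the product of the relative weights
along its root-to-leaf path.  These composite weights define the
fixed-weight (report-style) score, and the category level is used to
aggregate goal-programming weight estimates for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "Indicator",
    "IssueCategory",
    "PolicyObjective",
    "Hierarchy",
    "load_hierarchy",
    "epi2018_hierarchy",
    "composite_weights",
]

#: tolerance for sibling weights summing to one
SUM_TOL = 1e-9


def _parse_weight(value) -> float:
    """Accept either a fraction (0.4) or a percentage string ("40%")."""
    if isinstance(value, str):
        value = value.strip()
        if value.endswith("%"):
            value = float(value[:-1]) / 100.0
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"relative weight {value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class Indicator:
    name: str
    code: str
    weight: float


@dataclass(frozen=True)
class IssueCategory:
    name: str
    code: str
    weight: float
    indicators: tuple[Indicator, ...]


@dataclass(frozen=True)
class PolicyObjective:
    name: str
    code: str
    weight: float
    categories: tuple[IssueCategory, ...]


def _check_children_sum(weights, where: str) -> None:
    total = sum(weights)
    if abs(total - 1.0) > SUM_TOL:
        raise ValueError(f"relative weights under {where} sum to {total!r}, not 1")


@dataclass(frozen=True)
class Hierarchy:
    """Three-level weighted tree: objective -> issue category -> indicator."""

    name: str
    objectives: tuple[PolicyObjective, ...]

    def __post_init__(self) -> None:
        _check_children_sum([o.weight for o in self.objectives], "root")
        for obj in self.objectives:
            _check_children_sum([c.weight for c in obj.categories], obj.code)
            for cat in obj.categories:
                _check_children_sum([i.weight for i in cat.indicators], cat.code)
        codes = self.indicator_codes
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate indicator codes in hierarchy")
        cat_codes = [c.code for c in self.categories]
        if len(set(cat_codes)) != len(cat_codes):
            raise ValueError("duplicate issue-category codes in hierarchy")

    @property
    def categories(self) -> tuple[IssueCategory, ...]:
        return tuple(c for o in self.objectives for c in o.categories)

    @property
    def indicator_codes(self) -> list[str]:
        return [i.code for c in self.categories for i in c.indicators]

    def category_of(self) -> dict[str, str]:
        """Map each indicator code to its issue-category code."""
        return {
            ind.code: cat.code
            for obj in self.objectives
            for cat in obj.categories
            for ind in cat.indicators
        }


def composite_weights(hierarchy: Hierarchy) -> dict[str, float]:
    """Composite per-indicator weights: products of path relative weights.

    The returned weights are keyed by indicator code, follow the
    hierarchy's leaf order, and sum to one (each level's sibling weights
    sum to one, so the products telescope).
    """
    weights: dict[str, float] = {}
    for obj in hierarchy.objectives:
        for cat in obj.categories:
            for ind in cat.indicators:
                weights[ind.code] = obj.weight * cat.weight * ind.weight
    total = sum(weights.values())
    if abs(total - 1.0) > SUM_TOL:  # pragma: no cover - guarded by __post_init__
        raise ValueError(f"composite weights sum to {total!r}, not 1")
    return weights


def _hierarchy_from_mapping(doc: dict) -> Hierarchy:
    objectives = []
    for obj in doc["objectives"]:
        categories = []
        for cat in obj["categories"]:
            indicators = tuple(
                Indicator(i["name"], str(i["code"]), _parse_weight(i["weight"]))
                for i in cat["indicators"]
            )
            categories.append(
                IssueCategory(cat["name"], str(cat["code"]), _parse_weight(cat["weight"]), indicators)
            )
        objectives.append(
            PolicyObjective(obj["name"], str(obj["code"]), _parse_weight(obj["weight"]), tuple(categories))
        )
    return Hierarchy(name=doc.get("name", "hierarchy"), objectives=tuple(objectives))


def load_hierarchy(path) -> Hierarchy:
    """Load a hierarchy from a YAML file (weights as fractions or "40%")."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _hierarchy_from_mapping(doc)


def epi2018_hierarchy() -> Hierarchy:
    """The 2018 Environmental Performance Index hierarchy (10 categories, 24 indicators)."""
    text = resources.files("mepgp").joinpath("data/epi2018_hierarchy.yaml").read_text("utf-8")
    return _hierarchy_from_mapping(yaml.safe_load(text))
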