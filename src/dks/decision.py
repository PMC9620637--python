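"""Boolean rule engine and occluder-size suggestion.

The closure plan is decided by an explicit, auditable Boolean expression over
named millimetre measurements.  Leaves are conditional statements
(``measurement <cmp> threshold``); internal nodes are AND / OR / NOT.  If all
conditions hold and a catalogue device fits, transcatheter closure is
suggested together with an occluder size; otherwise surgical closure.

The suggested waist diameter is the maximum defect diameter over the three
views plus a safety margin (default 4 mm), rounded up to the smallest
available catalogue size.  The default catalogue spans integer waist
diameters 8..32 mm.  A leaf's threshold may be the literal string
``"suggested_size_mm"``, resolved at decision time against the size the
catalogue would supply — this expresses rules such as "the atrial septum must
be longer than the device".

All thresholds, comparators and the rule tree itself are configuration, so
the rules can be adapted to a different occluder without touching any code.
"""

from __future__ import annotations

import json
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Condition",
    "BooleanNode",
    "RuleSet",
    "OccluderCatalogue",
    "DecisionResult",
    "RuleError",
    "RuleParseError",
    "SizeUnavailableError",
    "evaluate",
    "suggest_size",
    "decide",
    "parse_ruleset",
    "default_ruleset",
    "default_catalogue",
]

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "=": lambda a, b: math.isclose(a, b, rel_tol=0.0, abs_tol=1e-9),
    # unicode aliases accepted in config files
    "≤": operator.le,
    "≥": operator.ge,
    "==": lambda a, b: math.isclose(a, b, rel_tol=0.0, abs_tol=1e-9),
}
_CANONICAL_CMP = {"<=": "<=", "≤": "<=", ">=": ">=", "≥": ">=", "==": "=", "=": "=",
                  "<": "<", ">": ">"}

SUGGESTED_SIZE_REF = "suggested_size_mm"


class RuleError(KeyError):
    """A rule references a measurement name that is not defined."""


class RuleParseError(ValueError):
    """Malformed rule configuration."""


class SizeUnavailableError(ValueError):
    """No catalogue device is large enough for the measured defect."""


@dataclass(frozen=True)
class Condition:
    """Leaf: compare a named measurement against a threshold.

    ``threshold`` is a number in mm, or the string ``"suggested_size_mm"`` to
    compare against the dynamically suggested occluder size.
    """

    measure: str
    cmp: str
    threshold: Union[float, str]

    def __post_init__(self) -> None:
        if self.cmp not in _COMPARATORS:
            raise RuleParseError(f"unknown comparator {self.cmp!r}")
        if isinstance(self.threshold, str) and self.threshold != SUGGESTED_SIZE_REF:
            raise RuleParseError(
                f"threshold must be numeric or {SUGGESTED_SIZE_REF!r}, "
                f"got {self.threshold!r}"
            )

    def to_dict(self) -> dict:
        thr = self.threshold if isinstance(self.threshold, str) else float(self.threshold)
        return {"measure": self.measure, "cmp": _CANONICAL_CMP[self.cmp], "threshold": thr}


@dataclass(frozen=True)
class BooleanNode:
    """Internal node: AND / OR over children, or NOT over one child."""

    op: str
    children: tuple["Node", ...]

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR", "NOT"):
            raise RuleParseError(f"unknown operator {self.op!r}")
        if len(self.children) == 0:
            raise RuleParseError(f"{self.op} needs at least one child")
        if self.op == "NOT" and len(self.children) != 1:
            raise RuleParseError("NOT takes exactly one child")

    def to_dict(self) -> dict:
        return {"op": self.op, "children": [c.to_dict() for c in self.children]}


Node = Union[Condition, BooleanNode]


@dataclass(frozen=True)
class RuleSet:
    """A finite Boolean expression tree over measurement names."""

    root: Node

    def leaves(self) -> list[Condition]:
        out: list[Condition] = []

        def walk(n: Node) -> None:
            if isinstance(n, Condition):
                out.append(n)
            else:
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def to_dict(self) -> dict:
        return self.root.to_dict()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class OccluderCatalogue:
    """Available device waist diameters (mm, strictly increasing) and the
    sizing margin added to the maximum defect diameter."""

    sizes_mm: tuple[int, ...] = tuple(range(8, 33))
    margin_mm: float = 4.0

    def __post_init__(self) -> None:
        if len(self.sizes_mm) == 0:
            raise ValueError("catalogue must be non-empty")
        if any(b <= a for a, b in zip(self.sizes_mm, self.sizes_mm[1:])):
            raise ValueError("catalogue sizes must be strictly increasing")

    def to_dict(self) -> dict:
        return {"sizes_mm": list(self.sizes_mm), "margin_mm": self.margin_mm}

    @classmethod
    def from_dict(cls, d: Mapping) -> "OccluderCatalogue":
        return cls(
            sizes_mm=tuple(int(s) for s in d["sizes_mm"]),
            margin_mm=float(d.get("margin_mm", 4.0)),
        )


@dataclass
class DecisionResult:
    """Plan suggestion with the full interpretability trace."""

    plan: str  # "transcatheter" | "surgical"
    suggested_size_mm: Optional[int]
    rule_trace: list[dict]
    rules_satisfied: bool
    size_available: bool

    def __post_init__(self) -> None:
        if self.plan not in ("transcatheter", "surgical"):
            raise ValueError(f"invalid plan {self.plan!r}")
        if (self.suggested_size_mm is not None) != (self.plan == "transcatheter"):
            raise ValueError("suggested_size_mm present iff plan is transcatheter")

    def to_dict(self) -> dict:
        return {
            "plan": self.plan,
            "suggested_size_mm": self.suggested_size_mm,
            "rules_satisfied": self.rules_satisfied,
            "size_available": self.size_available,
            "rule_trace": self.rule_trace,
        }

    def trace_table(self) -> str:
        """Human-readable per-leaf audit table (clinician review surface)."""
        lines = [f"{'measurement':<22}{'value':>9}  {'cmp':<3}{'threshold':>10}  result"]
        for t in self.rule_trace:
            lines.append(
                f"{t['measure']:<22}{t['value']:>9.2f}  {t['cmp']:<3}"
                f"{t['threshold']:>10.2f}  {'PASS' if t['result'] else 'FAIL'}"
            )
        return "\n".join(lines)


def evaluate(
    rules: RuleSet, measurements: Mapping[str, float]
) -> tuple[bool, list[dict]]:
    """Recursively evaluate ``rules`` against a name -> mm mapping.

    Returns the Boolean verdict and a trace recording, for every leaf, the
    measurement name, its value, the comparator, the resolved threshold and
    the leaf's truth value.
    """
    trace: list[dict] = []

    def walk(n: Node) -> bool:
        if isinstance(n, Condition):
            if n.measure not in measurements:
                raise RuleError(f"unknown measurement name {n.measure!r}")
            value = float(measurements[n.measure])
            if isinstance(n.threshold, str):
                if n.threshold not in measurements:
                    raise RuleError(
                        f"unresolved threshold reference {n.threshold!r}"
                    )
                threshold = float(measurements[n.threshold])
            else:
                threshold = float(n.threshold)
            result = bool(_COMPARATORS[n.cmp](value, threshold))
            trace.append(
                {
                    "measure": n.measure,
                    "value": value,
                    "cmp": _CANONICAL_CMP[n.cmp],
                    "threshold": threshold,
                    "result": result,
                }
            )
            return result
        if n.op == "NOT":
            return not walk(n.children[0])
        results = [walk(c) for c in n.children]  # full trace: no short-circuit
        return all(results) if n.op == "AND" else any(results)

    return walk(rules.root), trace


def suggest_size(
    measurements: Mapping[str, float], catalogue: OccluderCatalogue
) -> int:
    """Smallest catalogue waist diameter >= max defect diameter + margin.

    Raises :class:`SizeUnavailableError` when even the largest device is too
    small; the caller then falls back to surgical closure.
    """
    max_d = float(measurements["max_defect_diameter_mm"])
    if max_d < 0:
        raise ValueError("max_defect_diameter_mm must be >= 0")
    target = max_d + catalogue.margin_mm
    for size in catalogue.sizes_mm:
        if size >= target - 1e-9:
            return int(size)
    raise SizeUnavailableError(
        f"required size {target:.1f} mm exceeds largest catalogue device "
        f"{catalogue.sizes_mm[-1]} mm"
    )


def decide(
    measurements: Mapping[str, float],
    rules: Optional[RuleSet] = None,
    catalogue: Optional[OccluderCatalogue] = None,
) -> DecisionResult:
    """Apply the rule set and catalogue to a measurement mapping.

    Transcatheter closure is suggested iff every rule condition is satisfied
    AND a catalogue device fits; otherwise surgical.  The rule trace is always
    populated.  When no device fits, threshold references to the suggested
    size resolve to +inf so those leaves evaluate (to False) rather than fail.
    """
    rules = rules if rules is not None else default_ruleset()
    catalogue = catalogue if catalogue is not None else default_catalogue()

    size: Optional[int]
    try:
        size = suggest_size(measurements, catalogue)
        size_available = True
    except SizeUnavailableError:
        size = None
        size_available = False

    ctx = dict(measurements)
    ctx[SUGGESTED_SIZE_REF] = float(size) if size is not None else math.inf
    ok, trace = evaluate(rules, ctx)

    if ok and size_available:
        return DecisionResult(
            plan="transcatheter",
            suggested_size_mm=size,
            rule_trace=trace,
            rules_satisfied=ok,
            size_available=size_available,
        )
    return DecisionResult(
        plan="surgical",
        suggested_size_mm=None,
        rule_trace=trace,
        rules_satisfied=ok,
        size_available=size_available,
    )


def _parse_node(d: Mapping, depth: int = 0) -> Node:
    if depth > 64:
        raise RuleParseError("rule tree too deep (cycle?)")
    if not isinstance(d, Mapping):
        raise RuleParseError(f"expected a mapping node, got {type(d).__name__}")
    if "op" in d:
        children = d.get("children")
        if not isinstance(children, Sequence) or isinstance(children, (str, bytes)):
            raise RuleParseError("operator node needs a 'children' list")
        return BooleanNode(
            op=str(d["op"]).upper(),
            children=tuple(_parse_node(c, depth + 1) for c in children),
        )
    if "measure" in d:
        thr = d["threshold"]
        if not isinstance(thr, str):
            thr = float(thr)
        return Condition(measure=str(d["measure"]), cmp=str(d["cmp"]), threshold=thr)
    raise RuleParseError(f"node must contain 'op' or 'measure': {dict(d)!r}")


def parse_ruleset(config: Union[str, Path, Mapping]) -> RuleSet:
    """Parse a rule set from a nested mapping, a YAML/JSON string, or a file.

    Round-trips through :meth:`RuleSet.to_dict` / :meth:`RuleSet.to_yaml`.
    """
    if isinstance(config, Path) or (
        isinstance(config, str) and config.endswith((".yaml", ".yml", ".json"))
    ):
        config = Path(config).read_text()
    if isinstance(config, str):
        config = yaml.safe_load(config)  # YAML superset covers JSON
    if config is None or (isinstance(config, Mapping) and not config):
        raise RuleParseError("empty rule configuration")
    return RuleSet(root=_parse_node(config))


def default_ruleset() -> RuleSet:
    """Shipped default for a self-expanding double-disc septal occluder.

    All five rims (aortic wall, SVC, IVC, atrial roof, mitral annulus) must be
    at least 5 mm — the conventional sufficient-rim criterion — and the atrial
    septum must be longer than the suggested device waist diameter.
    """
    rim_leaves = [
        Condition(measure=name, cmp=">=", threshold=5.0)
        for name in (
            "rim_wall_mm",
            "rim_svc_mm",
            "rim_ivc_mm",
            "rim_roof_mm",
            "rim_mitral_mm",
        )
    ]
    septum = Condition(
        measure="septum_length_mm", cmp=">", threshold=SUGGESTED_SIZE_REF
    )
    return RuleSet(root=BooleanNode(op="AND", children=(*rim_leaves, septum)))


def default_catalogue() -> OccluderCatalogue:
    return OccluderCatalogue()


def write_ruleset(path: str | Path, rules: RuleSet) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(rules.to_dict(), indent=1))
    else:
        p.write_text(rules.to_yaml())
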