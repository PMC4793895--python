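"""Typed sequential filter chains.

Filters are typed by the field they target — numeric fields take the
relational operators ``< <= = != >= >``, flag fields ``is_true`` /
``is_false``, string fields ``in_set`` / ``not_in_set`` — and are applied
*consecutively*: each filter sees only the variants that survived the
previous ones, and the survivor count after each step is recorded.
Because every filter is a pure per-document predicate, the chain is a
conjunction: the final survivor set is order-invariant even though the
intermediate counts are not.

Missing values are first-class: a document lacking the field survives a
filter iff the filter's ``missing_policy`` is ``include_missing``
(default ``exclude_missing``). An absent flag is simply false — it
survives ``is_false``.

A chain, together with its sample groups and the names of the range
annotations it relies on, can be saved to a versioned JSON strategy file
and re-applied to other datasets; fields or samples a strategy references
that the new dataset lacks produce named errors, never silent drops.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, replace

from .errors import FilterSpecError, StrategyError, UnknownFieldError
from .groups import GroupFilter, SampleGroup, evaluate_group_filter

__all__ = [
    "FilterSpec", "FilterChain", "Session",
    "apply_filter", "apply_chain",
    "save_strategy", "load_strategy",
    "NUMERIC_OPS", "FLAG_OPS", "STRING_OPS", "STRATEGY_VERSION",
]

NUMERIC_OPS = ("<", "<=", "=", "!=", ">=", ">")
FLAG_OPS = ("is_true", "is_false")
STRING_OPS = ("in_set", "not_in_set")
STRATEGY_VERSION = 1

#: relative tolerance for numeric equality on text-parsed floats
_EQ_RTOL = 1e-9


def _num_eq(a: float, b: float) -> bool:
    if float(a).is_integer() and float(b).is_integer():
        return float(a) == float(b)
    return math.isclose(a, b, rel_tol=_EQ_RTOL, abs_tol=0.0)


@dataclass
class FilterSpec:
    """One typed predicate over a field path.

    ``kind`` is one of ``numeric``, ``flag``, ``string``, ``group`` or
    ``range`` (range-annotation flags behave exactly like flags). For
    ``kind="group"`` the predicate is carried by ``group_params``.
    """

    field: str
    kind: str
    operator: str
    value: object = None
    missing_policy: str = "exclude_missing"
    group_params: GroupFilter | None = None

    def label(self) -> str:
        """Short human-readable description for count displays."""
        if self.kind == "group":
            gf = self.group_params
            q = gf.quantifier if gf.quantifier != "at_least_fraction" \
                else f">= {gf.fraction:g} of"
            depth = f", alt depth >= {gf.min_alt_depth}" \
                if gf.min_alt_depth is not None else ""
            return (f"{gf.mode} {gf.zygosity_req} in {q} "
                    f"{gf.group.name}{depth}")
        if self.kind in ("flag", "range"):
            return f"{self.field} {self.operator}"
        if isinstance(self.value, (set, frozenset, list, tuple)):
            vals = ",".join(sorted(str(v) for v in self.value))
            return f"{self.field} {self.operator} {{{vals}}}"
        return f"{self.field} {self.operator} {self.value}"

    # -- validation --------------------------------------------------------

    def validate(self, ds=None) -> None:
        """Check operator-family/kind consistency, and field existence
        against a dataset when one is given."""
        if self.kind == "numeric":
            if self.operator not in NUMERIC_OPS:
                raise FilterSpecError(
                    f"operator {self.operator!r} invalid for numeric field "
                    f"{self.field!r}")
            if not isinstance(self.value, (int, float)):
                raise FilterSpecError(
                    f"numeric filter on {self.field!r} needs a numeric "
                    f"value, got {self.value!r}")
        elif self.kind in ("flag", "range"):
            if self.operator not in FLAG_OPS:
                raise FilterSpecError(
                    f"operator {self.operator!r} invalid for flag field "
                    f"{self.field!r}")
        elif self.kind == "string":
            if self.operator not in STRING_OPS:
                raise FilterSpecError(
                    f"operator {self.operator!r} invalid for string field "
                    f"{self.field!r}")
            if not self.value:
                raise FilterSpecError(
                    f"string filter on {self.field!r} needs a non-empty "
                    "value set")
        elif self.kind == "group":
            if self.group_params is None:
                raise FilterSpecError("group filter without group_params")
        else:
            raise FilterSpecError(f"unknown filter kind {self.kind!r}")
        if self.missing_policy not in ("exclude_missing", "include_missing"):
            raise FilterSpecError(
                f"unknown missing policy {self.missing_policy!r}")
        if ds is not None:
            if self.kind == "group":
                self.group_params.group.validate_against(ds.meta.sample_ids)
            elif self.field not in ds.field_catalog:
                raise UnknownFieldError(self.field)

    # -- evaluation --------------------------------------------------------

    def matches(self, doc) -> bool:
        """Per-document truth value (the linear-scan semantics)."""
        if self.kind == "group":
            return evaluate_group_filter(doc, self.group_params)
        value = doc.get_field(self.field)
        if self.kind in ("flag", "range"):
            truth = bool(value)  # absent flag is false
            return truth if self.operator == "is_true" else not truth
        present = value is not None and value != [] and \
            not (isinstance(value, list) and all(v is None for v in value))
        if not present:
            return self.missing_policy == "include_missing"
        values = value if isinstance(value, list) else [value]
        values = [v for v in values if v is not None]
        if self.kind == "numeric":
            return any(self._numeric_match(v) for v in values
                       if isinstance(v, (int, float)))
        # string
        wanted = {str(v) for v in (
            self.value if isinstance(self.value,
                                     (set, frozenset, list, tuple))
            else [self.value])}
        hit = any(str(v) in wanted for v in values)
        return hit if self.operator == "in_set" else not hit

    def _numeric_match(self, v: float) -> bool:
        t = self.value
        op = self.operator
        if op == "<":
            return v < t
        if op == "<=":
            return v <= t
        if op == "=":
            return _num_eq(v, t)
        if op == "!=":
            return not _num_eq(v, t)
        if op == ">=":
            return v >= t
        return v > t

    # -- (de)serialization -------------------------------------------------

    def to_json(self) -> dict:
        j: dict = {"field": self.field, "kind": self.kind,
                   "operator": self.operator,
                   "missing_policy": self.missing_policy}
        if self.value is not None:
            j["value"] = sorted(self.value) \
                if isinstance(self.value, (set, frozenset)) else self.value
        if self.group_params is not None:
            gf = self.group_params
            j["group"] = {"name": gf.group.name,
                          "zygosity_req": gf.zygosity_req,
                          "quantifier": gf.quantifier,
                          "fraction": gf.fraction,
                          "mode": gf.mode,
                          "min_alt_depth": gf.min_alt_depth}
        return j

    @classmethod
    def from_json(cls, j: dict, groups: dict[str, SampleGroup]
                  ) -> "FilterSpec":
        gp = None
        if j.get("group") is not None:
            g = j["group"]
            if g["name"] not in groups:
                raise StrategyError(
                    f"strategy references undefined group {g['name']!r}")
            gp = GroupFilter(group=groups[g["name"]],
                             zygosity_req=g["zygosity_req"],
                             quantifier=g["quantifier"],
                             fraction=g.get("fraction"),
                             mode=g["mode"],
                             min_alt_depth=g.get("min_alt_depth"))
        value = j.get("value")
        if j["kind"] == "string" and isinstance(value, list):
            value = set(value)
        return cls(field=j["field"], kind=j["kind"], operator=j["operator"],
                   value=value,
                   missing_policy=j.get("missing_policy", "exclude_missing"),
                   group_params=gp)

    def __eq__(self, other):
        if not isinstance(other, FilterSpec):
            return NotImplemented
        def norm(v):
            return set(v) if isinstance(v, (set, frozenset, list, tuple)) \
                else v
        return (self.field, self.kind, self.operator,
                norm(self.value), self.missing_policy,
                self.group_params) == \
               (other.field, other.kind, other.operator,
                norm(other.value), other.missing_policy,
                other.group_params)


@dataclass
class FilterChain:
    """An ordered list of filters with per-step survivor counts."""

    steps: list[FilterSpec] = dc_field(default_factory=list)
    counts: list[int] = dc_field(default_factory=list)
    initial_count: int | None = None

    def __post_init__(self):
        if self.counts and len(self.counts) != len(self.steps):
            raise FilterSpecError("counts length must match steps length")

    def summary_lines(self) -> list[str]:
        """Running tabulation: each filter with its remaining count."""
        lines = [f"{'(all variants)':<50s} {self.initial_count}"]
        for spec, n in zip(self.steps, self.counts):
            lines.append(f"{spec.label():<50s} {n}")
        return lines


def apply_filter(ds, spec: FilterSpec, within: set[int] | None = None
                 ) -> set[int]:
    """Survivor ids of one filter over ``within`` (default: all)."""
    return ds.query(spec, within)


def apply_chain(ds, chain: FilterChain | list[FilterSpec],
                within: set[int] | None = None
                ) -> tuple[FilterChain, set[int]]:
    """Apply filters consecutively, recording survivor counts per step.

    Step *i* is evaluated only on the survivors of step *i-1*; the final
    set equals the intersection of each filter's standalone survivors.
    """
    steps = chain.steps if isinstance(chain, FilterChain) else list(chain)
    survivors = set(within) if within is not None else ds.all_ids()
    initial = len(survivors)
    counts: list[int] = []
    for spec in steps:
        survivors = apply_filter(ds, spec, survivors)
        counts.append(len(survivors))
    return FilterChain(steps=list(steps), counts=counts,
                       initial_count=initial), survivors


class Session:
    """A dataset plus the current chain, survivors and saved analyses.

    Mirrors the interactive workflow: add filters one at a time (each
    immediately narrowing the survivor set), save the current analysis
    under a name, clear the filters, and start again — every saved
    analysis stays retrievable.
    """

    def __init__(self, ds):
        self.ds = ds
        self.groups: dict[str, SampleGroup] = {}
        self.range_names: list[str] = []
        self.chain = FilterChain(initial_count=len(ds))
        self.survivors: set[int] = ds.all_ids()
        self.saved: dict[str, tuple[FilterChain, set[int]]] = {}

    def add_group(self, group: SampleGroup) -> None:
        if group.name in self.groups:
            raise FilterSpecError(f"group name {group.name!r} already in use")
        group.validate_against(self.ds.meta.sample_ids)
        self.groups[group.name] = group

    def add_filter(self, spec: FilterSpec) -> int:
        """Apply one more filter; returns the new survivor count."""
        spec.validate(self.ds)
        self.survivors = apply_filter(self.ds, spec, self.survivors)
        self.chain.steps.append(spec)
        self.chain.counts.append(len(self.survivors))
        return len(self.survivors)

    def clear_filters(self) -> None:
        """Empty the chain and restore the full survivor set.

        Saved analyses are unaffected."""
        self.chain = FilterChain(initial_count=len(self.ds))
        self.survivors = self.ds.all_ids()

    def save_analysis(self, name: str) -> None:
        self.saved[name] = (replace(self.chain,
                                    steps=list(self.chain.steps),
                                    counts=list(self.chain.counts)),
                            set(self.survivors))

    def get_analysis(self, name: str) -> tuple[FilterChain, set[int]]:
        return self.saved[name]


# ---------------------------------------------------------------------------
# strategy files

def save_strategy(path, chain: FilterChain | list[FilterSpec],
                  groups: list[SampleGroup] | None = None,
                  range_names: list[str] | None = None) -> None:
    """Write a chain (+ groups + range-annotation names) to JSON."""
    steps = chain.steps if isinstance(chain, FilterChain) else list(chain)
    payload = {
        "format": "vcfsieve-strategy",
        "version": STRATEGY_VERSION,
        "filters": [s.to_json() for s in steps],
        "groups": [{"name": g.name, "members": list(g.members)}
                   for g in (groups or [])],
        "range_annotations": list(range_names or []),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_strategy(path, ds=None
                  ) -> tuple[FilterChain, list[SampleGroup], list[str]]:
    """Load a strategy; optionally resolve it against a dataset.

    With a dataset, every referenced field must exist in its catalog and
    every group member among its samples — otherwise a
    :class:`StrategyError` naming the offender is raised.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "vcfsieve-strategy":
        raise StrategyError(f"{path}: not a vcfsieve strategy file")
    if payload.get("version") != STRATEGY_VERSION:
        raise StrategyError(
            f"{path}: strategy version {payload.get('version')} not "
            f"supported (expected {STRATEGY_VERSION})")
    groups = {}
    for g in payload.get("groups", []):
        groups[g["name"]] = SampleGroup(g["name"], tuple(g["members"]))
    steps = [FilterSpec.from_json(j, groups)
             for j in payload.get("filters", [])]
    range_names = list(payload.get("range_annotations", []))
    if ds is not None:
        for group in groups.values():
            missing = [m for m in group.members
                       if m not in ds.meta.sample_ids]
            if missing:
                raise StrategyError(
                    f"strategy group {group.name!r} references samples "
                    f"absent from the dataset: {', '.join(missing)}")
        for spec in steps:
            if spec.kind != "group" and spec.field not in ds.field_catalog:
                raise StrategyError(
                    f"strategy references field {spec.field!r} absent "
                    "from the dataset")
    return (FilterChain(steps=steps), list(groups.values()), range_names)
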