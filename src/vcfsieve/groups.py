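"""Sample groups and quantified genotype filters.

A :class:`SampleGroup` is a named subset of the VCF's samples (cases,
controls, parents, tumor, normal...). A :class:`GroupFilter` asks, per
variant, whether enough group members carry the variant in the required
zygosity, optionally with a minimum alternate-read depth:

* ``zygosity_req`` — ``either`` (any alternate allele), ``heterozygous``
  or ``homozygous``;
* ``quantifier`` — ``any`` (at least one member), ``all`` (every member),
  or ``at_least_fraction(p)`` (at least ``ceil(p * group size)`` members;
  uncalled members count in the denominator and never match);
* ``mode`` — ``require`` keeps variants satisfying the condition,
  ``exclude`` keeps exactly the others (case/control exclusion is the
  document-wise negation of the corresponding requirement);
* ``min_alt_depth`` — a member only matches if its AD-derived alternate
  depth is present and at least this many reads; without AD the depth
  requirement is unsatisfiable.

No-call samples never match any requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

from .errors import GroupError
from .genotypes import SampleCall, Zygosity

__all__ = ["SampleGroup", "GroupFilter", "sample_matches",
           "evaluate_group_filter", "group_filter_spec",
           "ZYGOSITY_REQS", "QUANTIFIERS"]

ZYGOSITY_REQS = ("either", "heterozygous", "homozygous")
QUANTIFIERS = ("any", "all", "at_least_fraction")


@dataclass(frozen=True)
class SampleGroup:
    """A named, non-empty, ordered set of sample ids.

    Samples may belong to any number of groups; group names must be
    unique within a session/strategy.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise GroupError(f"group {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise GroupError(f"group {self.name!r} has duplicate members")

    def validate_against(self, sample_ids) -> None:
        missing = [m for m in self.members if m not in sample_ids]
        if missing:
            raise GroupError(
                f"group {self.name!r} references samples absent from the "
                f"dataset: {', '.join(missing)}")


@dataclass(frozen=True)
class GroupFilter:
    """A quantified genotype condition over one sample group."""

    group: SampleGroup
    zygosity_req: str = "either"
    quantifier: str = "any"
    fraction: float | None = None  # required when quantifier=at_least_fraction
    mode: str = "require"          # require | exclude
    min_alt_depth: int | None = None

    def __post_init__(self):
        if self.zygosity_req not in ZYGOSITY_REQS:
            raise GroupError(f"unknown zygosity requirement "
                             f"{self.zygosity_req!r}")
        if self.quantifier not in QUANTIFIERS:
            raise GroupError(f"unknown quantifier {self.quantifier!r}")
        if self.quantifier == "at_least_fraction":
            if self.fraction is None or not (0 < self.fraction <= 1):
                raise GroupError(
                    f"fraction must be in (0, 1], got {self.fraction!r}")
        if self.mode not in ("require", "exclude"):
            raise GroupError(f"unknown mode {self.mode!r}")
        if self.min_alt_depth is not None and self.min_alt_depth < 0:
            raise GroupError("min_alt_depth must be non-negative")

    @property
    def threshold(self) -> int:
        """Number of matching members needed for the condition to hold."""
        n = len(self.group.members)
        if self.quantifier == "any":
            return 1
        if self.quantifier == "all":
            return n
        # ceil(p * n); the tiny slack guards against float artifacts like
        # 0.1 * 30 = 3.0000000000000004 rounding up a full extra member
        return max(1, math.ceil(self.fraction * n - 1e-9))


def sample_matches(call: SampleCall, zygosity_req: str = "either",
                   min_alt_depth: int | None = None) -> bool:
    """Does one sample's call satisfy a zygosity + depth requirement?

    A no-call or reference call never matches. A depth requirement fails
    whenever the alternate depth is absent (no AD in the VCF).
    """
    if zygosity_req == "either":
        if call.alt_allele_count < 1:
            return False
    elif zygosity_req == "heterozygous":
        if call.zygosity is not Zygosity.HETEROZYGOUS:
            return False
    elif zygosity_req == "homozygous":
        if call.zygosity is not Zygosity.HOMOZYGOUS:
            return False
    else:
        raise GroupError(f"unknown zygosity requirement {zygosity_req!r}")
    if min_alt_depth is not None:
        if call.alt_depth is None or call.alt_depth < min_alt_depth:
            return False
    return True


def evaluate_group_filter(doc, gf: GroupFilter) -> bool:
    """Evaluate a group filter on one variant document.

    Counts the group members whose calls match, compares against the
    quantifier's threshold, and negates for ``mode="exclude"``.
    """
    m = 0
    for sid in gf.group.members:
        call = doc.calls.get(sid)
        if call is None:
            raise GroupError(
                f"group {gf.group.name!r} member {sid!r} is absent from "
                "the dataset")
        if sample_matches(call, gf.zygosity_req, gf.min_alt_depth):
            m += 1
    satisfied = m >= gf.threshold
    return satisfied if gf.mode == "require" else not satisfied


def group_filter_spec(gf: GroupFilter):
    """Wrap a GroupFilter as a FilterSpec so chains treat it uniformly."""
    from .filters import FilterSpec
    return FilterSpec(field=f"GROUP.{gf.group.name}", kind="group",
                      operator="matches", value=None, group_params=gf)
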