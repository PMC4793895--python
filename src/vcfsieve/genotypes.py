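"""Per-sample genotype logic.

Three pieces of sample-level logic drive everything downstream:

1. **Zygosity classification** of the GT string. Allele tokens are split on
   the ``/`` and ``|`` separators; a token counts as an alternate allele iff
   it is neither ``.`` nor ``0``. The number of such tokens is the sample's
   alternate-allele count: 0 means the variant was not detected (reference
   call, or no-call when every token is ``.``), 1 is heterozygous, and >1 is
   homozygous. Counting tokens rather than literally deleting characters
   keeps multi-digit allele indices (``0/10``) intact, and works for any
   ploidy — ``0/1`` and ``0/0/1`` are both heterozygous.

   Note that under this count rule a diploid ``1/2`` call (two different
   alternate alleles) is classified *homozygous*: two alternate alleles are
   present, even though the site is biologically a heterozygous-alt site.
   Normalizing multi-allelic records to one allele per row avoids the
   ambiguity.

2. **Allelic-depth extraction** from the AD field: the first comma-separated
   element is the read depth supporting the reference allele, the second the
   depth supporting the alternate. Records should be normalized to a single
   alternate per row first; extra elements are tolerated with a warning.

3. **Numeric min/max summaries** of any numeric per-sample (FORMAT) field
   across all samples at a variant, exposed as filterable derived fields.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

from .errors import GenotypeError, VCFSieveError

logger = logging.getLogger(__name__)

__all__ = [
    "Zygosity",
    "SampleCall",
    "classify_genotype",
    "parse_ad",
    "summarize_numeric_format",
]


class Zygosity(str, enum.Enum):
    """Zygosity of one sample at one site, by alternate-allele count."""

    NO_CALL = "NO_CALL"          # every allele token is '.'
    REFERENCE = "REFERENCE"      # called, zero alternate alleles
    HETEROZYGOUS = "HETEROZYGOUS"  # exactly one alternate allele
    HOMOZYGOUS = "HOMOZYGOUS"    # more than one alternate allele

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SampleCall:
    """One sample's parsed genotype at one variant.

    Attributes
    ----------
    gt_raw:
        The GT string exactly as read (``"."`` when GT was absent).
    zygosity:
        Classification per the alternate-allele count rule.
    alt_allele_count:
        Number of allele tokens that are neither ``.`` nor ``0``.
    ref_depth, alt_depth:
        Reads supporting the reference / alternate allele (from AD), or
        ``None`` when AD is absent or missing.
    other_format:
        Remaining FORMAT values for this sample, typed per the header.
    """

    gt_raw: str = "."
    zygosity: Zygosity = Zygosity.NO_CALL
    alt_allele_count: int = 0
    ref_depth: int | None = None
    alt_depth: int | None = None
    other_format: dict = field(default_factory=dict)

    @property
    def is_carrier(self) -> bool:
        """True iff the sample carries at least one alternate allele."""
        return self.alt_allele_count >= 1

    @property
    def phased(self) -> bool:
        return "|" in self.gt_raw


def classify_genotype(gt: str) -> tuple[Zygosity, int]:
    """Classify a GT string into (zygosity, alternate-allele count).

    Tokens are obtained by splitting on ``/`` and ``|``; a token counts as
    an alternate allele iff it is neither ``.`` nor ``0``. Works for any
    ploidy, including hemizygous single-token calls ("1" on male X).

    Raises
    ------
    GenotypeError
        If ``gt`` is empty or contains a non-numeric, non-``.`` token.
    """
    if not gt:
        raise GenotypeError("empty GT string")
    tokens = gt.replace("|", "/").split("/")
    alt = 0
    called = False
    for tok in tokens:
        if tok == ".":
            continue
        if not tok.isdigit():
            raise GenotypeError(f"malformed GT token {tok!r} in {gt!r}")
        called = True
        if tok != "0" and int(tok) != 0:
            alt += 1
    if alt > 1:
        return Zygosity.HOMOZYGOUS, alt
    if alt == 1:
        return Zygosity.HETEROZYGOUS, alt
    return (Zygosity.REFERENCE if called else Zygosity.NO_CALL), 0


def parse_ad(ad: str) -> tuple[int | None, int | None]:
    """Parse an AD field into (ref_depth, alt_depth).

    ``"."`` yields ``(None, None)``. More than two elements (an
    unnormalized multi-allelic record) is tolerated with a warning, keeping
    the first alternate's depth.

    Raises
    ------
    GenotypeError
        On a single-element or negative-valued AD.
    """
    if ad == "." or ad == "":
        return None, None
    parts = ad.split(",")
    if len(parts) < 2:
        raise GenotypeError(
            f"AD field {ad!r} has a single element; expected ref,alt depths")
    if len(parts) > 2:
        logger.warning(
            "AD field %r has %d elements; using the first alternate depth "
            "(normalize multi-allelic records first)", ad, len(parts))
    try:
        ref_depth = int(parts[0]) if parts[0] != "." else None
        alt_depth = int(parts[1]) if parts[1] != "." else None
    except ValueError as exc:
        raise GenotypeError(f"non-integer AD element in {ad!r}") from exc
    if (ref_depth is not None and ref_depth < 0) or \
            (alt_depth is not None and alt_depth < 0):
        raise GenotypeError(f"negative depth in AD field {ad!r}")
    return ref_depth, alt_depth


def summarize_numeric_format(doc, fmt_field: str) -> tuple[float, float] | None:
    """Minimum and maximum of a numeric FORMAT field across samples.

    Returns ``None`` when no sample carries a value. The document's header
    metadata must declare the field as Integer or Float.
    """
    meta = getattr(doc, "meta", None)
    if meta is not None:
        decl = meta.format_fields.get(fmt_field)
        if decl is not None and decl.type not in ("Integer", "Float"):
            raise VCFSieveError(
                f"FORMAT field {fmt_field!r} is declared {decl.type}, "
                "not numeric")
    values: list[float] = []
    for call in doc.calls.values():
        v = call.other_format.get(fmt_field)
        if v is None:
            continue
        if isinstance(v, (list, tuple)):
            values.extend(x for x in v if x is not None
                          and isinstance(x, (int, float)) and math.isfinite(x))
        elif isinstance(v, (int, float)) and math.isfinite(v):
            values.append(v)
    if not values:
        return None
    return min(values), max(values)
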