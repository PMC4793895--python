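"""Genomic-range annotations from BED files or pasted range strings.

Each loaded range set becomes a named boolean annotation: every variant
is labeled TRUE iff its position falls inside some interval of the set,
FALSE otherwise, and the label is filterable like any flag field.

Coordinate conventions, fixed and tested:

* BED is 0-based, half-open ``[chromStart, chromEnd)``;
* pasted ranges ``chrom:start-end`` are 1-based, inclusive on both ends;
* VCF POS is 1-based.

A variant at POS therefore belongs to a BED interval iff
``chromStart < POS <= chromEnd``. Membership uses POS only (point
semantics); the REF allele's span is not considered. Chromosome names
match by exact string equality, optionally after stripping/ignoring a
``chr`` prefix (off by default).
"""

from __future__ import annotations

import re

from intervaltree import IntervalTree

from .errors import RangeError

__all__ = ["RangeAnnotation", "load_bed", "parse_adhoc_ranges",
           "annotate_ranges"]

_ADHOC_TOKEN = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def _norm_chrom(chrom: str, strip_chr: bool) -> str:
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


class RangeAnnotation:
    """A named set of genomic intervals, 0-based half-open internally."""

    def __init__(self, name: str, *, normalize_chr: bool = False):
        if not name:
            raise RangeError("range annotation needs a non-empty name")
        self.name = name
        self.normalize_chr = normalize_chr
        self.trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        """Add a 0-based half-open interval [start, end)."""
        if start < 0 or start >= end:
            raise RangeError(
                f"invalid interval {chrom}:{start}-{end} (need "
                "0 <= start < end)")
        chrom = _norm_chrom(chrom, self.normalize_chr)
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based variant position."""
        chrom = _norm_chrom(chrom, self.normalize_chr)
        tree = self.trees.get(chrom)
        if tree is None:
            return False
        # POS (1-based) sits in [start, end) iff start <= POS-1 < end
        return bool(tree.overlaps_point(pos - 1))

    def interval_set(self) -> frozenset:
        return frozenset((c, iv.begin, iv.end)
                         for c, t in self.trees.items() for iv in t)

    def __eq__(self, other):
        if not isinstance(other, RangeAnnotation):
            return NotImplemented
        return self.name == other.name and \
            self.interval_set() == other.interval_set()

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def load_bed(path, name: str, *, normalize_chr: bool = False
             ) -> RangeAnnotation:
    """Load the first three columns of a BED file as a named annotation.

    ``track``/``browser``/comment lines are skipped; extra columns are
    ignored. A start >= end raises with the line number.
    """
    ra = RangeAnnotation(name, normalize_chr=normalize_chr)
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise RangeError(
                    f"{path} line {ln}: BED needs >= 3 columns")
            chrom, start_s, end_s = cols[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise RangeError(
                    f"{path} line {ln}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}")
            if start >= end:
                raise RangeError(
                    f"{path} line {ln}: start {start} >= end {end}")
            ra.add(chrom, start, end)
    return ra


def parse_adhoc_ranges(text: str, name: str = "adhoc", *,
                       normalize_chr: bool = False) -> RangeAnnotation:
    """Parse pasted ``chrom:start-end`` tokens (1-based inclusive).

    Tokens are separated by whitespace and/or commas. Internally each
    token becomes the 0-based half-open interval [start-1, end), so a
    single-base range ``chr1:5-5`` matches exactly POS 5.
    """
    ra = RangeAnnotation(name, normalize_chr=normalize_chr)
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t]
    if not tokens:
        raise RangeError("no range tokens found")
    for token in tokens:
        m = _ADHOC_TOKEN.match(token)
        if m is None:
            raise RangeError(f"malformed range token {token!r} "
                             "(expected chrom:start-end)")
        start, end = int(m.group("start")), int(m.group("end"))
        if start < 1 or end < start:
            raise RangeError(f"invalid range token {token!r} "
                             "(need 1 <= start <= end)")
        ra.add(m.group("chrom"), start - 1, end)
    return ra


def annotate_ranges(ds, ra: RangeAnnotation):
    """Label every document with boolean derived field ``RANGE.<name>``.

    Idempotent for a given name; re-annotating an existing name with a
    *different* interval set is an error (names must be distinct).
    Chromosomes absent from the annotation label FALSE.
    """
    existing = ds.range_annotations.get(ra.name)
    if existing is not None and existing != ra:
        raise RangeError(
            f"range annotation name {ra.name!r} is already in use; "
            "each loaded range set must have a distinct name")
    key = f"RANGE.{ra.name}"
    for doc in ds.docs:
        doc.derived[key] = ra.contains(doc.chrom, doc.pos)
    ds.range_annotations[ra.name] = ra
    ds.invalidate_catalog()
    return ds
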