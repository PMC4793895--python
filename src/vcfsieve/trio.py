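"""Trio inheritance-pattern and compound-heterozygote annotation.

Given a mother/father/child trio, two custom annotations are injected
into the document model as ordinary INFO fields, so they are filterable
and exportable like any native annotation:

``INFO.InheritancePattern`` (string) — one of:

* ``AR`` (autosomal recessive candidate): autosome, child homozygous,
  both parents heterozygous;
* ``deNovo``: child carries at least one alternate allele while both
  parents are called reference;
* ``NonMendelian``: all three called, and the child's alternate-allele
  count is impossible under Mendelian transmission from the parental
  diploid genotypes (e.g. a homozygous child with a reference parent) —
  de novo candidates are labeled ``deNovo``, never ``NonMendelian``;
* ``XLD`` (X-linked dominant candidate): on X, the child carries the
  variant, exactly one parent carries it, and that carrier parent's
  affected status matches the child's. A hemizygous single-allele
  genotype ("1" on male X) counts as carrying.

Variants on Y or MT, uncalled trios, and patterns matching no rule leave
the field absent.

``INFO.CompoundHet`` (flag) — true on every child-heterozygous variant V
in gene G such that V is transmitted from exactly one parent and some
other child-heterozygous variant in G is transmitted from exactly the
other parent. "Transmitted from parent P" is strict: P carries the
alternate and the other parent does not. When both child genotypes are
phased, the two variants must additionally lie on opposite haplotypes.

The rule table above is this package's explicit reconstruction of the
field's standard definitions; individual rules can be disabled via
``InheritanceRules``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

from .errors import TrioError
from .genotypes import SampleCall, Zygosity

__all__ = ["TrioSpec", "InheritanceRules", "classify_chromosome",
           "annotate_inheritance", "annotate_compound_het", "annotate_trio"]

_NUM_CHROM = re.compile(r"^\d+$")


def classify_chromosome(chrom: str) -> str:
    """Classify a chromosome name as autosome / X / Y / MT / other.

    An optional ``chr`` prefix is ignored; purely numeric names are
    autosomes. Unrecognized names are ``other`` and receive no label.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    upper = name.upper()
    if _NUM_CHROM.match(name):
        return "autosome"
    if upper == "X":
        return "X"
    if upper == "Y":
        return "Y"
    if upper in ("MT", "M"):
        return "MT"
    return "other"


@dataclass(frozen=True)
class InheritanceRules:
    """Which inheritance labels to compute (all on by default)."""

    ar: bool = True
    de_novo: bool = True
    non_mendelian: bool = True
    xld: bool = True
    strict_transmission: bool = True  # CompoundHet: other parent non-carrier


@dataclass
class TrioSpec:
    """A mother/father/child trio with affected status and gene field."""

    mother_id: str
    father_id: str
    child_id: str
    affected: dict[str, bool] = dc_field(default_factory=dict)
    child_sex: str = "unknown"  # male | female | unknown
    gene_field: str = "INFO.Gene"
    rules: InheritanceRules = dc_field(default_factory=InheritanceRules)

    def __post_init__(self):
        ids = (self.mother_id, self.father_id, self.child_id)
        if len(set(ids)) != 3:
            raise TrioError("mother, father and child ids must be distinct")
        # affected status defaults: child affected, parents unaffected
        for sid, default in ((self.child_id, True), (self.mother_id, False),
                             (self.father_id, False)):
            self.affected.setdefault(sid, default)

    def validate_against(self, sample_ids) -> None:
        missing = [s for s in (self.mother_id, self.father_id, self.child_id)
                   if s not in sample_ids]
        if missing:
            raise TrioError(
                f"trio samples absent from the dataset: "
                f"{', '.join(missing)}")


def _trio_calls(doc, trio: TrioSpec
                ) -> tuple[SampleCall, SampleCall, SampleCall] | None:
    try:
        return (doc.calls[trio.mother_id], doc.calls[trio.father_id],
                doc.calls[trio.child_id])
    except KeyError as exc:
        raise TrioError(f"trio sample {exc.args[0]!r} has no call; "
                        "was the trio resolved against this dataset?")


def _transmission_bounds(mother: SampleCall, father: SampleCall
                         ) -> tuple[int, int]:
    """Feasible child alt-allele count range under diploid transmission.

    Each parent transmits one allele: a homozygous parent must pass an
    alternate, a heterozygous parent may, a reference parent cannot.
    """
    lo = hi = 0
    for parent in (mother, father):
        if parent.zygosity is Zygosity.HOMOZYGOUS:
            lo += 1
            hi += 1
        elif parent.alt_allele_count >= 1:
            hi += 1
    return lo, hi


def _diploid(call: SampleCall) -> bool:
    return call.gt_raw.count("/") + call.gt_raw.count("|") == 1


def inheritance_label(doc, trio: TrioSpec) -> str | None:
    """The InheritancePattern label for one document, or None."""
    mother, father, child = _trio_calls(doc, trio)
    ctype = classify_chromosome(doc.chrom)
    rules = trio.rules
    all_called = all(c.zygosity is not Zygosity.NO_CALL
                     for c in (mother, father, child))
    if ctype == "autosome":
        if not all_called:
            return None
        parents_ref = (mother.zygosity is Zygosity.REFERENCE and
                       father.zygosity is Zygosity.REFERENCE)
        if rules.de_novo and child.is_carrier and parents_ref:
            return "deNovo"
        if rules.ar and child.zygosity is Zygosity.HOMOZYGOUS and \
                mother.zygosity is Zygosity.HETEROZYGOUS and \
                father.zygosity is Zygosity.HETEROZYGOUS:
            return "AR"
        if rules.non_mendelian and not parents_ref and \
                all(_diploid(c) for c in (mother, father, child)):
            lo, hi = _transmission_bounds(mother, father)
            if not (lo <= child.alt_allele_count <= hi):
                return "NonMendelian"
        return None
    if ctype == "X" and rules.xld:
        if not all_called or not child.is_carrier:
            return None
        carriers = [sid for sid, call in
                    ((trio.mother_id, mother), (trio.father_id, father))
                    if call.is_carrier]
        if len(carriers) != 1:
            return None
        if trio.affected.get(carriers[0]) == \
                trio.affected.get(trio.child_id):
            return "XLD"
        return None
    return None  # Y, MT, unrecognized chromosomes: no label


def annotate_inheritance(ds, trio: TrioSpec):
    """Add ``INFO.InheritancePattern`` to every labelable document."""
    trio.validate_against(ds.meta.sample_ids)
    for doc in ds.docs:
        label = inheritance_label(doc, trio)
        if label is not None:
            doc.info["InheritancePattern"] = label
        else:
            doc.info.pop("InheritancePattern", None)
    ds.meta.declare_info("InheritancePattern", "1", "String",
                         "Trio inheritance pattern (AR/deNovo/"
                         "NonMendelian/XLD)")
    ds.invalidate_catalog()
    return ds


def _transmitting_parent(mother: SampleCall, father: SampleCall,
                         strict: bool) -> str | None:
    """Which single parent transmitted the alternate: 'M', 'F' or None."""
    m, f = mother.is_carrier, father.is_carrier
    if m and not f:
        return "M"
    if f and not m:
        return "F"
    if not strict and m and f:
        return None  # ambiguous either way
    return None


def _child_haplotype(call: SampleCall) -> int | None:
    """Index of the haplotype carrying the alternate, for a phased
    diploid heterozygous call; None when unphased or not applicable."""
    if not call.phased or not _diploid(call):
        return None
    tokens = call.gt_raw.split("|")
    alt_positions = [i for i, t in enumerate(tokens)
                     if t not in (".", "0")]
    if len(alt_positions) != 1:
        return None
    return alt_positions[0]


def annotate_compound_het(ds, trio: TrioSpec):
    """Flag compound-heterozygote candidate variants per gene.

    Documents lacking the gene field are skipped. Both members of a
    qualifying pair are flagged; the relation is symmetric and
    independent of document order.
    """
    trio.validate_against(ds.meta.sample_ids)
    by_gene: dict[str, list[int]] = {}
    origin: dict[int, str] = {}
    for doc_id, doc in enumerate(ds.docs):
        doc.info.pop("CompoundHet", None)
        gene = doc.get_field(trio.gene_field)
        if gene is None:
            continue
        if isinstance(gene, list):
            gene = next((g for g in gene if g is not None), None)
            if gene is None:
                continue
        mother, father, child = _trio_calls(doc, trio)
        if child.zygosity is not Zygosity.HETEROZYGOUS:
            continue
        parent = _transmitting_parent(mother, father,
                                      trio.rules.strict_transmission)
        if parent is None:
            continue
        origin[doc_id] = parent
        by_gene.setdefault(str(gene), []).append(doc_id)

    flagged: set[int] = set()
    for gene, ids in by_gene.items():
        for v in ids:
            if v in flagged:
                continue
            for w in ids:
                if w == v or origin[w] == origin[v]:
                    continue
                hv = _child_haplotype(ds.docs[v].calls[trio.child_id])
                hw = _child_haplotype(ds.docs[w].calls[trio.child_id])
                if hv is not None and hw is not None and hv == hw:
                    continue  # phased onto the same haplotype: cis, not trans
                flagged.add(v)
                flagged.add(w)
                break
    for doc_id in flagged:
        ds.docs[doc_id].info["CompoundHet"] = True
    ds.meta.declare_info("CompoundHet", "0", "Flag",
                         "Compound-heterozygote candidate")
    ds.invalidate_catalog()
    return ds


def annotate_trio(ds, trio: TrioSpec):
    """Run both trio annotators."""
    annotate_inheritance(ds, trio)
    annotate_compound_het(ds, trio)
    return ds
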