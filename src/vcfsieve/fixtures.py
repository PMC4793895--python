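"""Deterministic synthetic VCF / BED / trio inputs.

Every test input in this package is generated, never downloaded. A
single integer seed controls all randomness and the generation order is
fixed, so the same call yields byte-identical output on any platform.
Two generators exist:

* :func:`generate_vcf` — a general multi-sample VCF with controllable
  genotype composition (homozygous / heterozygous / no-call rates),
  missing-value rate, multi-allelic fraction and ploidy, plus a typed
  INFO block (depth, per-alternate allele frequency, impact class, a
  somatic flag and a gene symbol). Defaults are desk-scale but
  structurally faithful: sparse annotations, mixed zygosity, AD depths
  consistent with the genotypes.

* :func:`generate_trio` — a mother/father/child VCF in which each
  variant is *planted* with a known inheritance pattern (AR, deNovo,
  NonMendelian, XLD, a CompoundHet pair, or none), returning the
  per-variant ground truth alongside the text, for exact-recovery tests
  of the trio annotators.

Generated files pass strict validation with zero errors.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

from .errors import FixtureError

__all__ = ["generate_vcf", "generate_trio", "TrioFixture",
           "generate_bed"]

_IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_BASES = ("A", "C", "G", "T")

_HEADER_FIELDS = """\
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted impact class">
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">
##INFO=<ID=Gene,Number=1,Type=String,Description="Gene symbol">
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample read depth">"""


def _ref_alt(rng: random.Random, n_alts: int) -> tuple[str, list[str]]:
    ref = rng.choice(_BASES)
    alts = rng.sample([b for b in _BASES if b != ref], n_alts)
    return ref, alts


def _genotype(rng: random.Random, ploidy: int, n_alts: int,
              hom_fraction: float, het_fraction: float,
              nocall_fraction: float) -> str:
    """Draw one genotype with the requested zygosity composition."""
    r = rng.random()
    if r < nocall_fraction:
        return "/".join(["."] * ploidy)
    r -= nocall_fraction
    alt = lambda: str(rng.randint(1, n_alts))
    if r < hom_fraction:
        # all tokens alternate -> alt count = ploidy > 1 (homozygous)
        return "/".join(alt() for _ in range(ploidy))
    r -= hom_fraction
    if r < het_fraction:
        tokens = ["0"] * ploidy
        tokens[rng.randrange(ploidy)] = alt()
        return "/".join(tokens)
    return "/".join(["0"] * ploidy)


def generate_vcf(n_variants: int, n_samples: int, *, ploidy: int = 2,
                 seed: int = 0, hom_fraction: float = 0.1,
                 het_fraction: float = 0.3, nocall_fraction: float = 0.05,
                 missing_info_fraction: float = 0.15,
                 multiallelic_fraction: float = 0.0,
                 n_genes: int = 20,
                 chroms: tuple[str, ...] = ("1", "2")) -> str:
    """Generate a valid, deterministic multi-sample VCF as text.

    Genotypes are drawn per sample with the requested homozygous /
    heterozygous / no-call fractions (the remainder is reference). INFO
    annotations are sparse at ``missing_info_fraction``. With
    ``multiallelic_fraction > 0`` that share of records carries two
    alternate alleles, with Number=A/R arrays sized accordingly.
    """
    if n_variants < 0 or n_samples < 0:
        raise FixtureError("n_variants and n_samples must be >= 0")
    if ploidy < 1:
        raise FixtureError("ploidy must be >= 1")
    if hom_fraction + het_fraction + nocall_fraction > 1:
        raise FixtureError("zygosity fractions exceed 1")
    if ploidy == 1 and hom_fraction > 0:
        raise FixtureError("haploid genotypes cannot be homozygous "
                           "(alt-allele count cannot exceed 1)")
    rng = random.Random(seed)
    lines = ["##fileformat=VCFv4.2", _HEADER_FIELDS]
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    if sample_ids:
        header += "\tFORMAT\t" + "\t".join(sample_ids)
    lines.append(header)

    pos_by_chrom = {c: 0 for c in chroms}
    for i in range(n_variants):
        chrom = chroms[i % len(chroms)]
        pos_by_chrom[chrom] += rng.randint(50, 500)
        pos = pos_by_chrom[chrom]
        n_alts = 2 if rng.random() < multiallelic_fraction else 1
        ref, alts = _ref_alt(rng, n_alts)
        qual = round(rng.uniform(10, 2000), 2)
        filt = "PASS" if rng.random() > 0.1 else "LowQual"
        info_parts = []
        if rng.random() > missing_info_fraction:
            info_parts.append(f"DP={rng.randint(5, 400)}")
        if rng.random() > missing_info_fraction:
            afs = ",".join(f"{rng.uniform(0.001, 0.999):.4f}"
                           for _ in range(n_alts))
            info_parts.append(f"AF={afs}")
        if rng.random() > missing_info_fraction:
            info_parts.append(f"IMPACT={rng.choice(_IMPACTS)}")
        if rng.random() < 0.1:
            info_parts.append("SOMATIC")
        info_parts.append(f"Gene=GENE{rng.randint(1, n_genes)}")
        row = [chrom, str(pos), f"rs{seed}_{i}" if rng.random() < 0.3
               else ".", ref, ",".join(alts), f"{qual:g}", filt,
               ";".join(info_parts)]
        if sample_ids:
            row.append("GT:AD:DP")
            for _ in sample_ids:
                gt = _genotype(rng, ploidy, n_alts, hom_fraction,
                               het_fraction, nocall_fraction)
                tokens = gt.replace("|", "/").split("/")
                ref_depth = rng.randint(5, 60)
                depths = [ref_depth]
                for a in range(1, n_alts + 1):
                    carried = str(a) in tokens
                    depths.append(rng.randint(3, 40) if carried else 0)
                dp = sum(depths)
                row.append(f"{gt}:{','.join(map(str, depths))}:{dp}")
        lines.append("\t".join(row))
    # emit body grouped by chromosome so positions are monotone per file scan
    head, body = lines[:3], lines[3:]
    body.sort(key=lambda l: chroms.index(l.split("\t", 1)[0]))
    return "\n".join(head + body) + "\n"


def generate_bed(n_intervals: int, *, seed: int = 0,
                 chroms: tuple[str, ...] = ("1", "2"),
                 max_pos: int = 100_000) -> str:
    """Random BED3 text (0-based half-open intervals)."""
    rng = random.Random(seed)
    lines = []
    for _ in range(n_intervals):
        chrom = rng.choice(chroms)
        start = rng.randrange(0, max_pos - 1)
        end = rng.randrange(start + 1, min(start + 2000, max_pos))
        lines.append(f"{chrom}\t{start}\t{end}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# trio fixture with planted ground truth

@dataclass
class TrioFixture:
    """A generated trio VCF plus its planted per-variant ground truth.

    ``truth`` is aligned with the body rows (file order); each entry
    records the planted inheritance pattern (or None), whether the
    variant is half of a compound-het pair, and its IMPACT and gene.
    """

    vcf_text: str
    truth: list[dict] = dc_field(default_factory=list)
    mother_id: str = "MOTHER"
    father_id: str = "FATHER"
    child_id: str = "CHILD"
    affected: dict[str, bool] = dc_field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.truth)


#: planted genotype templates: (mother GT, father GT, child GT)
_PATTERN_GTS = {
    "AR": ("0/1", "0/1", "1/1"),
    "deNovo": ("0/0", "0/0", "0/1"),
    "NonMendelian": ("0/0", "0/1", "1/1"),
    "XLD": ("0/1", "0/0", "0/1"),  # on X; mother affected like child
}
#: label-free genotype templates (must never trigger any rule)
_NONE_GTS = (
    ("0/1", "0/0", "0/1"),  # inherited het from mother
    ("0/0", "0/1", "0/1"),  # inherited het from father
    ("0/1", "0/1", "0/1"),  # het trio, Mendelian, child not hom
    ("0/0", "0/0", "0/0"),  # monomorphic reference
    ("0/1", "0/1", "0/0"),  # child non-carrier
)

_TRIO_KINDS = ("AR", "deNovo", "NonMendelian", "XLD", "CompoundHet", "none")


def generate_trio(n_variants: int, planted: dict[str, int] | None = None,
                  seed: int = 0) -> TrioFixture:
    """Generate a trio VCF with known planted inheritance patterns.

    ``planted`` maps pattern names (``AR``, ``deNovo``, ``NonMendelian``,
    ``XLD``, ``CompoundHet`` — counted in *pairs* — and ``none``) to
    counts. Unassigned variants up to ``n_variants`` are planted as
    ``none``. Raises :class:`FixtureError` when the request does not fit
    in ``n_variants``.
    """
    planted = dict(planted or {})
    for key in planted:
        if key not in _TRIO_KINDS:
            raise FixtureError(f"unknown planted pattern {key!r}")
        if planted[key] < 0:
            raise FixtureError(f"negative count for {key!r}")
    used = sum(planted.get(k, 0) for k in
               ("AR", "deNovo", "NonMendelian", "XLD", "none"))
    used += 2 * planted.get("CompoundHet", 0)
    if used > n_variants:
        raise FixtureError(
            f"planted patterns need {used} variants but n_variants="
            f"{n_variants}")
    planted["none"] = planted.get("none", 0) + (n_variants - used)

    rng = random.Random(seed)
    # build (chrom_class, gene, gts, truth_pattern, compound) tuples
    autosomal: list[tuple[str, tuple[str, str, str], str | None, bool]] = []
    x_linked: list[tuple[str, tuple[str, str, str], str | None, bool]] = []
    gene_serial = 0

    def fresh_gene() -> str:
        nonlocal gene_serial
        gene_serial += 1
        return f"GENE{gene_serial}"

    for kind in ("AR", "deNovo", "NonMendelian"):
        for _ in range(planted.get(kind, 0)):
            autosomal.append((fresh_gene(), _PATTERN_GTS[kind], kind, False))
    for _ in range(planted.get("XLD", 0)):
        x_linked.append((fresh_gene(), _PATTERN_GTS["XLD"], "XLD", False))
    for _ in range(planted.get("CompoundHet", 0)):
        gene = fresh_gene()
        autosomal.append((gene, ("0/1", "0/0", "0/1"), None, True))
        autosomal.append((gene, ("0/0", "0/1", "0/1"), None, True))
    for i in range(planted.get("none", 0)):
        autosomal.append((fresh_gene(), _NONE_GTS[i % len(_NONE_GTS)],
                          None, False))
    rng.shuffle(autosomal)

    lines = ["##fileformat=VCFv4.2", _HEADER_FIELDS,
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             "MOTHER\tFATHER\tCHILD"]
    truth: list[dict] = []
    pos = {"1": 0, "X": 0}
    for chrom, variants in (("1", autosomal), ("X", x_linked)):
        for gene, gts, pattern, compound in variants:
            pos[chrom] += rng.randint(50, 500)
            ref, alts = _ref_alt(rng, 1)
            impact = rng.choice(_IMPACTS[:3])
            info = (f"DP={rng.randint(20, 300)};IMPACT={impact};"
                    f"Gene={gene}")
            row = [chrom, str(pos[chrom]), ".", ref, alts[0],
                   f"{rng.uniform(30, 1500):.2f}", "PASS", info, "GT:AD:DP"]
            for gt in gts:
                tokens = gt.split("/")
                ref_depth = rng.randint(8, 50)
                alt_depth = rng.randint(5, 45) if "1" in tokens else 0
                row.append(f"{gt}:{ref_depth},{alt_depth}:"
                           f"{ref_depth + alt_depth}")
            lines.append("\t".join(row))
            truth.append({"chrom": chrom, "pos": pos[chrom],
                          "pattern": pattern, "compound_het": compound,
                          "impact": impact, "gene": gene})
    vcf_text = "\n".join(lines) + "\n"
    return TrioFixture(vcf_text=vcf_text, truth=truth,
                       affected={"CHILD": True, "MOTHER": True,
                                 "FATHER": False})
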