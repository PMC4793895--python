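# vcfsieve

Mine, filter and export variants from VCF files — driven entirely by the
annotations already inside them.

Variant discovery pipelines end with a VCF whose INFO and FORMAT fields
carry everything downstream interpretation needs: caller metrics, predicted
impact, population frequencies, private institutional annotations. Most
filtering tools discard those annotations and re-annotate with their own
sources. `vcfsieve` does the opposite: it reads the VCF **header metadata**
to learn every declared field's type and arity, makes all of them queryable,
and lets you trim variants step by step with typed filters — each step
reporting how many variants remain. It is a scriptable library plus CLI for
the classic interactive variant-mining workflow (trio analysis, multi-group
case/control), built for reproducible batch use.

## What it does

* **Metadata-driven ingestion.** Every `##INFO`/`##FORMAT` declaration is
  parsed into a typed schema; body values are converted accordingly
  (arrays for multi-valued fields, booleans for flags, absent for `.`).
  Plain or gzip input (detected by magic bytes), streamed record by record.
  A strict validator reports every malformed line and every undeclared key
  with its line number and text.
* **Ploidy-agnostic zygosity.** A sample's genotype is classified by its
  alternate-allele count: tokens of the GT string that are neither `.` nor
  `0` are alternate alleles — one means heterozygous, more than one
  homozygous. `0/1` and `0/0/1` are both heterozygous; the rule needs no
  assumption about ploidy. (Under this count rule a diploid `1/2` call is
  *homozygous* — two alternate alleles; normalize multi-allelic records to
  avoid the ambiguity.)
* **Three per-sample logics.** Zygosity from GT; ref/alt read depths from
  AD (`ref,alt`); and min/max summaries of any numeric FORMAT field across
  samples, exposed as filterable `FORMAT.<field>.min`/`.max`.
* **Sequential typed filters.** Numeric (`< <= = != >= >`), flag
  (`is_true`/`is_false`), and string set filters (`in_set`/`not_in_set`),
  applied consecutively with a survivor count after each step. Filters are
  conjunctive, so the final set is order-invariant. Chains, groups and
  range-annotation references save to versioned JSON strategy files that
  replay on other datasets.
* **Group genotype queries.** Named sample groups with quantified
  conditions — heterozygous in *all* of group 1, homozygous in *50% of*
  group 2, not present in *any* control — optionally requiring a minimum
  alternate read depth from AD.
* **Range and trio annotations.** BED files or pasted `chrom:start-end`
  ranges become boolean `RANGE.<name>` fields; trio genotypes yield
  `INFO.InheritancePattern` (`AR`, `deNovo`, `NonMendelian`, `XLD`) and
  `INFO.CompoundHet`, injected as ordinary INFO fields and therefore
  filterable and exportable like any native annotation.
* **Normalization and export.** Multi-allelic records split to one allele
  per row (Number=A/R arrays sliced, AD and GT remapped); surviving
  variants export as a TSV with any choice of columns.

## Worked example: trio analysis

Generate a synthetic mother/father/child VCF with planted inheritance
patterns, annotate it, and mine it:

```bash
vcfsieve fixtures trio --variants 200 --plant AR=12 --plant deNovo=9 \
    --plant NonMendelian=7 --plant XLD=6 --plant CompoundHet=5 \
    --seed 5 -o trio.vcf
vcfsieve annotate-trio trio.vcf --mother MOTHER --father FATHER \
    --child CHILD --affected CHILD,MOTHER -o trio.json
vcfsieve filter trio.json \
    --where "INFO.InheritancePattern in AR,deNovo,NonMendelian,XLD" \
    --where "INFO.IMPACT in HIGH"
```

which prints the running tabulation of filters and remaining variants:

```
(all variants)                                     200
INFO.InheritancePattern in_set {AR,NonMendelian,XLD,deNovo} 34
INFO.IMPACT in_set {HIGH}                          12
```

Of 200 variants, 34 match an interesting inheritance mode (the 12+9+7+6
planted patterns), and 12 of those also have a HIGH predicted impact.
Clearing the filters and selecting compound heterozygotes instead:

```bash
vcfsieve filter trio.json --where "INFO.CompoundHet is-true"
```

```
(all variants)                                     200
INFO.CompoundHet is_true                           10
```

— the 5 planted pairs, i.e. 10 variants, each heterozygous in the child
and transmitted from opposite parents within one gene.

The same workflow from Python:

```python
from vcfsieve import Dataset, FilterSpec, Session, TrioSpec, annotate_trio

ds = Dataset.from_vcf("trio.vcf")
annotate_trio(ds, TrioSpec(mother_id="MOTHER", father_id="FATHER",
                           child_id="CHILD",
                           affected={"CHILD": True, "MOTHER": True}))
session = Session(ds)
session.add_filter(FilterSpec(field="INFO.InheritancePattern",
                              kind="string", operator="in_set",
                              value={"AR", "deNovo", "NonMendelian", "XLD"}))
session.add_filter(FilterSpec(field="INFO.IMPACT", kind="string",
                              operator="in_set", value={"HIGH"}))
print(session.chain.counts)        # [34, 12]
```

Case/control group queries follow the same pattern on any multi-sample
VCF:

```bash
vcfsieve filter study.vcf \
    --group "cases=S1,S2,S3" --group "controls=S4,S5" \
    --group-where "cases:require:0.5:hom" \
    --group-where "controls:exclude:any:either"
```

## Filter expression grammar

```
expr  := FIELD OP [VALUE]
OP    := "<" | "<=" | "=" | "!=" | ">=" | ">"      numeric
       | "in" | "not-in"                           string (VALUE = comma list)
       | "is-true" | "is-false"                    flag
FIELD := dot-separated path: CORE.QUAL, INFO.AF, FORMAT.DP.min,
         DERIVED.sample_count, RANGE.<name>
```

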