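# Methods

This note records the rules, conventions and design choices the package
implements — the parts a maintainer or reviewer would otherwise have to
reverse-engineer from the code.

## Metadata-driven parsing

A VCF's header is the schema: every `##INFO` and `##FORMAT` line declares
an ID, a `Type` (Integer, Float, Flag, String, Character) and a `Number`
(arity: a count, `A` per-alternate, `R` per-allele, `G` per-genotype, or
`.` unknown). The parser converts body values to these declared types;
`Number=1` fields stay scalar, anything else becomes an array; bare INFO
keys become boolean flags; `.` is *absent* — deliberately distinct from
zero and from the empty string, so filters over sparsely annotated fields
have well-defined missing-value semantics.

Two modes govern defects. **Strict** (used by validation): an undeclared
key or a value unparsable as its declared type is an error carrying the
line number and text. **Tolerant** (the loader default): the value is
retained as a string and a warning logged. Real-world VCF dialects stray
from their headers often enough that hard-failing on load would make the
tool useless on exactly the files people need to inspect; validation is
the tool for enforcing hygiene.

Gzip is detected from the two magic bytes `1f 8b`, never the file name.
Ingestion is a generator: memory is per record, not per file.

The validator reports: malformed header declarations; missing `#CHROM`;
body lines with fewer than 8 columns or unparsable core values;
undeclared INFO/FORMAT keys used in the body (errors); undeclared FILTER
codes and non-monotone within-chromosome positions (warnings).

## Zygosity by alternate-allele count

The GT string is split on `/` and `|` (so phasing never matters); a token
counts as an alternate allele iff it is neither `.` nor `0`. The count
determines zygosity: 0 → reference (or no-call when *every* token is
`.`), 1 → heterozygous, >1 → homozygous. The rule is ploidy-free: `0/1`
and `0/0/1` are both heterozygous, and a hemizygous `1` is a carrier.

Tokenizing, rather than literally deleting the characters `.`, `/`, `|`
and `0` and counting what remains, keeps multi-digit allele indices
(`0/10`) intact; an exhaustive property test verifies the two procedures
agree on every genotype with single-digit alleles up to ploidy 3.

Two consequences worth flagging:

* `1/2` (two different alternates) classifies as **homozygous** — two
  alternate alleles are present — although the site is biologically a
  heterozygous-alt site. Normalizing to one allele per row removes the
  ambiguity, and the loader warns on multi-allelic input.
* No-call and reference are distinguished internally, but group filters
  treat both as "variant not present": an uncalled sample never satisfies
  a genotype requirement and still counts in fraction denominators.

Half-calls (`./1`) count the called alternate: heterozygous.

## AD depths and numeric summaries

AD is read as `ref_depth,alt_depth` (first two elements). A one-element
AD is an error; more than two elements (unnormalized multi-allelic
record) is tolerated with a warning, keeping the first alternate's depth.
For every numeric FORMAT field, the minimum and maximum across samples at
each variant are precomputed as `FORMAT.<field>.min`/`.max` — the hook
for "remove events with too few supporting reads in any sample"-style
filters.

## Multi-allelic normalization

A record with k alternates splits into k single-alternate documents:

* `Number=A` arrays are sliced to the matching element, `Number=R` to
  (reference, retained alternate); other INFO/FORMAT fields are copied.
* AD becomes (reference depth, retained allele's depth).
* GT is remapped so the retained alternate has index 1; *other*
  alternates also map to 1 — they remain non-reference, so carrier status
  and count-rule zygosity are preserved in every split document. With
  `1/2` and alternates A,T: both output records show a homozygous
  carrier, record A with allele-A's depth, record T with allele-T's.
* `Number=G` (per-genotype) fields are dropped with a warning: their
  re-indexing depends on a genotype model this package does not assume.
* A per-alternate array whose length differs from k is an error naming
  the field.

The multiset of (chrom, pos, ref, alt) pairs is conserved — a tested
invariant.

## The document store

Documents get stable integer ids in file order. The field catalog types
every observed dot-separated path (`CORE.QUAL`, `INFO.AF`,
`FORMAT.DP.min`, `DERIVED.sample_count`, `RANGE.<name>`) as numeric, flag
or string from the header declarations; string fields carry their
observed distinct values and cardinality (the 25-value UI threshold for
checkbox-vs-type-ahead is surfaced as metadata, never enforced). Indexes
(a value→ids map plus a sorted array for numeric order queries) are pure
accelerators: indexed and unindexed queries must return bit-identical id
sets, enforced by randomized tests. No field is indexed by default.
Snapshots are versioned JSON.

## Filters and chains

Operator families per kind: numeric `< <= = != >= >`, flag `is_true` /
`is_false`, string `in_set` / `not_in_set`. The closure beyond the
minimal relational examples is deliberate: each family is the natural
completion of its type. Numeric equality uses relative tolerance 1e-9 on
non-integers, since values arrive as parsed text.

Chains apply filters consecutively; the count after each step is the
interactive "remaining variants" display. Per-filter `missing_policy`
(default `exclude_missing`) decides whether documents lacking the field
survive; an absent flag is false, so `is_false` keeps flag-free
documents. Array-valued fields match if **any** element satisfies the
predicate — after normalization per-alternate arrays are singletons, so
this only matters for unnormalized input.

Sessions mirror interactive use: add filters stepwise, save the current
analysis under a name, clear, start over; saved analyses persist.
Strategy files are versioned JSON carrying filters, groups and
range-annotation names; loading against a dataset resolves every
referenced field and sample and fails with the offender's name rather
than silently dropping anything.

## Group filters

A condition is (zygosity requirement) × (quantifier) × (mode) × (optional
minimum alternate depth). The fraction quantifier needs
`ceil(p · group size)` matching members, computed over **all** members —
uncalled samples inflate the denominator and never match, so missing
genotypes cannot satisfy a requirement by default. Ceiling was chosen
because "homozygous in 50% of a group of 7" most naturally means "at
least 4"; the choice is documented rather than assumed. Exclusion is the
document-wise negation of the corresponding requirement (both classic
control-exclusion scenarios reduce to it), and a tested duality
invariant. A depth requirement is unsatisfiable without AD. Groups may
overlap freely.

## Ranges

BED is 0-based half-open; pasted `chrom:start-end` ranges are 1-based
inclusive; VCF POS is 1-based. Internally everything becomes 0-based
half-open, and a variant belongs to an interval iff
`chromStart < POS ≤ chromEnd`. Membership is point semantics on POS —
the REF span of an indel is not considered (span semantics would be a
straightforward extension). Chromosome names match exactly; an opt-in
normalization strips the `chr` prefix. Annotation names must be distinct;
re-annotating the same name with the same intervals is idempotent.

## Trio rules

The annotation labels are standard field vocabulary; the package's rule
table makes them precise (and `InheritanceRules` lets a user disable
individual rules):

* **AR** — autosome, child homozygous, both parents heterozygous.
* **deNovo** — child carries ≥1 alternate, both parents called
  reference.
* **NonMendelian** — all three called diploid and the child's
  alternate-allele count falls outside the feasible transmission range
  [number of homozygous parents, number of carrier parents]; de novo
  candidates are labeled deNovo, never NonMendelian. The labels are
  mutually exclusive by construction (an exhaustive 27-genotype test
  pins the table).
* **XLD** — on X: child carries, exactly one parent carries, and the
  carrier parent's affected status equals the child's. Carrier status,
  not zygosity, is used on X so hemizygous males (`1`) are handled.
* Y and MT variants are never labeled.

**CompoundHet** flags child-heterozygous variants in a gene transmitted
from opposite parents. Transmission is strict: the transmitting parent
carries the alternate and the other parent does not (the configurable
`strict_transmission` relaxation point exists because requiring the
other parent to be a non-carrier is a choice, not a law). When both
child genotypes are phased, the two variants must lie on opposite
haplotypes — phase confirms trans configuration instead of assuming it.
Both members of a qualifying pair are flagged; the relation is symmetric
and order-independent.

Both annotations are written as declared INFO fields, so they flow
through the catalog, filters, strategies and export like native
annotations.

## Export

TSV, UTF-8, LF, header row; `.` for absent; arrays comma-joined
(matching VCF syntax); booleans `TRUE`/`FALSE`. Rows follow original
file order. The default column set is the 8 fixed VCF columns plus
carrier count and carrier list. Hiding a column never removes it from
the filterable catalog.

## Synthetic data

The generators exist so every behavior is testable without downloads,
and their defaults describe the study conditions the tests run under:
multi-sample diploid VCFs with 10% homozygous / 30% heterozygous / 5%
no-call genotypes (the remainder reference), sparse INFO annotations at
15% missingness, AD depths drawn consistently with each genotype
(carriers 3–40 alternate reads, non-carriers 0), and an impact class and
gene symbol per variant. Randomized checks use 400–1000 variants and 1–6
samples — large enough that every operator, missing-value path and
quantifier is exercised many times, small enough that the whole suite
runs in seconds. A single integer seed fixes everything; identical seeds
give byte-identical files.

`generate_trio` plants each requested pattern with a fixed genotype
template (e.g. AR = 0/1 × 0/1 → 1/1; a CompoundHet pair = two
child-heterozygous variants in one gene, one transmitted from each
parent), shuffles autosomal variants deterministically, places XLD
plants on X with the mother as the affected transmitting carrier, and
returns the per-variant truth for exact-recovery tests.

What the generators do **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, sequencing-error structure, indels/complex
alleles, or annotation dialects that violate their own headers. Passing
tests therefore demonstrate the engine's logic — parsing fidelity,
filter/oracle equivalence, truth-table correctness, recovery of planted
patterns — not robustness to every malformed file in the wild; the
tolerant parse mode and the validator are the mitigation for the latter.

## Numerical and degenerate-input choices

* Fraction thresholds: `ceil(p·n)` with a 1e-9 slack against float
  artifacts (`0.1·30 = 3.0000000000000004`).
* Numeric filter equality: relative tolerance 1e-9 on non-integers.
* Empty chain = identity; empty survivor set exports a header-only file;
  an empty BED labels everything FALSE; a zero-variant VCF is valid.
* Ties/order: catalog iteration and exports are deterministic; carrier
  lists are sorted by sample id so results are invariant under sample
  column order.

## Known limitations

* No VCF output of filtered/annotated results (TSV only); the
  `normalize` command is the one VCF writer, covering the one-allele-
  per-row best practice.
* No OR composition of filters; chains are conjunctions.
* `Number=G` fields are dropped on multi-allelic splitting.
* Trio support covers one trio; general pedigrees are out of scope.
* The in-memory store targets desk-scale files (hundreds of thousands of
  variants), not database-scale deployments; the narrow query interface
  is the seam where a document-database backend could be added.
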