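"""Metadata-driven VCF ingestion.

The header of a VCF declares, for every INFO and FORMAT field, an ID, a
Type (Integer, Float, Flag, String, Character) and an arity (Number).
Parsing here is driven entirely by those declarations: values in the body
are converted to the declared type, multi-valued entries become arrays,
bare INFO keys become boolean flags, and ``.`` means *absent* (distinct
from zero or the empty string, so sparse annotations filter predictably).

Two parse modes exist. In **strict** mode an undeclared key or an
ill-typed value is an error carrying its line number and text, mirroring
the requirement that files pass format validation before mining. In
**tolerant** mode (the loader's default) the offending value is retained
as a string and a warning is logged — real-world VCF dialects vary.

Multi-allelic records are accepted but flagged; :func:`split_multiallelic`
normalizes them to one alternate allele per row, slicing per-alternate
(Number=A) and per-allele (Number=R) arrays and remapping genotypes so
every retained document reads like a biallelic record.

Gzip input is detected from the magic bytes, never the file extension,
and ingestion streams record by record.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field as dc_field
from typing import IO, Iterable, Iterator

from .errors import UnknownFieldError, VCFParseError
from .genotypes import SampleCall, Zygosity, classify_genotype, parse_ad, \
    summarize_numeric_format

logger = logging.getLogger(__name__)

__all__ = [
    "FieldDef",
    "HeaderMeta",
    "VariantDocument",
    "ValidationIssue",
    "ValidationReport",
    "parse_header",
    "parse_record",
    "load_vcf",
    "validate_vcf",
    "split_multiallelic",
    "render_vcf",
]

CORE_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")
_VALID_TYPES = {"Integer", "Float", "Flag", "String", "Character"}


@dataclass(frozen=True)
class FieldDef:
    """One ##INFO or ##FORMAT declaration: ID, Number (arity) and Type."""

    id: str
    number: str  # "0", "1", "2", ..., "A", "R", "G" or "."
    type: str    # Integer | Float | Flag | String | Character
    description: str = ""

    @property
    def is_numeric(self) -> bool:
        return self.type in ("Integer", "Float")

    @property
    def is_scalar(self) -> bool:
        return self.number == "1"


@dataclass
class HeaderMeta:
    """Declared INFO/FORMAT/FILTER fields and the sample column order."""

    info_fields: dict[str, FieldDef] = dc_field(default_factory=dict)
    format_fields: dict[str, FieldDef] = dc_field(default_factory=dict)
    filter_ids: set[str] = dc_field(default_factory=set)
    sample_ids: list[str] = dc_field(default_factory=list)
    extra_lines: list[str] = dc_field(default_factory=list)

    def declare_info(self, field_id: str, number: str, type_: str,
                     description: str = "") -> None:
        """Register an INFO field (used by annotators injecting new fields)."""
        self.info_fields[field_id] = FieldDef(field_id, number, type_,
                                              description)


@dataclass
class VariantDocument:
    """One variant row, flattened for querying.

    ``info`` maps declared INFO ids to typed values (scalars, arrays, or
    ``True`` for flags); ``calls`` maps sample ids to parsed
    :class:`~vcfsieve.genotypes.SampleCall` objects; ``derived`` holds
    computed summaries (per-field sample minima/maxima, carrier count and
    list, range-membership flags) addressed by dot-separated field paths.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str
    qual: float | None
    filter_status: str
    info: dict = dc_field(default_factory=dict)
    calls: dict[str, SampleCall] = dc_field(default_factory=dict)
    derived: dict = dc_field(default_factory=dict)
    meta: HeaderMeta | None = None
    alts: tuple[str, ...] = ()
    line_number: int | None = None

    def __post_init__(self):
        if not self.alts:
            self.alts = tuple(self.alt.split(","))

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    def get_field(self, path: str):
        """Resolve a dot-separated field path to this document's value.

        Namespaces: ``CORE.CHROM`` … ``CORE.FILTER``; ``INFO.<id>``;
        ``FORMAT.<id>.min`` / ``.max``; ``DERIVED.sample_count`` /
        ``sample_list``; ``RANGE.<name>``. Returns ``None`` for an absent
        value; raises :class:`UnknownFieldError` for an unknown namespace.
        """
        ns, _, rest = path.partition(".")
        if ns == "CORE":
            if rest == "CHROM":
                return self.chrom
            if rest == "POS":
                return self.pos
            if rest == "ID":
                return self.id
            if rest == "REF":
                return self.ref
            if rest == "ALT":
                return self.alt
            if rest == "QUAL":
                return self.qual
            if rest == "FILTER":
                return self.filter_status
            raise UnknownFieldError(path)
        if ns == "INFO":
            return self.info.get(rest)
        if ns in ("FORMAT", "DERIVED", "RANGE"):
            return self.derived.get(path)
        raise UnknownFieldError(path)

    def compute_derived(self) -> None:
        """Populate carrier summaries and numeric FORMAT min/max fields."""
        carriers = [sid for sid, call in self.calls.items() if call.is_carrier]
        self.derived["DERIVED.sample_count"] = len(carriers)
        # sorted so the list is invariant under sample-column order
        self.derived["DERIVED.sample_list"] = ",".join(sorted(carriers))
        if self.meta is not None:
            for fid, decl in self.meta.format_fields.items():
                if fid == "GT" or not decl.is_numeric:
                    continue
                mm = summarize_numeric_format(self, fid)
                if mm is not None:
                    self.derived[f"FORMAT.{fid}.min"] = mm[0]
                    self.derived[f"FORMAT.{fid}.max"] = mm[1]


@dataclass(frozen=True)
class ValidationIssue:
    line_number: int
    severity: str  # "error" | "warning"
    message: str
    line_text: str

    def as_tsv(self) -> str:
        return f"{self.line_number}\t{self.severity}\t{self.message}"


@dataclass
class ValidationReport:
    """Outcome of validating a whole file; ``ok`` iff no error-severity issue."""

    issues: list[ValidationIssue] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def add(self, line_number: int, severity: str, message: str,
            line_text: str = "") -> None:
        self.issues.append(ValidationIssue(line_number, severity, message,
                                           line_text))


# ---------------------------------------------------------------------------
# header parsing

def _parse_structured_line(body: str, line_number: int) -> dict[str, str]:
    """Parse the ``<ID=...,Number=...,Type=...,Description="...">`` payload."""
    if not (body.startswith("<") and body.endswith(">")):
        raise VCFParseError("structured header value must be <...>",
                            line_number, body)
    attrs: dict[str, str] = {}
    key, buf, in_quotes, state = "", [], False, "key"
    for ch in body[1:-1] + ",":
        if state == "key":
            if ch == "=":
                key = "".join(buf).strip()
                buf, state = [], "value"
            else:
                buf.append(ch)
        else:
            if ch == '"':
                in_quotes = not in_quotes
                buf.append(ch)
            elif ch == "," and not in_quotes:
                val = "".join(buf).strip()
                if len(val) >= 2 and val[0] == '"' and val[-1] == '"':
                    val = val[1:-1]
                if not key:
                    raise VCFParseError("attribute without a key",
                                        line_number, body)
                attrs[key] = val
                buf, state = [], "key"
            else:
                buf.append(ch)
    if in_quotes:
        raise VCFParseError("unterminated quote in header declaration",
                            line_number, body)
    return attrs


def parse_header(header_lines: Iterable[str]) -> HeaderMeta:
    """Build :class:`HeaderMeta` from the ``##``/``#CHROM`` lines.

    Raises :class:`VCFParseError` (with line number) on a malformed or
    duplicate declaration, or when the ``#CHROM`` column line is missing.
    """
    meta = HeaderMeta()
    saw_chrom = False
    for ln, raw in enumerate(header_lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            if key in ("INFO", "FORMAT"):
                attrs = _parse_structured_line(value, ln)
                for required in ("ID", "Type"):
                    if required not in attrs:
                        raise VCFParseError(
                            f"##{key} declaration missing {required}=",
                            ln, line)
                if attrs["Type"] not in _VALID_TYPES:
                    raise VCFParseError(
                        f"invalid Type={attrs['Type']!r} in ##{key}",
                        ln, line)
                target = meta.info_fields if key == "INFO" \
                    else meta.format_fields
                fid = attrs["ID"]
                if fid in target:
                    raise VCFParseError(
                        f"duplicate ##{key} declaration for {fid!r}",
                        ln, line)
                target[fid] = FieldDef(fid, attrs.get("Number", "."),
                                       attrs["Type"],
                                       attrs.get("Description", ""))
            elif key == "FILTER":
                attrs = _parse_structured_line(value, ln)
                if "ID" not in attrs:
                    raise VCFParseError("##FILTER declaration missing ID=",
                                        ln, line)
                if attrs["ID"] in meta.filter_ids:
                    raise VCFParseError(
                        f"duplicate ##FILTER declaration for {attrs['ID']!r}",
                        ln, line)
                meta.filter_ids.add(attrs["ID"])
            else:
                meta.extra_lines.append(line)
        elif line.startswith("#CHROM"):
            cols = line[1:].split("\t")
            if tuple(cols[:8]) != CORE_COLUMNS:
                raise VCFParseError(
                    "#CHROM line must start with the 8 fixed columns",
                    ln, line)
            if len(cols) > 8:
                if cols[8] != "FORMAT":
                    raise VCFParseError(
                        "column 9 must be FORMAT when samples are present",
                        ln, line)
                meta.sample_ids = cols[9:]
                if not meta.sample_ids:
                    raise VCFParseError("FORMAT column with no sample columns",
                                        ln, line)
                if len(set(meta.sample_ids)) != len(meta.sample_ids):
                    raise VCFParseError("duplicate sample ids", ln, line)
            saw_chrom = True
        else:
            raise VCFParseError("unexpected non-header line in header",
                                ln, line)
    if not saw_chrom:
        raise VCFParseError("missing #CHROM column line")
    return meta


# ---------------------------------------------------------------------------
# record parsing

def _convert(token: str, decl: FieldDef):
    if decl.type == "Integer":
        return int(token)
    if decl.type == "Float":
        return float(token)
    return token  # String / Character


def _parse_typed_value(value: str, decl: FieldDef, *, strict: bool,
                       line_number: int | None, context: str):
    """Convert an INFO/FORMAT value string per its declaration.

    Scalar (Number=1) fields yield a scalar; every other arity yields a
    list. ``.`` elements inside arrays become ``None``.
    """
    try:
        if decl.is_scalar and "," not in value:
            return _convert(value, decl)
        return [None if t == "." else _convert(t, decl)
                for t in value.split(",")]
    except ValueError:
        msg = (f"{context} value {value!r} is not parsable as declared type "
               f"{decl.type}")
        if strict:
            raise VCFParseError(msg, line_number, value)
        logger.warning("%s; retained as string", msg)
        return value


def parse_record(line: str, meta: HeaderMeta, *, strict: bool = False,
                 line_number: int | None = None) -> VariantDocument:
    """Parse one tab-delimited body line into a :class:`VariantDocument`.

    INFO key=value pairs are converted to the declared type; bare keys
    become ``True`` flags; ``.`` values are absent. Per-sample FORMAT
    values are bound positionally to the FORMAT key column; GT and AD get
    dedicated zygosity/depth parsing. In strict mode an undeclared or
    ill-typed field raises; in tolerant mode it is kept as a string with a
    logged warning.
    """
    cols = line.rstrip("\n").rstrip("\r").split("\t")
    if len(cols) < 8:
        raise VCFParseError(
            f"record has {len(cols)} columns; at least 8 required",
            line_number, line)
    chrom, pos_s, vid, ref, alt, qual_s, filt, info_s = cols[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VCFParseError(f"POS {pos_s!r} is not an integer",
                            line_number, line)
    if pos < 1:
        raise VCFParseError(f"POS must be >= 1, got {pos}", line_number, line)
    if not ref or not alt:
        raise VCFParseError("REF and ALT must be non-empty",
                            line_number, line)
    qual: float | None
    if qual_s == ".":
        qual = None
    else:
        try:
            qual = float(qual_s)
        except ValueError:
            raise VCFParseError(f"QUAL {qual_s!r} is not numeric",
                                line_number, line)

    info: dict = {}
    if info_s not in (".", ""):
        for token in info_s.split(";"):
            if not token:
                continue
            key, eq, value = token.partition("=")
            decl = meta.info_fields.get(key)
            if decl is None:
                msg = f"INFO key {key!r} is not declared in the header"
                if strict:
                    raise VCFParseError(msg, line_number, line)
                logger.warning("%s; retained as string", msg)
                info[key] = True if not eq else value
                continue
            if not eq:  # bare key: flag
                info[key] = True
                continue
            if value == ".":
                continue  # absent
            info[key] = _parse_typed_value(
                value, decl, strict=strict, line_number=line_number,
                context=f"INFO {key}")

    calls: dict[str, SampleCall] = {}
    if len(cols) > 8:
        if len(cols) < 10:
            raise VCFParseError("FORMAT column present but no sample columns",
                                line_number, line)
        fmt_keys = cols[8].split(":")
        for fid in fmt_keys:
            if fid not in meta.format_fields:
                msg = f"FORMAT key {fid!r} is not declared in the header"
                if strict:
                    raise VCFParseError(msg, line_number, line)
                logger.warning(msg)
        sample_cols = cols[9:]
        if len(sample_cols) != len(meta.sample_ids):
            raise VCFParseError(
                f"{len(sample_cols)} sample columns for "
                f"{len(meta.sample_ids)} declared samples",
                line_number, line)
        for sid, scol in zip(meta.sample_ids, sample_cols):
            call = SampleCall()
            values = scol.split(":")
            # trailing FORMAT fields may be dropped per the VCF spec
            for fid, value in zip(fmt_keys, values):
                if value == "" or value == ".":
                    if fid == "GT":
                        call.gt_raw = "."
                    continue
                if fid == "GT":
                    call.gt_raw = value
                    try:
                        call.zygosity, call.alt_allele_count = \
                            classify_genotype(value)
                    except Exception:
                        if strict:
                            raise VCFParseError(
                                f"malformed GT {value!r} for sample {sid}",
                                line_number, line)
                        logger.warning("malformed GT %r for sample %s",
                                       value, sid)
                    continue
                decl = meta.format_fields.get(fid)
                if decl is not None:
                    typed = _parse_typed_value(
                        value, decl, strict=strict, line_number=line_number,
                        context=f"FORMAT {fid} (sample {sid})")
                else:
                    typed = value
                call.other_format[fid] = typed
                if fid == "AD":
                    try:
                        call.ref_depth, call.alt_depth = parse_ad(value)
                    except Exception:
                        if strict:
                            raise VCFParseError(
                                f"malformed AD {value!r} for sample {sid}",
                                line_number, line)
                        logger.warning("malformed AD %r for sample %s",
                                       value, sid)
            calls[sid] = call

    doc = VariantDocument(chrom=chrom, pos=pos,
                          id=None if vid == "." else vid,
                          ref=ref, alt=alt, qual=qual, filter_status=filt,
                          info=info, calls=calls, meta=meta,
                          line_number=line_number)
    return doc


# ---------------------------------------------------------------------------
# file-level operations

def _open_text(source) -> IO[str]:
    """Open a path or binary/text stream, transparently un-gzipping.

    Gzip is recognized from the two magic bytes, not the file name.
    """
    if isinstance(source, (str, os.PathLike)):
        if not os.path.exists(source):
            raise VCFParseError(f"no such file: {source}")
        if os.path.getsize(source) == 0:
            raise VCFParseError(f"empty file: {source}")
        raw: IO[bytes] = open(source, "rb")
    elif isinstance(source, io.TextIOBase):
        return source
    else:
        raw = source
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def load_vcf(source, *, strict: bool = False,
             compute_derived: bool = True
             ) -> tuple[HeaderMeta, Iterator[VariantDocument]]:
    """Load a VCF from a path or stream; yields documents in file order.

    Returns the parsed header and a generator of documents, so ingestion
    is streaming — memory is per record, not per file. Multi-allelic
    records are loaded as-is but flagged via ``doc.is_multiallelic``.
    """
    handle = _open_text(source)
    header_lines: list[str] = []
    body_start = 0
    first_body: str | None = None
    for ln, line in enumerate(handle, start=1):
        if line.startswith("#"):
            header_lines.append(line)
        else:
            first_body = line
            body_start = ln
            break
    meta = parse_header(header_lines)

    def _records() -> Iterator[VariantDocument]:
        multiallelic_seen = False
        def emit(line: str, ln: int):
            nonlocal multiallelic_seen
            if not line.strip():
                return None
            doc = parse_record(line, meta, strict=strict, line_number=ln)
            if doc.is_multiallelic and not multiallelic_seen:
                multiallelic_seen = True
                logger.warning(
                    "multi-allelic record at line %d; consider normalizing "
                    "to one allele per row", ln)
            if compute_derived:
                doc.compute_derived()
            return doc

        if first_body is not None:
            doc = emit(first_body, body_start)
            if doc is not None:
                yield doc
            for ln, line in enumerate(handle, start=body_start + 1):
                doc = emit(line, ln)
                if doc is not None:
                    yield doc
        handle.close()

    return meta, _records()


def validate_vcf(source) -> ValidationReport:
    """Validate a VCF: header declarations, line structure, key usage.

    Reports (with line numbers and the offending text):

    * malformed header declarations and a missing ``#CHROM`` line (error)
    * body lines with fewer than 8 columns or unparsable core values (error)
    * INFO/FORMAT keys used in the body but undeclared in the header (error)
    * FILTER codes used but undeclared (warning; ``PASS``/``.`` exempt)
    * values unparsable as their declared type (error)
    * non-monotone positions within a chromosome (warning)
    """
    report = ValidationReport()
    try:
        handle = _open_text(source)
    except VCFParseError as exc:
        report.add(0, "error", str(exc))
        return report

    header_lines: list[str] = []
    meta: HeaderMeta | None = None
    last_pos: dict[str, int] = {}
    undeclared_reported: set[str] = set()
    in_header = True
    body_seen = False
    for ln, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if in_header and line.startswith("#"):
            header_lines.append(raw)
            continue
        if in_header:
            in_header = False
            try:
                meta = parse_header(header_lines)
            except VCFParseError as exc:
                report.add(exc.line_number or 0, "error", str(exc),
                           exc.line_text or "")
                handle.close()
                return report
        if not line.strip():
            continue
        body_seen = True
        assert meta is not None
        try:
            doc = parse_record(line, meta, strict=True, line_number=ln)
        except VCFParseError as exc:
            report.add(ln, "error",
                       str(exc).removeprefix(f"line {ln}: "), line)
            continue
        filt = doc.filter_status
        if filt not in (".", "PASS", ""):
            for code in filt.split(";"):
                if code not in meta.filter_ids and \
                        f"FILTER:{code}" not in undeclared_reported:
                    undeclared_reported.add(f"FILTER:{code}")
                    report.add(ln, "warning",
                               f"FILTER code {code!r} is not declared "
                               "in the header", line)
        prev = last_pos.get(doc.chrom)
        if prev is not None and doc.pos < prev:
            report.add(ln, "warning",
                       f"position {doc.pos} on {doc.chrom} is below the "
                       f"previous record's position {prev}", line)
        last_pos[doc.chrom] = max(prev or 0, doc.pos)
    if in_header:
        try:
            parse_header(header_lines)
        except VCFParseError as exc:
            report.add(exc.line_number or 0, "error", str(exc),
                       exc.line_text or "")
    if not body_seen and not header_lines:
        report.add(0, "error", "file contains no VCF content")
    handle.close()
    return report


# ---------------------------------------------------------------------------
# multi-allelic normalization

def _slice_value(value, number: str, k: int, idx: int, field_id: str,
                 line_number=None):
    """Slice one per-alternate/per-allele array for retained alternate idx."""
    if number == "A":
        if not isinstance(value, list) or len(value) != k:
            raise VCFParseError(
                f"field {field_id!r} declared Number=A has "
                f"{len(value) if isinstance(value, list) else 1} values "
                f"for {k} alternate alleles", line_number)
        v = value[idx]
        return [v]
    if number == "R":
        if not isinstance(value, list) or len(value) != k + 1:
            raise VCFParseError(
                f"field {field_id!r} declared Number=R has "
                f"{len(value) if isinstance(value, list) else 1} values "
                f"for {k} alternate alleles", line_number)
        return [value[0], value[idx + 1]]
    return value


def _remap_gt(gt: str, retained: int) -> str:
    """Remap allele indices so the retained alternate is 1.

    Other alternate alleles still count as non-reference (they map to 1 as
    well), preserving carrier status and the count-rule zygosity.
    """
    if gt in (".", ""):
        return gt
    sep = "|" if "|" in gt and "/" not in gt else "/"
    out = []
    for tok in gt.replace("|", "/").split("/"):
        if tok == "." or tok == "0":
            out.append(tok)
        else:
            out.append("1")
    return sep.join(out)


def split_multiallelic(doc: VariantDocument,
                       meta: HeaderMeta | None = None
                       ) -> list[VariantDocument]:
    """Normalize a record with k alternate alleles into k single-alt documents.

    Number=A INFO/FORMAT arrays are sliced to the matching element and
    Number=R arrays to (reference, retained alternate); shared fields are
    copied. AD is re-derived so each output carries the reference depth
    and the retained allele's depth. Genotypes are remapped so the
    retained alternate has index 1; other alternates remain non-reference,
    so every carrier stays a carrier. Number=G (per-genotype) fields are
    dropped with a warning, since their re-indexing is genotype-model
    specific.

    A single-alternate record is returned unchanged as a singleton list.
    """
    meta = meta or doc.meta
    if meta is None:
        raise VCFParseError("split_multiallelic requires header metadata")
    k = len(doc.alts)
    if k == 1:
        return [doc]

    out: list[VariantDocument] = []
    for idx, allele in enumerate(doc.alts):
        info: dict = {}
        for key, value in doc.info.items():
            decl = meta.info_fields.get(key)
            number = decl.number if decl else "."
            if number == "G":
                logger.warning(
                    "dropping Number=G INFO field %r during normalization",
                    key)
                continue
            info[key] = _slice_value(value, number, k, idx, key,
                                     doc.line_number)
        calls: dict[str, SampleCall] = {}
        for sid, call in doc.calls.items():
            new_gt = _remap_gt(call.gt_raw, idx + 1)
            try:
                zyg, alt_count = classify_genotype(new_gt) \
                    if new_gt not in (".", "") else (Zygosity.NO_CALL, 0)
            except Exception:
                zyg, alt_count = Zygosity.NO_CALL, 0
            other: dict = {}
            for fid, value in call.other_format.items():
                decl = meta.format_fields.get(fid)
                number = decl.number if decl else "."
                if fid == "AD":
                    # AD is ref + one depth per alternate
                    if not isinstance(value, list) or len(value) != k + 1:
                        raise VCFParseError(
                            f"AD for sample {sid} has "
                            f"{len(value) if isinstance(value, list) else 1} "
                            f"elements for {k} alternate alleles",
                            doc.line_number)
                    other[fid] = [value[0], value[idx + 1]]
                    continue
                if number == "G":
                    continue
                other[fid] = _slice_value(value, number, k, idx, fid,
                                          doc.line_number)
            new_call = SampleCall(gt_raw=new_gt, zygosity=zyg,
                                  alt_allele_count=alt_count,
                                  other_format=other)
            if "AD" in other:
                ref_d, alt_d = other["AD"]
                new_call.ref_depth = ref_d
                new_call.alt_depth = alt_d
            calls[sid] = new_call
        new_doc = VariantDocument(
            chrom=doc.chrom, pos=doc.pos, id=doc.id, ref=doc.ref,
            alt=allele, qual=doc.qual, filter_status=doc.filter_status,
            info=info, calls=calls, meta=meta, line_number=doc.line_number)
        new_doc.compute_derived()
        out.append(new_doc)
    return out


# ---------------------------------------------------------------------------
# VCF serialization (used by the CLI `normalize` command and fixtures)

def _render_info_value(value) -> str:
    if isinstance(value, bool):
        return ""  # flags are bare keys
    if isinstance(value, list):
        return ",".join("." if v is None else _render_scalar(v)
                        for v in value)
    return _render_scalar(value)


def _render_scalar(v) -> str:
    if isinstance(v, float):
        return repr(v) if v != int(v) else str(int(v))
    return str(v)


def render_vcf(meta: HeaderMeta, docs: Iterable[VariantDocument]) -> str:
    """Serialize header metadata and documents back to VCF text."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [l for l in meta.extra_lines if not l.startswith("##fileformat")]
    for decl in meta.info_fields.values():
        lines.append(
            f'##INFO=<ID={decl.id},Number={decl.number},Type={decl.type},'
            f'Description="{decl.description}">')
    for fid in meta.filter_ids:
        lines.append(f'##FILTER=<ID={fid},Description="">')
    for decl in meta.format_fields.values():
        lines.append(
            f'##FORMAT=<ID={decl.id},Number={decl.number},Type={decl.type},'
            f'Description="{decl.description}">')
    header = "#" + "\t".join(CORE_COLUMNS)
    fmt_ids = list(meta.format_fields)
    if meta.sample_ids:
        header += "\tFORMAT\t" + "\t".join(meta.sample_ids)
    lines.append(header)
    for doc in docs:
        info_parts = []
        for key, value in doc.info.items():
            if isinstance(value, bool):
                if value:
                    info_parts.append(key)
            else:
                info_parts.append(f"{key}={_render_info_value(value)}")
        info_s = ";".join(info_parts) or "."
        row = [doc.chrom, str(doc.pos), doc.id or ".", doc.ref, doc.alt,
               "." if doc.qual is None else _render_scalar(doc.qual),
               doc.filter_status or ".", info_s]
        if meta.sample_ids:
            keys = [f for f in fmt_ids
                    if f == "GT" or any(f in c.other_format
                                        for c in doc.calls.values())]
            if "GT" in fmt_ids and "GT" not in keys:
                keys.insert(0, "GT")
            row.append(":".join(keys))
            for sid in meta.sample_ids:
                call = doc.calls.get(sid, SampleCall())
                parts = []
                for fid in keys:
                    if fid == "GT":
                        parts.append(call.gt_raw or ".")
                    else:
                        v = call.other_format.get(fid)
                        parts.append("." if v is None
                                     else _render_info_value(v))
                row.append(":".join(parts))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
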