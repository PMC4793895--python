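"""In-memory indexed document store.

A :class:`Dataset` holds the parsed variant documents with stable integer
ids (assigned in file order and never renumbered by filtering), a field
catalog typing every observed field path as numeric / flag / string, and
optional per-field indexes. Indexes are a pure acceleration: a query
answered through an index is bit-identical to the linear scan — a property
the test-suite enforces.

The store is deliberately a plain in-memory structure with a versioned
JSON snapshot, rather than a database server: desk-scale reproducibility
with zero deployment burden. The query surface (``query(predicate,
within)``) is narrow enough that a document-database adapter could be
slotted behind it.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

from .errors import UnknownFieldError, VCFSieveError
from .genotypes import SampleCall, Zygosity
from .ingest import FieldDef, HeaderMeta, VariantDocument, load_vcf

__all__ = ["FieldInfo", "Dataset", "SNAPSHOT_VERSION"]

SNAPSHOT_VERSION = 1

#: core columns always present in the catalog, with their kinds
_CORE_KINDS = {
    "CORE.CHROM": "string",
    "CORE.POS": "numeric",
    "CORE.ID": "string",
    "CORE.REF": "string",
    "CORE.ALT": "string",
    "CORE.QUAL": "numeric",
    "CORE.FILTER": "string",
    "DERIVED.sample_count": "numeric",
    "DERIVED.sample_list": "string",
}


@dataclass
class FieldInfo:
    """Catalog entry for one field path.

    ``kind`` drives which filter operators apply. String fields carry
    their observed distinct values and cardinality — the UI convention of
    switching from a checkbox list to type-ahead above 25 distinct values
    is exposed as metadata here, never enforced.
    """

    path: str
    kind: str  # numeric | flag | string
    distinct_values: set = dc_field(default_factory=set)

    @property
    def cardinality(self) -> int:
        return len(self.distinct_values)


def _kind_from_decl(decl: FieldDef) -> str:
    if decl.type == "Flag":
        return "flag"
    if decl.is_numeric:
        return "numeric"
    return "string"


class Dataset:
    """Ordered collection of variant documents with catalog and indexes."""

    def __init__(self, meta: HeaderMeta,
                 docs: Iterable[VariantDocument] = ()):
        self.meta = meta
        self.docs: list[VariantDocument] = list(docs)
        self.indexes: dict[str, dict] = {}
        self.range_annotations: dict[str, object] = {}
        self._catalog: dict[str, FieldInfo] | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_vcf(cls, source, *, strict: bool = False,
                 normalize: bool = False) -> "Dataset":
        """Load a VCF into a dataset, optionally splitting multi-allelics."""
        from .ingest import split_multiallelic
        meta, records = load_vcf(source, strict=strict)
        docs: list[VariantDocument] = []
        for doc in records:
            if normalize and doc.is_multiallelic:
                docs.extend(split_multiallelic(doc, meta))
            else:
                docs.append(doc)
        return cls(meta, docs)

    # -- basic access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.docs)

    def all_ids(self) -> set[int]:
        return set(range(len(self.docs)))

    def doc(self, doc_id: int) -> VariantDocument:
        return self.docs[doc_id]

    def get_value(self, doc_id: int, path: str):
        return self.docs[doc_id].get_field(path)

    # -- field catalog -----------------------------------------------------

    @property
    def field_catalog(self) -> dict[str, FieldInfo]:
        if self._catalog is None:
            self._catalog = self._build_catalog()
        return self._catalog

    def invalidate_catalog(self) -> None:
        """Force a catalog rebuild (after annotators add fields)."""
        self._catalog = None
        self.indexes.clear()

    def _build_catalog(self) -> dict[str, FieldInfo]:
        catalog: dict[str, FieldInfo] = {
            path: FieldInfo(path, kind) for path, kind in _CORE_KINDS.items()
        }
        for fid, decl in self.meta.info_fields.items():
            catalog[f"INFO.{fid}"] = FieldInfo(f"INFO.{fid}",
                                               _kind_from_decl(decl))
        for fid, decl in self.meta.format_fields.items():
            if fid != "GT" and decl.is_numeric:
                for suffix in ("min", "max"):
                    p = f"FORMAT.{fid}.{suffix}"
                    catalog[p] = FieldInfo(p, "numeric")
        for doc in self.docs:
            for path in doc.derived:
                if path not in catalog:
                    kind = "flag" if path.startswith("RANGE.") else "string"
                    catalog[path] = FieldInfo(path, kind)
            for key in doc.info:
                path = f"INFO.{key}"
                if path not in catalog:  # tolerant-mode undeclared field
                    catalog[path] = FieldInfo(path, "string")
        # observed distinct values for string fields
        for path, fi in catalog.items():
            if fi.kind != "string":
                continue
            for doc in self.docs:
                try:
                    v = doc.get_field(path)
                except UnknownFieldError:
                    continue
                if v is None:
                    continue
                if isinstance(v, list):
                    fi.distinct_values.update(str(x) for x in v
                                              if x is not None)
                else:
                    fi.distinct_values.add(str(v))
        return catalog

    def catalog_fields(self) -> dict[str, FieldInfo]:
        """Public alias returning the full field catalog."""
        return self.field_catalog

    def field_kind(self, path: str) -> str:
        fi = self.field_catalog.get(path)
        if fi is None:
            raise UnknownFieldError(path)
        return fi.kind

    # -- indexing ----------------------------------------------------------

    def build_index(self, path: str) -> "Dataset":
        """Build an equality/order index on a field path.

        Queries on the field may then be answered through the index;
        results are identical to the unindexed linear scan.
        """
        if path not in self.field_catalog:
            raise UnknownFieldError(path)
        by_value: dict = {}
        numeric_pairs: list[tuple[float, int]] = []
        missing: set[int] = set()
        kind = self.field_catalog[path].kind
        for doc_id, doc in enumerate(self.docs):
            v = doc.get_field(path)
            if v is None:
                missing.add(doc_id)
                continue
            values = v if isinstance(v, list) else [v]
            present = False
            for x in values:
                if x is None:
                    continue
                present = True
                by_value.setdefault(x if not isinstance(x, bool) else x,
                                    set()).add(doc_id)
                if kind == "numeric" and isinstance(x, (int, float)):
                    numeric_pairs.append((float(x), doc_id))
            if not present:
                missing.add(doc_id)
        numeric_pairs.sort()
        self.indexes[path] = {
            "by_value": by_value,
            "sorted": numeric_pairs,
            "keys": [p[0] for p in numeric_pairs],
            "missing": missing,
        }
        return self

    def _index_numeric_range(self, path: str, op: str, value: float
                             ) -> set[int] | None:
        """Answer a numeric comparison from the index, if one exists."""
        idx = self.indexes.get(path)
        if idx is None:
            return None
        keys: Sequence[float] = idx["keys"]
        pairs: Sequence[tuple[float, int]] = idx["sorted"]
        if op == "<":
            hi = bisect.bisect_left(keys, value)
            sel = pairs[:hi]
        elif op == "<=":
            hi = bisect.bisect_right(keys, value)
            sel = pairs[:hi]
        elif op == ">":
            lo = bisect.bisect_right(keys, value)
            sel = pairs[lo:]
        elif op == ">=":
            lo = bisect.bisect_left(keys, value)
            sel = pairs[lo:]
        else:
            return None
        return {doc_id for _, doc_id in sel}

    # -- querying ----------------------------------------------------------

    def query(self, spec, within: set[int] | None = None) -> set[int]:
        """Ids in ``within`` whose documents satisfy the predicate.

        Delegates the per-document truth test to the filter spec; uses an
        index for numeric order comparisons when available (identical
        results either way).
        """
        from .filters import FilterSpec  # cycle: filters import Dataset type
        if within is None:
            within = self.all_ids()
        if not isinstance(spec, FilterSpec):
            raise VCFSieveError("query requires a FilterSpec predicate")
        spec.validate(self)
        fast = None
        if spec.kind == "numeric" and spec.operator in ("<", "<=", ">", ">=") \
                and spec.missing_policy == "exclude_missing":
            fast = self._index_numeric_range(spec.field, spec.operator,
                                             spec.value)
        if fast is not None:
            return within & fast
        return {doc_id for doc_id in within
                if spec.matches(self.docs[doc_id])}

    # -- snapshots ---------------------------------------------------------

    def save_snapshot(self, path) -> None:
        """Write the dataset as a versioned JSON snapshot."""
        payload = {
            "format": "vcfsieve-snapshot",
            "version": SNAPSHOT_VERSION,
            "meta": _meta_to_json(self.meta),
            "docs": [_doc_to_json(d) for d in self.docs],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_snapshot(cls, path) -> "Dataset":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "vcfsieve-snapshot":
            raise VCFSieveError(f"{path}: not a vcfsieve snapshot")
        if payload.get("version") != SNAPSHOT_VERSION:
            raise VCFSieveError(
                f"{path}: snapshot version {payload.get('version')} "
                f"not supported (expected {SNAPSHOT_VERSION})")
        meta = _meta_from_json(payload["meta"])
        docs = [_doc_from_json(d, meta) for d in payload["docs"]]
        return cls(meta, docs)


# ---------------------------------------------------------------------------
# snapshot (de)serialization helpers

def _meta_to_json(meta: HeaderMeta) -> dict:
    def fdefs(d):
        return [{"id": f.id, "number": f.number, "type": f.type,
                 "description": f.description} for f in d.values()]
    return {"info": fdefs(meta.info_fields),
            "format": fdefs(meta.format_fields),
            "filters": sorted(meta.filter_ids),
            "samples": meta.sample_ids,
            "extra": meta.extra_lines}


def _meta_from_json(j: dict) -> HeaderMeta:
    meta = HeaderMeta()
    for f in j["info"]:
        meta.info_fields[f["id"]] = FieldDef(f["id"], f["number"], f["type"],
                                             f.get("description", ""))
    for f in j["format"]:
        meta.format_fields[f["id"]] = FieldDef(f["id"], f["number"],
                                               f["type"],
                                               f.get("description", ""))
    meta.filter_ids = set(j["filters"])
    meta.sample_ids = list(j["samples"])
    meta.extra_lines = list(j.get("extra", []))
    return meta


def _doc_to_json(doc: VariantDocument) -> dict:
    return {
        "chrom": doc.chrom, "pos": doc.pos, "id": doc.id,
        "ref": doc.ref, "alt": doc.alt, "qual": doc.qual,
        "filter": doc.filter_status, "info": doc.info,
        "derived": doc.derived,
        "calls": {sid: {"gt": c.gt_raw, "zyg": c.zygosity.value,
                        "ac": c.alt_allele_count, "rd": c.ref_depth,
                        "ad": c.alt_depth, "fmt": c.other_format}
                  for sid, c in doc.calls.items()},
    }


def _doc_from_json(j: dict, meta: HeaderMeta) -> VariantDocument:
    calls = {sid: SampleCall(gt_raw=c["gt"], zygosity=Zygosity(c["zyg"]),
                             alt_allele_count=c["ac"], ref_depth=c["rd"],
                             alt_depth=c["ad"], other_format=c["fmt"])
             for sid, c in j["calls"].items()}
    return VariantDocument(chrom=j["chrom"], pos=j["pos"], id=j["id"],
                           ref=j["ref"], alt=j["alt"], qual=j["qual"],
                           filter_status=j["filter"], info=j["info"],
                           calls=calls, derived=j["derived"], meta=meta)
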