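"""Tab-delimited export of surviving variants.

The export mirrors the tabular results view: one row per surviving
variant in original file order, with a chosen, ordered set of columns.
Hidden columns remain fully filterable — visibility is presentation
only. Absent values render as ``.``; array values are comma-joined
(matching VCF syntax); booleans render ``TRUE``/``FALSE``.
"""

from __future__ import annotations

from .errors import UnknownFieldError

__all__ = ["default_columns", "select_columns", "export_table",
           "render_value"]

#: the 8 fixed VCF columns plus the carrier summaries
_DEFAULT = ("CORE.CHROM", "CORE.POS", "CORE.ID", "CORE.REF", "CORE.ALT",
            "CORE.QUAL", "CORE.FILTER", "CORE.INFO",
            "DERIVED.sample_count", "DERIVED.sample_list")


def default_columns(ds=None) -> list[str]:
    """The default visible column set (core 8 + carrier count/list)."""
    return list(_DEFAULT)


def _known(ds, name: str) -> bool:
    return name == "CORE.INFO" or name in ds.field_catalog


def select_columns(ds, show: list[str] | None = None,
                   hide: list[str] | None = None) -> list[str]:
    """Resolve show/hide requests into an ordered visible column list.

    Starts from the default set; ``show`` appends extra catalog fields
    (and re-reveals hidden defaults at their original position); ``hide``
    removes columns from view. Hiding a field never affects filtering.
    """
    show = list(show or [])
    hide = list(hide or [])
    for name in show + hide:
        if not _known(ds, name):
            raise UnknownFieldError(name)
    visible = list(_DEFAULT)
    for name in show:
        if name not in visible:
            visible.append(name)
    hidden = set(hide) - set(show)  # show wins over hide
    return [c for c in visible if c not in hidden]


def render_value(value) -> str:
    """Render one field value for the TSV (``.`` for absent)."""
    if value is None:
        return "."
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, (list, tuple)):
        if not value:
            return "."
        return ",".join(render_value(v) for v in value)
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else repr(value)
    return str(value)


def _render_info_column(doc) -> str:
    parts = []
    for key, value in doc.info.items():
        if isinstance(value, bool):
            if value:
                parts.append(key)
        else:
            parts.append(f"{key}={render_value(value)}")
    return ";".join(parts) or "."


def export_table(ds, survivors, columns: list[str] | None, path) -> int:
    """Write surviving documents as a TSV; returns rows written.

    Rows appear in original file (document-id) order. ``columns=None``
    uses the default set. Raises on an unknown column name.
    """
    columns = list(columns) if columns else default_columns(ds)
    if not columns:
        raise UnknownFieldError("(empty column list)")
    for name in columns:
        if not _known(ds, name):
            raise UnknownFieldError(name)
    rows = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for doc_id in sorted(survivors):
            doc = ds.docs[doc_id]
            cells = []
            for name in columns:
                if name == "CORE.INFO":
                    cells.append(_render_info_column(doc))
                else:
                    cells.append(render_value(doc.get_field(name)))
            fh.write("\t".join(cells) + "\n")
            rows += 1
    return rows
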