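"""Reading and writing gapped alignments and feature tables.

Alignments travel in a small gapped multi-FASTA dialect:

* pairwise files hold exactly two records, query first, template second;
  the template header may carry an ``EVALUE=<float>`` token;
* multi-template files hold the target first and then the templates in
  significance rank order (first = most significant) — the file order is
  preserved exactly because it encodes the rank-precedence rule used by
  the multi-template features;
* the only gap character is ``-`` (a ``.`` is rejected to avoid silent
  dialect drift), and a column gapped in every row is rejected at parse
  time because no feature can observe it.

Column indices are 0-based internally; residue positions shown to users
are 1-based.  Feature tables are TSV with columns ``id``, the schema's
feature names, and an optional ``gdtts`` label column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

GAP = "-"

__all__ = [
    "AlignmentFormatError",
    "PairwiseAlignment",
    "MultiAlignment",
    "read_pairwise_alignment",
    "read_multi_alignment",
    "write_feature_table",
    "read_feature_table",
]


class AlignmentFormatError(ValueError):
    """Raised on any violation of the gapped multi-FASTA dialect."""


def _check_row(row: str, name: str, path) -> None:
    if "." in row:
        raise AlignmentFormatError(f"{path}: '.' gap characters are not accepted ({name})")
    if not row.replace(GAP, ""):
        raise AlignmentFormatError(f"{path}: {name} row is empty after gap removal")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped query/template pair with optional alignment e-value."""

    query_id: str
    template_id: str
    query_row: str
    template_row: str
    evalue: float | None = None

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.template_row):
            raise AlignmentFormatError(
                f"rows have unequal lengths ({len(self.query_row)} vs {len(self.template_row)})"
            )
        for q, t in zip(self.query_row, self.template_row):
            if q == GAP and t == GAP:
                raise AlignmentFormatError("column gapped in both rows")
        if not self.query_row.replace(GAP, ""):
            raise AlignmentFormatError("query row is empty after gap removal")
        if self.evalue is not None and self.evalue <= 0:
            raise AlignmentFormatError(f"e-value must be positive, got {self.evalue}")


@dataclass(frozen=True)
class MultiAlignment:
    """A gapped target aligned with one or more templates in rank order."""

    target_id: str
    target_row: str
    templates: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.templates:
            raise AlignmentFormatError("at least one template is required")
        width = len(self.target_row)
        for tid, row in self.templates:
            if len(row) != width:
                raise AlignmentFormatError(
                    f"template {tid} row length {len(row)} != target row length {width}"
                )
        if not self.target_row.replace(GAP, ""):
            raise AlignmentFormatError("target row is empty after gap removal")
        for col in range(width):
            if self.target_row[col] == GAP and all(row[col] == GAP for _, row in self.templates):
                raise AlignmentFormatError(f"column {col + 1} gapped in every row")


def _parse_evalue(description: str, path) -> float | None:
    for token in description.split():
        if token.startswith("EVALUE="):
            try:
                return float(token[len("EVALUE="):])
            except ValueError as exc:
                raise AlignmentFormatError(f"{path}: non-parsable {token!r}") from exc
    return None


def read_pairwise_alignment(path: str | Path) -> PairwiseAlignment:
    """Read a two-record gapped FASTA file, query first.

    The template's e-value, if present, is taken from an ``EVALUE=<float>``
    token in its FASTA header.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise AlignmentFormatError(
            f"{path}: pairwise alignment needs exactly 2 records, found {len(records)}"
        )
    query, template = records
    q_row, t_row = str(query.seq).upper(), str(template.seq).upper()
    _check_row(q_row, "query", path)
    _check_row(t_row, "template", path)
    if len(q_row) != len(t_row):
        raise AlignmentFormatError(
            f"{path}: rows have unequal lengths ({len(q_row)} vs {len(t_row)})"
        )
    try:
        return PairwiseAlignment(
            query_id=query.id,
            template_id=template.id,
            query_row=q_row,
            template_row=t_row,
            evalue=_parse_evalue(template.description, path),
        )
    except AlignmentFormatError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from None


def read_multi_alignment(path: str | Path) -> MultiAlignment:
    """Read a target-plus-templates gapped FASTA file; file order is rank order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentFormatError(
            f"{path}: multi-template alignment needs >=2 records, found {len(records)}"
        )
    target, templates = records[0], records[1:]
    t_row = str(target.seq).upper()
    _check_row(t_row, "target", path)
    rows = []
    for rec in templates:
        row = str(rec.seq).upper()
        _check_row(row, f"template {rec.id}", path)
        rows.append((rec.id, row))
    try:
        return MultiAlignment(target_id=target.id, target_row=t_row, templates=tuple(rows))
    except AlignmentFormatError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from None


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def write_feature_table(
    records: list[tuple[str, "object", float | None]],
    path: str | Path,
) -> None:
    """Write ``(id, feature vector, optional gdtts label)`` records as TSV.

    All feature vectors must share one schema; the label column is emitted
    only when at least one record carries a label (records without one get
    an empty cell).  Round-trips losslessly with :func:`read_feature_table`.
    """
    path = Path(path)
    schemas = {vec.schema for _, vec, _ in records}
    if len(schemas) > 1:
        raise ValueError(f"mixed feature schemas in one table: {sorted(schemas)}")
    names = list(records[0][1].feature_names) if records else []
    has_label = any(label is not None for _, _, label in records)
    header = ["id", *names] + (["gdtts"] if has_label else [])
    lines = ["\t".join(header)]
    for rec_id, vec, label in records:
        cells = [rec_id] + [repr(float(v)) for v in vec.as_array()]
        if has_label:
            cells.append("" if label is None else repr(float(label)))
        lines.append("\t".join(cells))
    _atomic_write(path, "\n".join(lines) + "\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV feature table into a DataFrame indexed by ``id``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: feature table lacks an 'id' column")
    return df
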