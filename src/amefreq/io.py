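"""Reading and writing the tab-separated table formats.

Variant tables are plain TSV with one header row, lowercase snake-case
column names and per-ancestry allele-count columns prefixed ``ac_`` (the
layout of a gnomAD browser export flattened to counts).  Missing optional
cells are empty strings; a zero is always a real value, never a missing
marker.

Ancestry panels are two-column TSV (``group``, ``n_individuals``) with an
optional ``excluded`` marker column.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .hgvs import infer_consequence
from .schema import (
    AncestryPanel,
    AnnotationScores,
    ClinvarClass,
    Consequence,
    VariantRecord,
)

PathLike = Union[str, Path]


class VariantTableError(Exception):
    """Base class for table-format failures."""

    #: short machine-readable code emitted by the CLI
    code = "table_error"


class SchemaError(VariantTableError):
    """The table header does not match the expected schema."""

    code = "schema_error"


class TableValidationError(VariantTableError):
    """One or more data rows violate the schema or an invariant."""

    code = "validation_error"


MANDATORY_COLUMNS = (
    "gene",
    "protein_change",
    "cdna_change",
    "clinvar_class",
    "literature_reported",
    "allele_count_total",
)
SCORE_COLUMNS = ("cadd", "sift", "polyphen2", "revel", "spliceai", "pangolin")
OPTIONAL_COLUMNS = (
    "consequence",
    "clinvar_variation_id",
    "rsid",
    *SCORE_COLUMNS,
    "sift_indel_damaging",
)

_CLINVAR_ALIASES = {c.value.lower(): c for c in ClinvarClass}
_CLINVAR_ALIASES.update(
    {
        "p/lp": ClinvarClass.P_LP,
        "b/lb": ClinvarClass.B_LB,
        "pathogenic": ClinvarClass.P,
        "likely pathogenic": ClinvarClass.LP,
        "benign": ClinvarClass.B,
        "likely benign": ClinvarClass.LB,
        "conflicting classifications": ClinvarClass.CONFLICTING,
        "uncertain significance": ClinvarClass.VUS,
        "": ClinvarClass.NOT_REPORTED,
        "-": ClinvarClass.NOT_REPORTED,
    }
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(cell: str, column: str, row: int) -> bool:
    v = cell.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise TableValidationError(f"row {row}: column {column!r}: not a boolean: {cell!r}")


def _parse_int(cell: str, column: str, row: int) -> int:
    try:
        return int(cell.strip().replace(",", ""))
    except ValueError:
        raise TableValidationError(
            f"row {row}: column {column!r}: not an integer: {cell!r}"
        ) from None


def _parse_optional_float(cell: str, column: str, row: int) -> Optional[float]:
    v = cell.strip()
    if v == "":
        return None
    try:
        return float(v)
    except ValueError:
        raise TableValidationError(
            f"row {row}: column {column!r}: not a number: {cell!r}"
        ) from None


def read_variant_table(
    path: PathLike, panel: Optional[AncestryPanel] = None
) -> list[VariantRecord]:
    """Read a TSV variant table into validated :class:`VariantRecord` rows.

    Parameters
    ----------
    path
        TSV file with the schema header.  A ``consequence`` column is
        optional; when absent the class is inferred from the HGVS strings.
    panel
        When given, ``ac_<group>`` columns must be a subset of the panel's
        groups and each count is checked against 2N for its group.

    Raises
    ------
    SchemaError
        A mandatory column is missing, or an ``ac_`` column names a group
        not in the panel.
    TableValidationError
        A data cell is malformed or violates an invariant; the message
        lists every offending row by number (header = row 1).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        ac_columns = [c for c in header if c.startswith("ac_")]
        if panel is not None:
            unknown = [c for c in ac_columns if c[3:] not in panel.groups]
            if unknown:
                raise SchemaError(
                    f"ancestry column(s) not in panel: {', '.join(unknown)}"
                )
        rows = list(reader)

    records: list[VariantRecord] = []
    errors: list[str] = []
    for i, row in enumerate(rows, start=2):  # header is row 1
        try:
            records.append(_parse_row(row, i, ac_columns))
        except (TableValidationError, ValueError) as exc:
            errors.append(str(exc) if str(exc).startswith("row ") else f"row {i}: {exc}")
    if panel is not None:
        for rec in records:
            try:
                rec.validate_against_panel(panel)
            except ValueError as exc:
                errors.append(str(exc))
    if errors:
        raise TableValidationError("; ".join(errors))
    return records


def _parse_row(row: dict, i: int, ac_columns: Sequence[str]) -> VariantRecord:
    def cell(name: str) -> str:
        return (row.get(name) or "").strip()

    protein = cell("protein_change") or None
    cdna = cell("cdna_change") or None

    consequence_cell = cell("consequence")
    if consequence_cell:
        try:
            consequence = Consequence(consequence_cell.lower())
        except ValueError:
            raise TableValidationError(
                f"row {i}: column 'consequence': unknown value {consequence_cell!r}"
            ) from None
    else:
        consequence = infer_consequence(protein, cdna)

    clinvar_cell = cell("clinvar_class").lower()
    if clinvar_cell not in _CLINVAR_ALIASES:
        raise TableValidationError(
            f"row {i}: column 'clinvar_class': unknown value {row.get('clinvar_class')!r}"
        )

    varid_cell = cell("clinvar_variation_id")
    varid = _parse_int(varid_cell, "clinvar_variation_id", i) if varid_cell else None

    scores = AnnotationScores(
        cadd=_parse_optional_float(cell("cadd"), "cadd", i),
        sift=_parse_optional_float(cell("sift"), "sift", i),
        polyphen2=_parse_optional_float(cell("polyphen2"), "polyphen2", i),
        revel=_parse_optional_float(cell("revel"), "revel", i),
        spliceai=_parse_optional_float(cell("spliceai"), "spliceai", i),
        pangolin=_parse_optional_float(cell("pangolin"), "pangolin", i),
        sift_indel_damaging=(
            _parse_bool(cell("sift_indel_damaging"), "sift_indel_damaging", i)
            if cell("sift_indel_damaging")
            else None
        ),
    )

    by_group = {
        c[3:]: _parse_int(cell(c), c, i) for c in ac_columns if cell(c) != ""
    }

    return VariantRecord(
        gene=cell("gene"),
        protein_change=protein,
        cdna_change=cdna,
        consequence=consequence,
        clinvar_class=_CLINVAR_ALIASES[clinvar_cell],
        clinvar_variation_id=varid,
        rsid=cell("rsid") or None,
        literature_reported=_parse_bool(cell("literature_reported"), "literature_reported", i),
        allele_count_total=_parse_int(cell("allele_count_total"), "allele_count_total", i),
        allele_counts_by_group=by_group,
        scores=scores,
    )


def _fmt_float(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))


def write_variant_table(
    records: Iterable[VariantRecord],
    path: PathLike,
    panel: Optional[AncestryPanel] = None,
) -> None:
    """Write records as TSV; reading the file back reproduces them exactly.

    Group columns follow panel order when a panel is given, else the sorted
    union of groups present in the records.
    """
    records = list(records)
    if panel is not None:
        groups = list(panel.groups)
    else:
        groups = sorted({g for r in records for g in r.allele_counts_by_group})
    columns = [*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS, *(f"ac_{g}" for g in groups)]

    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            s = r.scores
            row = [
                r.gene,
                r.protein_change or "",
                r.cdna_change or "",
                r.clinvar_class.value,
                "true" if r.literature_reported else "false",
                str(r.allele_count_total),
                r.consequence.value,
                "" if r.clinvar_variation_id is None else str(r.clinvar_variation_id),
                r.rsid or "",
                _fmt_float(s.cadd),
                _fmt_float(s.sift),
                _fmt_float(s.polyphen2),
                _fmt_float(s.revel),
                _fmt_float(s.spliceai),
                _fmt_float(s.pangolin),
                (
                    ""
                    if s.sift_indel_damaging is None
                    else ("true" if s.sift_indel_damaging else "false")
                ),
            ]
            row += [
                (
                    str(r.allele_counts_by_group[g])
                    if g in r.allele_counts_by_group
                    else ""
                )
                for g in groups
            ]
            writer.writerow(row)


def read_panel(path: PathLike) -> AncestryPanel:
    """Read an ancestry panel TSV (``group``, ``n_individuals``, optional
    ``excluded``)."""
    path = Path(path)
    groups: dict[str, int] = {}
    excluded: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("group", "n_individuals"):
            if col not in header:
                raise SchemaError(f"panel file missing column {col!r}")
        for i, row in enumerate(reader, start=2):
            g = (row["group"] or "").strip()
            groups[g] = _parse_int(row["n_individuals"] or "", "n_individuals", i)
            if "excluded" in header and _parse_bool(row.get("excluded") or "", "excluded", i):
                excluded.add(g)
    return AncestryPanel(groups=groups, excluded_groups=frozenset(excluded))


def write_panel(panel: AncestryPanel, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group", "n_individuals", "excluded"])
        for g, n in panel.groups.items():
            writer.writerow([g, n, "true" if g in panel.excluded_groups else "false"])
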