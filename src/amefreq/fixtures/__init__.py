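"""Packaged reference data.

Three small TSVs ship with the package:

``panel``
    The ten gnomAD v4.1 genetic-ancestry groups with their sample sizes
    (total 807,162 individuals); the Amish group is marked excluded from
    stratified analyses because of its size (n = 456).
``table1``
    The 32 curated HSD11B2 variants reported in ClinVar or in the AME
    literature, with overall allele counts — loadable directly as
    :class:`~amefreq.schema.VariantRecord` rows.
``table2``
    The published list of ancestry-enriched HSD11B2 variants with
    within-group allele counts and the printed within-group carrier
    frequencies (per 100,000), kept as a DataFrame for cross-checks.
    ``clinvar_or_literature`` marks rows backed by ClinVar or the
    literature (the strict evidence tier); the remaining rows qualified
    through in-silico prediction only.

Files are checksummed on load so a silently corrupted installation fails
loudly rather than producing wrong frequencies.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from ..io import read_panel, read_variant_table
from ..schema import AncestryPanel, ClinvarClass, Consequence, VariantRecord

_CHECKSUMS = {
    "panel.tsv": "d9a9de29afcc779a2a1f7683dd618104beeaa4d4cb19f297ad73a52fbeeb1531",
    "table1.tsv": "e6e3e92dbe530b57423d71f54ec7bf93b12d9e5e55a9e9b5ef83da0f3533d40a",
    "table2.tsv": "70cb4dea86225b4ce1492f11b26446d328e45c703ace9f9108f5c7dde55e6dfa",
}


def fixture_path(filename: str) -> Path:
    """Return the on-disk path of a packaged fixture, after verifying its
    checksum."""
    if filename not in _CHECKSUMS:
        raise ValueError(f"unknown fixture file {filename!r}")
    path = Path(resources.files(__package__) / filename)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise RuntimeError(
            f"fixture {filename} is corrupted (sha256 {digest}, "
            f"expected {_CHECKSUMS[filename]})"
        )
    return path


def load_fixture(name: str) -> Union[list[VariantRecord], pd.DataFrame, AncestryPanel]:
    """Load a packaged fixture by name: ``table1``, ``table2`` or ``panel``."""
    if name == "panel":
        return read_panel(fixture_path("panel.tsv"))
    if name == "table1":
        panel = read_panel(fixture_path("panel.tsv"))
        return read_variant_table(fixture_path("table1.tsv"), panel=panel)
    if name == "table2":
        return pd.read_csv(
            fixture_path("table2.tsv"),
            sep="\t",
            dtype={
                "group": str,
                "protein_change": str,
                "cdna_change": str,
                "consequence": str,
                "rsid": str,
                "clinvar_or_literature": bool,
                "allele_count_in_group": int,
                "cf_per_1e5_printed": float,
            },
        )
    raise ValueError(f"unknown fixture {name!r}; expected table1, table2 or panel")


def table2_records() -> list[VariantRecord]:
    """Convert the ``table2`` fixture into variant records with per-group
    allele counts.

    The published table reports within-group counts only, so each record's
    total allele count equals its within-group count.  Rows flagged
    ``clinvar_or_literature`` are encoded as literature-reported, which
    places exactly those rows in the strict tier; the in-silico-only rows
    carry no scores here (their predictor values are not reprinted), so
    the converted table supports strict-tier estimation and per-variant
    frequency checks, not liberal-tier membership.
    """
    frame = load_fixture("table2")
    records = []
    for row in frame.itertuples(index=False):
        protein = row.protein_change if isinstance(row.protein_change, str) else None
        records.append(
            VariantRecord(
                gene="HSD11B2",
                protein_change=protein or None,
                cdna_change=row.cdna_change,
                consequence=Consequence(row.consequence),
                clinvar_class=ClinvarClass.NOT_REPORTED,
                clinvar_variation_id=None,
                rsid=row.rsid if isinstance(row.rsid, str) else None,
                literature_reported=bool(row.clinvar_or_literature),
                allele_count_total=int(row.allele_count_in_group),
                allele_counts_by_group={row.group: int(row.allele_count_in_group)},
            )
        )
    return records
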