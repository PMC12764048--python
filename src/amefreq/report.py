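"""Numeric summaries for reporting (score-by-class distributions)."""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import BLB_CLASSES, PLP_CLASSES, ClinvarClass, VariantRecord

_SUMMARY_COLUMNS = ["class", "n", "mean", "q25", "median", "q75"]


def score_summary(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-class CADD summary (n, mean, quartiles).

    Classes are the reporting strata used for curated variant tables:
    ClinVar B/LB, VUS, conflicting, P/LP, not reported, plus an
    overlapping ``literature`` stratum for literature-reported variants.
    Variants without a CADD score are left out of every stratum; if no
    variant has a CADD score at all, an empty frame is returned with a
    warning.
    """
    strata: dict[str, list[float]] = {
        "B/LB": [],
        "VUS": [],
        "conflicting": [],
        "P/LP": [],
        "not_reported": [],
        "literature": [],
    }
    any_cadd = False
    for v in variants:
        cadd = v.scores.cadd
        if cadd is None:
            continue
        any_cadd = True
        if v.clinvar_class in BLB_CLASSES:
            strata["B/LB"].append(cadd)
        elif v.clinvar_class is ClinvarClass.VUS:
            strata["VUS"].append(cadd)
        elif v.clinvar_class is ClinvarClass.CONFLICTING:
            strata["conflicting"].append(cadd)
        elif v.clinvar_class in PLP_CLASSES:
            strata["P/LP"].append(cadd)
        else:
            strata["not_reported"].append(cadd)
        if v.literature_reported:
            strata["literature"].append(cadd)

    if not any_cadd:
        warnings.warn("no CADD scores present; score summary is empty")
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)

    rows = []
    for name, values in strata.items():
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        rows.append(
            {
                "class": name,
                "n": len(arr),
                "mean": float(arr.mean()),
                "q25": float(np.quantile(arr, 0.25)),
                "median": float(np.quantile(arr, 0.5)),
                "q75": float(np.quantile(arr, 0.75)),
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
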