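"""Three-arm variant qualification.

A variant qualifies as potentially disease-causing through any of three
evidence arms:

1. **ClinVar** — classified pathogenic or likely pathogenic (P/LP);
2. **literature** — reported in a patient in the curated literature
   (benign/likely-benign ClinVar calls veto this arm; VUS do not);
3. **in silico** — consequence-dependent predictor thresholds: nonsense
   and frameshift variants qualify unconditionally; in-frame indels need
   CADD > 20 and a damaging SIFT-indel verdict; splice-site variants need
   SpliceAI >= 0.8, CADD > 20 and |Pangolin| > 0.2; missense variants need
   CADD > 20, SIFT < 0.05, PolyPhen2 > 0.85 and REVEL > 0.75.  A missing
   required score fails the rule (no imputation).

Arms 1–2 define the **strict** tier (higher confidence); adding arm 3
gives the **liberal** tier.  By default, ClinVar benign/likely-benign
variants are excluded from every arm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

import pandas as pd

from .schema import (
    BLB_CLASSES,
    PLP_CLASSES,
    Consequence,
    QualificationConfig,
    VariantRecord,
)


class Tier(str, enum.Enum):
    STRICT = "strict"
    LIBERAL_ONLY = "liberal_only"
    NONE = "none"


@dataclass(frozen=True)
class QualificationResult:
    """Per-variant evidence flags and the resulting tier."""

    variant_id: str
    clinvar_plp: bool
    literature: bool
    in_silico: bool
    excluded_blb: bool
    tier: Tier


def clinvar_arm(v: VariantRecord) -> bool:
    """True iff the ClinVar classification is P, LP or P/LP."""
    return v.clinvar_class in PLP_CLASSES


def literature_arm(v: VariantRecord) -> bool:
    """True iff literature-reported and not ClinVar benign/likely benign.

    Uncertain-significance and conflicting classifications do not veto a
    literature report; only B/LB do.
    """
    return v.literature_reported and v.clinvar_class not in BLB_CLASSES


def in_silico_arm(v: VariantRecord, cfg: Optional[QualificationConfig] = None) -> bool:
    """Apply the consequence-specific predictor thresholds.

    Missing scores make the rule fail quietly — a variant is never
    qualified on evidence it does not have.
    """
    cfg = cfg or QualificationConfig()
    s = v.scores
    c = v.consequence
    if c in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
        return True
    if c is Consequence.INFRAME_INDEL:
        return (
            s.cadd is not None
            and s.cadd > cfg.cadd_min
            and s.sift_indel_damaging is True
        )
    if c is Consequence.SPLICE_SITE:
        return (
            s.spliceai is not None
            and s.spliceai >= cfg.spliceai_min
            and s.cadd is not None
            and s.cadd > cfg.cadd_min
            and s.pangolin is not None
            and abs(s.pangolin) > cfg.pangolin_abs_min
        )
    if c is Consequence.MISSENSE:
        return (
            s.cadd is not None
            and s.cadd > cfg.cadd_min
            and s.sift is not None
            and s.sift < cfg.sift_max
            and s.polyphen2 is not None
            and s.polyphen2 > cfg.polyphen2_min
            and s.revel is not None
            and s.revel > cfg.revel_min
        )
    return False


def assign_tier(v: VariantRecord, cfg: Optional[QualificationConfig] = None) -> QualificationResult:
    """Combine the three arms into a tier assignment.

    ``strict`` = ClinVar P/LP or literature; ``liberal_only`` = in-silico
    evidence only; B/LB exclusion (when configured) dominates everything.
    """
    cfg = cfg or QualificationConfig()
    excluded = cfg.exclude_blb and v.clinvar_class in BLB_CLASSES
    plp = clinvar_arm(v)
    lit = literature_arm(v)
    insil = in_silico_arm(v, cfg)
    if excluded:
        tier = Tier.NONE
    elif plp or lit:
        tier = Tier.STRICT
    elif insil:
        tier = Tier.LIBERAL_ONLY
    else:
        tier = Tier.NONE
    return QualificationResult(
        variant_id=v.variant_id,
        clinvar_plp=plp,
        literature=lit,
        in_silico=insil,
        excluded_blb=excluded,
        tier=tier,
    )


def qualify_variants(
    variants: Iterable[VariantRecord], cfg: Optional[QualificationConfig] = None
) -> list[QualificationResult]:
    cfg = cfg or QualificationConfig()
    return [assign_tier(v, cfg) for v in variants]


def qualification_summary(results: Iterable[QualificationResult]) -> dict[str, int]:
    """Arm counts (non-exclusive), tier counts (exclusive) and the overall
    number of qualifying variants."""
    results = list(results)
    return {
        "n_variants": len(results),
        "clinvar_plp": sum(r.clinvar_plp for r in results),
        "literature": sum(r.literature for r in results),
        "in_silico": sum(r.in_silico for r in results),
        "excluded_blb": sum(r.excluded_blb for r in results),
        "strict": sum(r.tier is Tier.STRICT for r in results),
        "liberal_only": sum(r.tier is Tier.LIBERAL_ONLY for r in results),
        "none": sum(r.tier is Tier.NONE for r in results),
        "qualifying": sum(r.tier is not Tier.NONE for r in results),
    }


def tier_subset(
    variants: Sequence[VariantRecord],
    results: Sequence[QualificationResult],
    tier: Literal["strict", "liberal"],
) -> list[VariantRecord]:
    """Variants belonging to a reporting tier.

    ``strict`` returns the strict set; ``liberal`` the strict set plus the
    in-silico-only set (so strict ⊆ liberal by construction).
    """
    if tier == "strict":
        keep = {Tier.STRICT}
    elif tier == "liberal":
        keep = {Tier.STRICT, Tier.LIBERAL_ONLY}
    else:
        raise ValueError(f"tier must be 'strict' or 'liberal', got {tier!r}")
    if len(variants) != len(results):
        raise ValueError("variants and results differ in length")
    return [v for v, r in zip(variants, results) if r.tier in keep]


def results_frame(results: Iterable[QualificationResult]) -> pd.DataFrame:
    """Qualification results as a tidy DataFrame (one row per variant)."""
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "clinvar_plp": r.clinvar_plp,
                "literature": r.literature,
                "in_silico": r.in_silico,
                "excluded_blb": r.excluded_blb,
                "tier": r.tier.value,
            }
            for r in results
        ],
        columns=[
            "variant_id",
            "clinvar_plp",
            "literature",
            "in_silico",
            "excluded_blb",
            "tier",
        ],
    )


class VariantQualifier(TransformerMixin, BaseEstimator):
    """Scikit-learn-style transformer wrapping the three-arm qualification.

    Parameters mirror :class:`~amefreq.schema.QualificationConfig`, so the
    thresholds are tunable through ``set_params`` / grid search like any
    estimator hyper-parameter.  ``transform`` maps a sequence of
    :class:`~amefreq.schema.VariantRecord` to the tidy results DataFrame.
    """

    def __init__(
        self,
        cadd_min: float = 20.0,
        sift_max: float = 0.05,
        polyphen2_min: float = 0.85,
        revel_min: float = 0.75,
        spliceai_min: float = 0.8,
        pangolin_abs_min: float = 0.2,
        exclude_blb: bool = True,
    ):
        self.cadd_min = cadd_min
        self.sift_max = sift_max
        self.polyphen2_min = polyphen2_min
        self.revel_min = revel_min
        self.spliceai_min = spliceai_min
        self.pangolin_abs_min = pangolin_abs_min
        self.exclude_blb = exclude_blb

    def _config(self) -> QualificationConfig:
        return QualificationConfig(
            cadd_min=self.cadd_min,
            sift_max=self.sift_max,
            polyphen2_min=self.polyphen2_min,
            revel_min=self.revel_min,
            spliceai_min=self.spliceai_min,
            pangolin_abs_min=self.pangolin_abs_min,
            exclude_blb=self.exclude_blb,
        )

    def fit(self, X: Sequence[VariantRecord], y=None) -> "VariantQualifier":
        self.config_ = self._config()  # validates thresholds
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[VariantRecord]) -> pd.DataFrame:
        cfg = getattr(self, "config_", None) or self._config()
        return results_frame(qualify_variants(X, cfg))
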