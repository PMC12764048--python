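"""Carrier frequency, Hardy–Weinberg prevalence and ancestry enrichment.

Carrier frequency is operationalized as the combined allele count of
qualifying variants divided by the number of sequenced individuals
(alleles per individual, AC/N) — for rare variants this is, to first
order, the proportion of carriers.  Its standard error is the binomial
``sqrt(p(1-p)/N)``.

Disease prevalence under Hardy–Weinberg (random mating, no selection)
follows from the carrier frequency.  Two conventions are implemented:

``cf_squared`` (default)
    prevalence = p², with delta-method SE = 2·p·SE(p).  This is the
    convention that reproduces the published headline prevalence values
    and is therefore the default.
``half_cf_squared``
    prevalence = (p/2)², with delta-method SE = (p/2)·SE(p) — the
    textbook Hardy–Weinberg biallelic genotype frequency q² when the
    allele frequency is taken as q = p/2.  Exactly one quarter of the
    default; both are reported with the convention named so the choice
    is always explicit.

Reports print carrier frequencies per 100,000 individuals and
prevalences per 10,000,000, rounded to one decimal with ties away from
zero; raw proportions are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import math

import pandas as pd
from sklearn.base import BaseEstimator

from .qualify import (
    QualificationConfig,
    QualificationResult,
    qualify_variants,
    tier_subset,
)
from .schema import AncestryPanel, VariantRecord

Convention = Literal["cf_squared", "half_cf_squared"]
CONVENTIONS = ("cf_squared", "half_cf_squared")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (131.97 -> 132.0, 0.25 -> 0.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def combined_allele_count(variants: Iterable[VariantRecord]) -> int:
    return sum(v.allele_count_total for v in variants)


def proportion_se(p: float, n: int) -> float:
    """Binomial standard error of a sample proportion."""
    return math.sqrt(p * (1.0 - p) / n)


def carrier_frequency(
    variants: Iterable[VariantRecord], n_individuals: int
) -> tuple[float, float]:
    """Combined carrier frequency (alleles per individual) and its SE.

    Returns the raw proportion; scale by 1e5 and round for reporting.
    """
    if n_individuals <= 0:
        raise ValueError(f"n_individuals must be positive, got {n_individuals}")
    ac = combined_allele_count(variants)
    p = ac / n_individuals
    return p, proportion_se(p, n_individuals)


def prevalence_from_cf(
    p: float, se_p: float, convention: Convention = "cf_squared"
) -> tuple[float, float]:
    """Hardy–Weinberg prevalence and delta-method SE from a carrier
    frequency proportion.

    ``cf_squared``: prevalence = p², SE = 2p·SE(p).
    ``half_cf_squared``: prevalence = (p/2)², SE = (p/2)·SE(p).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"carrier frequency proportion must be in [0, 1], got {p}")
    if convention == "cf_squared":
        return p * p, 2.0 * p * se_p
    if convention == "half_cf_squared":
        return (p / 2.0) ** 2, (p / 2.0) * se_p
    raise ValueError(f"unknown convention {convention!r}")


def per_variant_group_cf(allele_count_in_group: int, n_group: int) -> float:
    """Within-group carrier frequency per 100,000, rounded to 1 decimal.

    Defined as allele count divided by the number of individuals in the
    group.
    """
    if n_group <= 0:
        raise ValueError(f"n_group must be positive, got {n_group}")
    if not (0 <= allele_count_in_group <= 2 * n_group):
        raise ValueError(
            f"allele count {allele_count_in_group} outside [0, 2N] for N={n_group}"
        )
    return round_half_away(allele_count_in_group / n_group * 1e5, 1)


@dataclass(frozen=True)
class FrequencyEstimate:
    """Carrier frequency and prevalence for one scope (global or group)
    and tier."""

    scope: str
    tier: str
    combined_allele_count: int
    n_individuals: int
    carrier_frequency: float
    carrier_frequency_se: float
    prevalence: float
    prevalence_se: float
    convention: str

    @property
    def cf_per_1e5(self) -> float:
        return round_half_away(self.carrier_frequency * 1e5, 1)

    @property
    def cf_se_per_1e5(self) -> float:
        return round_half_away(self.carrier_frequency_se * 1e5, 1)

    @property
    def prevalence_per_1e7(self) -> float:
        return round_half_away(self.prevalence * 1e7, 1)

    @property
    def prevalence_se_per_1e7(self) -> float:
        return round_half_away(self.prevalence_se * 1e7, 1)


def make_estimate(
    scope: str,
    tier: str,
    allele_count: int,
    n_individuals: int,
    convention: Convention = "cf_squared",
) -> FrequencyEstimate:
    """Build a :class:`FrequencyEstimate` from a combined allele count."""
    if n_individuals <= 0:
        raise ValueError(f"n_individuals must be positive, got {n_individuals}")
    p = allele_count / n_individuals
    if p > 1.0:
        raise ValueError(
            f"{scope}: carrier frequency {p:.3g} exceeds 1 allele per individual; "
            "outside the rare-disease regime this estimator is defined for"
        )
    se = proportion_se(p, n_individuals)
    prev, prev_se = prevalence_from_cf(p, se, convention)
    return FrequencyEstimate(
        scope=scope,
        tier=tier,
        combined_allele_count=allele_count,
        n_individuals=n_individuals,
        carrier_frequency=p,
        carrier_frequency_se=se,
        prevalence=prev,
        prevalence_se=prev_se,
        convention=convention,
    )


def stratified_estimates(
    variants: Sequence[VariantRecord],
    results: Sequence[QualificationResult],
    panel: AncestryPanel,
    tier: Literal["strict", "liberal"],
    convention: Convention = "cf_squared",
) -> list[FrequencyEstimate]:
    """Global plus per-ancestry-group estimates for one tier.

    The global estimate uses each variant's overall allele count and the
    panel's total N (all groups, excluded ones included); group estimates
    use that group's allele counts and N only, for every non-excluded
    group.  Variants carrying counts for groups absent from the panel are
    rejected.
    """
    subset = tier_subset(variants, results, tier)
    for v in subset:
        unknown = set(v.allele_counts_by_group) - set(panel.groups)
        if unknown:
            raise ValueError(
                f"{v.variant_id}: ancestry group(s) {sorted(unknown)} not in panel"
            )
    out = [
        make_estimate(
            "global", tier, combined_allele_count(subset), panel.total_n, convention
        )
    ]
    for g in panel.included_groups:
        ac = sum(v.allele_count_in(g) for v in subset)
        out.append(make_estimate(g, tier, ac, panel.groups[g], convention))
    return out


def estimates_frame(estimates: Iterable[FrequencyEstimate]) -> pd.DataFrame:
    """Estimates as the reporting DataFrame (rounded display scales plus
    raw proportions)."""
    return pd.DataFrame(
        [
            {
                "scope": e.scope,
                "tier": e.tier,
                "combined_ac": e.combined_allele_count,
                "n": e.n_individuals,
                "cf_per_1e5": e.cf_per_1e5,
                "cf_se_per_1e5": e.cf_se_per_1e5,
                "prevalence_per_1e7": e.prevalence_per_1e7,
                "prevalence_se_per_1e7": e.prevalence_se_per_1e7,
                "convention": e.convention,
                "cf_raw": e.carrier_frequency,
                "cf_se_raw": e.carrier_frequency_se,
                "prevalence_raw": e.prevalence,
                "prevalence_se_raw": e.prevalence_se,
            }
            for e in estimates
        ]
    )


@dataclass(frozen=True)
class EnrichmentFlag:
    """A (variant, ancestry group) pair whose within-group carrier
    frequency exceeds the global one by the configured ratio."""

    variant_id: str
    group: str
    within_group_cf_per_1e5: float
    global_cf_per_1e5: float
    ratio: float
    flagged: bool


def enrichment_scan(
    variants: Sequence[VariantRecord],
    panel: AncestryPanel,
    min_ratio: float = 2.0,
    min_ac: int = 1,
) -> list[EnrichmentFlag]:
    """Scan per-variant within-group carrier frequencies for ancestry
    enrichment.

    A (variant, group) pair is flagged when the within-group CF is at
    least ``min_ratio`` times the variant's global CF and the group
    allele count is at least ``min_ac``.  Only flagged pairs are
    returned, sorted by group label then descending within-group CF.
    Ratios are computed on raw (unrounded) frequencies; the per-1e5
    fields are raw values too (round only for display).
    """
    flags: list[EnrichmentFlag] = []
    total_n = panel.total_n
    for v in variants:
        global_cf = v.allele_count_total / total_n
        if global_cf == 0:
            continue
        for g in panel.included_groups:
            ac = v.allele_count_in(g)
            if ac < max(min_ac, 1):
                continue
            within_cf = ac / panel.groups[g]
            ratio = within_cf / global_cf
            if ratio >= min_ratio:
                flags.append(
                    EnrichmentFlag(
                        variant_id=v.variant_id,
                        group=g,
                        within_group_cf_per_1e5=within_cf * 1e5,
                        global_cf_per_1e5=global_cf * 1e5,
                        ratio=ratio,
                        flagged=True,
                    )
                )
    flags.sort(key=lambda f: (f.group, -f.within_group_cf_per_1e5))
    return flags


def enrichment_frame(flags: Iterable[EnrichmentFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": f.group,
                "variant_id": f.variant_id,
                "cf_in_group_per_1e5": round_half_away(f.within_group_cf_per_1e5, 1),
                "global_cf_per_1e5": round_half_away(f.global_cf_per_1e5, 1),
                "ratio": round_half_away(f.ratio, 1),
            }
            for f in flags
        ]
    )


class CarrierFrequencyEstimator(BaseEstimator):
    """Scikit-learn-style estimator: fit on variant records, expose the
    carrier-frequency and prevalence estimates as fitted attributes.

    Parameters
    ----------
    panel
        Ancestry panel supplying N (total and per group).
    tier
        ``"strict"`` (ClinVar/literature) or ``"liberal"`` (adds
        in-silico-qualified variants).
    convention
        Prevalence convention, ``"cf_squared"`` (default) or
        ``"half_cf_squared"``.
    config
        Qualification thresholds; defaults to the standard ones.

    Attributes (after ``fit``)
    --------------------------
    results_ : list[QualificationResult]
    summary_ : dict  — arm and tier counts
    estimates_ : list[FrequencyEstimate]  — global first, then groups
    carrier_frequency_, carrier_frequency_se_ : float (raw proportions)
    prevalence_, prevalence_se_ : float
    combined_allele_count_, n_individuals_ : int
    """

    def __init__(
        self,
        panel: Optional[AncestryPanel] = None,
        tier: Literal["strict", "liberal"] = "strict",
        convention: Convention = "cf_squared",
        config: Optional[QualificationConfig] = None,
    ):
        self.panel = panel
        self.tier = tier
        self.convention = convention
        self.config = config

    def fit(self, X: Sequence[VariantRecord], y=None) -> "CarrierFrequencyEstimator":
        if self.panel is None:
            raise ValueError("CarrierFrequencyEstimator requires a panel")
        if self.tier not in ("strict", "liberal"):
            raise ValueError(f"tier must be 'strict' or 'liberal', got {self.tier!r}")
        from .qualify import qualification_summary

        X = list(X)
        cfg = self.config or QualificationConfig()
        self.results_ = qualify_variants(X, cfg)
        self.summary_ = qualification_summary(self.results_)
        self.estimates_ = stratified_estimates(
            X, self.results_, self.panel, self.tier, self.convention
        )
        g = self.estimates_[0]
        self.combined_allele_count_ = g.combined_allele_count
        self.n_individuals_ = g.n_individuals
        self.carrier_frequency_ = g.carrier_frequency
        self.carrier_frequency_se_ = g.carrier_frequency_se
        self.prevalence_ = g.prevalence
        self.prevalence_se_ = g.prevalence_se
        return self

    def estimates_frame(self) -> pd.DataFrame:
        return estimates_frame(self.estimates_)


class EnrichmentScanner(BaseEstimator):
    """Estimator wrapper over :func:`enrichment_scan`; ``fit`` stores the
    flagged (variant, group) pairs in ``flags_``."""

    def __init__(
        self,
        panel: Optional[AncestryPanel] = None,
        min_ratio: float = 2.0,
        min_ac: int = 1,
    ):
        self.panel = panel
        self.min_ratio = min_ratio
        self.min_ac = min_ac

    def fit(self, X: Sequence[VariantRecord], y=None) -> "EnrichmentScanner":
        if self.panel is None:
            raise ValueError("EnrichmentScanner requires a panel")
        self.flags_ = enrichment_scan(
            list(X), self.panel, min_ratio=self.min_ratio, min_ac=self.min_ac
        )
        return self
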