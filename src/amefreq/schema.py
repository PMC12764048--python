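"""Core data model for gnomAD-style variant allele-count tables.

The analysis operates entirely on per-variant allele counts (no genotypes,
no coordinates): each :class:`VariantRecord` carries its identity (HGVS
protein/cDNA change), a consequence class, a ClinVar germline
classification, a literature-curation flag, an overall allele count,
optional per-ancestry-group allele counts, and optional in-silico
deleteriousness scores.  An :class:`AncestryPanel` supplies the number of
sequenced individuals per genetic-ancestry group, which converts allele
counts into carrier frequencies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Consequence(str, enum.Enum):
    """Molecular consequence class of a variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    OTHER = "other"


class ClinvarClass(str, enum.Enum):
    """ClinVar germline classification.

    ``CONFLICTING`` ("conflicting classifications of pathogenicity") is kept
    distinct from ``VUS``: a conflicting variant has discordant submissions,
    not an agreed uncertain call, and the two behave differently downstream
    (neither qualifies via ClinVar, but curated tables report them apart).
    """

    P = "P"
    LP = "LP"
    P_LP = "P_LP"
    VUS = "VUS"
    B = "B"
    LB = "LB"
    B_LB = "B_LB"
    CONFLICTING = "conflicting"
    NOT_REPORTED = "not_reported"


#: Classifications counting as pathogenic / likely pathogenic.
PLP_CLASSES = frozenset({ClinvarClass.P, ClinvarClass.LP, ClinvarClass.P_LP})
#: Classifications counting as benign / likely benign (excluded everywhere).
BLB_CLASSES = frozenset({ClinvarClass.B, ClinvarClass.LB, ClinvarClass.B_LB})


class ScoreValidationError(ValueError):
    """An in-silico score lies outside its defined range."""


@dataclass(frozen=True)
class AnnotationScores:
    """In-silico deleteriousness scores attached to one variant.

    A value of ``None`` means the predictor did not score the variant
    (e.g. SIFT for an intronic change).  ``None`` is never conflated with
    zero: SIFT = 0 is a maximally damaging prediction, not a missing one.

    Ranges: CADD is PHRED-scaled and non-negative; SIFT, PolyPhen2, REVEL
    and SpliceAI live in [0, 1]; Pangolin in [-1, 1] (sign encodes gain vs
    loss of splicing).
    """

    cadd: Optional[float] = None
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    revel: Optional[float] = None
    spliceai: Optional[float] = None
    pangolin: Optional[float] = None
    sift_indel_damaging: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ScoreValidationError(f"CADD score must be >= 0, got {self.cadd}")
        for name in ("sift", "polyphen2", "revel", "spliceai"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ScoreValidationError(f"{name} score must be in [0, 1], got {v}")
        if self.pangolin is not None and not (-1.0 <= self.pangolin <= 1.0):
            raise ScoreValidationError(
                f"pangolin score must be in [-1, 1], got {self.pangolin}"
            )


@dataclass(frozen=True)
class AncestryPanel:
    """Per-ancestry-group sample sizes of a sequencing cohort.

    ``groups`` maps group label -> number of sequenced individuals; order is
    preserved and used for reporting.  ``excluded_groups`` are groups kept
    in the total N but left out of ancestry-stratified analyses (e.g. a
    group too small to estimate from).
    """

    groups: Mapping[str, int]
    excluded_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("AncestryPanel requires at least one group")
        object.__setattr__(self, "groups", dict(self.groups))
        object.__setattr__(self, "excluded_groups", frozenset(self.excluded_groups))
        for g, n in self.groups.items():
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"group {g!r} must have a positive integer N, got {n!r}")
        unknown = self.excluded_groups - set(self.groups)
        if unknown:
            raise ValueError(f"excluded groups not in panel: {sorted(unknown)}")

    @property
    def total_n(self) -> int:
        """Total individuals, including excluded groups."""
        return sum(self.groups.values())

    @property
    def included_groups(self) -> list[str]:
        """Group labels used in stratified analyses, in panel order."""
        return [g for g in self.groups if g not in self.excluded_groups]

    def n_for(self, group: str) -> int:
        return self.groups[group]


@dataclass
class VariantRecord:
    """One row of a gnomAD-style variant table.

    ``allele_counts_by_group`` may be empty (overall count only).  When
    per-group counts are present their sum must equal
    ``allele_count_total``, and no group count may exceed twice that
    group's sample size.
    """

    gene: str
    protein_change: Optional[str]
    cdna_change: Optional[str]
    consequence: Consequence
    clinvar_class: ClinvarClass
    allele_count_total: int
    literature_reported: bool = False
    clinvar_variation_id: Optional[int] = None
    rsid: Optional[str] = None
    allele_counts_by_group: dict[str, int] = field(default_factory=dict)
    scores: AnnotationScores = field(default_factory=AnnotationScores)

    def __post_init__(self) -> None:
        if self.protein_change is None and self.cdna_change is None:
            raise ValueError("variant needs a protein or a cDNA change")
        if self.allele_count_total < 0:
            raise ValueError(
                f"{self.variant_id}: allele_count_total must be non-negative, "
                f"got {self.allele_count_total}"
            )
        for g, ac in self.allele_counts_by_group.items():
            if ac < 0:
                raise ValueError(f"{self.variant_id}: negative allele count for {g!r}")
        if self.allele_counts_by_group:
            s = sum(self.allele_counts_by_group.values())
            if s != self.allele_count_total:
                raise ValueError(
                    f"{self.variant_id}: per-group allele counts sum to {s} but "
                    f"allele_count_total is {self.allele_count_total}"
                )

    @property
    def variant_id(self) -> str:
        """Human-readable identifier: the protein change, else the cDNA change."""
        return self.protein_change or self.cdna_change or "?"

    def validate_against_panel(self, panel: AncestryPanel) -> None:
        """Check per-group counts against the panel (AC <= 2N per group)."""
        for g, ac in self.allele_counts_by_group.items():
            if g not in panel.groups:
                raise ValueError(f"{self.variant_id}: unknown ancestry group {g!r}")
            if ac > 2 * panel.groups[g]:
                raise ValueError(
                    f"{self.variant_id}: allele count {ac} in group {g!r} exceeds "
                    f"2N = {2 * panel.groups[g]}"
                )

    def allele_count_in(self, group: str) -> int:
        return self.allele_counts_by_group.get(group, 0)


@dataclass(frozen=True)
class QualificationConfig:
    """Thresholds for the in-silico evidence arm, plus the benign-exclusion
    switch.

    Inequality directions are part of the contract: every threshold is
    strict ("greater than" / "less than") except ``spliceai_min``, which is
    inclusive (>= 0.8).  ``exclude_blb`` removes ClinVar benign / likely
    benign variants from *all* arms, not just the literature arm.
    """

    cadd_min: float = 20.0
    sift_max: float = 0.05
    polyphen2_min: float = 0.85
    revel_min: float = 0.75
    spliceai_min: float = 0.8
    pangolin_abs_min: float = 0.2
    exclude_blb: bool = True

    def __post_init__(self) -> None:
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")
        for name, hi in (
            ("sift_max", 1.0),
            ("polyphen2_min", 1.0),
            ("revel_min", 1.0),
            ("spliceai_min", 1.0),
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= hi):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.pangolin_abs_min <= 1.0):
            raise ValueError("pangolin_abs_min must be in [0, 1]")
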