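"""Synthetic gnomAD-like cohort generator with known truth.

The generator emulates the statistical structure the estimator assumes,
at the level the analysis actually consumes — per-variant allele counts,
not genotypes:

* every variant is rare and biallelic; its allele count in each ancestry
  group is drawn ``Binomial(2·N_group, q_group)`` independently across
  variants and groups (no linkage, no shared haplotypes);
* in-silico scores are drawn from consequence- and pathogenicity-
  conditional distributions chosen so that truly pathogenic variants
  mostly pass the predictor thresholds and benign ones mostly fail them
  (qualitatively separated CADD distributions, not a fit to real data);
* the ClinVar label is a noisy categorical draw conditioned on the true
  pathogenicity, and a truly pathogenic variant is literature-reported
  with probability ``literature_sensitivity``.

Because the truth (``q`` per group, pathogenic flag) is known, closed-form
expected carrier frequencies and prevalences are available for recovery
tests: E[AC/N] = 2q per variant and group, additive over variants.

Reproducibility: one root ``numpy`` SeedSequence derived from the config
seed is spawned into one child stream per variant, so results do not
depend on iteration order and identical configs give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .estimate import prevalence_from_cf
from .schema import AncestryPanel, AnnotationScores, ClinvarClass, Consequence, VariantRecord


class ConfigError(ValueError):
    """A simulation configuration parameter is out of range."""


@dataclass(frozen=True)
class TrueVariant:
    """Ground truth for one simulated variant."""

    consequence: Consequence
    pathogenic: bool
    q_by_group: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_by_group", dict(self.q_by_group))
        for g, q in self.q_by_group.items():
            if not (0.0 <= q <= 0.01):
                raise ConfigError(
                    f"true allele frequency for {g!r} must be in [0, 0.01] "
                    f"(rare-variant regime), got {q}"
                )


@dataclass(frozen=True)
class ScoreModel:
    """Conditional score distributions, (loc, scale) for truncated normals
    and (a, b) for betas.

    Defaults separate pathogenic from benign variants across every
    predictor threshold without claiming realism: e.g. pathogenic
    missense CADD ~ Normal(28, 3) truncated at 0, benign ~ Normal(10, 5)
    truncated at 0.
    """

    cadd_pathogenic: tuple[float, float] = (28.0, 3.0)
    cadd_benign: tuple[float, float] = (10.0, 5.0)
    sift_pathogenic: tuple[float, float] = (0.3, 12.0)
    sift_benign: tuple[float, float] = (4.0, 2.0)
    polyphen2_pathogenic: tuple[float, float] = (12.0, 1.0)
    polyphen2_benign: tuple[float, float] = (1.0, 4.0)
    revel_pathogenic: tuple[float, float] = (12.0, 1.5)
    revel_benign: tuple[float, float] = (1.5, 6.0)
    spliceai_pathogenic: tuple[float, float] = (12.0, 1.0)
    spliceai_benign: tuple[float, float] = (1.0, 12.0)
    pangolin_abs_pathogenic: tuple[float, float] = (4.0, 2.0)
    pangolin_abs_benign: tuple[float, float] = (1.0, 15.0)
    p_sift_indel_damaging_pathogenic: float = 0.9
    p_sift_indel_damaging_benign: float = 0.1

    def _trunc_normal(self, rng: np.random.Generator, loc: float, scale: float) -> float:
        x = rng.normal(loc, scale)
        return float(max(x, 0.0))

    def draw(
        self, rng: np.random.Generator, consequence: Consequence, pathogenic: bool
    ) -> AnnotationScores:
        """Draw the scores a real annotation pipeline would attach to a
        variant of this consequence class."""
        suffix = "pathogenic" if pathogenic else "benign"

        def beta(name: str) -> float:
            a, b = getattr(self, f"{name}_{suffix}")
            return float(rng.beta(a, b))

        cadd = self._trunc_normal(rng, *getattr(self, f"cadd_{suffix}"))
        kwargs: dict = {"cadd": cadd}
        if consequence is Consequence.MISSENSE:
            kwargs.update(
                sift=beta("sift"),
                polyphen2=beta("polyphen2"),
                revel=beta("revel"),
            )
        elif consequence is Consequence.INFRAME_INDEL:
            p = (
                self.p_sift_indel_damaging_pathogenic
                if pathogenic
                else self.p_sift_indel_damaging_benign
            )
            kwargs.update(sift_indel_damaging=bool(rng.random() < p))
        elif consequence is Consequence.SPLICE_SITE:
            sign = -1.0 if rng.random() < 0.5 else 1.0
            kwargs.update(
                spliceai=beta("spliceai"),
                pangolin=sign * beta("pangolin_abs"),
            )
        return AnnotationScores(**kwargs)


@dataclass(frozen=True)
class LabelModel:
    """P(ClinVar class | true pathogenicity); imperfect on purpose —
    real databases under-curate, so many truly pathogenic variants sit at
    VUS or are absent."""

    class_probs_pathogenic: Mapping[str, float] = field(
        default_factory=lambda: {
            "P": 0.15,
            "LP": 0.15,
            "P_LP": 0.05,
            "VUS": 0.30,
            "conflicting": 0.05,
            "not_reported": 0.30,
        }
    )
    class_probs_benign: Mapping[str, float] = field(
        default_factory=lambda: {
            "B": 0.10,
            "LB": 0.10,
            "VUS": 0.25,
            "conflicting": 0.05,
            "not_reported": 0.50,
        }
    )

    def __post_init__(self) -> None:
        for name in ("class_probs_pathogenic", "class_probs_benign"):
            probs = dict(getattr(self, name))
            object.__setattr__(self, name, probs)
            for k, p in probs.items():
                ClinvarClass(k)  # raises on unknown label
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"{name}[{k!r}] must be a probability, got {p}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, sums to {total}")

    def draw(self, rng: np.random.Generator, pathogenic: bool) -> ClinvarClass:
        probs = self.class_probs_pathogenic if pathogenic else self.class_probs_benign
        labels = list(probs)
        idx = rng.choice(len(labels), p=[probs[k] for k in labels])
        return ClinvarClass(labels[int(idx)])


def perfect_label_model() -> LabelModel:
    """Oracle labels: pathogenic -> P, benign -> B (for convergence tests)."""
    return LabelModel(
        class_probs_pathogenic={"P": 1.0},
        class_probs_benign={"B": 1.0},
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of a synthetic cohort."""

    panel: AncestryPanel
    variants: Sequence[TrueVariant]
    seed: int
    score_model: ScoreModel = field(default_factory=ScoreModel)
    label_model: LabelModel = field(default_factory=LabelModel)
    literature_sensitivity: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        if not (0.0 <= self.literature_sensitivity <= 1.0):
            raise ConfigError(
                f"literature_sensitivity must be in [0, 1], "
                f"got {self.literature_sensitivity}"
            )
        for v in self.variants:
            unknown = set(v.q_by_group) - set(self.panel.groups)
            if unknown:
                raise ConfigError(f"q_by_group names unknown groups: {sorted(unknown)}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# pseudo-HGVS templates so simulated rows stay consistent with the
# consequence-inference rules and survive a table round trip
_HGVS_TEMPLATES = {
    Consequence.MISSENSE: ("p.Ala{i}Val", "c.{i}C>T"),
    Consequence.NONSENSE: ("p.Ala{i}Ter", "c.{i}C>A"),
    Consequence.FRAMESHIFT: ("p.Ala{i}GlyfsTer9", "c.{i}dup"),
    Consequence.INFRAME_INDEL: ("p.Ala{i}del", "c.{i}_{j}del"),
    Consequence.SPLICE_SITE: (None, "c.{i}-1G>A"),
    Consequence.OTHER: (None, "c.{i}C=T"),
}


def simulate_cohort(cfg: SimulationConfig) -> list[VariantRecord]:
    """Draw one synthetic cohort table from the generative model.

    Identical config (including seed) gives an identical table.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(cfg.variants))
    records: list[VariantRecord] = []
    for i, (tv, child) in enumerate(zip(cfg.variants, children), start=1):
        rng = np.random.default_rng(child)
        by_group = {
            g: int(rng.binomial(2 * n, tv.q_by_group.get(g, 0.0)))
            for g, n in cfg.panel.groups.items()
        }
        scores = cfg.score_model.draw(rng, tv.consequence, tv.pathogenic)
        clinvar = cfg.label_model.draw(rng, tv.pathogenic)
        literature = bool(
            tv.pathogenic and rng.random() < cfg.literature_sensitivity
        )
        p_tmpl, c_tmpl = _HGVS_TEMPLATES[tv.consequence]
        pos = 100 + 3 * i
        records.append(
            VariantRecord(
                gene="GENE1",
                protein_change=None if p_tmpl is None else p_tmpl.format(i=pos),
                cdna_change=c_tmpl.format(i=pos, j=pos + 2),
                consequence=tv.consequence,
                clinvar_class=clinvar,
                clinvar_variation_id=None,
                rsid=None,
                literature_reported=literature,
                allele_count_total=sum(by_group.values()),
                allele_counts_by_group=by_group,
                scores=scores,
            )
        )
    return records


def truth_report(cfg: SimulationConfig) -> dict:
    """Closed-form expectations implied by the config.

    For each scope (``global`` plus every non-excluded group) and for the
    truly pathogenic subset ("pathogenic", what a perfect strict filter
    would recover) and all variants ("all"), reports the expected carrier
    frequency (per individual and per 100,000; E[AC/N] = 2q summed over
    variants) and the expected prevalence under both conventions.
    """
    panel = cfg.panel
    scopes = {"global": None, **{g: g for g in panel.included_groups}}
    out: dict = {}
    for scope, group in scopes.items():
        out[scope] = {}
        for subset_name, keep in (("pathogenic", True), ("all", None)):
            variants = [
                v for v in cfg.variants if keep is None or v.pathogenic == keep
            ]
            if group is None:
                total = panel.total_n
                exp_ac = sum(
                    2 * n * v.q_by_group.get(g, 0.0)
                    for v in variants
                    for g, n in panel.groups.items()
                )
                cf = exp_ac / total
            else:
                cf = sum(2 * v.q_by_group.get(group, 0.0) for v in variants)
            prev_sq, _ = prevalence_from_cf(cf, 0.0, "cf_squared")
            prev_half, _ = prevalence_from_cf(cf, 0.0, "half_cf_squared")
            out[scope][subset_name] = {
                "carrier_frequency": cf,
                "cf_per_1e5": cf * 1e5,
                "prevalence_cf_squared": prev_sq,
                "prevalence_half_cf_squared": prev_half,
            }
    return out


def _panel_from_obj(obj: dict) -> AncestryPanel:
    return AncestryPanel(
        groups={str(g): int(n) for g, n in obj["groups"].items()},
        excluded_groups=frozenset(obj.get("excluded_groups", [])),
    )


def load_config(path, seed: Optional[int] = None) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML.

    Layout::

        seed: 1
        literature_sensitivity: 0.5
        panel:
          groups: {afr: 37545, nfe: 590031}
          excluded_groups: []
        variants:
          - {consequence: missense, pathogenic: true, q: {nfe: 1.0e-4}}

    ``seed`` given here overrides the file's value.
    """
    obj = yaml.safe_load(Path(path).read_text())
    variants = [
        TrueVariant(
            consequence=Consequence(v["consequence"]),
            pathogenic=bool(v["pathogenic"]),
            q_by_group={str(g): float(q) for g, q in v.get("q", {}).items()},
        )
        for v in obj.get("variants", [])
    ]
    kwargs: dict = {}
    if "score_model" in obj:
        kwargs["score_model"] = ScoreModel(
            **{
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in obj["score_model"].items()
            }
        )
    if "label_model" in obj:
        kwargs["label_model"] = LabelModel(**obj["label_model"])
    return SimulationConfig(
        panel=_panel_from_obj(obj["panel"]),
        variants=variants,
        seed=int(seed if seed is not None else obj.get("seed", 0)),
        literature_sensitivity=float(obj.get("literature_sensitivity", 0.5)),
        **kwargs,
    )
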