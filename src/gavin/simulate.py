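"""Synthetic annotated-variant generator with planted statistical structure.

Emulates per-gene collections of labelled variants with the features the
calibration consumes: CADD scores as truncated normals (per-group mean
and spread mirror the summary statistics that describe real pathogenic
vs matched-benign sets), allele-frequency spectra with a point mass at 0
(absent from the population) plus a log-uniform body, multinomial effect
impact mixes, and planted duplicates of pathogenic variants inside the
population candidate pool (exercising the known-pathogenic exclusion
stage).  Positions are consecutive integers per gene on a synthetic
contig so step-over removal order is well-defined and test-stable.

It deliberately does not model linkage, transcript structure, or
realistic genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .model import AnnotatedVariant, Impact, Label

__all__ = [
    "AFModel",
    "GeneScenario",
    "generate_gene",
    "generate_cohort",
    "scenario_presets",
    "preset_cgd_map",
    "dispersed_cutoff_scenarios",
]

_CONTIG = "chrS"
_GENE_SPAN = 100_000  # positions reserved per gene on the synthetic contig


@dataclass(frozen=True, slots=True)
class AFModel:
    """Benign allele-frequency model: point mass at 0 + log-uniform body."""

    zero_fraction: float = 0.3
    log10_min: float = -6.0
    log10_max: float = float(np.log10(0.5))

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must lie in [0, 1]")
        if self.log10_min > self.log10_max:
            raise ValueError("log10_min must not exceed log10_max")


@dataclass(frozen=True, slots=True)
class GeneScenario:
    """Planted parameters for one synthetic gene."""

    gene: str
    n_patho: int = 50
    n_benign: int = 400
    patho_cadd_mean: float = 28.0
    patho_cadd_sd: float = 3.0
    benign_cadd_mean: float = 18.0
    benign_cadd_sd: float = 3.0
    patho_af_zero_fraction: float = 0.8
    patho_af_log10_min: float = -6.0
    patho_af_log10_max: float = -4.0
    af_model: AFModel = field(default_factory=AFModel)
    patho_impact_probs: tuple[float, float, float, float] = (0.05, 0.75, 0.20, 0.0)
    benign_impact_probs: tuple[float, float, float, float] = (0.10, 0.50, 0.20, 0.20)
    n_known_duplicates: int = 5
    planted_category: Optional[str] = None

    def __post_init__(self) -> None:
        for name, probs in (
            ("patho_impact_probs", self.patho_impact_probs),
            ("benign_impact_probs", self.benign_impact_probs),
        ):
            if len(probs) != 4 or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must be 4 non-negative values summing to 1")
        if self.n_patho < 0 or self.n_benign < 0:
            raise ValueError("counts must be non-negative")
        if self.patho_cadd_sd <= 0 or self.benign_cadd_sd <= 0:
            raise ValueError("CADD standard deviations must be positive")
        if not 0.0 <= self.patho_af_zero_fraction <= 1.0:
            raise ValueError("patho_af_zero_fraction must lie in [0, 1]")
        if self.n_known_duplicates > self.n_benign:
            raise ValueError("cannot plant more duplicates than candidates")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 (CADD scores are non-negative)."""
    a = (0.0 - mean) / sd
    return _sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _log_uniform(rng: np.random.Generator, lo10: float, hi10: float, n: int) -> np.ndarray:
    return 10.0 ** rng.uniform(lo10, hi10, size=n)


def _impacts(rng: np.random.Generator, probs: Sequence[float], n: int) -> list[Impact]:
    order = (Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER)
    draws = rng.choice(4, size=n, p=np.asarray(probs, dtype=float))
    return [order[i] for i in draws]


def generate_gene(
    scenario: GeneScenario,
    seed: int,
    position_offset: int = 1,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Generate (pathogenic, population-candidate) variants for one gene.

    Deterministic under ``seed``.  Pathogenic variants occupy consecutive
    positions starting at ``position_offset``; candidates follow in a
    disjoint block.  The first ``n_known_duplicates`` candidates are
    planted at pathogenic sites (same chrom/pos/ref/alt) so the
    known-pathogenic exclusion stage has work to do.
    """
    rng = np.random.default_rng(seed)
    s = scenario

    patho_cadd = _truncated_normal(rng, s.patho_cadd_mean, s.patho_cadd_sd, s.n_patho)
    patho_zero = rng.random(s.n_patho) < s.patho_af_zero_fraction
    patho_af = _log_uniform(rng, s.patho_af_log10_min, s.patho_af_log10_max, s.n_patho)
    patho_impacts = _impacts(rng, s.patho_impact_probs, s.n_patho)
    patho = [
        AnnotatedVariant(
            chrom=_CONTIG,
            pos=position_offset + i,
            ref="A",
            alt="G",
            gene=s.gene,
            impact=patho_impacts[i],
            cadd=float(patho_cadd[i]),
            af=None if patho_zero[i] else float(min(patho_af[i], 1.0)),
            label=Label.PATHOGENIC,
            significance="Pathogenic",
        )
        for i in range(s.n_patho)
    ]

    benign_cadd = _truncated_normal(rng, s.benign_cadd_mean, s.benign_cadd_sd, s.n_benign)
    benign_zero = rng.random(s.n_benign) < s.af_model.zero_fraction
    benign_af = _log_uniform(rng, s.af_model.log10_min, s.af_model.log10_max, s.n_benign)
    benign_impacts = _impacts(rng, s.benign_impact_probs, s.n_benign)
    candidates = []
    for i in range(s.n_benign):
        if i < s.n_known_duplicates and patho:
            dup_of = patho[i % len(patho)]
            chrom, pos, ref, alt = dup_of.site
        else:
            chrom, pos, ref, alt = _CONTIG, position_offset + _GENE_SPAN // 2 + i, "C", "T"
        candidates.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=s.gene,
                impact=benign_impacts[i],
                cadd=float(benign_cadd[i]),
                af=None if benign_zero[i] else float(min(benign_af[i], 1.0)),
                label=Label.BENIGN,
                significance="Benign",
            )
        )
    return patho, candidates


def generate_cohort(
    scenarios: Sequence[GeneScenario],
    seed: int,
    out_dir: Optional[str] = None,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Generate a multi-gene cohort; optionally write VCF + truth fixtures.

    Gene symbols must be unique; each gene occupies a disjoint position
    block.  When ``out_dir`` is given, writes ``pathogenic.vcf``,
    ``population.vcf`` and ``truth.tsv`` consumable by
    :mod:`gavin.variant_io`.
    """
    names = [s.gene for s in scenarios]
    if len(set(names)) != len(names):
        raise ValueError("gene symbols must be unique across scenarios")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(scenarios))]
    patho_all: list[AnnotatedVariant] = []
    pop_all: list[AnnotatedVariant] = []
    for i, scenario in enumerate(scenarios):
        patho, pop = generate_gene(
            scenario, seed=child_seeds[i], position_offset=1 + i * _GENE_SPAN
        )
        patho_all.extend(patho)
        pop_all.extend(pop)
    if out_dir is not None:
        from pathlib import Path

        from .variant_io import write_truth_table, write_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(patho_all, out / "pathogenic.vcf")
        write_vcf(pop_all, out / "population.vcf")
        write_truth_table(patho_all + pop_all, out / "truth.tsv")
    return patho_all, pop_all


def scenario_presets() -> dict[str, GeneScenario]:
    """Named single-gene scenarios, one per calibration category.

    Each preset is designed so that calibrating its output lands in the
    intended category with high probability (deterministically for the
    degenerate presets).
    """
    base = GeneScenario(gene="GENE")
    return {
        # clear 10-point CADD separation, ample data on both sides
        "cadd_predictive": replace(
            base, gene="CPRED", patho_cadd_mean=28.0, benign_cadd_mean=18.0,
            planted_category="CADD_PREDICTIVE",
        ),
        # identical CADD distributions: only type-I errors escape
        "cadd_less_predictive": replace(
            base, gene="CLESS", patho_cadd_mean=20.0, benign_cadd_mean=20.0,
            planted_category="CADD_LESS_PREDICTIVE",
        ),
        # too few pathogenic variants for a trustworthy test; impact
        # supports overlap by construction so only scarcity drives the
        # category
        "little_data": replace(
            base, gene="LDATA", n_patho=3, n_benign=40, n_known_duplicates=2,
            patho_impact_probs=(0.0, 1.0, 0.0, 0.0),
            benign_impact_probs=(0.0, 0.7, 0.2, 0.1),
            planted_category="LITTLE_DATA",
        ),
        # HIGH impact occurs only among pathogenic variants
        "impact_predictive": replace(
            base, gene="IMPRED", n_patho=20, n_benign=200,
            patho_impact_probs=(0.4, 0.6, 0.0, 0.0),
            benign_impact_probs=(0.0, 0.6, 0.2, 0.2),
            planted_category="IMPACT_PREDICTIVE",
        ),
        # every candidate too common for the pathogenic frequency range
        "maf_only": replace(
            base, gene="MAFONLY", n_patho=10, n_benign=50,
            patho_af_zero_fraction=1.0, n_known_duplicates=0,
            af_model=AFModel(zero_fraction=0.0, log10_min=-2.0,
                             log10_max=float(np.log10(0.5))),
            planted_category="MAF_ONLY",
        ),
        # a single variant: nothing to calibrate
        "not_calibrated": replace(
            base, gene="NOCAL", n_patho=1, n_benign=0, n_known_duplicates=0,
            planted_category="NOT_CALIBRATED",
        ),
        # inverted direction: population CADD above pathogenic CADD
        "artifact": replace(
            base, gene="ARTIF", patho_cadd_mean=18.0, benign_cadd_mean=28.0,
            planted_category="ARTIFACT",
        ),
    }


def myh7_like_fixture() -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Synthetic reconstruction of the published MYH7 calibration example.

    Deterministically builds 407 pathogenic variants (impact counts
    22 HIGH / 315 MODERATE / 70 LOW / 0 MODIFIER, allele frequencies
    planted so the type-7 95th percentile is exactly 4.942e-5) and 1799
    population candidates: 99 at known pathogenic sites, 246 with
    frequency above the threshold, and 1454 rare-and-novel candidates
    whose impact mix makes MODERATE the binding category for impact
    equalization.  Only the published summary counts constrain the
    construction; per-variant values (positions, CADD scores) are
    synthetic stand-ins.
    """
    gene = "MYH7"
    imp = (Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER)

    def _block(counts, pos0, ref, alt, af_fn, label):
        out = []
        i = 0
        for c, n in zip(imp, counts):
            for _ in range(n):
                out.append(
                    AnnotatedVariant(
                        chrom=_CONTIG, pos=pos0 + i, ref=ref, alt=alt, gene=gene,
                        impact=c, cadd=20.0, af=af_fn(i), label=label,
                    )
                )
                i += 1
        return out

    # pathogenic AFs: ranks 1..370 zero (absent), 371..385 at 1e-5,
    # 386..397 at the threshold value, 398..407 common-ish; the type-7
    # 95th percentile sits at rank h = 386.7, between two equal values.
    def patho_af(i):
        rank = i + 1
        if rank <= 370:
            return None
        if rank <= 385:
            return 1e-5
        if rank <= 397:
            return 4.942e-5
        return 5e-4

    # impacts and AFs are independent in the published summary, so the
    # deterministic pairing below is arbitrary but stable
    patho = _block((22, 315, 70, 0), 1, "A", "G", patho_af, Label.PATHOGENIC)

    overlap = _block((2, 30, 20, 47), 1, "A", "G", lambda i: 1e-5, Label.BENIGN)
    common = _block((7, 12, 100, 127), 10_000, "C", "T", lambda i: 1e-3, Label.BENIGN)
    rare = _block((27, 383, 466, 578), 20_000, "C", "T", lambda i: 1e-5, Label.BENIGN)
    return patho, overlap + common + rare


def preset_cgd_map() -> dict[str, set[str]]:
    """CGD-style manifestation categories for the preset genes."""
    return {
        "CPRED": {"Cardiovascular"},
        "CLESS": {"Neurologic"},
        "LDATA": {"Cardiovascular", "Musculoskeletal"},
        "IMPRED": {"Renal"},
        "MAFONLY": {"Dermatologic"},
        "ARTIF": {"Oncologic"},
        # NOCAL intentionally absent: exercises the NotInCGD panel
    }


def dispersed_cutoff_scenarios(
    n_genes: int,
    seed: int,
    cutoff_range: tuple[float, float] = (10.0, 30.0),
    half_separation: float = 5.0,
    sd: float = 3.0,
    n_patho: int = 120,
    n_benign: int = 500,
) -> list[GeneScenario]:
    """Scenarios whose per-gene optimal CADD cutoffs are dispersed.

    Gene g gets a cutoff c_g uniform over ``cutoff_range``; pathogenic
    CADD ~ N(c_g + half_separation, sd) and benign ~ N(c_g -
    half_separation, sd).  A single genome-wide cutoff cannot be optimal
    for all such genes, which is what makes gene-specific thresholds pay
    off.
    """
    rng = np.random.default_rng(seed)
    cutoffs = rng.uniform(*cutoff_range, size=n_genes)
    return [
        GeneScenario(
            gene=f"DG{i:03d}",
            n_patho=n_patho,
            n_benign=n_benign,
            patho_cadd_mean=float(c + half_separation),
            benign_cadd_mean=float(max(c - half_separation, 1.0)),
            patho_cadd_sd=sd,
            benign_cadd_sd=sd,
        )
        for i, c in enumerate(cutoffs)
    ]
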