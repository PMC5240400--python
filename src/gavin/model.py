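"""Core data model for gene-aware variant classification.

The unit of analysis is a single-allele, single-gene annotated variant:
one chromosomal substitution/indel carrying a SnpEff-style effect impact,
a scaled CADD deleteriousness score, and a population minor allele
frequency (MAF).  Multi-allelic VCF records and multi-gene annotations
are expanded upstream so that every :class:`AnnotatedVariant` here has
exactly one alternate allele and at most one gene symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Impact",
    "Label",
    "Verdict",
    "CalibrationCategory",
    "AnnotatedVariant",
    "ImpactDistribution",
    "GeneCalibration",
    "Judgment",
    "JudgmentSource",
]

_ALLELE_CHARS = frozenset("ACGTN")


class Impact(str, Enum):
    """SnpEff generalized effect-impact category.

    Severity order (most to least severe): HIGH > MODERATE > LOW > MODIFIER.
    """

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"

    @property
    def severity(self) -> int:
        """Integer rank, larger = more severe (HIGH=3 ... MODIFIER=0)."""
        return _SEVERITY[self]


_SEVERITY = {Impact.MODIFIER: 0, Impact.LOW: 1, Impact.MODERATE: 2, Impact.HIGH: 3}

#: Impacts from most to least severe.
IMPACT_ORDER = (Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER)


class Label(str, Enum):
    """Truth label attached to a variant (expert classification)."""

    BENIGN = "Benign"
    PATHOGENIC = "Pathogenic"
    VUS = "VUS"


class Verdict(str, Enum):
    """Classifier outcome."""

    BENIGN = "Benign"
    PATHOGENIC = "Pathogenic"
    VUS = "VUS"


class JudgmentSource(str, Enum):
    GENE_SPECIFIC = "gene-specific"
    GENOME_WIDE = "genome-wide"


class CalibrationCategory(str, Enum):
    """Outcome of calibrating one gene; the seven categories partition genes."""

    CADD_PREDICTIVE = "CADD_PREDICTIVE"
    CADD_LESS_PREDICTIVE = "CADD_LESS_PREDICTIVE"
    LITTLE_DATA = "LITTLE_DATA"
    IMPACT_PREDICTIVE = "IMPACT_PREDICTIVE"
    MAF_ONLY = "MAF_ONLY"
    NOT_CALIBRATED = "NOT_CALIBRATED"
    ARTIFACT = "ARTIFACT"


@dataclass(slots=True)
class AnnotatedVariant:
    """One annotated variant: single alt allele, single gene context.

    Parameters
    ----------
    chrom, pos, ref, alt
        VCF-style coordinates; 1-based inclusive position, alleles over
        {A,C,G,T,N}.  Symbolic alleles are rejected.
    gene
        Gene symbol the impact applies to; ``None`` when unannotated.
    impact
        SnpEff effect impact, or ``None``.
    cadd
        Scaled (phred-like) CADD score, or ``None``.
    af
        Population minor allele frequency in [0, 1].  ``None`` means the
        variant was not observed in the population resource (distinct
        from an observed frequency of 0 at I/O level; calibration maps
        absent to 0 explicitly).
    label
        Optional truth label.
    significance
        Raw clinical-significance string as annotated (free text).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    impact: Optional[Impact] = None
    cadd: Optional[float] = None
    af: Optional[float] = None
    label: Optional[Label] = None
    significance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele.upper()) <= _ALLELE_CHARS:
                raise ValueError(
                    f"{name} allele {allele!r} is empty or not a plain "
                    "A/C/G/T/N sequence (symbolic alleles are rejected)"
                )
        if self.impact is not None and not isinstance(self.impact, Impact):
            self.impact = Impact(str(self.impact).upper())
        if self.cadd is not None:
            self.cadd = float(self.cadd)
            if not math.isfinite(self.cadd):
                raise ValueError(f"cadd must be finite, got {self.cadd}")
        if self.af is not None:
            self.af = float(self.af)
            if not 0.0 <= self.af <= 1.0:
                raise ValueError(f"af must lie in [0, 1], got {self.af}")
        if self.label is not None and not isinstance(self.label, Label):
            self.label = Label(self.label)

    @property
    def site(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) identity used for known-variant exclusion."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def af_or_zero(self) -> float:
        """Allele frequency with absent-from-population mapped to 0."""
        return 0.0 if self.af is None else self.af


@dataclass(frozen=True, slots=True)
class ImpactDistribution:
    """Relative proportions of the four effect-impact categories.

    An *absent* distribution (all fields ``None``) represents "no variants";
    a defined distribution has proportions in [0, 1] summing to 1.
    """

    high: Optional[float] = None
    moderate: Optional[float] = None
    low: Optional[float] = None
    modifier: Optional[float] = None

    def __post_init__(self) -> None:
        vals = (self.high, self.moderate, self.low, self.modifier)
        defined = [v for v in vals if v is not None]
        if defined and len(defined) != 4:
            raise ValueError("all four proportions must be set, or none")
        if defined:
            if any(v < -1e-12 for v in defined):
                raise ValueError("proportions must be non-negative")
            if abs(sum(defined) - 1.0) > 1e-9:
                raise ValueError(f"proportions must sum to 1, got {sum(defined)}")

    @property
    def defined(self) -> bool:
        return self.high is not None

    def proportion(self, impact: Impact) -> float:
        if not self.defined:
            raise ValueError("distribution is absent")
        return {
            Impact.HIGH: self.high,
            Impact.MODERATE: self.moderate,
            Impact.LOW: self.low,
            Impact.MODIFIER: self.modifier,
        }[impact]

    def as_tuple(self) -> tuple[float, float, float, float]:
        if not self.defined:
            raise ValueError("distribution is absent")
        return (self.high, self.moderate, self.low, self.modifier)

    @classmethod
    def absent(cls) -> "ImpactDistribution":
        return cls()

    @classmethod
    def from_counts(cls, counts: Mapping[Impact, int]) -> "ImpactDistribution":
        n = sum(counts.get(i, 0) for i in Impact)
        if n == 0:
            return cls.absent()
        return cls(
            high=counts.get(Impact.HIGH, 0) / n,
            moderate=counts.get(Impact.MODERATE, 0) / n,
            low=counts.get(Impact.LOW, 0) / n,
            modifier=counts.get(Impact.MODIFIER, 0) / n,
        )

    @classmethod
    def from_variants(cls, variants: Iterable[AnnotatedVariant]) -> "ImpactDistribution":
        counts: dict[Impact, int] = {}
        for v in variants:
            if v.impact is None:
                raise ValueError(
                    f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} has no impact annotation"
                )
            counts[v.impact] = counts.get(v.impact, 0) + 1
        return cls.from_counts(counts)

    def supported(self) -> frozenset[Impact]:
        """Impact categories with non-zero proportion (empty when absent)."""
        if not self.defined:
            return frozenset()
        return frozenset(i for i in Impact if self.proportion(i) > 0)


@dataclass(slots=True)
class GeneCalibration:
    """Per-gene calibration result: one row of the gene calibration table.

    Numeric fields are ``None`` exactly when the category implies their
    inputs were unavailable (e.g. NOT_CALIBRATED rows carry no thresholds;
    IMPACT_PREDICTIVE rows carry no CADD thresholds).
    """

    gene: str
    category: CalibrationCategory
    patho_maf_threshold: Optional[float] = None
    mean_patho_cadd: Optional[float] = None
    mean_benign_cadd: Optional[float] = None
    sens95_cadd: Optional[float] = None
    spec95_cadd: Optional[float] = None
    patho_impact_dist: ImpactDistribution = field(default_factory=ImpactDistribution.absent)
    benign_impact_dist: ImpactDistribution = field(default_factory=ImpactDistribution.absent)
    mwu_p: Optional[float] = None
    n_patho: int = 0
    n_benign: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.category, CalibrationCategory):
            self.category = CalibrationCategory(self.category)
        if self.n_patho < 0 or self.n_benign < 0:
            raise ValueError("variant counts must be non-negative")
        if self.mwu_p is not None and not 0.0 <= self.mwu_p <= 1.0:
            raise ValueError(f"mwu_p must lie in [0, 1], got {self.mwu_p}")

    def replace(self, **kwargs) -> "GeneCalibration":
        return replace(self, **kwargs)

    def pathogenic_unique_impacts(self) -> frozenset[Impact]:
        """Impacts observed in pathogenic variants but never in benign ones."""
        return self.patho_impact_dist.supported() - self.benign_impact_dist.supported()


@dataclass(frozen=True, slots=True)
class Judgment:
    """Classification outcome with its provenance.

    ``rule`` is a short machine-readable code for the rule that fired
    (e.g. ``MAF_ABOVE_THRESHOLD``, ``IMPACT_DIRECT``, ``CADD_ABOVE_SENS95``,
    ``FALLBACK_CADD``); ``reason`` is a human-readable explanation.
    """

    verdict: Verdict
    source: JudgmentSource
    rule: str
    reason: str = ""


def group_by_gene(
    variants: Iterable[AnnotatedVariant],
) -> dict[Optional[str], list[AnnotatedVariant]]:
    """Partition variants by gene symbol (``None`` bucket for unannotated)."""
    groups: dict[Optional[str], list[AnnotatedVariant]] = {}
    for v in variants:
        groups.setdefault(v.gene, []).append(v)
    return groups
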