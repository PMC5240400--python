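"""Per-gene calibration of classification thresholds.

For each gene with labelled training variants the calibration derives,
from the pathogenic set and a population candidate set:

1. a pathogenic MAF threshold — the type-7 95th percentile of the
   pathogenic variants' population allele frequencies (absent = 0);
2. a *matched* benign set — population candidates with known pathogenic
   sites excluded, frequency-filtered to the pathogenic MAF range, and
   downsampled by a deterministic "step over" scheme until the effect
   impact distribution equals that of the pathogenic set.  Matching
   removes the consequence/rarity bias that otherwise inflates apparent
   CADD separation between pathogenic and typical benign variants;
3. CADD statistics on the two matched sets — group means, a Mann–Whitney
   U test, the 95th-percentile *sensitivity* threshold (CADD value
   exceeded by 95% of pathogenic variants) and *specificity* threshold
   (value below which 95% of benign variants fall);
4. one of seven mutually exclusive calibration categories.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    AnnotatedVariant,
    CalibrationCategory,
    GeneCalibration,
    Impact,
    ImpactDistribution,
    group_by_gene,
)
from .stats import mann_whitney_u, percentile_r7

__all__ = [
    "select_pathogenic",
    "compute_patho_maf_threshold",
    "impact_distribution",
    "match_benign_set",
    "MatchedBenignSet",
    "calibrate_gene",
    "calibrate",
    "genome_wide_defaults",
    "GenomeWideDefaults",
    "apply_sensitivity_adjustment",
    "GENOME_WIDE_CADD_THRESHOLD",
]

#: Fixed genome-wide CADD cutoff of the fallback rule (< benign, > pathogenic).
GENOME_WIDE_CADD_THRESHOLD = 15.0


def select_pathogenic(
    variants: Iterable[AnnotatedVariant],
    negations: Sequence[str] = (),
) -> list[AnnotatedVariant]:
    """Select variants whose clinical significance contains "pathogenic".

    The match is a case-insensitive substring test, so "Likely pathogenic"
    is kept alongside "Pathogenic".  ``negations`` is an optional list of
    substrings whose presence excludes a variant (default: none).  Variants
    without a significance string fall back to their normalized label.
    """
    negs = [n.lower() for n in negations]
    out = []
    for v in variants:
        if v.significance is not None:
            s = v.significance.lower()
            if "pathogenic" in s and not any(n in s for n in negs):
                out.append(v)
        elif v.label is not None and v.label.name == "PATHOGENIC":
            out.append(v)
    return out


def compute_patho_maf_threshold(
    patho_variants: Sequence[AnnotatedVariant],
) -> Optional[float]:
    """Type-7 95th percentile of pathogenic allele frequencies.

    A variant absent from the population resource contributes frequency 0.
    Returns ``None`` on an empty pathogenic set.
    """
    if not patho_variants:
        return None
    return percentile_r7([v.af_or_zero for v in patho_variants], 0.95)


def impact_distribution(variants: Iterable[AnnotatedVariant]) -> ImpactDistribution:
    """Relative proportions of the four impact categories over ``variants``.

    Every variant must carry an impact annotation; an empty input yields
    the absent distribution.
    """
    return ImpactDistribution.from_variants(variants)


@dataclass(slots=True)
class MatchedBenignSet:
    """Result of building an impact/frequency-matched benign set.

    Conservation always holds:
    ``n_candidates == len(variants) + removed_known + removed_af + removed_stepover``.
    """

    variants: list[AnnotatedVariant]
    n_candidates: int
    removed_known: int
    removed_af: int
    removed_stepover: int
    infeasible: bool = False
    achieved_dist: ImpactDistribution = field(default_factory=ImpactDistribution.absent)
    prefilter_counts: dict[Impact, int] = field(default_factory=dict)

    @property
    def n_equalized(self) -> int:
        return len(self.variants)

    def conserved(self) -> bool:
        return (
            self.n_candidates
            == self.n_equalized + self.removed_known + self.removed_af + self.removed_stepover
        )


def _step_over_removals(n: int, r: int) -> set[int]:
    """Indices (0-based, position order) to remove: r interspersed of n.

    Each pass removes every ceil(remaining/need)-th surviving element,
    repeating until exactly ``r`` are gone.  Deterministic and order-stable.
    """
    if r <= 0:
        return set()
    if r >= n:
        return set(range(n))
    removed: set[int] = set()
    while len(removed) < r:
        remaining = [i for i in range(n) if i not in removed]
        need = r - len(removed)
        step = math.ceil(len(remaining) / need)
        for j in range(step - 1, len(remaining), step):
            if len(removed) < r:
                removed.add(remaining[j])
    return removed


def _largest_remainder(targets: dict[Impact, float], total: int) -> dict[Impact, int]:
    """Apportion ``total`` among impacts proportionally to ``targets``."""
    quotas = {c: targets.get(c, 0.0) * total for c in Impact}
    keep = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = total - sum(keep.values())
    for c in sorted(Impact, key=lambda c: quotas[c] - keep[c], reverse=True)[:short]:
        keep[c] += 1
    return keep


def match_benign_set(
    candidates: Sequence[AnnotatedVariant],
    known_patho: Sequence[AnnotatedVariant],
    maf_threshold: float,
    target_dist: ImpactDistribution,
) -> MatchedBenignSet:
    """Build the benign set matched to the pathogenic impact/MAF profile.

    Three deterministic stages:

    1. exclude candidates whose (chrom, pos, ref, alt) equals a known
       pathogenic variant;
    2. exclude candidates with allele frequency above ``maf_threshold``
       (absent frequency counts as 0, i.e. is retained);
    3. equalize the impact distribution to ``target_dist`` by removing
       interspersed variants (genomic-position order) from
       over-represented categories — the "step over" stage.  The largest
       achievable matched size is ``n* = min over categories c with
       target > 0 of floor(count_c / target_c)``; categories with target
       0 are removed entirely.

    If a target-required impact category has no surviving candidate the
    match is infeasible: an empty set is returned with ``infeasible=True``
    (the MAF_ONLY signal), never a silent approximation.
    """
    if not target_dist.defined:
        raise ValueError("target impact distribution is absent")

    known_sites = {v.site for v in known_patho}
    after_known = [v for v in candidates if v.site not in known_sites]
    removed_known = len(candidates) - len(after_known)

    survivors = [v for v in after_known if v.af_or_zero <= maf_threshold]
    removed_af = len(after_known) - len(survivors)

    for v in survivors:
        if v.impact is None:
            raise ValueError(
                f"candidate {v.chrom}:{v.pos} {v.ref}>{v.alt} has no impact annotation"
            )
    by_impact: dict[Impact, list[AnnotatedVariant]] = {c: [] for c in Impact}
    for v in sorted(survivors, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        by_impact[v.impact].append(v)
    prefilter_counts = {c: len(by_impact[c]) for c in Impact}

    targets = {c: target_dist.proportion(c) for c in Impact}
    required = [c for c in Impact if targets[c] > 0]
    n_star = min(
        (int(math.floor(prefilter_counts[c] / targets[c])) for c in required),
        default=0,
    )
    if n_star == 0:
        return MatchedBenignSet(
            variants=[],
            n_candidates=len(candidates),
            removed_known=removed_known,
            removed_af=removed_af,
            removed_stepover=len(survivors),
            infeasible=True,
            achieved_dist=ImpactDistribution.absent(),
            prefilter_counts=prefilter_counts,
        )

    keep = _largest_remainder(targets, n_star)
    kept: list[AnnotatedVariant] = []
    removed_stepover = 0
    for c in Impact:
        group = by_impact[c]
        r = len(group) - keep[c]
        removed_idx = _step_over_removals(len(group), r)
        removed_stepover += len(removed_idx)
        kept.extend(v for i, v in enumerate(group) if i not in removed_idx)

    return MatchedBenignSet(
        variants=kept,
        n_candidates=len(candidates),
        removed_known=removed_known,
        removed_af=removed_af,
        removed_stepover=removed_stepover,
        infeasible=False,
        achieved_dist=impact_distribution(kept),
        prefilter_counts=prefilter_counts,
    )


def _cadds(variants: Iterable[AnnotatedVariant]) -> list[float]:
    return [v.cadd for v in variants if v.cadd is not None]


def calibrate_gene(
    gene: str,
    patho: Sequence[AnnotatedVariant],
    candidates: Sequence[AnnotatedVariant],
    alpha: float = 0.05,
    min_n: int = 5,
) -> GeneCalibration:
    """Calibrate one gene, assigning exactly one of the seven categories.

    Decision order: NOT_CALIBRATED (fewer than 2 variants combined, or no
    pathogenic variants at all) → IMPACT_PREDICTIVE (some impact category
    occurs in pathogenic variants but never among frequency-filtered benign
    candidates, which themselves are non-empty; no CADD calibration is
    performed for these genes) → MAF_ONLY (no matched benign set could be
    formed) → LITTLE_DATA (fewer than ``min_n`` CADD-scored variants in
    either group) → ARTIFACT (significant but inverted: benign mean CADD
    above pathogenic) → CADD_PREDICTIVE / CADD_LESS_PREDICTIVE by the
    Mann–Whitney p-value at ``alpha``.
    """
    n_patho = len(patho)
    if n_patho + len(candidates) < 2 or n_patho == 0:
        return GeneCalibration(
            gene=gene, category=CalibrationCategory.NOT_CALIBRATED,
            n_patho=n_patho, n_benign=0,
        )

    maf_thr = compute_patho_maf_threshold(patho)
    patho_dist = impact_distribution(patho)
    match = match_benign_set(candidates, patho, maf_thr, patho_dist)

    prefilter_total = sum(match.prefilter_counts.values())
    if prefilter_total > 0:
        prefilter_dist = ImpactDistribution.from_counts(match.prefilter_counts)
        unique = patho_dist.supported() - prefilter_dist.supported()
        if unique:
            return GeneCalibration(
                gene=gene,
                category=CalibrationCategory.IMPACT_PREDICTIVE,
                patho_maf_threshold=maf_thr,
                patho_impact_dist=patho_dist,
                benign_impact_dist=prefilter_dist,
                n_patho=n_patho,
                n_benign=prefilter_total,
            )

    if match.infeasible or match.n_equalized == 0:
        return GeneCalibration(
            gene=gene,
            category=CalibrationCategory.MAF_ONLY,
            patho_maf_threshold=maf_thr,
            patho_impact_dist=patho_dist,
            n_patho=n_patho,
            n_benign=0,
        )

    benign = match.variants
    patho_cadds = _cadds(patho)
    benign_cadds = _cadds(benign)
    mean_p = fmean(patho_cadds) if patho_cadds else None
    mean_b = fmean(benign_cadds) if benign_cadds else None
    sens95 = percentile_r7(patho_cadds, 0.05) if patho_cadds else None
    spec95 = percentile_r7(benign_cadds, 0.95) if benign_cadds else None
    mwu_p = None
    if patho_cadds and benign_cadds:
        _, mwu_p = mann_whitney_u(patho_cadds, benign_cadds)

    common = dict(
        gene=gene,
        patho_maf_threshold=maf_thr,
        mean_patho_cadd=mean_p,
        mean_benign_cadd=mean_b,
        sens95_cadd=sens95,
        spec95_cadd=spec95,
        patho_impact_dist=patho_dist,
        benign_impact_dist=match.achieved_dist,
        mwu_p=mwu_p,
        n_patho=n_patho,
        n_benign=match.n_equalized,
    )

    if len(patho_cadds) < min_n or len(benign_cadds) < min_n:
        return GeneCalibration(category=CalibrationCategory.LITTLE_DATA, **common)
    if mwu_p < alpha and mean_b > mean_p:
        return GeneCalibration(category=CalibrationCategory.ARTIFACT, **common)
    if mwu_p < alpha:
        return GeneCalibration(category=CalibrationCategory.CADD_PREDICTIVE, **common)
    return GeneCalibration(category=CalibrationCategory.CADD_LESS_PREDICTIVE, **common)


def calibrate(
    patho_variants: Iterable[AnnotatedVariant],
    population_variants: Iterable[AnnotatedVariant],
    alpha: float = 0.05,
    min_n: int = 5,
) -> dict[str, GeneCalibration]:
    """Calibrate every gene appearing in either input set.

    Variants without a gene symbol are ignored (they cannot be calibrated).
    """
    patho_by_gene = group_by_gene(patho_variants)
    pop_by_gene = group_by_gene(population_variants)
    genes = (set(patho_by_gene) | set(pop_by_gene)) - {None}
    return {
        g: calibrate_gene(
            g, patho_by_gene.get(g, []), pop_by_gene.get(g, []), alpha=alpha, min_n=min_n
        )
        for g in sorted(genes)
    }


@dataclass(frozen=True, slots=True)
class GenomeWideDefaults:
    """Fallback thresholds: fixed CADD cutoff and the mean pathogenic MAF."""

    cadd_threshold: float = GENOME_WIDE_CADD_THRESHOLD
    maf_threshold: float = 0.00426  # published release mean of gene MAF thresholds


def genome_wide_defaults(
    calibrations: Mapping[str, GeneCalibration],
) -> GenomeWideDefaults:
    """Derive fallback thresholds from a calibration set.

    The CADD threshold is fixed at 15 (< benign, > pathogenic); the MAF
    threshold is the arithmetic mean of all present gene-specific
    pathogenic 95th-percentile MAF thresholds.
    """
    thresholds = [
        c.patho_maf_threshold
        for c in calibrations.values()
        if c.patho_maf_threshold is not None
    ]
    if not thresholds:
        raise ValueError("no gene calibration carries a pathogenic MAF threshold")
    return GenomeWideDefaults(
        cadd_threshold=GENOME_WIDE_CADD_THRESHOLD, maf_threshold=fmean(thresholds)
    )


def apply_sensitivity_adjustment(
    cal: GeneCalibration, setting: float = 5.0
) -> GeneCalibration:
    """Relax a gene's thresholds toward sensitivity by ``setting``.

    The calibration itself balances sensitivity and specificity; clinical
    screening values sensitivity more.  With adjustment ``s``:

    - pathogenic MAF threshold is multiplied by ``max(1, s)`` (harder to
      dismiss a variant as too common);
    - the pathogenic CADD decision bound becomes
      ``max(min(sens95, spec95), sens95 - s)`` — lowered from the
      sensitivity threshold toward the benign specificity threshold but
      never past it (stored in ``sens95_cadd`` of the returned copy).

    ``setting=0`` is the identity; both thresholds are monotone in the
    setting, so a larger setting never produces fewer pathogenic calls.
    """
    if setting < 0:
        raise ValueError(f"setting must be non-negative, got {setting}")
    out = cal.replace()
    if cal.patho_maf_threshold is not None:
        out = out.replace(patho_maf_threshold=cal.patho_maf_threshold * max(1.0, setting))
    if cal.sens95_cadd is not None:
        floor = cal.sens95_cadd if cal.spec95_cadd is None else min(
            cal.sens95_cadd, cal.spec95_cadd
        )
        out = out.replace(sens95_cadd=max(floor, cal.sens95_cadd - setting))
    return out


# Convenience used by the published-release reporting layer and tests: a
# regex equivalent of select_pathogenic's substring rule.
_PATHOGENIC_RE = re.compile("pathogenic", re.IGNORECASE)
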