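"""Rule cascade classifying variants as Benign / Pathogenic / VUS.

Per variant, in order:

1. **Gene MAF rule** — if the gene is calibrated with a pathogenic MAF
   threshold and the variant's population frequency exceeds the
   (sensitivity-adjusted) threshold, the variant is too common to be
   pathogenic in that gene: Benign.
2. **Impact rule** — for IMPACT_PREDICTIVE genes, an impact at or above
   the least-severe pathogenic-unique category is a direct Pathogenic
   call; an impact strictly below every pathogenic-observed category is
   Benign; otherwise fall through.
3. **Gene CADD rule** — for CADD-calibrated genes (CADD_PREDICTIVE,
   CADD_LESS_PREDICTIVE, LITTLE_DATA): CADD at or above the adjusted
   pathogenic bound is Pathogenic, at or below the benign specificity
   bound is Benign, in between is VUS (a gene-specific answer, not a
   failure; ``fallback_on_vus`` routes it to the fallback instead).
4. **Genome-wide fallback** — when no gene rule could apply (no or
   uninformative calibration, missing gene annotation): frequency above
   the genome-wide MAF threshold is Benign; otherwise CADD above 15 is
   Pathogenic, at or below 15 Benign (the boundary value is assigned to
   benign), and absent CADD is VUS.

Classification is deterministic and total: every variant receives
exactly one verdict and missing annotations degrade to VUS, never to an
exception.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Optional

from .calibration import GenomeWideDefaults, apply_sensitivity_adjustment
from .model import (
    AnnotatedVariant,
    CalibrationCategory,
    GeneCalibration,
    Judgment,
    JudgmentSource,
    Verdict,
)

__all__ = ["classify", "classify_stream", "summarize_judgments"]

_CADD_CATEGORIES = frozenset(
    {
        CalibrationCategory.CADD_PREDICTIVE,
        CalibrationCategory.CADD_LESS_PREDICTIVE,
        CalibrationCategory.LITTLE_DATA,
    }
)


def _fallback(
    v: AnnotatedVariant, defaults: GenomeWideDefaults, enabled: bool
) -> Judgment:
    if not enabled:
        return Judgment(
            Verdict.VUS, JudgmentSource.GENOME_WIDE, "NO_FALLBACK",
            "no gene-specific rule applied and the fallback is disabled",
        )
    if v.af_or_zero > defaults.maf_threshold:
        return Judgment(
            Verdict.BENIGN, JudgmentSource.GENOME_WIDE, "FALLBACK_MAF",
            f"allele frequency {v.af_or_zero:g} exceeds genome-wide "
            f"threshold {defaults.maf_threshold:g}",
        )
    if v.cadd is None:
        return Judgment(
            Verdict.VUS, JudgmentSource.GENOME_WIDE, "FALLBACK_NO_CADD",
            "no CADD score available for the genome-wide rule",
        )
    if v.cadd > defaults.cadd_threshold:
        return Judgment(
            Verdict.PATHOGENIC, JudgmentSource.GENOME_WIDE, "FALLBACK_CADD",
            f"CADD {v.cadd:g} above genome-wide threshold {defaults.cadd_threshold:g}",
        )
    return Judgment(
        Verdict.BENIGN, JudgmentSource.GENOME_WIDE, "FALLBACK_CADD",
        f"CADD {v.cadd:g} at or below genome-wide threshold "
        f"{defaults.cadd_threshold:g}",
    )


def classify(
    v: AnnotatedVariant,
    calibrations: Mapping[str, GeneCalibration],
    defaults: GenomeWideDefaults,
    setting: float = 5.0,
    fallback_on_vus: bool = False,
    use_fallback: bool = True,
) -> Judgment:
    """Classify one variant through the gene-specific cascade.

    ``setting`` is the sensitivity adjustment applied to gene thresholds
    (see :func:`gavin.calibration.apply_sensitivity_adjustment`).
    """
    cal: Optional[GeneCalibration] = (
        calibrations.get(v.gene) if v.gene is not None else None
    )
    if cal is None:
        return _fallback(v, defaults, use_fallback)

    adj = apply_sensitivity_adjustment(cal, setting)

    if adj.patho_maf_threshold is not None and v.af_or_zero > adj.patho_maf_threshold:
        return Judgment(
            Verdict.BENIGN, JudgmentSource.GENE_SPECIFIC, "MAF_ABOVE_THRESHOLD",
            f"allele frequency {v.af_or_zero:g} exceeds adjusted pathogenic "
            f"MAF threshold {adj.patho_maf_threshold:g} for {cal.gene}",
        )

    if cal.category is CalibrationCategory.IMPACT_PREDICTIVE and v.impact is not None:
        unique = cal.pathogenic_unique_impacts()
        observed = cal.patho_impact_dist.supported()
        if unique:
            least_unique = min(i.severity for i in unique)
            if v.impact.severity >= least_unique:
                return Judgment(
                    Verdict.PATHOGENIC, JudgmentSource.GENE_SPECIFIC, "IMPACT_DIRECT",
                    f"impact {v.impact.value} reaches the pathogenic-unique "
                    f"impact range of {cal.gene}",
                )
        if observed and v.impact.severity < min(i.severity for i in observed):
            return Judgment(
                Verdict.BENIGN, JudgmentSource.GENE_SPECIFIC, "IMPACT_BELOW_PATHOGENIC",
                f"impact {v.impact.value} below every pathogenic-observed "
                f"impact of {cal.gene}",
            )
        # interleaved impact: no gene-specific impact decision possible

    if cal.category in _CADD_CATEGORIES:
        patho_bound = adj.sens95_cadd
        benign_bound = adj.spec95_cadd
        if patho_bound is None and benign_bound is None:
            return _fallback(v, defaults, use_fallback)
        if v.cadd is None:
            return Judgment(
                Verdict.VUS, JudgmentSource.GENE_SPECIFIC, "NO_CADD",
                f"{cal.gene} is CADD-calibrated but the variant has no CADD score",
            )
        if patho_bound is not None and v.cadd >= patho_bound:
            return Judgment(
                Verdict.PATHOGENIC, JudgmentSource.GENE_SPECIFIC, "CADD_ABOVE_SENS95",
                f"CADD {v.cadd:g} at or above adjusted pathogenic bound "
                f"{patho_bound:g} for {cal.gene}",
            )
        if benign_bound is not None and v.cadd <= benign_bound:
            return Judgment(
                Verdict.BENIGN, JudgmentSource.GENE_SPECIFIC, "CADD_BELOW_SPEC95",
                f"CADD {v.cadd:g} at or below benign bound {benign_bound:g} "
                f"for {cal.gene}",
            )
        if fallback_on_vus:
            return _fallback(v, defaults, use_fallback)
        return Judgment(
            Verdict.VUS, JudgmentSource.GENE_SPECIFIC, "CADD_INBETWEEN",
            f"CADD {v.cadd:g} between the benign and pathogenic bounds of {cal.gene}",
        )

    # MAF_ONLY / NOT_CALIBRATED / ARTIFACT / impact rule fell through:
    # no further gene-specific rule exists.
    return _fallback(v, defaults, use_fallback)


def classify_stream(
    variants: Iterable[AnnotatedVariant],
    calibrations: Mapping[str, GeneCalibration],
    defaults: GenomeWideDefaults,
    **kwargs,
) -> Iterator[tuple[AnnotatedVariant, Judgment]]:
    """Order-preserving lazy map of :func:`classify` over a variant stream."""
    for v in variants:
        yield v, classify(v, calibrations, defaults, **kwargs)


def summarize_judgments(
    pairs: Iterable[tuple[AnnotatedVariant, Judgment]],
) -> tuple[dict[Verdict, int], dict[str, int]]:
    """Tally judgments per verdict and per fired rule."""
    by_verdict: dict[Verdict, int] = {v: 0 for v in Verdict}
    by_rule: dict[str, int] = {}
    for _, j in pairs:
        by_verdict[j.verdict] += 1
        by_rule[j.rule] = by_rule.get(j.rule, 0) + 1
    return by_verdict, by_rule
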