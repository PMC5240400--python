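"""Reproducibility studies on synthetic cohorts.

Self-contained experiments that exercise the full pipeline — generate,
calibrate, classify, score — and return the quantities a user would
inspect to judge the method: category recovery rates across seeds, the
gene-specific vs genome-wide bootstrap comparison on dispersed-cutoff
cohorts, the sensitivity-adjustment sweep, and the matched-benign-set
accounting of the MYH7-style worked example.  Problem sizes default to
values that keep each study in the seconds-to-a-minute range on one
core while leaving the planted effects far above sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .benchmark import BootstrapResult, bootstrap_compare, score
from .calibration import (
    calibrate_gene,
    compute_patho_maf_threshold,
    impact_distribution,
    match_benign_set,
    MatchedBenignSet,
)
from .estimator import GavinClassifier, GenomeWideClassifier
from .model import Label
from .simulate import (
    dispersed_cutoff_scenarios,
    generate_cohort,
    generate_gene,
    myh7_like_fixture,
    scenario_presets,
)

__all__ = [
    "category_recovery_rate",
    "threshold_comparison_study",
    "sensitivity_sweep",
    "myh7_accounting",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def category_recovery_rate(
    preset: str, n_seeds: int = 1000, seed: int = 0
) -> float:
    """Fraction of seeds on which a preset calibrates to its planted category."""
    sc = scenario_presets()[preset]
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        patho, cands = generate_gene(sc, seed=s)
        cal = calibrate_gene(sc.gene, patho, cands)
        hits += cal.category.value == sc.planted_category
    return hits / n_seeds


def threshold_comparison_study(
    seed: int = 0,
    n_genes: int = 12,
    n_samples: int = 1000,
    n_benign: int = 100,
    n_patho: int = 100,
) -> BootstrapResult:
    """Bootstrap gene-specific vs genome-wide accuracy on dispersed cutoffs.

    Genes get optimal CADD cutoffs spread uniformly over [10, 30], so a
    single genome-wide cutoff is badly placed for many of them.  A
    training cohort calibrates the gene-specific classifier; an
    independently generated evaluation cohort from the same scenarios is
    bootstrapped (``n_samples`` replicates of ``n_benign`` + ``n_patho``
    with replacement) under both classifiers on the same samples.
    """
    train_seed, eval_seed, boot_seed = _child_seeds(seed, 3)
    scenarios = dispersed_cutoff_scenarios(n_genes, seed=seed)
    train_p, train_c = generate_cohort(scenarios, seed=train_seed)
    gene_specific = GavinClassifier().fit(train_p + train_c)
    genome_wide = GenomeWideClassifier(
        cadd_threshold=gene_specific.defaults_.cadd_threshold,
        maf_threshold=gene_specific.defaults_.maf_threshold,
    ).fit()
    eval_p, eval_c = generate_cohort(scenarios, seed=eval_seed)
    pool = eval_p + eval_c
    return bootstrap_compare(
        pool,
        gene_specific.predict,
        genome_wide.predict,
        n_samples=n_samples,
        n_benign=n_benign,
        n_patho=n_patho,
        seed=boot_seed,
    )


@dataclass(frozen=True, slots=True)
class SweepPoint:
    setting: float
    sensitivity: float
    specificity: float


def sensitivity_sweep(
    settings: Sequence[float] = tuple(range(11)),
    seed: int = 0,
    n_genes: int = 8,
) -> list[SweepPoint]:
    """Sensitivity/specificity across sensitivity-adjustment settings.

    Calibrates once on a training cohort, then re-scores a fixed
    evaluation cohort under each setting.  Relaxing thresholds toward
    sensitivity can only add pathogenic calls, so sensitivity is
    non-decreasing and specificity non-increasing along the sweep.
    """
    train_seed, eval_seed = _child_seeds(seed, 2)
    scenarios = dispersed_cutoff_scenarios(n_genes, seed=seed)
    train_p, train_c = generate_cohort(scenarios, seed=train_seed)
    eval_p, eval_c = generate_cohort(scenarios, seed=eval_seed)
    pool = eval_p + eval_c
    truth = [v.label for v in pool]
    base = GavinClassifier().fit(train_p + train_c)
    out = []
    for s in settings:
        clf = GavinClassifier.from_calibrations(
            base.calibrations_, base.defaults_, setting=float(s)
        )
        counts, sens, spec, _ = score(list(zip(truth, clf.predict(pool))))
        out.append(SweepPoint(setting=float(s), sensitivity=sens, specificity=spec))
    return out


def myh7_accounting() -> tuple[float, MatchedBenignSet]:
    """Run matched-benign-set construction on the MYH7-style fixture.

    Returns the pathogenic MAF threshold and the full stage accounting
    (candidates, known-pathogenic / frequency / step-over removals,
    equalized set and its impact distribution).
    """
    patho, cands = myh7_like_fixture()
    thr = compute_patho_maf_threshold(patho)
    res = match_benign_set(cands, patho, thr, impact_distribution(patho))
    return thr, res
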