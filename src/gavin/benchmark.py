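"""Three-state benchmark metrics, panel stratification, and the
bootstrap comparison of classifiers.

A three-outcome classifier (Benign / Pathogenic / VUS) cannot be scored
with plain binary metrics: abstentions must count against recall.  The
definitions used here fold VUS calls and unclassified variants into
"missed" terms:

    sensitivity = TP / (TP + FN + MissedPositive)
    specificity = TN / (TN + FP + MissedNegative)
    accuracy    = (TP + TN) / (TP + TN + FP + FN + MissedPos + MissedNeg)

Positive/negative predictive values, by contrast, are computed over
*classified* variants only (TP/(TP+FP), TN/(TN+FN)), which is the fair
way to score deliberately abstaining ("picky") predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .model import AnnotatedVariant, Label, Verdict
from .stats import mann_whitney_u

__all__ = [
    "BenchmarkCounts",
    "score",
    "predictive_values",
    "stratify",
    "bootstrap_compare",
    "BootstrapResult",
]


@dataclass(frozen=True, slots=True)
class BenchmarkCounts:
    """Six-cell confusion accounting for a three-outcome classifier."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    missed_pos: int = 0
    missed_neg: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn, self.missed_pos, self.missed_neg) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pathogenic(self) -> int:
        return self.tp + self.fn + self.missed_pos

    @property
    def n_benign(self) -> int:
        return self.tn + self.fp + self.missed_neg

    @property
    def total(self) -> int:
        return self.n_pathogenic + self.n_benign

    @property
    def sensitivity(self) -> Optional[float]:
        return self.tp / self.n_pathogenic if self.n_pathogenic else None

    @property
    def specificity(self) -> Optional[float]:
        return self.tn / self.n_benign if self.n_benign else None

    @property
    def accuracy(self) -> Optional[float]:
        return (self.tp + self.tn) / self.total if self.total else None


_TruthVerdict = tuple[Union[Label, str], Union[Verdict, str, None]]


def score(
    judgments: Iterable[_TruthVerdict],
) -> tuple[BenchmarkCounts, Optional[float], Optional[float], Optional[float]]:
    """Score (truth, verdict) pairs; VUS / None verdicts count as missed.

    Truth labels must be binary (Benign or Pathogenic); a VUS truth label
    raises, since uncertain truth cannot anchor a benchmark.
    Returns ``(counts, sensitivity, specificity, accuracy)``.
    """
    tp = tn = fp = fn = mp = mn = 0
    for truth, verdict in judgments:
        truth = Label(truth)
        if truth is Label.VUS:
            raise ValueError("truth labels must be binary (Benign/Pathogenic)")
        v = None if verdict is None else Verdict(verdict)
        if truth is Label.PATHOGENIC:
            if v is Verdict.PATHOGENIC:
                tp += 1
            elif v is Verdict.BENIGN:
                fn += 1
            else:
                mp += 1
        else:
            if v is Verdict.BENIGN:
                tn += 1
            elif v is Verdict.PATHOGENIC:
                fp += 1
            else:
                mn += 1
    counts = BenchmarkCounts(tp=tp, tn=tn, fp=fp, fn=fn, missed_pos=mp, missed_neg=mn)
    return counts, counts.sensitivity, counts.specificity, counts.accuracy


def predictive_values(
    counts: BenchmarkCounts,
) -> tuple[Optional[float], Optional[float]]:
    """(PPV, NPV) over classified variants only; missed variants excluded."""
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else None
    return ppv, npv


NOT_IN_CGD = "NotInCGD"


def stratify(
    variants: Sequence[AnnotatedVariant],
    cgd: Mapping[str, set[str]],
) -> dict[str, list[AnnotatedVariant]]:
    """Assign variants to manifestation panels by gene.

    A variant enters every panel of every one of its genes but at most
    once per panel (variant instances sharing a site are deduplicated
    within a panel).  A variant lands in the ``NotInCGD`` panel only if
    none of its genes occur in the CGD map.
    """
    panels: dict[str, list[AnnotatedVariant]] = {}
    seen: dict[str, set[tuple]] = {}
    # genes per site, so multi-gene variants are judged on all their genes
    genes_by_site: dict[tuple, set[str]] = {}
    for v in variants:
        if v.gene is not None:
            genes_by_site.setdefault(v.site, set()).add(v.gene)

    def _add(panel: str, v: AnnotatedVariant) -> None:
        if v.site not in seen.setdefault(panel, set()):
            seen[panel].add(v.site)
            panels.setdefault(panel, []).append(v)

    for v in variants:
        site_genes = genes_by_site.get(v.site, set())
        in_cgd = any(g in cgd for g in site_genes)
        if v.gene is not None and v.gene in cgd:
            for category in sorted(cgd[v.gene]):
                _add(category, v)
        elif not in_cgd:
            _add(NOT_IN_CGD, v)
    return panels


@dataclass(frozen=True, slots=True)
class BootstrapResult:
    accuracies_a: np.ndarray
    accuracies_b: np.ndarray
    median_a: float
    median_b: float
    mwu_p: float


Classifier = Callable[[Sequence[AnnotatedVariant]], Sequence[Union[Verdict, str, None]]]


def bootstrap_compare(
    variants: Sequence[AnnotatedVariant],
    classifier_a: Classifier,
    classifier_b: Classifier,
    n_samples: int = 10_000,
    n_benign: int = 100,
    n_patho: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap accuracy comparison of two classifiers on one variant pool.

    Each replicate samples, with replacement, ``n_benign`` truth-benign and
    ``n_patho`` truth-pathogenic variants and computes three-state accuracy
    for both classifiers *on the same sample*.  Each classifier is a
    callable mapping a variant sequence to verdicts; classification being
    deterministic per variant, both are evaluated once on the full pool and
    replicates are index resamples.  Returns both accuracy distributions,
    their medians, and a two-sided Mann–Whitney p-value comparing them.
    """
    benign = [v for v in variants if v.label is Label.BENIGN]
    patho = [v for v in variants if v.label is Label.PATHOGENIC]
    if len(benign) < n_benign:
        raise ValueError(
            f"insufficient benign variants: need {n_benign}, have {len(benign)}"
        )
    if len(patho) < n_patho:
        raise ValueError(
            f"insufficient pathogenic variants: need {n_patho}, have {len(patho)}"
        )

    pool = benign + patho
    truth = np.array([v.label is Label.PATHOGENIC for v in pool])

    def _correct(clf: Classifier) -> np.ndarray:
        verdicts = list(clf(pool))
        if len(verdicts) != len(pool):
            raise ValueError("classifier returned a verdict count != input count")
        pred_p = np.array([Verdict(x) is Verdict.PATHOGENIC if x is not None else False
                           for x in verdicts])
        pred_b = np.array([Verdict(x) is Verdict.BENIGN if x is not None else False
                           for x in verdicts])
        return np.where(truth, pred_p, pred_b)

    correct_a = _correct(classifier_a)
    correct_b = _correct(classifier_b)

    rng = np.random.default_rng(seed)
    idx_benign = rng.integers(0, len(benign), size=(n_samples, n_benign))
    idx_patho = rng.integers(len(benign), len(pool), size=(n_samples, n_patho))
    idx = np.concatenate([idx_benign, idx_patho], axis=1)
    denom = n_benign + n_patho
    acc_a = correct_a[idx].sum(axis=1) / denom
    acc_b = correct_b[idx].sum(axis=1) / denom

    if np.array_equal(acc_a, acc_b):
        p = 1.0
    else:
        _, p = mann_whitney_u(acc_a, acc_b)
    return BootstrapResult(
        accuracies_a=acc_a,
        accuracies_b=acc_b,
        median_a=float(np.median(acc_a)),
        median_b=float(np.median(acc_b)),
        mwu_p=p,
    )
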