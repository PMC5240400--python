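"""Scikit-learn-style estimators wrapping calibration and classification.

:class:`GavinClassifier` learns per-gene thresholds from a labelled
training set (``fit``) and classifies variants with the gene-specific
cascade plus genome-wide fallback (``predict``).
:class:`GenomeWideClassifier` applies only the fixed fallback rules.
Both follow sklearn conventions — ``get_params``/``set_params``,
fitted attributes with trailing underscores, ``check_is_fitted`` — and
accept either a sequence of :class:`~gavin.model.AnnotatedVariant` or a
DataFrame with columns ``chrom, pos, ref, alt, gene, impact, cadd, af``
(missing coordinate columns are synthesized, since only calibration
order and known-site exclusion depend on them).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .benchmark import score as _score
from .calibration import (
    GenomeWideDefaults,
    calibrate,
    genome_wide_defaults,
    select_pathogenic,
)
from .classify import classify
from .model import AnnotatedVariant, Judgment, Label, Verdict

__all__ = ["GavinClassifier", "GenomeWideClassifier", "frame_to_variants"]

VariantsLike = Union[Sequence[AnnotatedVariant], pd.DataFrame]


def frame_to_variants(X: pd.DataFrame) -> list[AnnotatedVariant]:
    """Convert a variant DataFrame into AnnotatedVariants.

    Recognized columns: chrom, pos, ref, alt, gene, impact, cadd, af,
    label, significance.  Absent coordinate columns get synthetic,
    row-order defaults; NaN cells become absent values.
    """
    n = len(X)

    def col(name, default):
        if name in X.columns:
            return list(X[name])
        return [default(i) for i in range(n)]

    def opt(x):
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        if isinstance(x, str) and not x:
            return None
        return x

    chrom = col("chrom", lambda i: "chrS")
    pos = col("pos", lambda i: i + 1)
    ref = col("ref", lambda i: "A")
    alt = col("alt", lambda i: "G")
    gene = col("gene", lambda i: None)
    impact = col("impact", lambda i: None)
    cadd = col("cadd", lambda i: None)
    af = col("af", lambda i: None)
    label = col("label", lambda i: None)
    sig = col("significance", lambda i: None)
    return [
        AnnotatedVariant(
            chrom=str(chrom[i]),
            pos=int(pos[i]),
            ref=str(ref[i]),
            alt=str(alt[i]),
            gene=opt(gene[i]),
            impact=opt(impact[i]),
            cadd=opt(cadd[i]),
            af=opt(af[i]),
            label=opt(label[i]),
            significance=opt(sig[i]),
        )
        for i in range(n)
    ]


def _as_variants(X: VariantsLike) -> list[AnnotatedVariant]:
    if isinstance(X, pd.DataFrame):
        return frame_to_variants(X)
    return list(X)


class GavinClassifier(BaseEstimator):
    """Gene-aware Benign/Pathogenic/VUS classifier.

    Parameters
    ----------
    alpha : float
        Significance level of the per-gene Mann–Whitney CADD test.
    min_n : int
        Minimum CADD-scored variants per group for the CADD categories.
    setting : float
        Sensitivity adjustment applied to gene thresholds at predict time.
    fallback_on_vus : bool
        Route the gene-specific "CADD in between" zone to the genome-wide
        fallback instead of returning VUS.
    use_fallback : bool
        Disable to return VUS wherever the fallback would have fired.

    Attributes
    ----------
    calibrations_ : dict[str, GeneCalibration]
        Per-gene thresholds learned by ``fit``.
    defaults_ : GenomeWideDefaults
        Genome-wide fallback thresholds (CADD fixed at 15; MAF the mean
        of gene-specific pathogenic MAF thresholds).
    classes_ : ndarray of str
        ``["Benign", "Pathogenic", "VUS"]``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        min_n: int = 5,
        setting: float = 5.0,
        fallback_on_vus: bool = False,
        use_fallback: bool = True,
    ):
        self.alpha = alpha
        self.min_n = min_n
        self.setting = setting
        self.fallback_on_vus = fallback_on_vus
        self.use_fallback = use_fallback

    @classmethod
    def from_calibrations(
        cls,
        calibrations,
        defaults: Optional[GenomeWideDefaults] = None,
        **params,
    ) -> "GavinClassifier":
        """Build a ready-to-predict classifier from a calibration table."""
        est = cls(**params)
        est.calibrations_ = dict(calibrations)
        if defaults is None:
            try:
                defaults = genome_wide_defaults(est.calibrations_)
            except ValueError:
                defaults = GenomeWideDefaults()
        est.defaults_ = defaults
        est.classes_ = np.array([v.value for v in Verdict])
        return est

    def fit(self, X: VariantsLike, y: Optional[Sequence] = None) -> "GavinClassifier":
        """Calibrate per-gene thresholds from labelled training variants.

        ``y``, when given, holds training labels ("Pathogenic" marks the
        pathogenic set; everything else is a population candidate).  When
        ``y`` is omitted, the variants' own significance/label annotations
        are used via the "contains pathogenic" selection rule.
        """
        variants = _as_variants(X)
        if y is not None:
            y = [Label(v) if not isinstance(v, Label) else v for v in y]
            if len(y) != len(variants):
                raise ValueError("X and y length mismatch")
            patho = [v for v, lab in zip(variants, y) if lab is Label.PATHOGENIC]
            candidates = [v for v, lab in zip(variants, y) if lab is not Label.PATHOGENIC]
        else:
            patho = select_pathogenic(variants)
            patho_ids = {id(v) for v in patho}
            candidates = [v for v in variants if id(v) not in patho_ids]
        self.calibrations_ = calibrate(
            patho, candidates, alpha=self.alpha, min_n=self.min_n
        )
        try:
            self.defaults_ = genome_wide_defaults(self.calibrations_)
        except ValueError:
            self.defaults_ = GenomeWideDefaults()
        self.classes_ = np.array([v.value for v in Verdict])
        self.n_features_in_ = len(variants)
        return self

    def predict_judgments(self, X: VariantsLike) -> list[Judgment]:
        """Full judgments (verdict, source, rule, reason) per variant."""
        check_is_fitted(self, "calibrations_")
        return [
            classify(
                v,
                self.calibrations_,
                self.defaults_,
                setting=self.setting,
                fallback_on_vus=self.fallback_on_vus,
                use_fallback=self.use_fallback,
            )
            for v in _as_variants(X)
        ]

    def predict(self, X: VariantsLike) -> np.ndarray:
        """Verdict strings ("Benign" / "Pathogenic" / "VUS") per variant."""
        return np.array([j.verdict.value for j in self.predict_judgments(X)])

    def score(self, X: VariantsLike, y: Sequence) -> float:
        """Three-state accuracy against binary truth labels ``y``.

        VUS predictions count against accuracy (missed), per the metric
        definitions in :mod:`gavin.benchmark`.
        """
        verdicts = self.predict(X)
        _, _, _, acc = _score(list(zip(y, verdicts)))
        return acc if acc is not None else 0.0


class GenomeWideClassifier(BaseEstimator):
    """Fixed-threshold fallback classifier (no gene-specific rules).

    Frequency above ``maf_threshold`` is Benign; otherwise CADD above
    ``cadd_threshold`` is Pathogenic, at or below it Benign, absent VUS.
    """

    def __init__(self, cadd_threshold: float = 15.0, maf_threshold: float = 0.00426):
        self.cadd_threshold = cadd_threshold
        self.maf_threshold = maf_threshold

    def fit(self, X: Optional[VariantsLike] = None, y=None) -> "GenomeWideClassifier":
        self.defaults_ = GenomeWideDefaults(
            cadd_threshold=self.cadd_threshold, maf_threshold=self.maf_threshold
        )
        self.classes_ = np.array([v.value for v in Verdict])
        return self

    def predict_judgments(self, X: VariantsLike) -> list[Judgment]:
        check_is_fitted(self, "defaults_")
        return [classify(v, {}, self.defaults_) for v in _as_variants(X)]

    def predict(self, X: VariantsLike) -> np.ndarray:
        return np.array([j.verdict.value for j in self.predict_judgments(X)])

    def score(self, X: VariantsLike, y: Sequence) -> float:
        verdicts = self.predict(X)
        _, _, _, acc = _score(list(zip(y, verdicts)))
        return acc if acc is not None else 0.0
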