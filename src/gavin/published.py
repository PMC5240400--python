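"""Summary of the original GAVIN calibration release (ClinVar Nov 2015).

Shipped for reference and reporting, in the spirit of the example
datasets bundled with statsmodels: the per-dataset benchmark sizes, the
seven-way gene calibration partition, the genome-wide fallback
thresholds, the release-wide CADD group means, and the MYH7 worked
example of matched-benign-set construction.  The reporting helpers
recompute the release's arithmetic (totals, partitions, mean
separations) from these inputs rather than hard-coding results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import CalibrationCategory

__all__ = [
    "BenchmarkDataset",
    "BENCHMARK_DATASETS",
    "GENE_CATEGORY_COUNTS",
    "RELEASE_MEAN_PATHO_CADD",
    "RELEASE_MEAN_BENIGN_CADD",
    "RELEASE_GENOME_WIDE_MAF",
    "MYH7_EXAMPLE",
    "Myh7Example",
    "combined_totals",
    "category_partition_total",
    "informative_calibrations",
    "mean_cadd_separation",
]


@dataclass(frozen=True, slots=True)
class BenchmarkDataset:
    name: str
    n_benign: int
    n_pathogenic: int

    @property
    def total(self) -> int:
        return self.n_benign + self.n_pathogenic


#: The six expert-classified benchmark sets of the original evaluation.
BENCHMARK_DATASETS: tuple[BenchmarkDataset, ...] = (
    BenchmarkDataset("VariBench tolerance DS7, training set", 11_347, 6_143),
    BenchmarkDataset("VariBench tolerance DS7, test set", 1_377, 510),
    BenchmarkDataset("MutationTaster2 benchmark set", 1_194, 161),
    BenchmarkDataset("ClinVar additions Nov 2015 - Feb 2016", 1_668, 1_688),
    BenchmarkDataset("UMCG diagnostic interpretation list", 1_176, 174),
    BenchmarkDataset("UMCG familial cancer list", 301, 26),
)

#: Seven-way partition of the 3237 calibrated genes in the release.
GENE_CATEGORY_COUNTS: dict[CalibrationCategory, int] = {
    CalibrationCategory.CADD_PREDICTIVE: 681,
    CalibrationCategory.CADD_LESS_PREDICTIVE: 732,
    CalibrationCategory.LITTLE_DATA: 774,
    CalibrationCategory.IMPACT_PREDICTIVE: 159,
    CalibrationCategory.MAF_ONLY: 178,
    CalibrationCategory.NOT_CALIBRATED: 712,
    CalibrationCategory.ARTIFACT: 1,
}

#: Release-wide mean of per-gene mean CADD scores, by group.
RELEASE_MEAN_PATHO_CADD = 28.44
RELEASE_MEAN_BENIGN_CADD = 23.08

#: Genome-wide fallback MAF (mean of gene pathogenic 95th-percentile MAFs).
RELEASE_GENOME_WIDE_MAF = 0.00426


@dataclass(frozen=True, slots=True)
class Myh7Example:
    """Published MYH7 worked example of matched benign-set construction."""

    n_pathogenic: int = 407
    patho_impact_counts: tuple[int, int, int, int] = (22, 315, 70, 0)  # H/M/L/Mod
    maf_threshold: float = 4.942e-5
    n_candidates: int = 1_799
    n_known_pathogenic_overlap: int = 99
    n_above_maf: int = 246


MYH7_EXAMPLE = Myh7Example()


def combined_totals(
    datasets: Sequence[BenchmarkDataset] = BENCHMARK_DATASETS,
) -> tuple[int, int, int]:
    """(n_benign, n_pathogenic, total) summed over benchmark datasets."""
    nb = sum(d.n_benign for d in datasets)
    np_ = sum(d.n_pathogenic for d in datasets)
    return nb, np_, nb + np_


def category_partition_total(
    counts: Mapping[CalibrationCategory, int] = GENE_CATEGORY_COUNTS,
) -> int:
    """Total genes across the seven calibration categories (a partition)."""
    return sum(counts[c] for c in CalibrationCategory)


def informative_calibrations(
    counts: Mapping[CalibrationCategory, int] = GENE_CATEGORY_COUNTS,
) -> int:
    """Genes with any learned rule: all categories except NOT_CALIBRATED."""
    return sum(
        n for c, n in counts.items() if c is not CalibrationCategory.NOT_CALIBRATED
    )


def mean_cadd_separation(
    mean_patho: float = RELEASE_MEAN_PATHO_CADD,
    mean_benign: float = RELEASE_MEAN_BENIGN_CADD,
) -> float:
    """Gene-averaged pathogenic-minus-benign mean CADD difference."""
    return mean_patho - mean_benign
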