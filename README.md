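# gavin-calib

Gene-aware variant classification for clinical sequencing: a Python
implementation of the GAVIN protocol. Variants annotated with a SnpEff
effect impact, a scaled CADD score and a population allele frequency are
classified as **Benign**, **Pathogenic** or **VUS** using per-gene
thresholds calibrated on matched pathogenic/benign variant sets, with
fixed genome-wide rules (CADD 15, MAF 0.00426) as a fallback.

It is aimed at people building or evaluating variant-prioritization
pipelines: it provides the calibration procedure itself, a classifier
with an auditable rule trail, missed-aware benchmark metrics for
three-outcome classifiers, CGD-style panel stratification, bootstrap
classifier comparison, and a synthetic-data generator that makes the
whole pipeline testable without any external downloads.

## The method in brief

For each gene with labelled training variants:

- the **pathogenic MAF threshold** is the Hyndman–Fan type-7 95th
  percentile of the pathogenic variants' allele frequencies (absent from
  the population = 0);
- a **matched benign set** is built from population candidates by
  excluding known pathogenic sites, filtering to the pathogenic
  frequency range, and equalizing the impact distribution with a
  deterministic "step-over" downsampling — removing the
  consequence/rarity bias that otherwise inflates apparent score
  separation;
- on the matched sets the calibration records mean CADD per group, the
  95%-sensitivity bound (5th percentile of pathogenic CADDs), the
  95%-specificity bound (95th percentile of benign CADDs) and a
  Mann–Whitney U test, then assigns one of seven categories:
  `CADD_PREDICTIVE`, `CADD_LESS_PREDICTIVE`, `LITTLE_DATA`,
  `IMPACT_PREDICTIVE`, `MAF_ONLY`, `NOT_CALIBRATED`, `ARTIFACT`.

Classification walks a fixed cascade — gene MAF rule, impact rule, gene
CADD bounds (relaxed toward sensitivity by an adjustable `setting`,
default 5), genome-wide fallback — and is deterministic and total.
Details, design rationale and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from gavin import GavinClassifier
from gavin.simulate import GeneScenario, generate_cohort

# two genes: one with clear CADD separation, one with none
scenarios = [
    GeneScenario(gene="G1", patho_cadd_mean=30.0, benign_cadd_mean=18.0),
    GeneScenario(gene="G2", patho_cadd_mean=20.0, benign_cadd_mean=20.0),
]
patho, population = generate_cohort(scenarios, seed=11)

clf = GavinClassifier().fit(patho + population)
for gene, cal in clf.calibrations_.items():
    print(gene, cal.category.value, f"p={cal.mwu_p:.3g}",
          f"sens95={cal.sens95_cadd:.2f}", f"spec95={cal.spec95_cadd:.2f}")

j = clf.predict_judgments(patho[:1])[0]
print(j.verdict.value, "|", j.rule, "|", j.reason)
```

prints

```
G1 CADD_PREDICTIVE p=4.03e-26 sens95=25.27 spec95=22.97
G2 CADD_LESS_PREDICTIVE p=0.927 sens95=14.69 spec95=24.78
Pathogenic | CADD_ABOVE_SENS95 | CADD 29.8894 at or above adjusted pathogenic bound 22.9679 for G1
```

G1's pathogenic and matched-benign CADD distributions separate (tiny
Mann–Whitney p), so the gene gets its own decision bounds; G2's do not,
and its calls will lean on the wider bounds and the fallback. The
judgment carries the fired rule and a human-readable reason, so every
call is auditable.

The same operations are exposed on the command line:

```bash
gavin simulate --preset cadd_predictive --genes 3 --seed 7 --out-dir fx/
gavin calibrate --pathogenic fx/pathogenic.vcf --population fx/population.vcf --out genes.tsv
gavin classify  --vcf fx/population.vcf --calibration genes.tsv --out classified.vcf
gavin benchmark --classified classified.vcf --truth fx/truth.tsv --report report.tsv
```

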