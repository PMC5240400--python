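# Methods

## The problem

Clinical sequencing produces thousands of variants per genome that must
be sorted into benign, pathogenic, or uncertain (VUS). CADD-style
deleteriousness scores rank variants well, but a single genome-wide
cutoff is a poor classifier because genes differ in their tolerance to
damaging variation: the optimal boundary between benign and pathogenic
CADD scores is gene-specific. A second, subtler problem is calibration
bias — typical benign variants are more common and of milder consequence
than pathogenic ones, so a naive comparison of score distributions
overstates any predictor's power. This package implements a gene-aware
classification protocol (the GAVIN method) that addresses both: it
calibrates thresholds per gene on *matched* pathogenic/benign sets, and
falls back to fixed genome-wide rules where per-gene evidence is
lacking.

## Calibration

Inputs per gene: a set of pathogenic variants (clinical-significance
strings containing "pathogenic", case-insensitively, so likely
pathogenic is included) and a set of population candidate variants, all
annotated with a SnpEff effect impact (HIGH/MODERATE/LOW/MODIFIER), a
scaled CADD score, and a population minor allele frequency (MAF; absent
means not observed, mapped to 0 inside calibration).

1. **Pathogenic MAF threshold.** The 95th percentile of the pathogenic
   variants' MAFs, Hyndman–Fan type-7 (`h = (n-1)p + 1`, linear
   interpolation between order statistics). This bounds the frequency
   range in which pathogenic variants of that gene live.
2. **Matched benign set.** Starting from the population candidates:
   (a) remove any candidate at a known pathogenic site
   (chrom, pos, ref, alt identity); (b) remove candidates with MAF above
   the pathogenic MAF threshold; (c) equalize the effect-impact
   distribution to the pathogenic one by the deterministic *step-over*
   scheme. The largest achievable matched size is
   `n* = min over impact categories c with target_c > 0 of
   floor(count_c / target_c)`; categories with target 0 are removed
   entirely; per-category keep counts are apportioned by largest
   remainder (so achieved proportions deviate from the target by at most
   `1/n*`), and the removals within a category take every
   `ceil(remaining/needed)`-th variant in genomic-position order,
   repeating passes until the quota is met — deterministic, order-stable
   and interspersed. If a required category has no surviving candidate,
   the match is infeasible and is flagged, never approximated.
3. **CADD statistics** on the matched sets: group means, the
   95th-percentile *sensitivity* threshold (type-7 5th percentile of
   pathogenic CADDs — exceeded by 95% of pathogenic variants), the
   95th-percentile *specificity* threshold (type-7 95th percentile of
   benign CADDs), and a two-sided Mann–Whitney U test of the two CADD
   samples (exact enumeration when both n ≤ 8 without ties, otherwise
   the tie-corrected normal approximation without continuity correction,
   so identical samples give p = 1 exactly).
4. **Category assignment**, in this order, each gene getting exactly one
   of seven categories: `NOT_CALIBRATED` (fewer than 2 variants in
   total, or no pathogenic variants at all — with no pathogenic data no
   rule of any kind can be learned); `IMPACT_PREDICTIVE` (some impact
   category occurs among pathogenic variants but never among the
   frequency-filtered benign candidates, which are themselves non-empty;
   impact alone is then a direct classifier and no CADD calibration is
   performed); `MAF_ONLY` (no matched benign set could be formed);
   `LITTLE_DATA` (< 5 CADD-scored variants in either group; CADD
   statistics are still recorded where computable); `ARTIFACT`
   (significant but inverted — benign mean CADD above pathogenic);
   otherwise `CADD_PREDICTIVE` (p < α, pathogenic mean higher) or
   `CADD_LESS_PREDICTIVE` (p ≥ α). α defaults to 0.05, the group-size
   floor to 5.

The genome-wide fallback thresholds are a fixed CADD cutoff of 15
(below benign, above pathogenic) and a MAF cutoff equal to the
arithmetic mean of all gene-specific pathogenic MAF thresholds (0.00426
in the published release; recomputed from whatever calibration set is
loaded).

## Sensitivity adjustment

The calibration is symmetric in the two classes, but diagnostic practice
values sensitivity over specificity. A single adjustment `setting`
(default 5) relaxes gene thresholds toward sensitivity:

- adjusted MAF threshold = `patho_maf_threshold × max(1, setting)`;
- adjusted pathogenic CADD bound =
  `max(min(sens95, spec95), sens95 − setting)`.

The exact mechanism of the original implementation's "setting" is not
published; the rule above was chosen as the simplest form that (i) is
the identity at `setting = 0`, (ii) is monotone — a larger setting can
only add pathogenic calls, never remove them — and (iii) never lowers
the pathogenic bound past the benign specificity bound (when the two
distributions already overlap, i.e. `sens95 ≤ spec95`, the CADD bound is
left at `sens95`). The multiplicative MAF factor uses `max(1, ·)` for
the same identity/monotonicity reasons.

## Classification cascade

Per variant, deterministically and totally (missing annotations degrade
to VUS, never to errors):

1. gene calibrated with a MAF threshold and variant MAF above the
   adjusted threshold → **Benign** (frequency dominates CADD by design);
2. `IMPACT_PREDICTIVE` gene: impact at/above the least-severe
   pathogenic-unique category → **Pathogenic**; impact strictly below
   every pathogenic-observed category → **Benign**; otherwise fall
   through to the fallback;
3. CADD-calibrated gene (`CADD_PREDICTIVE`, `CADD_LESS_PREDICTIVE`,
   `LITTLE_DATA`): CADD ≥ adjusted pathogenic bound → **Pathogenic**;
   CADD ≤ specificity bound → **Benign**; in between → **VUS** (an
   answer, not a failure; `fallback_on_vus` reroutes it); CADD missing →
   VUS;
4. otherwise (no calibration, `MAF_ONLY`/`NOT_CALIBRATED`/`ARTIFACT`,
   or missing gene): genome-wide fallback — MAF above threshold →
   Benign; CADD above 15 → Pathogenic; CADD ≤ 15 → Benign (the boundary
   value is assigned to benign, the conservative reading of a strict
   "<15 benign / >15 pathogenic" rule pair); CADD missing → VUS.

MODIFIER-impact variants with no calibration and no CADD score are VUS,
not benign: there is no published MODIFIER rule, and a silent benign
call would be the one unrecoverable error mode.

## Benchmark metrics

Three-outcome classifiers are scored with missed-aware metrics:
sensitivity = TP/(TP+FN+MissedPos), specificity = TN/(TN+FP+MissedNeg),
accuracy = (TP+TN)/all six cells, where VUS calls and unclassified
variants are "missed" on their truth side. PPV/NPV are computed over
classified variants only, which is the fair score for deliberately
abstaining predictors. Panel stratification assigns a variant to every
manifestation panel of every one of its genes, at most once per panel;
a variant is `NotInCGD` only if none of its genes appear in the map.

The bootstrap comparison draws, per replicate, 100 benign + 100
pathogenic variants with replacement, scores both classifiers on the
same sample, and compares the two accuracy distributions with a
two-sided Mann–Whitney test. Classification is deterministic per
variant, so both classifiers are evaluated once on the pool and
replicates are index resamples — bit-identical results under a fixed
seed at a fraction of the cost.

## Synthetic data

The generator plants the statistical structure calibration consumes.
Choices, with rationale:

- **CADD ~ truncated normal at 0.** Real calibration sets are described
  by per-group means and spreads (release-wide means 28.44 pathogenic /
  23.08 benign, σ ≈ 4.8); a truncated normal is the minimal model
  matching such summaries. Preset groups use σ = 3 and a 10-point
  separation for the clearly-predictive case.
- **Allele frequencies**: pathogenic variants are absent from the
  population with probability 0.8 (most pathogenic alleles are unseen in
  reference panels), otherwise log-uniform on [1e-6, 1e-4]; benign AFs
  are log-uniform on [1e-6, 0.5] with a 0.3 point mass at 0, so both the
  absent→0 mapping and the frequency filter are exercised.
- **Impact mixes** are multinomial; default preset sizes are 50
  pathogenic / 400 candidates so the frequency-filtered, equalized
  benign set stays comfortably above the 5-per-group floor and every
  pathogenic impact category is represented among candidates with high
  probability.
- Positions are consecutive integers per gene on one synthetic contig,
  making step-over order well-defined; a configurable number of
  candidates is planted at pathogenic sites to exercise the
  known-pathogenic exclusion stage.

What the generator does *not* model: linkage, transcript structure,
multi-gene overlap, realistic coordinates, or the long-tailed empirical
CADD distributions of real genes. Passing tests therefore demonstrate
the correctness and statistical behaviour of the machinery (category
routing, threshold recovery, the direction and significance of the
gene-specific advantage), not clinical performance on real cohorts —
the published benchmark numbers on VariBench/ClinVar-scale data require
the external resources themselves.

## Study problem sizes

The bundled studies (`gavin.studies`, also driven by
`scripts/acceptance.py`) use 1000 seeds for category-recovery rates,
and 12 dispersed-cutoff genes (cutoffs uniform on [10, 30], ±5 CADD
separation, σ = 3, 120/500 variants per gene) with 1000 bootstrap
replicates of 100+100 for the gene-specific vs genome-wide comparison.
These sizes put Monte-Carlo error well below the effects being measured
(recovery rates pinned at ~100%, bootstrap median gap ≈ 14 percentage
points against a replicate standard error of ~3) while keeping each
study in the seconds range.

## Numerical notes and limitations

- VCF float INFO fields are stored at single precision by htslib, so a
  write→read cycle starting from in-memory doubles agrees to ~1e-7
  relative; re-reading a file already read once is exactly idempotent.
- Percentiles interpolate ties naturally (no deduplication); the
  Mann–Whitney wrapper returns p = 1 when the null variance collapses
  (all values tied).
- Whether the "<2 variants" rule for uncalibrated genes counts the two
  sources separately or combined is ambiguous in the published
  description; this implementation uses the combined count.
- The step-over equalization and the sensitivity-adjustment mechanism
  are pinned by the explicit constructions above; the original
  implementation's exact mechanics are unpublished, so numerical
  agreement with it on shared inputs is expected only at the level of
  the published worked example (which the MYH7 reconstruction
  reproduces exactly).
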