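import math
import re
from dataclasses import replace

import pytest

from gavin.calibration import (
    GenomeWideDefaults,
    apply_sensitivity_adjustment,
    calibrate,
    calibrate_gene,
    compute_patho_maf_threshold,
    genome_wide_defaults,
    impact_distribution,
    match_benign_set,
    select_pathogenic,
)
from gavin.model import (
    AnnotatedVariant,
    CalibrationCategory,
    GeneCalibration,
    Impact,
    ImpactDistribution,
    Label,
)
from gavin.simulate import generate_gene, myh7_like_fixture, scenario_presets


def _v(pos, impact=Impact.MODERATE, af=None, cadd=20.0, gene="G", ref="A", alt="G"):
    return AnnotatedVariant(
        chrom="chrS", pos=pos, ref=ref, alt=alt, gene=gene, impact=impact,
        cadd=cadd, af=af,
    )


class TestSelectPathogenic:
    def test_substring_rule(self):
        sigs = [
            "Pathogenic", "Likely pathogenic", "Benign", "Likely benign",
            "Uncertain significance", "Conflicting, one submitter pathogenic",
        ]
        variants = [
            AnnotatedVariant("1", i + 1, "A", "G", significance=s)
            for i, s in enumerate(sigs)
        ]
        kept = select_pathogenic(variants)
        oracle = [v for v in variants if re.search("pathogenic", v.significance, re.I)]
        assert kept == oracle
        assert {v.significance for v in kept} == {
            "Pathogenic", "Likely pathogenic", "Conflicting, one submitter pathogenic",
        }

    def test_negation_list(self):
        v = AnnotatedVariant("1", 1, "A", "G", significance="non-pathogenic")
        assert select_pathogenic([v]) == [v]
        assert select_pathogenic([v], negations=["non-pathogenic"]) == []

    def test_label_fallback_when_no_significance(self):
        v = AnnotatedVariant("1", 1, "A", "G", label=Label.PATHOGENIC)
        assert select_pathogenic([v]) == [v]


class TestMafThreshold:
    def test_all_absent_from_population_gives_zero(self):
        assert compute_patho_maf_threshold([_v(i + 1) for i in range(5)]) == 0.0

    def test_interpolated_95th(self):
        variants = [_v(i + 1, af=0.0) for i in range(9)] + [_v(10, af=0.001)]
        assert compute_patho_maf_threshold(variants) == pytest.approx(0.00055)

    def test_empty_is_absent(self):
        assert compute_patho_maf_threshold([]) is None


class TestImpactDistribution:
    def test_proportions(self):
        vs = [_v(1, Impact.HIGH)] + [_v(i + 2, Impact.MODERATE) for i in range(3)]
        assert impact_distribution(vs).as_tuple() == (0.25, 0.75, 0.0, 0.0)

    def test_empty_is_absent(self):
        assert not impact_distribution([]).defined

    def test_missing_impact_names_variant(self):
        with pytest.raises(ValueError, match="chrS:5"):
            impact_distribution([_v(5, impact=None)])


class TestMatchBenignSet:
    target = ImpactDistribution(high=0.25, moderate=0.75, low=0.0, modifier=0.0)

    def test_noop_when_already_matched_and_rare(self):
        cands = [_v(1, Impact.HIGH)] + [_v(i + 2, Impact.MODERATE) for i in range(3)]
        res = match_benign_set(cands, [], 0.01, self.target)
        assert res.removed_stepover == 0 and res.n_equalized == 4
        assert res.achieved_dist.as_tuple() == self.target.as_tuple()

    def test_impossible_match_flagged(self):
        cands = [_v(i + 1, Impact.MODIFIER) for i in range(10)]
        target = ImpactDistribution(high=0.0, moderate=1.0, low=0.0, modifier=0.0)
        res = match_benign_set(cands, [], 1.0, target)
        assert res.infeasible and res.variants == [] and res.conserved()

    def test_known_pathogenic_and_af_stages(self):
        patho = [_v(i + 1, Impact.MODERATE) for i in range(3)]
        dup = [_v(i + 1, Impact.MODERATE, af=1e-5) for i in range(3)]  # same sites
        common = [_v(100 + i, Impact.MODERATE, af=0.2, ref="C", alt="T") for i in range(4)]
        rare = [_v(200 + i, Impact.MODERATE, af=1e-5, ref="C", alt="T") for i in range(5)]
        target = ImpactDistribution(high=0.0, moderate=1.0, low=0.0, modifier=0.0)
        res = match_benign_set(dup + common + rare, patho, 1e-3, target)
        assert res.removed_known == 3
        assert res.removed_af == 4
        assert res.n_equalized == 5
        assert res.conserved()

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_random_fixtures(self, seed):
        sc = scenario_presets()["cadd_predictive"]
        patho, cands = generate_gene(sc, seed=seed)
        thr = compute_patho_maf_threshold(patho)
        res = match_benign_set(cands, patho, thr, impact_distribution(patho))
        assert res.conserved()

    def test_myh7_scale_proportions_within_one_point(self):
        patho, cands = myh7_like_fixture()
        res = match_benign_set(
            cands, patho, compute_patho_maf_threshold(patho), impact_distribution(patho)
        )
        assert res.conserved()
        assert res.n_equalized == 494
        for got, want in zip(
            res.achieved_dist.as_tuple(), impact_distribution(patho).as_tuple()
        ):
            assert abs(got - want) < 0.01

    def test_absent_target_raises(self):
        with pytest.raises(ValueError):
            match_benign_set([], [], 0.1, ImpactDistribution.absent())


class TestCalibrateGene:
    @pytest.mark.parametrize("name", sorted(scenario_presets()))
    def test_preset_routes_to_planted_category(self, name, presets):
        sc = presets[name]
        for seed in range(3):
            patho, cands = generate_gene(sc, seed=seed)
            cal = calibrate_gene(sc.gene, patho, cands)
            assert cal.category.value == sc.planted_category, (name, seed)

    def test_cadd_predictive_invariants(self, presets):
        sc = presets["cadd_predictive"]
        patho, cands = generate_gene(sc, seed=0)
        cal = calibrate_gene(sc.gene, patho, cands)
        assert cal.category is CalibrationCategory.CADD_PREDICTIVE
        assert cal.mwu_p < 0.05
        assert cal.mean_patho_cadd > cal.mean_benign_cadd
        assert cal.n_patho >= 5 and cal.n_benign >= 5
        assert cal.sens95_cadd is not None and cal.spec95_cadd is not None
        # liberal bounds bracket the means
        assert cal.sens95_cadd < cal.mean_patho_cadd
        assert cal.spec95_cadd > cal.mean_benign_cadd

    def test_artifact_requires_inverted_direction(self, presets):
        sc = presets["artifact"]
        patho, cands = generate_gene(sc, seed=1)
        cal = calibrate_gene(sc.gene, patho, cands)
        assert cal.category is CalibrationCategory.ARTIFACT
        assert cal.mean_benign_cadd > cal.mean_patho_cadd and cal.mwu_p < 0.05

    def test_little_data_thresholds_still_computed(self, presets):
        sc = presets["little_data"]
        patho, cands = generate_gene(sc, seed=2)
        cal = calibrate_gene(sc.gene, patho, cands)
        assert cal.category is CalibrationCategory.LITTLE_DATA
        assert cal.n_patho < 5
        assert cal.sens95_cadd is not None

    def test_impact_predictive_skips_cadd(self, presets):
        sc = presets["impact_predictive"]
        patho, cands = generate_gene(sc, seed=0)
        cal = calibrate_gene(sc.gene, patho, cands)
        assert cal.category is CalibrationCategory.IMPACT_PREDICTIVE
        assert Impact.HIGH in cal.pathogenic_unique_impacts()
        assert cal.sens95_cadd is None and cal.spec95_cadd is None

    def test_single_variant_not_calibrated(self):
        cal = calibrate_gene("G", [_v(1)], [])
        assert cal.category is CalibrationCategory.NOT_CALIBRATED
        assert cal.patho_maf_threshold is None

    def test_categories_partition_cohort(self, small_cohort):
        patho, pop = small_cohort
        cals = calibrate(patho, pop)
        assert set(cals) == {"G1", "G2", "G3"}
        for cal in cals.values():
            assert isinstance(cal.category, CalibrationCategory)


class TestGenomeWideDefaults:
    def _cal(self, gene, thr):
        return GeneCalibration(
            gene=gene, category=CalibrationCategory.MAF_ONLY, patho_maf_threshold=thr,
            n_patho=1,
        )

    def test_mean_of_thresholds_and_fixed_cadd(self):
        d = genome_wide_defaults({"A": self._cal("A", 0.002), "B": self._cal("B", 0.006)})
        assert d.maf_threshold == pytest.approx(0.004)
        assert d.cadd_threshold == 15.0

    def test_mean_matches_arithmetic_oracle(self):
        import numpy as np

        rng = np.random.default_rng(5)
        thrs = rng.uniform(0, 0.01, 100)
        cals = {f"G{i}": self._cal(f"G{i}", t) for i, t in enumerate(thrs)}
        assert genome_wide_defaults(cals).maf_threshold == pytest.approx(thrs.mean())

    def test_no_thresholds_errors(self):
        empty = GeneCalibration(gene="X", category=CalibrationCategory.NOT_CALIBRATED)
        with pytest.raises(ValueError):
            genome_wide_defaults({"X": empty})


class TestSensitivityAdjustment:
    base = GeneCalibration(
        gene="G", category=CalibrationCategory.CADD_PREDICTIVE,
        patho_maf_threshold=1e-4, mean_patho_cadd=28.0, mean_benign_cadd=18.0,
        sens95_cadd=23.0, spec95_cadd=21.0, mwu_p=1e-6, n_patho=50, n_benign=50,
    )

    def test_zero_is_identity(self):
        adj = apply_sensitivity_adjustment(self.base, 0.0)
        assert adj.patho_maf_threshold == self.base.patho_maf_threshold
        assert adj.sens95_cadd == self.base.sens95_cadd

    def test_default_setting_relaxes(self):
        adj = apply_sensitivity_adjustment(self.base, 5.0)
        assert adj.patho_maf_threshold == pytest.approx(5e-4)
        assert adj.sens95_cadd <= self.base.sens95_cadd
        assert adj.sens95_cadd >= min(self.base.sens95_cadd, self.base.spec95_cadd)

    def test_monotone_in_setting(self):
        prev_maf, prev_bound = -math.inf, math.inf
        for s in range(0, 11):
            adj = apply_sensitivity_adjustment(self.base, float(s))
            assert adj.patho_maf_threshold >= prev_maf
            assert adj.sens95_cadd <= prev_bound
            prev_maf, prev_bound = adj.patho_maf_threshold, adj.sens95_cadd

    def test_overlapping_gene_never_crosses_benign_bound(self):
        overlap = self.base.replace(sens95_cadd=18.0, spec95_cadd=24.0)
        adj = apply_sensitivity_adjustment(overlap, 10.0)
        assert adj.sens95_cadd == 18.0  # already below spec95: no further drop

    def test_negative_setting_raises(self):
        with pytest.raises(ValueError):
            apply_sensitivity_adjustment(self.base, -1.0)
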