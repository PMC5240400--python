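import pytest

from gavin.calibration import calibrate, genome_wide_defaults
from gavin.classify import classify_stream
from gavin.model import AnnotatedVariant, Impact, Label, Verdict
from gavin.variant_io import (
    InfoFields,
    VcfParseError,
    read_annotated_vcf,
    read_calibration_table,
    read_cgd,
    read_classified_vcf,
    read_truth_table,
    write_calibration_table,
    write_classified_vcf,
    write_truth_table,
    write_vcf,
)

HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="ann">\n'
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="cadd">\n'
    '##INFO=<ID=EXAC_AF,Number=1,Type=Float,Description="af">\n'
    '##INFO=<ID=CLINSIG,Number=1,Type=String,Description="sig">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def _write(tmp_path, body, name="in.vcf"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadVcf:
    def test_direct_field_mapping(self, tmp_path):
        p = _write(
            tmp_path,
            "1\t100\t.\tA\tG\t.\t.\t"
            "ANN=G|missense_variant|MODERATE|MYH7|;CADD=24.1;EXAC_AF=0.0001\n",
        )
        (v,) = read_annotated_vcf(p)
        assert (v.gene, v.impact) == ("MYH7", Impact.MODERATE)
        # float INFO values carry VCF single precision
        assert v.cadd == pytest.approx(24.1, rel=1e-6)
        assert v.af == pytest.approx(1e-4, rel=1e-6)

    def test_missing_af_key_is_absent(self, tmp_path):
        p = _write(tmp_path, "1\t100\t.\tA\tG\t.\t.\tANN=G|mv|MODERATE|MYH7|;CADD=24.1\n")
        (v,) = read_annotated_vcf(p)
        assert v.af is None

    def test_two_genes_two_instances(self, tmp_path):
        p = _write(
            tmp_path,
            "1\t100\t.\tA\tG\t.\t.\t"
            "ANN=G|mv|MODERATE|MYH7|,G|sv|HIGH|TTN|;CADD=30\n",
        )
        vs = list(read_annotated_vcf(p))
        assert {(v.gene, v.impact) for v in vs} == {
            ("MYH7", Impact.MODERATE), ("TTN", Impact.HIGH),
        }
        # manual split oracle: both carry the shared record fields
        assert all(v.pos == 100 and v.cadd == 30.0 for v in vs)

    def test_most_severe_impact_per_gene(self, tmp_path):
        p = _write(
            tmp_path,
            "1\t100\t.\tA\tG\t.\t.\tANN=G|a|LOW|MYH7|,G|b|HIGH|MYH7|\n",
        )
        (v,) = read_annotated_vcf(p)
        assert v.impact is Impact.HIGH

    def test_multiallelic_split(self, tmp_path):
        p = _write(
            tmp_path,
            "1\t100\t.\tA\tG,T\t.\t.\tANN=G|a|MODERATE|MYH7|,T|b|LOW|MYH7|\n",
        )
        vs = list(read_annotated_vcf(p))
        assert [(v.alt, v.impact) for v in vs] == [
            ("G", Impact.MODERATE), ("T", Impact.LOW),
        ]

    def test_unknown_impact_token_errors_with_record(self, tmp_path):
        p = _write(tmp_path, "1\t100\t.\tA\tG\t.\t.\tANN=G|a|SEVERE|MYH7|\n")
        with pytest.raises(VcfParseError, match="record 1"):
            list(read_annotated_vcf(p))

    def test_symbolic_alt_rejected_and_counted(self, tmp_path):
        p = _write(
            tmp_path,
            "1\t100\t.\tA\t<DEL>\t.\t.\tCADD=10\n1\t200\t.\tA\tG\t.\t.\tCADD=10\n",
        )
        rejects = []
        vs = list(read_annotated_vcf(p, on_reject=lambda i, r: rejects.append((i, r))))
        # nothing silently dropped: 2 records in = 1 variant out + 1 reject
        assert len(vs) == 1 and len(rejects) == 1
        assert rejects[0][0] == 1

    def test_significance_merging(self, tmp_path):
        p = _write(
            tmp_path,
            "1\t100\t.\tA\tG\t.\t.\tCLINSIG=Likely_pathogenic\n"
            "1\t200\t.\tA\tG\t.\t.\tCLINSIG=Likely_benign\n",
        )
        a, b = read_annotated_vcf(p)
        assert a.label is Label.PATHOGENIC and b.label is Label.BENIGN

    def test_configurable_info_keys(self, tmp_path):
        p = tmp_path / "alt.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##INFO=<ID=CADD13,Number=1,Type=Float,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t5\t.\tA\tG\t.\t.\tCADD13=9.5\n"
        )
        (v,) = read_annotated_vcf(p, fields=InfoFields(cadd="CADD13"))
        assert v.cadd == 9.5


class TestRoundTrip:
    def _variants(self):
        from gavin.simulate import GeneScenario, generate_cohort

        patho, pop = generate_cohort(
            [GeneScenario(gene="G1", n_patho=20, n_benign=30, n_known_duplicates=0)],
            seed=5,
        )
        return (patho + pop)[:50]

    def test_vcf_round_trip_identity(self, tmp_path):
        variants = self._variants()
        p = tmp_path / "rt.vcf"
        write_vcf(variants, p)
        back = list(read_annotated_vcf(p))
        assert len(back) == len(variants)
        for a, b in zip(variants, back):
            assert a.site == b.site
            assert a.gene == b.gene and a.impact == b.impact
            # numeric INFO fields round-trip at VCF single precision
            assert a.cadd == pytest.approx(b.cadd, rel=1e-6)
            assert (a.af is None) == (b.af is None)
            if a.af is not None:
                assert a.af == pytest.approx(b.af, rel=1e-6)
            assert a.label == b.label

    def test_reread_is_exact_identity(self, tmp_path):
        # once a file has been read, write→read reproduces it exactly
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(self._variants(), p1)
        first = list(read_annotated_vcf(p1))
        write_vcf(first, p2)
        assert list(read_annotated_vcf(p2)) == first

    def test_empty_vcf_valid(self, tmp_path):
        p = tmp_path / "empty.vcf"
        write_vcf([], p)
        assert list(read_annotated_vcf(p)) == []

    def test_classified_round_trip(self, tmp_path):
        variants = self._variants()
        cals = calibrate(
            [v for v in variants if v.label is Label.PATHOGENIC],
            [v for v in variants if v.label is Label.BENIGN],
        )
        defaults = genome_wide_defaults(cals)
        pairs = list(classify_stream(variants, cals, defaults))
        p = tmp_path / "classified.vcf"
        write_classified_vcf(pairs, p)
        back = list(read_classified_vcf(p))
        assert [j.verdict for _, j in pairs] == [verdict for _, verdict in back]
        assert all(isinstance(verdict, Verdict) for _, verdict in back)


class TestCalibrationTable:
    def test_round_trip_equals_memory(self, tmp_path, small_cohort):
        patho, pop = small_cohort
        cals = calibrate(patho, pop)
        p = tmp_path / "genes.tsv"
        write_calibration_table(cals, p)
        back = read_calibration_table(p)
        assert set(back) == set(cals)
        for g in cals:
            a, b = cals[g], back[g]
            assert a.category == b.category
            assert a.n_patho == b.n_patho and a.n_benign == b.n_benign
            for attr in ("patho_maf_threshold", "mean_patho_cadd", "mean_benign_cadd",
                         "sens95_cadd", "spec95_cadd", "mwu_p"):
                x, y = getattr(a, attr), getattr(b, attr)
                assert (x is None) == (y is None)
                if x is not None:
                    assert x == pytest.approx(y, rel=1e-12)
            assert a.patho_impact_dist == b.patho_impact_dist
            assert a.benign_impact_dist == b.benign_impact_dist

    def test_duplicate_gene_errors(self, tmp_path):
        p = tmp_path / "dup.tsv"
        header = "\t".join(
            ["Gene", "Category", "PathoMafThreshold", "MeanPathogenicCadd",
             "MeanPopulationCadd", "Sens95CaddThreshold", "Spec95CaddThreshold",
             "PathogenicImpactDistribution", "BenignImpactDistribution",
             "NPathogenic", "NBenign", "MwuPValue"]
        )
        row = "G\tNOT_CALIBRATED\t\t\t\t\t\t\t\t0\t0\t"
        p.write_text(f"{header}\n{row}\n{row}\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_calibration_table(p)

    def test_unknown_category_errors(self, tmp_path, small_cohort):
        patho, pop = small_cohort
        cals = calibrate(patho, pop)
        p = tmp_path / "bad.tsv"
        write_calibration_table(cals, p)
        p.write_text(p.read_text().replace("CADD_PREDICTIVE", "WAT", 1))
        with pytest.raises(ValueError, match="unknown calibration category"):
            read_calibration_table(p)


class TestCgd:
    def test_three_gene_fixture(self, tmp_path):
        p = tmp_path / "cgd.tsv"
        p.write_text(
            "#GENE\tCONDITION\tMANIFESTATION CATEGORIES\n"
            "MYH7\tx\tCardiovascular; Musculoskeletal\n"
            "TTN\tx\tCardiovascular\n"
            "MYH7\tx\tOncologic\n"
        )
        cgd = read_cgd(p)
        assert cgd == {
            "MYH7": {"Cardiovascular", "Musculoskeletal", "Oncologic"},
            "TTN": {"Cardiovascular"},
        }

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("GENE\tOTHER\nMYH7\tx\n")
        with pytest.raises(ValueError, match="MANIFESTATION"):
            read_cgd(p)


class TestTruthTable:
    def test_round_trip(self, tmp_path):
        vs = [
            AnnotatedVariant("1", 1, "A", "G", gene="X", label=Label.PATHOGENIC),
            AnnotatedVariant("1", 2, "A", "G", gene="X", label=Label.BENIGN),
        ]
        p = tmp_path / "truth.tsv"
        write_truth_table(vs, p)
        table = read_truth_table(p)
        assert table[("1", 1, "A", "G")] is Label.PATHOGENIC
        assert table[("1", 2, "A", "G")] is Label.BENIGN
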