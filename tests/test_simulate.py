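import warnings

import numpy as np
import pandas as pd
import pytest

from th2axis.cohort import compare_groups, pearson_with_p
from th2axis.io import read_fasta, read_gene_models, write_fasta, write_gene_models_bed12
from th2axis.motifs import scan_gene
from th2axis.simulate import (
    SUBUNIT_A_PROBE,
    SUBUNIT_B_PROBE,
    AnalyteSpec,
    CohortSimSpec,
    ExpressionSimSpec,
    GeneSimSpec,
    GenomeSimSpec,
    PlantedMotif,
    gen_cohort,
    gen_expression,
    gen_genome,
    oracle_scan,
)


class TestGenExpression:
    def test_deterministic_under_seed(self):
        spec = ExpressionSimSpec(n_null_probes=50,
                                 planted_positive=[("G1", 0.8)])
        m1, a1, t1 = gen_expression(spec, seed=1)
        m2, a2, t2 = gen_expression(spec, seed=1)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert a1 == a2 and t1 == t2
        m3, _, _ = gen_expression(spec, seed=2)
        assert not m1.values.equals(m3.values)

    def test_noiseless_limit_gives_perfect_correlation(self):
        spec = ExpressionSimSpec(
            n_group_a=12, n_group_b=0, n_null_probes=0,
            planted_positive=[("POS", 1.0)],
            planted_negative=[("NEG", 1.0)],
            subunit_loading=1.0, noise_sd=1e-9,
        )
        matrix, _, _ = gen_expression(spec, seed=0)
        v = matrix.values
        r_pos = pearson_with_p(v.loc["POS_at"], v.loc[SUBUNIT_A_PROBE]).r
        r_neg = pearson_with_p(v.loc["NEG_at"], v.loc[SUBUNIT_B_PROBE]).r
        assert r_pos == pytest.approx(1.0, abs=1e-6)
        assert r_neg == pytest.approx(-1.0, abs=1e-6)

    def test_truth_lists_planted_symbols(self):
        spec = ExpressionSimSpec(planted_positive=[("aBc", 0.5)],
                                 planted_negative=[("xyz", 0.5)])
        _, annot, truth = gen_expression(spec, seed=0)
        assert truth == {"positive": ["ABC"], "negative": ["XYZ"]}
        assert annot["aBc_at"] == "ABC"

    def test_invalid_loading_errors(self):
        with pytest.raises(ValueError, match="loading"):
            gen_expression(
                ExpressionSimSpec(planted_positive=[("G", 1.5)]), seed=0
            )

    def test_invalid_noise_errors(self):
        with pytest.raises(ValueError, match="noise"):
            gen_expression(ExpressionSimSpec(noise_sd=0.0), seed=0)


class TestGenCohort:
    def test_deterministic_under_seed(self):
        spec = CohortSimSpec(n_per_group=10)
        pd.testing.assert_frame_equal(gen_cohort(spec, 3), gen_cohort(spec, 3))

    def test_null_effect_rejects_at_alpha(self):
        spec = CohortSimSpec(
            n_per_group=12, analytes={"X": AnalyteSpec(3.0, 3.0, 0.7)}, ct_genes={}
        )
        rejections = 0
        n_reps = 400
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(n_reps):
                table = gen_cohort(spec, 50_000 + rep)
                res = compare_groups(
                    table.loc[table.group == "case", "X"],
                    table.loc[table.group == "control", "X"],
                )
                rejections += res.p_value < 0.05
        # 3 sigma binomial band around 0.05 at 400 replicates is ~0.033
        assert rejections / n_reps == pytest.approx(0.05, abs=0.035)

    def test_large_effect_rejects_almost_always(self):
        spec = CohortSimSpec(
            n_per_group=30, analytes={"X": AnalyteSpec(3.0, 5.0, 0.8)}, ct_genes={}
        )
        rejections = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(50):
                table = gen_cohort(spec, 60_000 + rep)
                res = compare_groups(
                    table.loc[table.group == "case", "X"],
                    table.loc[table.group == "control", "X"],
                )
                rejections += res.p_value < 0.05
        assert rejections >= 48

    def test_small_cohort_errors(self):
        with pytest.raises(ValueError):
            gen_cohort(CohortSimSpec(n_per_group=2), seed=0)

    def test_ct_columns_present(self):
        table = gen_cohort(CohortSimSpec(n_per_group=5), seed=0)
        assert {"Ct_IL4R", "Ct_IL13RA1", "Ct_ref"} <= set(table.columns)


class TestGenGenome:
    def spec(self):
        return GenomeSimSpec(
            chrom_lengths={"chrS": 30_000},
            genes=[
                GeneSimSpec("TX1", "chrS", "+", tss=6_000),
                GeneSimSpec("TX2", "chrS", "-", tss=20_000),
            ],
            planted=[
                PlantedMotif("TX1", "intron1", 10, "AGGG"),
                PlantedMotif("TX2", "upstream5k", 100, "CTA"),
            ],
        )

    def test_deterministic_under_seed(self):
        g1, m1, t1 = gen_genome(self.spec(), seed=4)
        g2, m2, t2 = gen_genome(self.spec(), seed=4)
        assert g1 == g2 and m1 == m2
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_motif_lands_in_truth(self):
        _, _, truth = gen_genome(self.spec(), seed=4)
        hit = truth[
            (truth.transcript_id == "TX1")
            & (truth.region == "intron1")
            & (truth.offset == 10)
        ]
        assert len(hit) == 1
        assert hit.iloc[0].spacer == "AGGG"
        assert bool(hit.iloc[0].stat6_preferred)
        minus_hit = truth[
            (truth.transcript_id == "TX2")
            & (truth.region == "upstream5k")
            & (truth.offset == 100)
        ]
        assert minus_hit.iloc[0].spacer == "CTA"

    def test_truth_equals_scanner_on_round_tripped_files(self, tmp_path):
        genome, models, truth = gen_genome(self.spec(), seed=9)
        write_fasta(genome, tmp_path / "g.fa")
        write_gene_models_bed12(models, tmp_path / "m.bed")
        genome_back = read_fasta(tmp_path / "g.fa")
        models_back = read_gene_models(tmp_path / "m.bed", "bed12")
        scanned = pd.concat(
            [scan_gene(m, genome_back) for m in models_back], ignore_index=True
        ).sort_values(["transcript_id", "region", "offset"], kind="stable")
        pd.testing.assert_frame_equal(
            scanned.reset_index(drop=True), truth, check_dtype=False
        )

    def test_background_motifs_kept_in_truth(self):
        spec = self.spec()
        spec.planted = []
        genome, models, truth = gen_genome(spec, seed=11)
        # truth is exactly the oracle scan of the emitted background
        from th2axis.motifs import extract_regions

        n_oracle = sum(
            len(oracle_scan(region.sequence))
            for m in models
            for region in extract_regions(m, genome).regions.values()
        )
        assert len(truth) == n_oracle > 0

    def test_planted_outside_region_errors(self):
        spec = self.spec()
        spec.planted = [PlantedMotif("TX1", "intron1", 10_000, "AG")]
        with pytest.raises(ValueError, match="outside"):
            gen_genome(spec, seed=0)

    def test_overlapping_plants_error(self):
        spec = self.spec()
        spec.planted = [
            PlantedMotif("TX1", "intron1", 10, "AGGG"),
            PlantedMotif("TX1", "intron1", 12, "CC"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            gen_genome(spec, seed=0)

    def test_gc_fraction_respected(self):
        spec = GenomeSimSpec(chrom_lengths={"c": 50_000}, gc_fraction=0.6)
        genome, _, _ = gen_genome(spec, seed=0)
        gc = sum(b in "GC" for b in genome["c"]) / 50_000
        assert gc == pytest.approx(0.6, abs=0.02)
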