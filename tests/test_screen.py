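import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix
from th2axis.cohort import critical_r
from th2axis.screen import (
    CATEGORIES,
    ScreenConfig,
    categorize,
    collapse_to_genes,
    export_scatter_data,
    screen_heterodimer,
)
from th2axis.simulate import (
    SUBUNIT_A_PROBE,
    SUBUNIT_B_PROBE,
    ExpressionSimSpec,
    gen_expression,
)


def random_matrix(rng, n_probes=12, n_samples=10):
    return make_matrix(rng.normal(size=(n_probes, n_samples)))


def brute_force_screen(matrix, cfg):
    """Independent per-probe recomputation from the raw correlation formula."""
    samples = [s for s in matrix.sample_ids if matrix.sample_groups[s] == cfg.group]
    n = len(samples)
    t_star = stats.t.ppf(1 - cfg.alpha / 2, n - 2)
    thr = cfg.r_threshold if cfg.r_threshold is not None else t_star / np.sqrt(
        t_star**2 + n - 2
    )
    sub = matrix.values[samples]
    a = sub.loc[cfg.subunit_a_probe].to_numpy()
    b = sub.loc[cfg.subunit_b_probe].to_numpy()

    def r_of(x, y):
        xd, yd = x - x.mean(), y - y.mean()
        return float(np.sum(xd * yd) / np.sqrt(np.sum(xd**2) * np.sum(yd**2)))

    out = {}
    for pid in matrix.probe_ids:
        if pid in (cfg.subunit_a_probe, cfg.subunit_b_probe):
            continue
        x = sub.loc[pid].to_numpy()
        r_a, r_b = r_of(x, a), r_of(x, b)
        sa, sb = abs(r_a) > thr, abs(r_b) > thr
        if sa and sb:
            cat = (
                "both_positive" if r_a > 0 and r_b > 0
                else "both_negative" if r_a < 0 and r_b < 0
                else "discordant"
            )
        elif sa:
            cat = "a_only"
        elif sb:
            cat = "b_only"
        else:
            cat = "none"
        out[pid] = (r_a, r_b, cat)
    return thr, out


class TestScreen:
    def test_probe_duplicating_subunits_is_both_positive(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        values = np.vstack([base, base, base, -base])
        matrix = make_matrix(values)
        cfg = ScreenConfig("r1", "r2", "G")
        records, summary = screen_heterodimer(matrix, {}, cfg)
        rec = records.set_index("probe_id")
        assert rec.loc["r3", "category"] == "both_positive"
        assert rec.loc["r3", "r_a"] == pytest.approx(1.0)
        assert rec.loc["r3", "r_b"] == pytest.approx(1.0)
        assert rec.loc["r4", "category"] == "both_negative"
        # the subunit probes themselves are never scored
        assert set(rec.index) == {"r3", "r4"}

    def test_planted_genes_fully_recovered(self):
        spec = ExpressionSimSpec(
            n_group_a=12,
            n_group_b=6,
            n_null_probes=100,
            planted_positive=[(f"POS{i:02d}", 0.9) for i in range(10)],
            planted_negative=[(f"NEG{i:02d}", 0.9) for i in range(10)],
            noise_sd=0.3,
        )
        matrix, annot, truth = gen_expression(spec, seed=7)
        cfg = ScreenConfig(SUBUNIT_A_PROBE, SUBUNIT_B_PROBE, "AR")
        records, _ = screen_heterodimer(matrix, annot, cfg)
        genes = collapse_to_genes(records)
        assert set(truth["positive"]) <= genes["both_positive"]
        assert set(truth["negative"]) <= genes["both_negative"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, n_probes=rng.integers(5, 21), n_samples=9)
        cfg = ScreenConfig("r1", "r2", "G")
        records, summary = screen_heterodimer(matrix, {}, cfg)
        thr, oracle = brute_force_screen(matrix, cfg)
        assert summary.threshold == pytest.approx(thr, abs=1e-12)
        for _, row in records.iterrows():
            r_a, r_b, cat = oracle[row.probe_id]
            assert row.r_a == pytest.approx(r_a, abs=1e-12)
            assert row.r_b == pytest.approx(r_b, abs=1e-12)
            assert row.category == cat

    def test_category_partition_conserves_counts(self):
        rng = np.random.default_rng(5)
        matrix = random_matrix(rng, n_probes=40)
        records, summary = screen_heterodimer(matrix, {}, ScreenConfig("r1", "r2", "G"))
        assert records.category.isin(CATEGORIES).all()
        assert sum(summary.probe_counts.values()) == len(records) == 38

    def test_raising_threshold_shrinks_hit_sets(self):
        rng = np.random.default_rng(11)
        matrix = random_matrix(rng, n_probes=60)
        loose, _ = screen_heterodimer(matrix, {}, ScreenConfig("r1", "r2", "G", alpha=0.1))
        strict, _ = screen_heterodimer(matrix, {}, ScreenConfig("r1", "r2", "G", alpha=0.01))
        for cat in ("both_positive", "both_negative"):
            loose_set = set(loose.loc[loose.category == cat, "probe_id"])
            strict_set = set(strict.loc[strict.category == cat, "probe_id"])
            assert strict_set <= loose_set

    def test_subunit_swap_symmetry(self):
        rng = np.random.default_rng(13)
        matrix = random_matrix(rng, n_probes=50)
        fwd, _ = screen_heterodimer(matrix, {}, ScreenConfig("r1", "r2", "G"))
        rev, _ = screen_heterodimer(matrix, {}, ScreenConfig("r2", "r1", "G"))
        swap = {"a_only": "b_only", "b_only": "a_only"}
        fwd_cats = fwd.set_index("probe_id").category
        rev_cats = rev.set_index("probe_id").category
        for pid in fwd_cats.index:
            assert rev_cats[pid] == swap.get(fwd_cats[pid], fwd_cats[pid])

    def test_null_probe_per_subunit_hit_rate_near_alpha(self):
        # fraction of null probes with |r_a| beyond critical_r ~ alpha
        alpha, hits, trials = 0.05, 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            matrix = make_matrix(rng.normal(size=(202, 12)))
            records, summary = screen_heterodimer(
                matrix, {}, ScreenConfig("r1", "r2", "G", alpha=alpha)
            )
            hits += int((records.r_a.abs() > summary.threshold).sum())
            trials += len(records)
        assert hits / trials == pytest.approx(alpha, abs=0.02)

    def test_missing_values_use_pairwise_complete_cases(self):
        values = np.array(
            [
                [1.0, 2, 3, 4, 5, 6],
                [1.0, 2, 3, 4, 5, 6],
                [1.0, 2, 3, 4, 5, np.nan],
                [np.nan, np.nan, np.nan, np.nan, 1, 2],
            ]
        )
        matrix = make_matrix(values)
        records, _ = screen_heterodimer(matrix, {}, ScreenConfig("r1", "r2", "G"))
        rec = records.set_index("probe_id")
        assert rec.loc["r3", "n_complete"] == 5
        assert rec.loc["r3", "r_a"] == pytest.approx(1.0)
        # fewer than 3 complete pairs: unscored, category none
        assert rec.loc["r4", "category"] == "none"
        assert np.isnan(rec.loc["r4", "r_a"])

    def test_absent_subunit_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="absent"):
            screen_heterodimer(toy_matrix, {}, ScreenConfig("p1", "nope", "AR"))

    def test_small_group_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="n = 2 < 3"):
            screen_heterodimer(toy_matrix, {}, ScreenConfig("p1", "p2", "AR"))

    def test_explicit_threshold_override(self):
        rng = np.random.default_rng(3)
        matrix = random_matrix(rng)
        _, summary = screen_heterodimer(
            matrix, {}, ScreenConfig("r1", "r2", "G", r_threshold=0.603)
        )
        assert summary.threshold == 0.603


class TestCollapse:
    def test_two_probes_one_gene_count_one(self):
        records = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "gene_symbol": ["CLDN4", "CLDN4", ""],
                "category": ["both_positive"] * 3,
            }
        )
        genes = collapse_to_genes(records)
        assert genes["both_positive"] == {"CLDN4"}

    def test_empty_records_give_empty_sets(self):
        genes = collapse_to_genes(pd.DataFrame(columns=["gene_symbol", "category"]))
        assert all(v == set() for v in genes.values())


def test_scatter_export_rows_and_flags(tmp_path):
    rng = np.random.default_rng(21)
    matrix = make_matrix(rng.normal(size=(10, 8)))
    annot = {"r3": "CLDN4", "r4": "OTHER"}
    records, _ = screen_heterodimer(
        matrix, annot, ScreenConfig("r1", "r2", "G")
    )
    table = export_scatter_data(records, tmp_path / "scatter.tsv")
    assert len(table) == 8  # one row per scored probe
    flags = table.set_index("probe_id").watchlist
    assert bool(flags["r3"]) and not bool(flags["r4"])
    assert (tmp_path / "scatter.tsv").exists()


def test_categorize_rule_table():
    thr = 0.5
    assert categorize(0.6, 0.7, thr) == "both_positive"
    assert categorize(-0.6, -0.7, thr) == "both_negative"
    assert categorize(0.6, -0.7, thr) == "discordant"
    assert categorize(0.6, 0.1, thr) == "a_only"
    assert categorize(0.1, -0.7, thr) == "b_only"
    assert categorize(0.1, 0.2, thr) == "none"
    assert categorize(np.nan, 0.9, thr) == "none"
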