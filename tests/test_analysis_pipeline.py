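import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import binning_sweep, pair_interaction_loops
from chromex import analysis_pipeline as ap
from chromex import synthetic_data as sd
from chromex.core_io import (
    ChromSizes,
    CoexpressionTable,
    ContactMatrix,
    Gene,
    GeneAnnotation,
    RegulatoryNetwork,
)
from chromex.errors import ConfigError, InsufficientDataError, ValidationError
from chromex.pair_metrics import GenePairTable, PairRecord
from conftest import random_symmetric_counts


def make_matrices(rng, chroms, cell_types, n_bins=10, resolution=1_000_000):
    out = {}
    for ct in cell_types:
        out[ct] = {
            c: ContactMatrix(
                c, ct, resolution, random_symmetric_counts(rng, n_bins, 20), n_bins
            )
            for c in chroms
        }
    return out


def full_coexpr(gene_ids, rng):
    table = CoexpressionTable()
    for i, a in enumerate(gene_ids):
        for b in gene_ids[i + 1:]:
            table.add(a, b, float(rng.integers(1, 200)))
    return table


def full_net(gene_ids, rng):
    edges = []
    for g in gene_ids:
        for t in rng.choice(5, size=int(rng.integers(1, 4)), replace=False):
            edges.append((f"TF{t}", g))
    return RegulatoryNetwork(edges)


class TestBuildPairTable:
    def make_annotation(self, n_per_chrom, rng, chrom_len=10_000_000):
        genes = []
        i = 0
        sizes = {}
        for chrom, n in n_per_chrom.items():
            sizes[chrom] = chrom_len
            for _ in range(n):
                start = int(rng.integers(0, chrom_len - 200_000))
                i += 1
                genes.append(Gene(f"g{i:03d}", chrom, start, start + 150_000))
        return GeneAnnotation(genes, ChromSizes(sizes))

    def test_four_genes_give_six_pairs(self, rng):
        ann = self.make_annotation({"chr1": 4}, rng)
        ids = [g.id for g in ann]
        table = ap.build_pair_table(
            ann,
            make_matrices(rng, ["chr1"], ["cellA"]),
            full_coexpr(ids, rng),
            full_net(ids, rng),
        )
        assert len(table) == 6

    def test_intra_chromosomal_only(self, rng):
        ann = self.make_annotation({"chr1": 2, "chr2": 2}, rng)
        ids = [g.id for g in ann]
        table = ap.build_pair_table(
            ann,
            make_matrices(rng, ["chr1", "chr2"], ["cellA"]),
            full_coexpr(ids, rng),
            full_net(ids, rng),
        )
        assert len(table) == 2
        assert set(table.df["chrom"]) == {"chr1", "chr2"}

    def test_oh_matches_nested_loop_oracle(self, rng):
        ann = self.make_annotation({"chr1": 25, "chr2": 25}, rng)
        ids = [g.id for g in ann]
        matrices = make_matrices(rng, ["chr1", "chr2"], ["cellA", "cellB"])
        table = ap.build_pair_table(
            ann, matrices, full_coexpr(ids, rng), full_net(ids, rng)
        )
        assert len(table) == 2 * (25 * 24 // 2)
        for row in table.df.sample(n=60, random_state=7).itertuples():
            ga, gb = ann.get(row.gene_a), ann.get(row.gene_b)
            for ct in ("cellA", "cellB"):
                want = pair_interaction_loops(
                    ga, gb, matrices[ct][row.chrom].counts, 1_000_000
                )
                assert getattr(row, f"oh_{ct}") == pytest.approx(want, abs=1e-9)

    def test_gene_without_tf_or_coexpression_excluded(self, rng):
        ann = self.make_annotation({"chr1": 4}, rng)
        ids = [g.id for g in ann]
        coexpr = full_coexpr(ids[:3], rng)  # last gene absent
        net = full_net(ids[:2] + ids[3:], rng)  # third gene has no TF
        table = ap.build_pair_table(
            ann, make_matrices(rng, ["chr1"], ["cellA"]), coexpr, net
        )
        # only the first two genes survive both requirements
        assert len(table) == 1

    def test_empty_cohort_rejected(self, rng):
        ann = self.make_annotation({"chr1": 3}, rng)
        with pytest.raises(InsufficientDataError, match="cohort"):
            ap.build_pair_table(
                ann,
                make_matrices(rng, ["chr1"], ["cellA"]),
                CoexpressionTable(),
                RegulatoryNetwork([]),
            )

    def test_missing_chromosome_matrix_rejected(self, rng):
        ann = self.make_annotation({"chr1": 3}, rng)
        ids = [g.id for g in ann]
        mats = make_matrices(rng, ["chr2"], ["cellA"])
        with pytest.raises(ValidationError, match="chr1"):
            ap.build_pair_table(
                ann,
                mats,
                full_coexpr(ids, rng),
                full_net(ids, rng),
            )


def hand_table(rank_a, rank_b, **extra):
    """Build a minimal table with hand-assigned percentile ranks."""
    records = []
    n = len(rank_a)
    for i in range(n):
        records.append(
            PairRecord(
                f"a{i:02d}", f"b{i:02d}", "chr1",
                oh={"cellA": float(i), "cellB": float(i)},
                pc={"cellA": 0.0, "cellB": 0.0},
                rank_pct={"cellA": rank_a[i], "cellB": rank_b[i]},
                mutual_rank=extra.get("mr", [np.nan] * n)[i],
                tcs=extra.get("tcs", [0.0] * n)[i],
                norm_dist=extra.get("nd", [0.5] * n)[i],
            )
        )
    return GenePairTable.from_records(records, ["cellA", "cellB"])


class TestRankMatchFilter:
    def test_threshold_one_retains_all(self):
        t = hand_table([0.1, 0.5, 0.9], [0.9, 0.1, 0.2])
        assert len(ap.rank_match_filter(t, "cellA", "cellB", 1.0)) == 3

    def test_identical_matrices_retain_all(self, rng):
        ann = TestBuildPairTable().make_annotation({"chr1": 6}, rng)
        ids = [g.id for g in ann]
        mats = make_matrices(rng, ["chr1"], ["cellA"])
        mats["cellB"] = {
            "chr1": ContactMatrix("chr1", "cellB", 1_000_000,
                                  mats["cellA"]["chr1"].counts.copy(), 10)
        }
        table = ap.build_pair_table(ann, mats, full_coexpr(ids, rng), full_net(ids, rng))
        out = ap.rank_match_filter(table, "cellA", "cellB", 1e-9)
        assert len(out) == len(table)

    def test_hand_listed_survivors(self):
        ra = [0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00]
        rb = [0.12, 0.30, 0.30, 0.46, 0.455, 0.64, 0.70, 0.86, 0.85, 0.96]
        # |diff|:  .02  .10   0   .06  .045  .04    0   .06  .05  .04
        t = hand_table(ra, rb)
        out = ap.rank_match_filter(t, "cellA", "cellB", 0.05)
        survivors = {f"a{i:02d}" for i in (0, 2, 4, 5, 6, 9)}
        assert set(out.df["gene_a"]) == survivors

    def test_threshold_validation(self):
        t = hand_table([0.5], [0.5])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ConfigError):
                ap.rank_match_filter(t, "cellA", "cellB", bad)

    def test_filter_chain_monotone(self):
        t = hand_table([0.1, 0.5, 0.9], [0.15, 0.9, 0.9],
                       mr=[10.0, 60.0, 40.0], nd=[0.1, 0.5, 0.3])
        matched = ap.rank_match_filter(t, "cellA", "cellB", 0.3)
        assert len(matched) <= len(t)
        for rule in ap.STRATUM_RULES:
            assert len(ap.stratify(matched, rule)) <= len(matched)
        assert matched.meta["filters"][0]["n_before"] == 3


class TestStratify:
    def test_distant_stratum_empty_when_all_close(self):
        t = hand_table([0.5] * 3, [0.5] * 3, nd=[0.1, 0.1, 0.1])
        assert len(ap.stratify(t, "distant")) == 0

    def test_distant_strict_inequality(self):
        t = hand_table([0.5] * 2, [0.5] * 2, nd=[0.2, 0.2000001])
        assert len(ap.stratify(t, "distant")) == 1

    def test_tcs_partition(self):
        t = hand_table([0.5] * 4, [0.5] * 4, tcs=[0.0, 0.3, 1.0, 0.0])
        zero = ap.stratify(t, "tcs_zero")
        nonzero = ap.stratify(t, "tcs_nonzero")
        assert len(zero) + len(nonzero) == 4

    def test_coexpressed_boundary_inclusive(self):
        t = hand_table([0.5] * 3, [0.5] * 3, mr=[10.0, 50.0, 51.0])
        kept = ap.stratify(t, "coexpressed")
        assert sorted(kept.df["mutual_rank"]) == [10.0, 50.0]

    def test_unknown_rule(self):
        t = hand_table([0.5], [0.5])
        with pytest.raises(ConfigError):
            ap.stratify(t, "closest")


class TestEqualSizeBinning:
    def test_exact_division(self):
        x = np.arange(40, dtype=float)
        assign = ap.equal_size_binning(x, 20)
        sizes = np.bincount(assign, minlength=20)
        assert list(sizes) == [2] * 20

    def test_total_tie_one_group(self):
        assign = ap.equal_size_binning(np.zeros(100), 20)
        assert set(assign) == {0}

    def test_heavy_tie_absorbed_matches_sweep_oracle(self, rng):
        x = np.concatenate([rng.random(70), np.full(30, 0.5)])
        rng.shuffle(x)
        assign = ap.equal_size_binning(x, 20)
        np.testing.assert_array_equal(assign, binning_sweep(x, 20))
        # the tie value's samples all share one group
        tie_groups = set(assign[x == 0.5])
        assert len(tie_groups) == 1

    @given(
        st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=80),
        st.integers(min_value=2, max_value=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_invariants_on_adversarial_ties(self, vals, n_groups):
        x = np.array(vals, dtype=float)
        assign = ap.equal_size_binning(x, n_groups)
        np.testing.assert_array_equal(assign, binning_sweep(x, n_groups))
        # ties never split
        for v in set(vals):
            assert len(set(assign[x == v])) == 1
        # groups ordered by x
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(assign[order]) >= 0)

    def test_distinct_sizes_differ_by_at_most_one(self, rng):
        x = rng.permutation(np.arange(37, dtype=float))
        assign = ap.equal_size_binning(x, 20)
        sizes = np.bincount(assign, minlength=20)
        assert sizes.max() - sizes.min() <= 1

    def test_config_and_input_validation(self):
        with pytest.raises(ConfigError):
            ap.equal_size_binning([1.0, 2.0], 1)
        with pytest.raises(ValidationError):
            ap.equal_size_binning([1.0, np.nan], 4)
        with pytest.raises(ValidationError):
            ap.equal_size_binning([], 4)


class TestBinnedCorrelationTest:
    def test_monotone_means_positive_r(self, rng):
        x = rng.random(400)
        y = 2.0 * x + rng.normal(0, 0.01, 400)
        res = ap.binned_correlation_test(x, y, 20)
        assert res.r > 0.9
        assert res.n_groups_nonempty == 20

    def test_group_mean_pearson_matches_direct_oracle(self, rng):
        x = rng.random(500)
        y = rng.random(500)
        res = ap.binned_correlation_test(x, y, 20)
        series = ap.binned_series(x, y, 20)
        mx = series.mean_x[series.nonempty]
        my = series.mean_y[series.nonempty]
        n = len(mx)
        num = np.sum((mx - mx.mean()) * (my - my.mean()))
        den = np.sqrt(np.sum((mx - mx.mean()) ** 2) * np.sum((my - my.mean()) ** 2))
        assert res.r == pytest.approx(num / den, abs=1e-12)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            ap.binned_correlation_test(np.zeros(50), np.arange(50.0), 20)

    def test_missing_values_dropped_pairwise(self, rng):
        x = rng.random(100)
        y = rng.random(100)
        x[:10] = np.nan
        res = ap.binned_correlation_test(x, y, 10)
        assert res.n_pairs == 90

    def test_null_p_uniformity(self):
        # y independent of x: rejection rate at alpha=.05 within binomial CI
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.random(300)
            y = rng.random(300)
            if ap.binned_correlation_test(x, y, 20).p < 0.05:
                rejections += 1
        import scipy.stats

        lo = scipy.stats.binom.ppf(0.025, reps, 0.05)
        hi = scipy.stats.binom.ppf(0.975, reps, 0.05)
        assert lo <= rejections <= hi


class TestBonferroni:
    def test_four_panels(self):
        assert ap.bonferroni_threshold(0.05, 4) == 0.0125

    def test_identity(self):
        assert ap.bonferroni_threshold(0.05, 1) == 0.05

    def test_arithmetic(self):
        assert ap.bonferroni_threshold(0.01, 5) == pytest.approx(0.002)

    def test_invalid_alpha(self):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ConfigError):
                ap.bonferroni_threshold(bad, 4)
        with pytest.raises(ConfigError):
            ap.bonferroni_threshold(0.05, 0)


class TestCoexpressedVsAllTTest:
    def test_hand_welch_six_values(self):
        t = hand_table(
            [0.5] * 6, [0.5] * 6,
            mr=[10.0, 20.0, 30.0, 100.0, 100.0, 100.0],
        )
        t.df["oh_cellA"] = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        t = GenePairTable(t.df, t.meta)
        res = ap.coexpressed_vs_all_ttest(t, "oh", "cellA")
        # Welch: means 6 and 2, each var 1, n=3 -> t = 4 / sqrt(2/3)
        assert res.statistic == pytest.approx(4.0 / np.sqrt(2.0 / 3.0))
        assert res.n_coexpressed == 3 and res.n_rest == 3
        assert res.mean_coexpressed == 6.0 and res.mean_rest == 2.0

    def test_shifted_group_tiny_p(self, rng):
        n = 400
        mr = np.r_[np.full(100, 10.0), np.full(300, 200.0)]
        oh = np.r_[rng.normal(5.0, 1.0, 100), rng.normal(0.0, 1.0, 300)]
        t = hand_table([0.5] * n, [0.5] * n, mr=list(mr))
        t.df["oh_cellA"] = oh
        t = GenePairTable(t.df, t.meta)
        assert ap.coexpressed_vs_all_ttest(t, "oh", "cellA").p < 1e-6

    def test_insufficient_group_rejected(self):
        t = hand_table([0.5] * 3, [0.5] * 3, mr=[10.0, 100.0, 100.0])
        with pytest.raises(InsufficientDataError):
            ap.coexpressed_vs_all_ttest(t, "oh", "cellA")

    def test_permutation_null_calibrated(self):
        rng = np.random.default_rng(7)
        reps = 200
        rejections = 0
        n = 300
        base_mr = np.r_[np.full(60, 10.0), np.full(240, 200.0)]
        t0 = hand_table([0.5] * n, [0.5] * n, mr=list(base_mr))
        for _ in range(reps):
            df = t0.df.copy()
            df["oh_cellA"] = rng.normal(0, 1, n)  # label-independent values
            t = GenePairTable(df, t0.meta)
            if ap.coexpressed_vs_all_ttest(t, "oh", "cellA").p < 0.05:
                rejections += 1
        import scipy.stats

        lo = scipy.stats.binom.ppf(0.025, reps, 0.05)
        hi = scipy.stats.binom.ppf(0.975, reps, 0.05)
        assert lo <= rejections <= hi


@pytest.fixture(scope="module")
def bundle_dir(tmp_path_factory):
    cfg = sd.strong_config(seed=5, n_genes=120, n_conditions=40)
    bundle = sd.simulate_bundle(cfg)
    out = tmp_path_factory.mktemp("bundle")
    sd.write_bundle(bundle, str(out))
    return out


class TestRunFullAnalysis:
    def test_end_to_end_recovers_coupling(self, bundle_dir, tmp_path):
        config = ap.load_config(str(bundle_dir / "config.yaml"))
        results = ap.run_full_analysis(config, str(tmp_path / "out"))
        panels = results.panels["all"]
        assert len(panels) == 4
        for payload in panels.values():
            assert payload["r"] < 0  # smaller mutual rank = stronger co-expression
            assert payload["significant"] is True
            assert payload["threshold"] == 0.0125
        assert (tmp_path / "out" / "results.json").exists()
        assert (tmp_path / "out" / "pair_table.tsv").exists()
        assert results.counts["pairs_rank_matched"] <= results.counts["pairs_built"]
        # GO coupling present in the strong preset
        assert "go_vs_interaction" in results.panels

    def test_deterministic_rerun_byte_identical(self, bundle_dir, tmp_path):
        config = ap.load_config(str(bundle_dir / "config.yaml"))
        ap.run_full_analysis(config, str(tmp_path / "r1"))
        ap.run_full_analysis(config, str(tmp_path / "r2"))
        b1 = (tmp_path / "r1" / "results.json").read_bytes()
        b2 = (tmp_path / "r2" / "results.json").read_bytes()
        assert b1 == b2

    def test_stage_errors_name_their_stage(self, bundle_dir):
        config = ap.load_config(str(bundle_dir / "config.yaml"))
        config["inputs"]["mutual_ranks"] = config["inputs"]["tf_targets"]
        with pytest.raises(Exception, match="stage"):
            ap.run_full_analysis(config)

    def test_results_json_schema(self, bundle_dir, tmp_path):
        config = ap.load_config(str(bundle_dir / "config.yaml"))
        ap.run_full_analysis(config, str(tmp_path / "out"))
        payload = json.loads((tmp_path / "out" / "results.json").read_text())
        assert set(payload) == {"meta", "counts", "panels", "ttests"}
        assert payload["counts"]["strata"]["all"] == payload["counts"]["pairs_rank_matched"]
        assert len(payload["ttests"]) == 4
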