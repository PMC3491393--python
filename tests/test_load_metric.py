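"""Mutational load and its aggregation procedures."""

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfbsload import load_metric as lm
from tfbsload.pwm import MotifInstance
from tfbsload.variation import Allele, InstanceAlleleSet


def make_set(scores_freqs, site_pos=None):
    inst = MotifInstance("c", 0, 8, "+", "A" * 8, scores_freqs[0][0],
                         "TF1")
    alleles = [Allele("A" * 8, f, s) for s, f in scores_freqs]
    major = int(np.argmax([f for _, f in scores_freqs]))
    return InstanceAlleleSet(inst, alleles, major, site_pos)


def make_record(load, tf="TF1", bls=None, region=None, start=0, w0=10.0,
                tss=None):
    inst = MotifInstance("c", start, start + 8, "+", "A" * 8, w0, tf)
    return lm.LoadRecord(inst, load, w0, 2, 1.0, bls=bls,
                         tss_distance=tss, region_id=region)


class TestMutationalLoad:
    def test_monomorphic_load_is_zero(self):
        assert lm.mutational_load(make_set([(7.3, 1.0)])) == 0.0

    def test_common_severe_mutation_gives_half(self):
        aset = make_set([(12.0, 0.5), (0.0, 0.5)])
        assert lm.mutational_load(aset) == pytest.approx(0.5)

    def test_score_gaining_minor_allele_gives_zero(self):
        aset = make_set([(8.0, 0.9), (11.0, 0.1)])
        assert lm.mutational_load(aset) == 0.0

    def test_direct_arithmetic_example(self):
        aset = make_set([(10.0, 0.9), (8.0, 0.1)])
        assert lm.mutational_load(aset) == pytest.approx(0.02)

    def test_multi_site_instances_take_max_per_site_load(self):
        weak = make_set([(10.0, 0.9), (9.0, 0.1)], site_pos=2)
        strong = make_set([(10.0, 0.9), (2.0, 0.1)], site_pos=5)
        assert lm.mutational_load([weak, strong]) == pytest.approx(
            (10.0 - (10.0 * 0.9 + 2.0 * 0.1)) / 10.0)

    def test_nonpositive_major_score_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            lm.mutational_load(make_set([(-1.0, 0.6), (2.0, 0.4)]))

    def test_fraction_oracle_small(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 5))
            scores = rng.integers(-200, 400, size=n) / 16
            counts = rng.integers(1, 50, size=n)
            if scores[np.argmax(counts)] <= 0:
                continue
            freqs = counts / counts.sum()
            aset = make_set(list(zip(scores.tolist(), freqs.tolist())))
            # exact rational recomputation of (w0 - sum wi pi)/w0
            fs = [Fraction(int(c), int(counts.sum())) for c in counts]
            ws = [Fraction(int(s * 16), 16) for s in scores]
            major = int(np.argmax(counts))
            w0 = ws[major]
            exact = max(Fraction(0), (w0 - sum(w * f for w, f in
                                               zip(ws, fs))) / w0)
            assert abs(lm.mutational_load(aset) - float(exact)) < 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.05, 0.45), st.floats(0.1, 9.9), st.floats(0.0, 5.0))
    def test_monotone_in_minor_score_drop(self, p_minor, minor, extra):
        w0 = 10.0
        base = lm.mutational_load(
            make_set([(w0, 1 - p_minor), (minor, p_minor)]))
        worse = lm.mutational_load(
            make_set([(w0, 1 - p_minor), (minor - extra, p_minor)]))
        assert worse >= base - 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.05, 0.44), st.floats(0.0, 0.05), st.floats(0.1, 9))
    def test_monotone_in_minor_frequency(self, p1, dp, minor):
        w0 = 10.0
        lo = lm.mutational_load(make_set([(w0, 1 - p1), (minor, p1)]))
        hi = lm.mutational_load(
            make_set([(w0, 1 - p1 - dp), (minor, p1 + dp)]))
        assert hi >= lo - 1e-12

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(0.05, 0.95), st.floats(0.0, 9))
    def test_scale_invariance(self, c, p_minor, minor):
        w0 = 10.0
        a = lm.mutational_load(make_set([(w0, 1 - p_minor),
                                         (minor, p_minor)]))
        b = lm.mutational_load(make_set([(w0 * c, 1 - p_minor),
                                         (minor * c, p_minor)]))
        assert a == pytest.approx(b, abs=1e-9)


class TestTrimmedMean:
    def test_basic_values(self):
        assert lm.trimmed_mean_load([1e-3, 2e-3, 3e-3]) == \
            pytest.approx(1.5e-3)
        assert lm.trimmed_mean_load([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_single_value_reports_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert lm.trimmed_mean_load([0.7]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lm.trimmed_mean_load([])

    def test_matches_sort_drop_last_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(1e-3, size=1000)
        expect = np.sort(vals)[:-1].mean()
        assert lm.trimmed_mean_load(vals) == pytest.approx(expect)


class TestWindowedLoad:
    def test_empty_input_gives_empty_table(self):
        assert lm.windowed_load([]).empty

    def test_single_instance_window_trims_to_zero(self):
        df = lm.windowed_load([make_record(0.9, start=5)])
        assert df.loc[0, "mean_load"] == 0.0
        assert not df.loc[0, "hotspot"]

    def test_planted_hotspot_is_the_only_flagged_window(self):
        records = []
        # quiet windows: many zero-load instances
        for w in range(5):
            for i in range(10):
                records.append(make_record(0.0, start=w * 100_000 + i * 50))
        # hotspot in window 5: large loads
        for i in range(10):
            records.append(make_record(0.02, start=5 * 100_000 + i * 50))
        df = lm.windowed_load(records)
        flagged = df[df["hotspot"]]
        assert list(flagged["window_start"]) == [500_000]
        assert flagged.iloc[0]["mean_load"] == pytest.approx(0.02)


class TestAggregateLoad:
    def test_all_bls_zero_single_bin(self):
        records = [make_record(1e-3 * i, bls=0.0) for i in range(6)]
        df = lm.aggregate_load(records, "bls")
        assert list(df["group"]) == ["BLS=0"]
        assert df.loc[0, "n"] == 6

    def test_bls_zero_bin_kept_separate(self):
        records = [make_record(1e-3, bls=0.0) for _ in range(3)]
        records += [make_record(1e-3, bls=0.1) for _ in range(3)]
        df = lm.aggregate_load(records, "bls")
        assert df.loc[0, "group"] == "BLS=0"
        assert df.loc[0, "n"] == 3

    def test_score_quintiles_of_equal_size(self):
        records = [make_record(0.0, w0=float(i)) for i in range(10)]
        df = lm.aggregate_load(records, "score")
        assert list(df["group"]) == [f"Q{i}" for i in range(1, 6)]
        assert list(df["n"]) == [2] * 5

    def test_tss_bins(self):
        records = [make_record(0.0, tss=d)
                   for d in [100, 700, 1500, 3000, 7000, 20_000]]
        df = lm.aggregate_load(records, "tss")
        assert len(df) == 6
        assert df["n"].sum() == 6


class TestHomotypicAnalyses:
    def _records(self, rng, n_singleton=40, n_duplet=30, shift=0.0):
        records = []
        for i in range(n_singleton):
            records.append(make_record(float(rng.exponential(1e-3)),
                                       bls=float(rng.uniform(0, 1)),
                                       region=f"s{i}", start=i * 1000))
        for i in range(n_duplet):
            for j in range(2):
                records.append(make_record(
                    float(rng.exponential(1e-3) + shift),
                    bls=float(rng.uniform(0, 1)),
                    region=f"d{i}", start=50_000 + i * 1000 + j * 40))
        return records

    def test_triplet_regions_excluded(self):
        rng = np.random.default_rng(2)
        records = self._records(rng)
        records += [make_record(0.5, region="t0", start=90_000 + j * 40)
                    for j in range(3)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, res = lm.singleton_duplet_comparison(
                records, n_draws=20, seed=0, n_perm=200)
        assert table["n_singleton"].max() <= 40
        # the 0.5-load triplet motifs never enter either class
        assert table["mean_singleton"].max() < 0.5
        assert table["mean_duplet"].max() < 0.5

    def test_planted_duplet_excess_gives_negative_statistic(self):
        rng = np.random.default_rng(3)
        records = self._records(rng, shift=5e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, res = lm.singleton_duplet_comparison(records, n_draws=20,
                                                    seed=0, n_perm=200)
        assert res.observed < 0

    def test_load_vs_motif_count_two_tfs(self):
        records = [make_record(1e-3, tf="A", region="r1"),
                   make_record(2e-3, tf="A", region="r1"),
                   make_record(5e-3, tf="B", region="r2"),
                   make_record(9e-3, tf="B", region="r3")]
        table, r, p = lm.load_vs_motif_count(records)
        assert len(table) == 2
        assert abs(r) == pytest.approx(1.0)

    def test_constant_loads_give_nan_correlation(self):
        records = [make_record(1e-3, tf=t, region="r")
                   for t in ["A", "B", "C"]]
        _, r, _ = lm.load_vs_motif_count(records)
        assert np.isnan(r)

    def test_variable_vs_constant_requires_zero_load_partner(self):
        # region whose motifs all vary is excluded
        records = [make_record(1e-3, region="r1", start=0),
                   make_record(2e-3, region="r1", start=40)]
        table, _, _ = lm.variable_vs_constant_scores(records, seed=0)
        assert table.empty

    def test_equal_scores_give_zero_difference(self):
        records = [make_record(1e-3, region="r1", start=0, w0=9.0),
                   make_record(0.0, region="r1", start=40, w0=9.0)]
        table, med, p = lm.variable_vs_constant_scores(records, seed=0)
        assert table.loc[0, "difference"] == 0.0
        assert p == 1.0


class TestAggregateTrend:
    def test_monotone_load_score_relation_detected(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(300):
            w0 = float(rng.uniform(5, 15))
            lam = 4e-3 * (15 - w0) / 10  # weaker motifs carry more load
            records.append(make_record(float(rng.exponential(lam)),
                                       w0=w0, start=i * 100))
        res = lm.aggregate_trend_test(records, "score", n_perm=300,
                                      seed=0, alternative="less")
        assert res.observed < 0
        assert res.p_value < 0.05
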