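"""Quantile normalization, buffering classification, interaction models."""

import numpy as np
import pandas as pd
import pytest

from tfbsload import buffering as buf
from tfbsload import synthetic as syn


def toy_table(sites_meta, signals, genotypes):
    individuals = [f"i{j}" for j in range(signals.shape[1])]
    idx = [f"s{i}" for i in range(signals.shape[0])]
    return buf.IndividualBindingTable(
        sites=pd.DataFrame(sites_meta, index=idx),
        signals=pd.DataFrame(signals, index=idx, columns=individuals),
        genotypes=pd.DataFrame(genotypes, index=idx, columns=individuals))


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        out = buf.quantile_normalize(m)
        assert np.allclose(out.to_numpy(), m)

    def test_permuted_columns_share_multiset(self):
        a = np.array([1.0, 5.0, 2.0, 9.0])
        m = np.stack([a, a[::-1]], axis=1)
        out = buf.quantile_normalize(m).to_numpy()
        assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))

    def test_three_by_four_hand_oracle(self):
        m = np.array([[5.0, 4.0, 3.0, 8.0],
                      [2.0, 1.0, 9.0, 4.0],
                      [3.0, 6.0, 6.0, 2.0]])
        # sorted columns: (2,3,5),(1,4,6),(3,6,9),(2,4,8); row means of
        # sorted values: (2, 4.25, 7); assign by each column's ranks
        expect = np.array([[7.0, 4.25, 2.0, 7.0],
                           [2.0, 1e9, 7.0, 4.25],
                           [4.25, 7.0, 4.25, 2.0]])
        expect[1, 1] = 2.0
        out = buf.quantile_normalize(m).to_numpy()
        assert np.allclose(out, expect)

    def test_ties_averaged(self):
        m = np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        out = buf.quantile_normalize(m).to_numpy()
        ref = np.sort(m, axis=0).mean(axis=1)   # (1, 1.5, 4)
        # col0 has a tie at ranks 1,2 -> both get (1 + 1.5)/2
        assert out[0, 0] == pytest.approx(1.25)
        assert out[1, 0] == pytest.approx(1.25)
        assert out[2, 0] == pytest.approx(ref[2])

    def test_output_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(40, 6))
        out = buf.quantile_normalize(m).to_numpy()
        first = np.sort(out[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out[:, j]), first)


class TestGenotypeSummary:
    def _table(self):
        meta = {"score_major": [10.0, 10.0], "score_minor": [7.0, 7.0],
                "bls": [0.2, 0.8]}
        signals = np.array([[4.0, 6.0, 5.0], [3.0, 3.0, 9.0]])
        genotypes = np.array([["major", "major", "minor"],
                              ["minor", "minor", "major"]])
        return toy_table(meta, signals, genotypes)

    def test_means_per_genotype_class(self):
        summary = buf.genotype_signal_summary(self._table())
        row = summary[(summary["site"] == "s0")
                      & (summary["genotype"] == "major")]
        assert row["mean_signal"].iloc[0] == pytest.approx(5.0)
        assert row["n_individuals"].iloc[0] == 2

    def test_missing_class_absent_not_zero(self):
        meta = {"score_major": [10.0], "score_minor": [7.0], "bls": [0.5]}
        signals = np.array([[4.0, 6.0]])
        genotypes = np.array([["major", "major"]])
        summary = buf.genotype_signal_summary(
            toy_table(meta, signals, genotypes))
        assert set(summary["genotype"]) == {"major"}

    def test_unknown_genotype_label_rejected(self):
        meta = {"score_major": [10.0], "score_minor": [7.0], "bls": [0.5]}
        signals = np.array([[4.0, 6.0]])
        genotypes = np.array([["major", "wild"]])
        with pytest.raises(ValueError, match="genotype"):
            toy_table(meta, signals, genotypes)


class TestClassifyBuffered:
    def test_ratio_boundaries(self):
        assert buf.classify_buffered(9.0, 6.3)          # 0.7
        assert not buf.classify_buffered(9.0, 4.5)      # 0.5
        assert buf.classify_buffered(9.0, 6.0)          # exactly 2/3

    def test_invariant_to_positive_rescaling(self):
        for c in [0.1, 1.0, 17.0]:
            assert buf.classify_buffered(9.0 * c, 6.3 * c) == \
                buf.classify_buffered(9.0, 6.3)

    def test_heterozygous_only_sites_not_classified(self):
        meta = {"score_major": [10.0], "score_minor": [7.0], "bls": [0.5]}
        signals = np.array([[4.0, 6.0]])
        genotypes = np.array([["major", "het"]])
        table = toy_table(meta, signals, genotypes)
        assert buf.site_buffering_table(table).empty


class TestBufferingByConservation:
    def _site_table(self, buffered_lo, buffered_hi):
        rows = []
        for i, b in enumerate(buffered_lo):
            rows.append({"site": f"lo{i}", "signal_major": 9.0,
                         "signal_minor": 8.0 if b else 1.0, "bls": 0.2,
                         "buffered": b})
        for i, b in enumerate(buffered_hi):
            rows.append({"site": f"hi{i}", "signal_major": 9.0,
                         "signal_minor": 8.0 if b else 1.0, "bls": 0.8,
                         "buffered": b})
        return pd.DataFrame(rows).set_index("site")

    def test_counts_and_fisher(self):
        table = self._site_table([True] * 5 + [False] * 5,
                                 [True] * 9 + [False] * 1)
        counts, odds, p = buf.buffering_by_conservation(table)
        assert counts.loc["BLS<0.5", "buffered"] == 5
        assert counts.loc["BLS>=0.5", "not_buffered"] == 1
        assert 0 < p <= 1

    def test_all_buffered_gives_nan_odds(self):
        table = self._site_table([True] * 5, [True] * 5)
        _, odds, _ = buf.buffering_by_conservation(table)
        assert np.isnan(odds)

    def test_empty_stratum_rejected(self):
        table = self._site_table([True] * 5, [])
        with pytest.raises(ValueError, match="stratum"):
            buf.buffering_by_conservation(table)


class TestDeltaAnalysis:
    def _records(self):
        return pd.DataFrame({
            "delta_score": [-0.5, -1.0, -2.0, -3.0],
            "delta_chip": [0.1, 0.2, 1.5, 2.0],
            "bls": [0.1, 0.9, 0.2, 0.8],
        }, index=["a", "b", "c", "d"])

    def test_exact_split_value_in_neither_group(self):
        out = buf.delta_analysis(self._records(), score_split=1.0)
        assert out.loc[0, "n_low"] == 1      # only |d|=0.5
        assert out.loc[0, "n_high"] == 2     # |d|=2,3 ; |d|=1 excluded

    def test_all_zero_changes_give_p_one(self):
        rec = self._records()
        rec["delta_chip"] = 0.0
        out = buf.delta_analysis(rec, score_split=1.0)
        assert out.loc[0, "wilcoxon_p"] == 1.0

    def test_sign_adjustment_convention(self):
        # score loss with signal loss = concordant -> positive
        assert buf.sign_adjust(-2.0, -1.5) == 2.0
        # score loss with signal gain = discordant -> negative
        assert buf.sign_adjust(1.0, -1.5) == -1.0
        assert buf.sign_adjust(5.0, 0.0) == 0.0


class TestInteractionModel:
    def test_exact_recovery_on_noise_free_fixture(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 4, 200)
        b = rng.uniform(0, 1, 200)
        y = 1.5 + 2.0 * x - 0.5 * b - 1.25 * x * b
        fit = buf.interaction_model(x, b, y)
        assert fit.params["const"] == pytest.approx(1.5, abs=1e-9)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params["bls"] == pytest.approx(-0.5, abs=1e-9)
        assert fit.interaction == pytest.approx(-1.25, abs=1e-9)

    def test_collinear_predictors_rejected_with_condition_number(self):
        x = np.ones(50)
        b = np.ones(50)
        with pytest.raises(ValueError, match="condition number"):
            buf.interaction_model(x, b, np.arange(50.0))

    def test_effect_curAccording_to_fit(self):
        x = np.linspace(0, 4, 100)
        b = np.tile([0.0, 1.0], 50)
        y = 1.0 + 3.0 * x - 3.0 * x * b   # full damping at bls = 1
        fit = buf.interaction_model(x, b, y)
        curve0 = fit.effect_curve(0.0, [0, 1, 2])
        curve1 = fit.effect_curve(1.0, [0, 1, 2])
        assert curve0 == pytest.approx([1.0, 4.0, 7.0], abs=1e-8)
        assert curve1 == pytest.approx([1.0, 1.0, 1.0], abs=1e-8)

    def test_null_interaction_p_roughly_uniform(self):
        """Permuting conservation labels breaks the interaction."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(50):
            chip = syn.make_chip_individuals(
                n_sites=120, seed=int(rng.integers(2 ** 31)))
            rec = buf.delta_records(chip.table)
            shuffled = rec["bls"].sample(
                frac=1.0, random_state=int(rng.integers(2 ** 31)))
            fit = buf.interaction_model(rec["delta_score"].abs(),
                                        shuffled.to_numpy(),
                                        rec["delta_chip"])
            rejections += fit.interaction_p < 0.05
        assert rejections <= 10


class TestPipelineRecovery:
    def test_planted_buffering_fraction_recovered(self):
        chip = syn.make_chip_individuals(n_sites=500, seed=3)
        st = buf.site_buffering_table(chip.table)
        probs = chip.buffering_probability.loc[st.index]
        for stratum in [st["bls"] < 0.5, st["bls"] >= 0.5]:
            observed = st.loc[stratum, "buffered"].mean()
            p = probs[stratum.to_numpy()]
            expect = p.mean()
            se = np.sqrt((p * (1 - p)).sum()) / len(p)
            assert abs(observed - expect) <= 2 * max(se, 1e-6) + 1e-9

    def test_full_buffering_limit_leaves_signal_flat(self):
        chip = syn.make_chip_individuals(n_sites=60, noise_sd=0.0,
                                         buffering_coef=1.0,
                                         bls=np.ones(60), seed=4)
        rec = buf.delta_records(chip.table)
        assert np.allclose(rec["delta_chip"], 0.0)

    def test_no_buffering_makes_delta_chip_track_delta_score(self):
        chip = syn.make_chip_individuals(n_sites=400, noise_sd=0.0,
                                         buffering_coef=0.0, seed=5)
        rec = buf.delta_records(chip.table)
        # signal = baseline + slope*score exactly -> sign-adjusted
        # delta chip == slope * |delta score|
        assert np.allclose(rec["delta_chip"],
                           chip.score_slope * rec["delta_score"].abs())
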