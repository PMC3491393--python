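"""Variant filtering, allele sets and position-wise diversity."""

import numpy as np
import pytest

from tfbsload import variation as var
from tfbsload.pwm import MotifInstance, PWM, scramble_pwm, score_window
from tfbsload.variation import (HET, MISSING, VariantSite,
                                alleles_for_instance, dereshuffle_profile,
                                filter_dgrp, instance_base_frequencies,
                                interspecies_profile, positional_diversity,
                                relative_interspecies_profile)

N_STRAINS = 162


def make_site(pos=100, eps=0.01, cov=(10.0, 8.0), med=12.0,
              n_alt=40, n_missing=0, n_het=0, ref="A", alt="T"):
    calls = np.zeros(N_STRAINS, dtype=np.int8)
    calls[:n_alt] = 1
    if n_missing:
        calls[n_alt:n_alt + n_missing] = MISSING
    if n_het:
        calls[n_alt + n_missing:n_alt + n_missing + n_het] = HET
    return VariantSite("chr2L", pos, ref, (alt,), calls, ploidy=1,
                       eps=eps, allele_coverage=cov, median_coverage=med)


class TestFilterDGRP:
    def test_eps_violation_removed_with_reason(self):
        kept, removed = filter_dgrp([make_site(eps=0.03)])
        assert kept == []
        assert removed[0][1] == "eps"

    def test_too_few_homozygous_strains_removed(self):
        # 99 confident homozygous calls < 100
        kept, removed = filter_dgrp([make_site(n_missing=63)])
        assert removed[0][1] == "n_homozygous"

    def test_het_fraction_bound(self):
        # 9/171 called strains het > 5%
        site = make_site(n_het=9)
        kept, removed = filter_dgrp([site])
        assert removed[0][1] == "het_fraction"
        kept, removed = filter_dgrp([make_site(n_het=8)])
        assert len(kept) == 1

    def test_allele_pruning_precedes_site_checks(self):
        # alt coverage < 3 prunes the alt allele -> monomorphic
        kept, removed = filter_dgrp([make_site(cov=(10.0, 2.0))])
        assert removed[0][1] == "monomorphic"
        # p * eps > 0.01 for the major allele prunes it likewise
        kept, removed = filter_dgrp([make_site(eps=0.018, n_alt=40)])
        assert removed[0][1] == "monomorphic"

    def test_planted_twenty_site_table_hand_enumerated(self):
        sites = [make_site(pos=i) for i in range(14)]           # clean
        sites += [make_site(pos=20, eps=0.05),                  # eps
                  make_site(pos=21, cov=(2.0, 10.0)),           # ref cov
                  make_site(pos=22, med=30.0),                  # median
                  make_site(pos=23, n_missing=70),              # n_hom
                  make_site(pos=24, n_het=20),                  # het
                  make_site(pos=25, cov=(10.0, 1.0))]           # alt cov
        kept, removed = filter_dgrp(sites)
        assert len(kept) == 14
        assert len(removed) == 6
        assert sorted(s.pos for s in kept) == list(range(14))

    def test_idempotent(self):
        sites = [make_site(pos=i) for i in range(5)]
        kept, _ = filter_dgrp(sites)
        kept2, removed2 = filter_dgrp(kept)
        assert removed2 == []
        assert [s.pos for s in kept2] == [s.pos for s in kept]

    def test_missing_fields_named(self):
        site = make_site()
        site.eps = None
        with pytest.raises(ValueError, match="eps"):
            filter_dgrp([site])


@pytest.fixture
def instance_pair(toy_pwm):
    seq = "".join("ACGT"[i % 4] for i in range(8))
    plus = MotifInstance("chr2L", 100, 108, "+", seq,
                         score_window(toy_pwm, seq, "+"), "TF1")
    minus = MotifInstance("chr2L", 100, 108, "-", seq,
                          score_window(toy_pwm, seq, "+"), "TF1")
    return plus, minus


class TestAllelesForInstance:
    def test_no_variants_single_reference_allele(self, toy_pwm,
                                                 instance_pair):
        plus, _ = instance_pair
        sets = alleles_for_instance(plus, [], toy_pwm)
        assert len(sets) == 1
        aset = sets[0]
        assert len(aset.alleles) == 1
        assert aset.alleles[0].frequency == 1.0
        assert aset.alleles[0].sequence == plus.matched_sequence

    def test_strain_counts_give_frequencies(self, toy_pwm, instance_pair):
        plus, _ = instance_pair
        calls = np.zeros(100, dtype=np.int8)
        calls[:10] = 1
        site = VariantSite("chr2L", 103, "T", ("G",), calls, ploidy=1)
        aset = alleles_for_instance(plus, [site], toy_pwm)[0]
        freqs = sorted(a.frequency for a in aset.alleles)
        assert freqs == pytest.approx([0.1, 0.9])
        minor = min(aset.alleles, key=lambda a: a.frequency)
        assert minor.sequence[3] == "G"

    def test_minus_strand_alleles_mirrored_and_complemented(
            self, toy_pwm, instance_pair):
        _, minus = instance_pair
        calls = np.zeros(100, dtype=np.int8)
        calls[:10] = 1
        # forward-strand C->T at genome offset 2 = motif offset 5 (G->A)
        site = VariantSite("chr2L", 102, "G", ("C",), calls, ploidy=1)
        aset = alleles_for_instance(minus, [site], toy_pwm)[0]
        minor = min(aset.alleles, key=lambda a: a.frequency)
        major = max(aset.alleles, key=lambda a: a.frequency)
        assert major.sequence[5] == "C"   # revcomp of ref G
        assert minor.sequence[5] == "G"   # revcomp of alt C

    def test_het_and_missing_strains_excluded(self, toy_pwm,
                                              instance_pair):
        plus, _ = instance_pair
        calls = np.zeros(10, dtype=np.int8)
        calls[0] = 1
        calls[1] = HET
        calls[2] = MISSING
        site = VariantSite("chr2L", 104, "A", ("C",), calls, ploidy=1)
        aset = alleles_for_instance(plus, [site], toy_pwm)[0]
        # 8 usable strains: 7 ref + 1 alt
        assert sorted(a.frequency for a in aset.alleles) == \
            pytest.approx([1 / 8, 7 / 8])

    def test_indel_site_skipped_with_warning(self, toy_pwm, instance_pair):
        plus, _ = instance_pair
        calls = np.zeros(10, dtype=np.int8)
        site = VariantSite("chr2L", 104, "A", ("AT",), calls, ploidy=1)
        with pytest.warns(UserWarning, match="indel"):
            sets = alleles_for_instance(plus, [site], toy_pwm)
        assert len(sets[0].alleles) == 1

    def test_diploid_sites_counted_per_allele(self, toy_pwm,
                                              instance_pair):
        plus, _ = instance_pair
        calls = np.array([[0, 1], [0, 0], [1, 1]], dtype=np.int8)
        site = VariantSite("chr2L", 101, "C", ("A",), calls, ploidy=2)
        aset = alleles_for_instance(plus, [site], toy_pwm)[0]
        assert aset.site_pos == 101
        assert sorted(a.frequency for a in aset.alleles) == \
            pytest.approx([3 / 6, 3 / 6])

    def test_frequencies_always_sum_to_one(self, toy_pwm, instance_pair):
        plus, _ = instance_pair
        rng = np.random.default_rng(3)
        for _ in range(20):
            calls = rng.integers(0, 2, size=50).astype(np.int8)
            calls[rng.random(50) < 0.1] = MISSING
            if (calls >= 0).sum() == 0:
                continue
            site = VariantSite("chr2L", int(rng.integers(100, 108)),
                               "A", ("G",), calls, ploidy=1)
            for aset in alleles_for_instance(plus, [site], toy_pwm):
                assert sum(a.frequency for a in aset.alleles) == \
                    pytest.approx(1.0, abs=1e-9)


class TestPositionalDiversity:
    def _aset(self, toy_pwm, inst, seq_freqs):
        alleles = [var.Allele(s, f, score_window(toy_pwm, s, "+"))
                   for s, f in seq_freqs.items()]
        major = int(np.argmax([a.frequency for a in alleles]))
        return var.InstanceAlleleSet(inst, alleles, major)

    def test_monomorphic_and_biallelic_values(self, toy_pwm):
        inst = MotifInstance("c", 0, 8, "+", "A" * 8, 1.0, "TF1")
        aset = self._aset(toy_pwm, inst,
                          {"A" * 8: 0.5, "C" + "A" * 7: 0.5})
        D = positional_diversity([inst], [[aset]])
        assert D[0] == pytest.approx(0.5)      # 1 - 2 * 0.25
        assert np.allclose(D[1:], 0.0)         # monomorphic positions

    def test_matches_strain_enumeration_oracle(self, toy_pwm):
        rng = np.random.default_rng(8)
        instances, allelesets, strain_bases = [], [], []
        for i in range(3):
            ref = "".join(rng.choice(list("ACGT"), size=8))
            inst = MotifInstance("c", i * 50, i * 50 + 8, "+", ref, 1.0,
                                 "TF1")
            strains = np.array([list(ref)] * 20)
            alt_pos = int(rng.integers(8))
            n_alt = int(rng.integers(1, 10))
            alt_base = rng.choice([b for b in "ACGT"
                                   if b != ref[alt_pos]])
            strains[:n_alt, alt_pos] = alt_base
            freqs = {}
            for row in strains:
                s = "".join(row)
                freqs[s] = freqs.get(s, 0.0) + 1 / 20
            instances.append(inst)
            allelesets.append([self._aset(toy_pwm, inst, freqs)])
            strain_bases.append(strains)
        D = positional_diversity(instances, allelesets)
        # oracle: per-instance heterozygosity from raw strain bases
        expect = np.zeros(8)
        for strains in strain_bases:
            for j in range(8):
                _, counts = np.unique(strains[:, j], return_counts=True)
                f = counts / counts.sum()
                expect[j] += (1.0 - np.sum(f ** 2)) / len(strain_bases)
        assert D == pytest.approx(expect)


class TestDereshuffle:
    def test_inverse_permutation_recovers_values(self, toy_pwm):
        recs = scramble_pwm(toy_pwm, n=4, seed=2)
        base = np.arange(8, dtype=float)
        profiles = [base[r.permutation] for r in recs]
        aligned = dereshuffle_profile(profiles, recs)
        assert np.allclose(aligned, base)

    def test_constant_profile_stays_constant(self, toy_pwm):
        recs = scramble_pwm(toy_pwm, n=3, seed=2)
        aligned = dereshuffle_profile([np.full(8, 0.3)] * 3, recs)
        assert np.allclose(aligned, 0.3)

    def test_hand_built_three_position_case(self):
        probs = np.array([[0.8, 0.1, 0.05, 0.05],
                          [0.1, 0.8, 0.05, 0.05],
                          [0.05, 0.05, 0.8, 0.1],
                          [0.05, 0.05, 0.1, 0.8]])
        pwm = PWM.from_probabilities("t", probs)
        rec = scramble_pwm(pwm, n=1, seed=0)[0]
        # value measured at scrambled position j belongs to parent
        # column permutation[j]
        measured = np.array([10.0, 20.0, 30.0, 40.0])
        aligned = dereshuffle_profile([measured], [rec])[0]
        for j, parent in enumerate(rec.permutation):
            assert aligned[parent] == measured[j]


class TestInterspeciesProfile:
    def _instances(self):
        return [MotifInstance("c", 0, 4, "+", "ACGT", 1.0, "T"),
                MotifInstance("c", 10, 14, "-", "ACGT", 1.0, "T")]

    def test_fully_conserved_gives_zero(self):
        track = {"c": np.ones(20)}
        prof = interspecies_profile(self._instances(), track)
        assert np.allclose(prof, 0.0)

    def test_hand_built_two_instance_case(self):
        track = {"c": np.zeros(20)}
        track["c"][0:4] = [1.0, 0.8, 0.6, 0.4]
        track["c"][10:14] = [0.2, 0.4, 0.6, 0.8]
        prof = interspecies_profile(self._instances(), track)
        # minus-strand instance contributes its values reversed
        expect = (np.array([0.0, 0.2, 0.4, 0.6])
                  + np.array([0.2, 0.4, 0.6, 0.8])) / 2
        assert prof == pytest.approx(expect)

    def test_equal_real_and_scrambled_gives_unit_ratio(self, toy_pwm):
        recs = scramble_pwm(toy_pwm, n=3, seed=1)
        real = np.full(8, 0.4)
        scr = [real[r.permutation] for r in recs]
        rel = relative_interspecies_profile(real, scr, recs)
        assert np.allclose(rel, 1.0)
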