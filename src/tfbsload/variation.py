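"""Population variation at motif instances.

This module carries variant sites from filtered population data onto
motif instances, producing per-instance allele sets (the w_i, p_i pairs
feeding the mutational load metric) and position-wise diversity
profiles.  Two kinds of genotype data are supported:

* isogenic strain panels (haploid-like calls, one haplotype per line,
  e.g. a DGRP-style freeze) — alleles are observed full-length motif
  haplotypes;
* unphased diploid cohorts (VCF genotypes) — each genotype contributes
  two allele observations per site, and instances spanning several
  variant sites are evaluated site-by-site because haplotypes are
  unknown.

Diversity per motif position is Nei's gene diversity 1 - sum(f^2) on
each instance's own population base frequencies, averaged over
instances (so it measures within-population variation, not sequence
differences between instances), and is normalised against
scrambled-motif nulls after "de-reshuffling" the scrambled positions
back onto the real motif's coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .pwm import (PWM, MotifInstance, ScrambleRecord, encode,
                  reverse_complement, score_window)

#: call codes for strain (haploid) data
MISSING = -1
HET = -2


@dataclass
class VariantSite:
    """A single-nucleotide variant with per-sample calls.

    ``pos`` is 0-based.  For strain panels ``calls`` is a 1-D int8 array
    of allele indices (-1 missing, -2 heterozygous); for diploid cohorts
    it is an (n, 2) array of allele indices with -1 for missing.
    DGRP-style confidence fields (``eps``, per-allele coverage, median
    coverage) are optional and only required by :func:`filter_dgrp`.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    calls: np.ndarray
    ploidy: int = 1
    eps: Optional[float] = None
    allele_coverage: Optional[tuple[float, ...]] = None
    median_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.pos < 0:
            raise ValueError("position must be >= 0")
        if self.ploidy == 1 and self.calls.ndim != 1:
            raise ValueError("haploid calls must be 1-D")
        if self.ploidy == 2 and (self.calls.ndim != 2
                                 or self.calls.shape[1] != 2):
            raise ValueError("diploid calls must be (n, 2)")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_snv(self) -> bool:
        return all(len(a) == 1 for a in self.alleles)

    def allele_counts(self) -> np.ndarray:
        """Counts of each allele over called (non-missing, non-het) calls."""
        flat = self.calls.ravel()
        called = flat[flat >= 0]
        return np.bincount(called, minlength=len(self.alleles)).astype(float)

    def allele_frequencies(self) -> np.ndarray:
        counts = self.allele_counts()
        total = counts.sum()
        if total == 0:
            raise ValueError(f"no called alleles at {self.contig}:{self.pos}")
        return counts / total

    @property
    def n_homozygous(self) -> int:
        """Strains with a confident homozygous call (haploid panels)."""
        if self.ploidy == 1:
            return int(np.sum(self.calls >= 0))
        return int(np.sum((self.calls[:, 0] >= 0)
                          & (self.calls[:, 0] == self.calls[:, 1])))

    @property
    def het_fraction(self) -> float:
        """Fraction of strains with any call that were scored heterozygous."""
        if self.ploidy == 1:
            n_het = int(np.sum(self.calls == HET))
            n_called = n_het + self.n_homozygous
        else:
            has_call = (self.calls >= 0).all(axis=1)
            n_het = int(np.sum(has_call
                               & (self.calls[:, 0] != self.calls[:, 1])))
            n_called = int(has_call.sum())
        return n_het / n_called if n_called else 0.0


# ----------------------------------------------------------------------
# DGRP-style filtering
# ----------------------------------------------------------------------

def filter_dgrp(sites: Iterable[VariantSite], *,
                eps_max: float = 0.02,
                p_eps_max: float = 0.01,
                min_allele_coverage: float = 3,
                max_median_coverage: float = 20,
                min_homozygous_strains: int = 100,
                max_het_fraction: float = 0.05
                ) -> tuple[list[VariantSite], list[tuple[VariantSite, str]]]:
    """Apply the six confidence filters for isogenic-panel SNP calls.

    Per-allele criteria (coverage >= 3 and p*eps <= 0.01) prune alleles
    first — calls of a pruned allele become missing — then the per-site
    criteria are checked: eps <= 0.02, median coverage <= 20 across
    strains, >= 100 strains with homozygous calls, and <= 5% of calls
    heterozygous.  A site is kept iff all criteria hold; sites pruned
    to fewer than two alleles carry no variation and are removed with
    reason ``monomorphic``.

    Returns ``(kept, removed)`` where ``removed`` pairs each site with
    the first failed criterion.  The filter is idempotent.
    """
    kept: list[VariantSite] = []
    removed: list[tuple[VariantSite, str]] = []
    for site in sites:
        if site.eps is None:
            raise ValueError(
                f"site {site.contig}:{site.pos} lacks required field 'eps'")
        if site.allele_coverage is None:
            raise ValueError(f"site {site.contig}:{site.pos} lacks required "
                             "field 'allele_coverage'")
        if site.median_coverage is None:
            raise ValueError(f"site {site.contig}:{site.pos} lacks required "
                             "field 'median_coverage'")
        if site.eps > eps_max:
            removed.append((site, "eps"))
            continue
        freqs = site.allele_frequencies()
        cov = np.asarray(site.allele_coverage, dtype=float)
        bad = (cov < min_allele_coverage) | (freqs * site.eps > p_eps_max)
        site = _prune_alleles(site, np.nonzero(bad)[0])
        n_left = int(np.sum(site.allele_counts() > 0))
        if n_left < 2:
            removed.append((site, "monomorphic"))
        elif site.median_coverage > max_median_coverage:
            removed.append((site, "median_coverage"))
        elif site.n_homozygous < min_homozygous_strains:
            removed.append((site, "n_homozygous"))
        elif site.het_fraction > max_het_fraction:
            removed.append((site, "het_fraction"))
        else:
            kept.append(site)
    return kept, removed


def _prune_alleles(site: VariantSite, bad_idx: np.ndarray) -> VariantSite:
    if bad_idx.size == 0:
        return site
    calls = site.calls.copy()
    for i in bad_idx:
        calls[calls == i] = MISSING
    return VariantSite(site.contig, site.pos, site.ref, site.alts, calls,
                       site.ploidy, site.eps, site.allele_coverage,
                       site.median_coverage)


# ----------------------------------------------------------------------
# Allele sets
# ----------------------------------------------------------------------

@dataclass
class Allele:
    sequence: str          # strand-oriented K-mer
    frequency: float
    score: float


@dataclass
class InstanceAlleleSet:
    """Observed alleles of one motif instance (houses w0, wi, pi).

    ``site_pos`` is set when the allele set describes a single variant
    site of an unphased multi-site instance; ``None`` means the alleles
    are full haplotypes of the instance.
    """

    instance: MotifInstance
    alleles: list[Allele]
    major_index: int
    site_pos: Optional[int] = None

    def __post_init__(self) -> None:
        total = sum(a.frequency for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        fmax = max(a.frequency for a in self.alleles)
        if self.alleles[self.major_index].frequency < fmax - 1e-12:
            raise ValueError("major_index does not hold maximal frequency")

    @property
    def major(self) -> Allele:
        return self.alleles[self.major_index]

    @property
    def minor_frequency(self) -> float:
        return 1.0 - self.major.frequency


def _mapped_offsets(instance: MotifInstance,
                    sites: Sequence[VariantSite]) -> list[int]:
    """Forward-genome offsets of each site within the instance window."""
    return [s.pos - instance.start for s in sites]


def _orient(kmer: str, strand: str) -> str:
    return reverse_complement(kmer) if strand == "-" else kmer


def _build_set(instance: MotifInstance, pwm: PWM,
               seq_freqs: dict[str, float],
               site_pos: Optional[int]) -> InstanceAlleleSet:
    alleles = [Allele(seq, f, score_window(pwm, seq, "+"))
               for seq, f in sorted(seq_freqs.items())]
    # frequency ties break toward the higher-scoring allele
    major = max(range(len(alleles)),
                key=lambda i: (alleles[i].frequency, alleles[i].score))
    return InstanceAlleleSet(instance, alleles, major, site_pos)


def alleles_for_instance(instance: MotifInstance,
                         sites: Sequence[VariantSite],
                         pwm: PWM) -> list[InstanceAlleleSet]:
    """Observed alleles of a motif instance, scored with its own PWM.

    Alleles are reported in motif orientation (minus-strand instances
    are reverse complemented before scoring).  With strain data, alleles
    are full K-mer haplotypes with frequencies equal to strain
    fractions; strains with a missing or heterozygous call at any
    overlapping site are excluded.  With unphased diploid data each
    genotype contributes two allele observations per site, and one
    allele set per variant site is returned (downstream load takes the
    per-site maximum).  Sites with indel alleles are skipped with a
    warning (SNV-only model).
    """
    ref_kmer = instance.matched_sequence if instance.strand == "+" else \
        reverse_complement(instance.matched_sequence)
    overlapping = []
    for s in sites:
        if s.contig != instance.contig or not (
                instance.start <= s.pos < instance.end):
            continue
        if not s.is_snv:
            warnings.warn(
                f"skipping indel allele at {s.contig}:{s.pos} "
                "(SNV-only model)")
            continue
        overlapping.append(s)
    if not overlapping:
        full = _orient(ref_kmer, instance.strand)
        return [_build_set(instance, pwm, {full: 1.0}, None)]

    ploidies = {s.ploidy for s in overlapping}
    if ploidies == {1}:
        return [_haploid_set(instance, overlapping, pwm, ref_kmer)]
    sets = []
    for s in overlapping:
        sets.append(_per_site_set(instance, s, pwm, ref_kmer))
    return sets


def _haploid_set(instance: MotifInstance, sites: Sequence[VariantSite],
                 pwm: PWM, ref_kmer: str) -> InstanceAlleleSet:
    offsets = _mapped_offsets(instance, sites)
    calls = np.stack([s.calls for s in sites])          # (m, n_strains)
    usable = (calls >= 0).all(axis=0)
    if not usable.any():
        raise ValueError(
            f"no strain has confident calls across all sites of "
            f"{instance.instance_id}")
    seq_freqs: dict[str, float] = {}
    n = int(usable.sum())
    for strain in np.nonzero(usable)[0]:
        kmer = list(ref_kmer)
        for site, off, call in zip(sites, offsets, calls[:, strain]):
            kmer[off] = site.alleles[call]
        hap = _orient("".join(kmer), instance.strand)
        seq_freqs[hap] = seq_freqs.get(hap, 0.0) + 1.0 / n
    return _build_set(instance, pwm, seq_freqs, None)


def _per_site_set(instance: MotifInstance, site: VariantSite,
                  pwm: PWM, ref_kmer: str) -> InstanceAlleleSet:
    off = site.pos - instance.start
    freqs = site.allele_frequencies()
    seq_freqs: dict[str, float] = {}
    for allele, f in zip(site.alleles, freqs):
        if f == 0:
            continue
        kmer = list(ref_kmer)
        kmer[off] = allele
        seq = _orient("".join(kmer), instance.strand)
        seq_freqs[seq] = seq_freqs.get(seq, 0.0) + float(f)
    return _build_set(instance, pwm, seq_freqs, site.pos)


# ----------------------------------------------------------------------
# Position-wise diversity
# ----------------------------------------------------------------------

@dataclass
class PositionDiversityProfile:
    """Per-position diversity of a motif relative to its scrambled null."""

    tf_name: str
    diversity: np.ndarray            # D_j
    null_mean: np.ndarray            # scrambled-null mean per position
    relative: np.ndarray             # D_j / null mean
    information_content: Optional[np.ndarray] = None
    p_values: Optional[np.ndarray] = None
    flagged: Optional[np.ndarray] = None


def instance_base_frequencies(allelesets_per_instance:
                              Sequence[Sequence[InstanceAlleleSet]],
                              K: int) -> np.ndarray:
    """(n_instances, K, 4) population base frequencies per instance.

    Haplotype allele sets fill all positions; per-site sets fill only
    their own position, the reference base elsewhere.
    """
    out = np.zeros((len(allelesets_per_instance), K, 4))
    for i, sets in enumerate(allelesets_per_instance):
        if not sets:
            raise ValueError("each instance needs at least one allele set")
        inst = sets[0].instance
        ref_oriented = inst.matched_sequence
        out[i, np.arange(K), encode(ref_oriented)] = 1.0
        for aset in sets:
            if aset.site_pos is None:
                out[i] = 0.0
                for a in aset.alleles:
                    out[i, np.arange(K), encode(a.sequence)] += a.frequency
            else:
                off = aset.site_pos - inst.start
                j = off if inst.strand == "+" else K - 1 - off
                out[i, j, :] = 0.0
                for a in aset.alleles:
                    out[i, j, encode(a.sequence[j])[0]] += a.frequency
    return out


def per_instance_diversity(base_freqs: np.ndarray) -> np.ndarray:
    """(n, K) Nei gene diversity 1 - sum_a f^2 per instance and position.

    Each instance's diversity is computed from its own population base
    frequencies, so the statistic measures within-population variation
    at each genomic site rather than sequence degeneracy between
    instances.
    """
    return 1.0 - np.square(base_freqs).sum(axis=2)


def pooled_diversity(base_freqs: np.ndarray) -> np.ndarray:
    """Per-position diversity averaged over instances (equal weight)."""
    return per_instance_diversity(base_freqs).mean(axis=0)


def positional_diversity(instances: Sequence[MotifInstance],
                         allelesets: Sequence[Sequence[InstanceAlleleSet]]
                         ) -> np.ndarray:
    """Per-position pooled diversity over a set of motif instances."""
    if len(instances) != len(allelesets):
        raise ValueError("instances and allele sets must align")
    K = instances[0].end - instances[0].start
    return pooled_diversity(instance_base_frequencies(allelesets, K))


def dereshuffle_profile(scrambled_profiles: Sequence[np.ndarray],
                        scramble_records: Sequence[ScrambleRecord]
                        ) -> np.ndarray:
    """Map scrambled-position profiles back onto real motif positions.

    ``scrambled_profiles[s][j]`` was measured at scrambled position j of
    scramble s, i.e. at parent column ``permutation[j]``; the returned
    (n_scrambles, K) array is indexed by parent position.
    """
    if len(scrambled_profiles) != len(scramble_records):
        raise ValueError("profiles and scramble records must align")
    out = np.empty((len(scramble_records),
                    scramble_records[0].permutation.size))
    for s, (prof, rec) in enumerate(zip(scrambled_profiles,
                                        scramble_records)):
        prof = np.asarray(prof, dtype=float)
        if prof.size != rec.permutation.size:
            raise ValueError("profile length != motif length")
        out[s, rec.permutation] = prof
    return out


def dereshuffle_instance_freqs(freqs: np.ndarray,
                               record: ScrambleRecord) -> np.ndarray:
    """De-reshuffle per-instance (n, K, 4) base frequencies of a scramble."""
    out = np.empty_like(freqs)
    out[:, record.permutation, :] = freqs
    return out


def diversity_profile(tf_name: str,
                      real_freqs: np.ndarray,
                      scrambled_freqs: Sequence[np.ndarray],
                      scramble_records: Sequence[ScrambleRecord],
                      information: Optional[np.ndarray] = None,
                      n_perm: int = 2000,
                      seed: Optional[int] = None,
                      alpha: float = 5e-3) -> PositionDiversityProfile:
    """Real vs scrambled-null position-wise diversity with permutation p.

    ``scrambled_freqs[s]`` holds the (n_s, K, 4) per-instance base
    frequencies of scramble ``s`` in scrambled coordinates; they are
    de-reshuffled here.  Positions are flagged when relative diversity
    < 1 and the one-sided permutation p < ``alpha``.
    """
    from . import stats  # local import to avoid cycle

    aligned = [dereshuffle_instance_freqs(f, r)
               for f, r in zip(scrambled_freqs, scramble_records)]
    null_instances = np.concatenate(aligned, axis=0)
    null_profiles = np.stack([pooled_diversity(f) for f in aligned])
    real = pooled_diversity(real_freqs)
    null_mean = null_profiles.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(null_mean > 0, real / null_mean, np.nan)
    p = stats.positionwise_null_test(real_freqs, null_instances,
                                     n_perm=n_perm, seed=seed)
    flagged = (relative < 1.0) & (p < alpha)
    return PositionDiversityProfile(tf_name, real, null_mean, relative,
                                    information, p, flagged)


# ----------------------------------------------------------------------
# Interspecies (conservation score) profile
# ----------------------------------------------------------------------

def interspecies_profile(instances: Sequence[MotifInstance],
                         conservation: dict[str, np.ndarray]) -> np.ndarray:
    """Per-position mean of (1 - conservation score) in motif orientation.

    Scores are externally supplied per-base values in [0, 1] (e.g. a
    phastcons-like track); 1 - score acts as interspecies diversity.
    Normalisation against scrambled motifs uses the same de-reshuffling
    machinery as within-species diversity.
    """
    if not instances:
        raise ValueError("no instances")
    K = instances[0].end - instances[0].start
    acc = np.zeros(K)
    for inst in instances:
        track = conservation[inst.contig]
        vals = 1.0 - np.asarray(track[inst.start:inst.end], dtype=float)
        if inst.strand == "-":
            vals = vals[::-1]
        acc += vals
    return acc / len(instances)


def relative_interspecies_profile(real_profile: np.ndarray,
                                  scrambled_profiles: Sequence[np.ndarray],
                                  scramble_records: Sequence[ScrambleRecord]
                                  ) -> np.ndarray:
    """Real interspecies profile / de-reshuffled scrambled-null mean."""
    null = dereshuffle_profile(scrambled_profiles, scramble_records)
    null_mean = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(null_mean > 0, real_profile / null_mean, np.nan)
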