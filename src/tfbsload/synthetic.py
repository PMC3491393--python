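"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the real study
inputs without claiming biological realism: a random genome with
planted, TF-bound motif instances (plus decoys and homotypic duplets);
an isogenic-panel population whose per-position constraint is
proportional to motif information content; per-species motif retention
in multiple alignments calibrated to hit target branch length scores;
and genotype-dependent per-individual ChIP signals with a
conservation-dependent buffering term.  Every run is fully determined
by its seed, and the manifest records enough truth (planted positions
and scores, per-instance allele sets and expected loads, retention
indicators and true BLS, ChIP model parameters) to recompute every
expected output without rerunning the generator.

Model summary
-------------
* Allele frequencies follow a neutral-like spectrum: minor-allele
  count m is drawn with probability proportional to 1/m, floored at a
  single haplotype.
* A planted mutation at motif position j survives selection with
  probability exp(-selection_scale * IC_j * score_drop), so high-
  information positions are depleted of score-reducing variation.
* Species retain a planted motif independently with a probability
  solved (per instance) so that the expected branch length score
  equals the instance's BLS target; flanking columns evolve under a
  single-parameter per-branch substitution process (no indels).
* ChIP signal: baseline + slope * (genotype mean allele score) *
  (1 - buffering_coef * BLS) + Gaussian noise; with buffering_coef = 1
  and BLS = 1 mutations have no effect at all (full buffering limit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .buffering import IndividualBindingTable
from .conservation import AlignmentBlock, PhyloTree
from .io_formats import ChIPRegion
from .pwm import (ALPHABET, PWM, MotifInstance, encode, information_content,
                  reverse_complement, score_window)
from .variation import MISSING, VariantSite

#: 12-leaf phylogeny (branch lengths in substitutions/site) used as the
#: default tree; sp01 is the reference species
DEFAULT_TREE_NEWICK = (
    "((((sp01:0.05,sp02:0.06):0.04,(sp03:0.08,sp04:0.07):0.05):0.10,"
    "((sp05:0.12,sp06:0.10):0.08,sp07:0.22):0.06):0.15,"
    "(((sp08:0.18,sp09:0.16):0.10,sp10:0.30):0.08,"
    "(sp11:0.35,sp12:0.40):0.12):0.10);")

REF_SPECIES = "sp01"


def default_tree() -> PhyloTree:
    return PhyloTree.from_newick(DEFAULT_TREE_NEWICK, is_path=False)


# ----------------------------------------------------------------------
# PWM
# ----------------------------------------------------------------------

def _column_for_ic(target: float) -> float:
    """Dominant-base probability achieving a target information content."""
    if not 0.0 <= target <= 2.0:
        raise ValueError("information content must lie in [0, 2]")

    def ic(x: float) -> float:
        rest = (1.0 - x) / 3.0
        total = 0.0
        for p in (x, rest, rest, rest):
            if p > 0:
                total += p * np.log2(p)
        return 2.0 + total

    lo, hi = 0.25, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if ic(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def make_pwm(length: int, ic_profile: Sequence[float],
             seed: Optional[int] = None, name: str = "TF1") -> PWM:
    """A PWM whose per-position information content matches a profile.

    Each column has one dominant base (chosen at random) at the
    probability that yields the requested information content; the
    remaining mass is spread evenly.
    """
    ic_profile = np.asarray(ic_profile, dtype=float)
    if ic_profile.size != length:
        raise ValueError("ic_profile length must equal PWM length")
    rng = np.random.default_rng(seed)
    probs = np.empty((length, 4))
    for j, target in enumerate(ic_profile):
        x = _column_for_ic(float(target))
        col = np.full(4, (1.0 - x) / 3.0)
        col[rng.integers(4)] = x
        probs[j] = col / col.sum()
    return PWM.from_probabilities(name, probs)


# ----------------------------------------------------------------------
# Genome with planted instances
# ----------------------------------------------------------------------

@dataclass
class PlantedInstance:
    contig: str
    start: int
    strand: str
    sequence: str        # motif-oriented
    score: float
    region_id: Optional[str]   # None for decoys
    homotypic: bool = False


@dataclass
class GenomeTruth:
    genome: dict[str, str]
    regions: list[ChIPRegion]
    planted: list[PlantedInstance]
    tss: dict[str, list[int]]
    threshold: float


def _sample_motif(pwm: PWM, rng: np.random.Generator,
                  min_score: float, max_tries: int = 2000) -> str:
    probs = pwm.probabilities()
    for _ in range(max_tries):
        idx = [rng.choice(4, p=probs[j]) for j in range(pwm.length)]
        seq = "".join(ALPHABET[i] for i in idx)
        if score_window(pwm, seq, "+") >= min_score:
            return seq
    raise RuntimeError("could not sample a motif above the threshold")


def make_genome(pwm: PWM, n_instances: int = 80, n_decoys: int = 10,
                homotypic_pair_fraction: float = 0.2,
                length: int = 100_000,
                seed: Optional[int] = None,
                contig: str = "chr2L",
                threshold_fraction: float = 0.8) -> GenomeTruth:
    """Plant bound motif instances (and decoys) in a random genome.

    Bound regions are 200 bp windows around planted motifs; a stated
    fraction of regions carries two homotypic motifs.  Planted scores
    are drawn from the PWM's own sequence model truncated at the
    detection threshold (``threshold_fraction`` of the maximum
    achievable score), which is stored on the returned truth and set on
    the PWM.
    """
    rng = np.random.default_rng(seed)
    threshold = threshold_fraction * pwm.max_score
    pwm.threshold = threshold
    K = pwm.length

    n_pairs = int(round(n_instances * homotypic_pair_fraction
                        / (1.0 + homotypic_pair_fraction)))
    n_regions = n_instances - n_pairs
    slots = n_regions + n_decoys
    spacing = length // (slots + 1)
    if spacing < 400:
        raise ValueError("genome too short for the requested instances")

    seq = rng.choice(list(ALPHABET), size=length)
    planted: list[PlantedInstance] = []
    regions: list[ChIPRegion] = []

    def plant(start: int) -> PlantedInstance:
        # resample until the planted match dominates every overlapping
        # window, so overlap resolution can never displace the truth
        for _ in range(50):
            motif = _sample_motif(pwm, rng, threshold)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = motif if strand == "+" else reverse_complement(motif)
            seq[start:start + K] = list(genomic)
            score = score_window(pwm, motif, "+")
            lo = max(0, start - K + 1)
            local = encode("".join(seq[lo:start + 2 * K - 1]))
            from .pwm import _strand_scores
            rivals = np.concatenate([
                _strand_scores(pwm.matrix, local),
                _strand_scores(pwm.matrix[::-1, ::-1], local)])
            # mask the plant's own reading; everything else is a rival
            if strand == "+":
                rivals[start - lo] = -np.inf
            else:
                rivals[(start - lo) + (local.size - K + 1)] = -np.inf
            if rivals.max() < score:
                break
        return PlantedInstance(contig, start, strand, motif, score, None)

    order = rng.permutation(slots)
    decoy_slots = set(order[:n_decoys])
    pair_slots = set(order[n_decoys:n_decoys + n_pairs])
    region_no = 0
    for slot in range(slots):
        center = (slot + 1) * spacing
        if slot in decoy_slots:
            planted.append(plant(center))
            continue
        region_id = f"region{region_no:04d}"
        region_no += 1
        regions.append(ChIPRegion(contig, center - 100, center + 100,
                                  name=region_id,
                                  signal=float(rng.uniform(5, 50))))
        first = plant(center - K // 2)
        first.region_id = region_id
        planted.append(first)
        if slot in pair_slots:
            second = plant(center + 40)
            second.region_id = region_id
            first.homotypic = second.homotypic = True
            planted.append(second)

    tss = sorted(rng.choice(length, size=max(2, length // 5000),
                            replace=False).tolist())
    return GenomeTruth(genome={contig: "".join(seq)}, regions=regions,
                       planted=planted, tss={contig: tss},
                       threshold=threshold)


# ----------------------------------------------------------------------
# Population
# ----------------------------------------------------------------------

@dataclass
class PopulationTruth:
    sites: list[VariantSite]
    expected_loads: dict[str, float]   # planted instance key -> load
    selection_scale: float
    theta: float
    n_haplotypes: int


def _sfs_minor_count(rng: np.random.Generator, n: int) -> int:
    m_max = max(1, n // 2)
    m = np.arange(1, m_max + 1)
    p = 1.0 / m
    return int(rng.choice(m, p=p / p.sum()))


def _instance_key(p: PlantedInstance, K: int) -> str:
    return f"{p.contig}:{p.start}:{p.strand}"


def make_population(truth: GenomeTruth, pwm: PWM,
                    n_haplotypes: int = 162,
                    theta: float = 0.03,
                    selection_scale: float = 1.0,
                    seed: Optional[int] = None,
                    ploidy: int = 1,
                    filter_violation_fraction: float = 0.0
                    ) -> PopulationTruth:
    """Simulate population variation over a planted genome.

    Every base mutates with probability ``theta``; a mutation falling
    inside a bound planted motif is accepted with probability
    exp(-selection_scale * IC_j * score_drop).  Clean sites carry
    DGRP-style confidence fields that pass all six filters; a stated
    fraction of extra sites is emitted with planted filter violations
    (cycling through the six criteria) for filter testing.

    The truth records each bound instance's expected mutational load,
    computed directly from the emitted allele frequencies and scores.
    """
    rng = np.random.default_rng(seed)
    ic = information_content(pwm)
    K = pwm.length
    contig = next(iter(truth.genome))
    seq = truth.genome[contig]
    length = len(seq)

    # map genome position -> (instance, motif position) for bound motifs
    motif_at: dict[int, tuple[PlantedInstance, int]] = {}
    for p in truth.planted:
        if p.region_id is None:
            continue
        for off in range(K):
            j = off if p.strand == "+" else K - 1 - off
            motif_at[p.start + off] = (p, j)

    n_mut = rng.binomial(length, theta)
    positions = rng.choice(length, size=n_mut, replace=False)
    sites: list[VariantSite] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos in np.sort(positions):
        ref = seq[pos]
        alt = rng.choice([b for b in ALPHABET if b != ref])
        hit = motif_at.get(int(pos))
        if hit is not None and selection_scale > 0:
            p_inst, j = hit
            ref_m = ref if p_inst.strand == "+" else comp[ref]
            alt_m = alt if p_inst.strand == "+" else comp[alt]
            drop = max(0.0, pwm.matrix[j, ALPHABET.index(ref_m)]
                       - pwm.matrix[j, ALPHABET.index(alt_m)])
            if rng.random() > np.exp(-selection_scale * ic[j] * drop):
                continue
        m = _sfs_minor_count(rng, n_haplotypes * ploidy)
        if ploidy == 1:
            calls = np.zeros(n_haplotypes, dtype=np.int8)
            calls[rng.choice(n_haplotypes, size=m, replace=False)] = 1
        else:
            chroms = np.zeros(n_haplotypes * 2, dtype=np.int8)
            chroms[rng.choice(n_haplotypes * 2, size=m, replace=False)] = 1
            calls = rng.permutation(chroms).reshape(n_haplotypes, 2)
        sites.append(VariantSite(
            contig=contig, pos=int(pos), ref=ref, alts=(str(alt),),
            calls=calls, ploidy=ploidy,
            eps=float(rng.uniform(0.001, 0.0095)),
            allele_coverage=(float(rng.integers(5, 15)),
                             float(rng.integers(4, 12))),
            median_coverage=float(rng.integers(8, 18))))

    if filter_violation_fraction > 0:
        sites.extend(_violating_sites(
            rng, contig, seq, n_haplotypes,
            int(np.ceil(len(sites) * filter_violation_fraction))))

    expected = _expected_loads(truth, pwm, sites, K)
    return PopulationTruth(sites=sites, expected_loads=expected,
                           selection_scale=selection_scale, theta=theta,
                           n_haplotypes=n_haplotypes)


def _violating_sites(rng: np.random.Generator, contig: str, seq: str,
                     n: int, count: int) -> list[VariantSite]:
    """Sites each violating exactly one of the six confidence filters."""
    out = []
    kinds = ["eps", "p_eps", "allele_cov", "median_cov", "n_hom", "het"]
    for i in range(count):
        pos = int(rng.integers(len(seq)))
        ref = seq[pos]
        alt = str(rng.choice([b for b in ALPHABET if b != ref]))
        calls = np.zeros(n, dtype=np.int8)
        calls[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        eps, cov = 0.01, (10.0, 10.0)
        med = 12.0
        kind = kinds[i % len(kinds)]
        if kind == "eps":
            eps = 0.03
        elif kind == "p_eps":
            eps = 0.018          # major allele: p ~ 2/3, p*eps > 0.01
        elif kind == "allele_cov":
            cov = (10.0, 2.0)
        elif kind == "median_cov":
            med = 25.0
        elif kind == "n_hom":
            calls[: n - 90] = MISSING
            calls[n - 90:] = rng.integers(0, 2, size=90).astype(np.int8)
        elif kind == "het":
            calls[rng.choice(n, size=max(1, n // 10), replace=False)] = -2
        out.append(VariantSite(contig=contig, pos=pos, ref=ref,
                               alts=(alt,), calls=calls, ploidy=1,
                               eps=eps, allele_coverage=cov,
                               median_coverage=med))
    return out


def _expected_loads(truth: GenomeTruth, pwm: PWM,
                    sites: Sequence[VariantSite], K: int
                    ) -> dict[str, float]:
    """Ground-truth load per bound instance from emitted frequencies."""
    by_pos: dict[int, VariantSite] = {s.pos: s for s in sites}
    out: dict[str, float] = {}
    for p in truth.planted:
        if p.region_id is None:
            continue
        hits = [(off, by_pos[p.start + off])
                for off in range(K) if p.start + off in by_pos]
        if not hits:
            out[_instance_key(p, K)] = 0.0
            continue
        if hits[0][1].ploidy == 2:
            out[_instance_key(p, K)] = _diploid_load(p, pwm, hits)
            continue
        # enumerate strain haplotypes (all calls homozygous on clean sites)
        n = hits[0][1].calls.shape[0]
        haps: dict[str, float] = {}
        genomic = p.sequence if p.strand == "+" else \
            reverse_complement(p.sequence)
        for strain in range(n):
            kmer = list(genomic)
            ok = True
            for off, s in hits:
                c = s.calls[strain] if s.ploidy == 1 else s.calls[strain, 0]
                if c < 0:
                    ok = False
                    break
                kmer[off] = s.alleles[c]
            if not ok:
                continue
            hap = "".join(kmer)
            if p.strand == "-":
                hap = reverse_complement(hap)
            haps[hap] = haps.get(hap, 0.0) + 1.0
        total = sum(haps.values())
        scored = {h: score_window(pwm, h, "+") for h in haps}
        major = max(haps, key=lambda h: (haps[h], scored[h]))
        w0 = scored[major]
        mean_w = sum(scored[h] * f / total for h, f in haps.items())
        out[_instance_key(p, K)] = max(0.0, (w0 - mean_w) / w0)
    return out


def _diploid_load(p: PlantedInstance, pwm: PWM,
                  hits: Sequence[tuple[int, VariantSite]]) -> float:
    """Per-site allele counting over 2N chromosomes, max over sites."""
    genomic = p.sequence if p.strand == "+" else \
        reverse_complement(p.sequence)
    best = 0.0
    for off, s in hits:
        flat = s.calls.ravel()
        called = flat[flat >= 0]
        counts = np.bincount(called, minlength=len(s.alleles))
        total = counts.sum()
        scored, freqs = [], []
        for idx, allele in enumerate(s.alleles):
            if counts[idx] == 0:
                continue
            kmer = list(genomic)
            kmer[off] = allele
            hap = "".join(kmer)
            if p.strand == "-":
                hap = reverse_complement(hap)
            scored.append(score_window(pwm, hap, "+"))
            freqs.append(counts[idx] / total)
        major = int(np.lexsort((scored, freqs))[-1])
        w0 = scored[major]
        mean_w = float(np.dot(scored, freqs))
        best = max(best, max(0.0, (w0 - mean_w) / w0))
    return best


# ----------------------------------------------------------------------
# Alignments
# ----------------------------------------------------------------------

@dataclass
class AlignmentTruth:
    blocks: list[AlignmentBlock]
    retention: dict[str, dict[str, bool]]  # instance key -> species -> kept
    true_bls: dict[str, float]
    bls_targets: dict[str, float]


def expected_bls(tree: PhyloTree, reference: str, q: float) -> float:
    """Expected BLS when each non-reference species conserves i.i.d.
    with probability q (reference always conserves)."""
    total = 0.0
    for length, below in tree.edges:
        if reference in below:
            m = len(tree.species - below - {reference})
        else:
            m = len(below - {reference})
        total += length * (1.0 - (1.0 - q) ** m)
    return total / tree.total_length


def retention_probability(tree: PhyloTree, reference: str,
                          bls_target: float) -> float:
    """Per-species retention probability hitting a BLS target in
    expectation (solved by bisection; targets are clipped to [0, 1])."""
    target = float(np.clip(bls_target, 0.0, 1.0))
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected_bls(tree, reference, mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def make_alignments(truth: GenomeTruth, tree: PhyloTree,
                    bls_targets: Optional[dict[str, float]] = None,
                    seed: Optional[int] = None,
                    reference: str = REF_SPECIES,
                    flank: int = 55,
                    substitution_scale: float = 1.0) -> AlignmentTruth:
    """Gap-free alignment blocks with calibrated per-species retention.

    One block per bound region spans all its planted motifs +/-
    ``flank`` reference bases.  Flank columns substitute independently
    per species with probability 1 - exp(-scale *
    distance-to-reference); each planted motif's columns are either
    retained verbatim (with probability solved from the instance's BLS
    target) or randomized, independently per species and instance.
    """
    rng = np.random.default_rng(seed)
    contig = next(iter(truth.genome))
    seq = truth.genome[contig]
    K = len(truth.planted[0].sequence)
    # root-to-leaf path lengths relative to the reference
    dist = {}
    for sp in tree.species:
        dist[sp] = tree.subtree_length({sp}, reference=reference)
    bound = [p for p in truth.planted if p.region_id is not None]
    targets = bls_targets or {
        _instance_key(p, K): float(rng.uniform(0, 1)) for p in bound}
    by_region: dict[str, list[PlantedInstance]] = {}
    for p in bound:
        by_region.setdefault(p.region_id, []).append(p)

    blocks, retention, true_bls = [], {}, {}
    for region_id in sorted(by_region):
        members = sorted(by_region[region_id], key=lambda p: p.start)
        lo = max(0, members[0].start - flank)
        hi = min(len(seq), members[-1].start + K + flank)
        ref_row = seq[lo:hi]
        motif_cols = {p.start - lo: p for p in members}
        is_motif = np.zeros(hi - lo, dtype=bool)
        for m0 in motif_cols:
            is_motif[m0:m0 + K] = True
        rows = {reference: ref_row}
        kept_by_key: dict[str, dict[str, bool]] = {
            _instance_key(p, K): {} for p in members}
        for sp in sorted(tree.species - {reference}):
            p_sub = 1.0 - np.exp(-substitution_scale * dist[sp])
            chars = list(ref_row)
            for i in range(len(chars)):
                if is_motif[i]:
                    continue
                if rng.random() < p_sub:
                    chars[i] = rng.choice(
                        [b for b in ALPHABET if b != chars[i]])
            for m0, p in motif_cols.items():
                key = _instance_key(p, K)
                q = retention_probability(tree, reference, targets[key])
                kept = bool(rng.random() < q)
                kept_by_key[key][sp] = kept
                if not kept:
                    for i in range(m0, m0 + K):
                        chars[i] = rng.choice(list(ALPHABET))
            rows[sp] = "".join(chars)
        blocks.append(AlignmentBlock(
            ref_species=reference, ref_contig=contig, ref_start=lo,
            ref_size=hi - lo, sequences=rows,
            strands={sp: "+" for sp in rows}))
        for key, kept in kept_by_key.items():
            retention[key] = kept
            conserving = {sp for sp, k in kept.items() if k} | {reference}
            true_bls[key] = tree.subtree_length(
                conserving, reference=reference) / tree.total_length
    return AlignmentTruth(blocks=blocks, retention=retention,
                          true_bls=true_bls, bls_targets=targets)


# ----------------------------------------------------------------------
# Per-individual ChIP signals
# ----------------------------------------------------------------------

@dataclass
class ChIPTruth:
    table: IndividualBindingTable
    baseline: float
    score_slope: float
    buffering_coef: float
    noise_sd: float
    #: analytic probability that each site is classified buffered, given
    #: the realized genotype counts and the noise model (NaN when a
    #: homozygote class is absent)
    buffering_probability: pd.Series = field(default=None)


def make_chip_individuals(n_sites: int = 500, n_individuals: int = 12,
                          baseline: float = 3.0, score_slope: float = 1.0,
                          buffering_coef: float = 0.9,
                          noise_sd: float = 0.5,
                          seed: Optional[int] = None,
                          bls: Optional[np.ndarray] = None) -> ChIPTruth:
    """Genotype-dependent ChIP signals across individuals.

    signal(site, ind) = baseline + slope * (genotype mean allele score)
    * (1 - buffering_coef * BLS) + Normal(0, noise_sd).  Genotypes are
    drawn per individual under Hardy-Weinberg at a site-specific minor
    allele frequency.  The defaults put most of the signal on the
    score term so that mutations at non-conserved sites cost real
    signal while conserved sites are strongly damped, yielding a
    buffered fraction around three quarters overall and highest in the
    conserved stratum.
    """
    rng = np.random.default_rng(seed)
    score_major = rng.uniform(8, 16, size=n_sites)
    delta = rng.uniform(0.5, 8.0, size=n_sites)
    score_minor = score_major - delta
    b = rng.uniform(0, 1, size=n_sites) if bls is None else \
        np.asarray(bls, dtype=float)
    maf = rng.uniform(0.2, 0.5, size=n_sites)

    site_ids = [f"site{i:04d}" for i in range(n_sites)]
    individuals = [f"ind{j:02d}" for j in range(n_individuals)]
    gt_probs = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2],
                        axis=1)
    gt_codes = np.array(["major", "het", "minor"])
    genotypes = np.empty((n_sites, n_individuals), dtype=object)
    signals = np.empty((n_sites, n_individuals))
    for i in range(n_sites):
        g = rng.choice(3, size=n_individuals, p=gt_probs[i])
        genotypes[i] = gt_codes[g]
        mean_score = np.where(
            g == 0, score_major[i],
            np.where(g == 2, score_minor[i],
                     (score_major[i] + score_minor[i]) / 2))
        mu = baseline + score_slope * mean_score * (1 - buffering_coef * b[i])
        signals[i] = mu + rng.normal(0, noise_sd, size=n_individuals)

    sites = pd.DataFrame({"score_major": score_major,
                          "score_minor": score_minor, "bls": b},
                         index=site_ids)
    table = IndividualBindingTable(
        sites=sites,
        signals=pd.DataFrame(signals, index=site_ids, columns=individuals),
        genotypes=pd.DataFrame(genotypes, index=site_ids,
                               columns=individuals))

    probs = np.full(n_sites, np.nan)
    for i in range(n_sites):
        n_maj = int(np.sum(genotypes[i] == "major"))
        n_min = int(np.sum(genotypes[i] == "minor"))
        if n_maj == 0 or n_min == 0:
            continue
        damp = 1 - buffering_coef * b[i]
        mu_maj = baseline + score_slope * score_major[i] * damp
        mu_min = baseline + score_slope * score_minor[i] * damp
        sd = noise_sd * np.sqrt(1 / n_min + (4 / 9) / n_maj)
        probs[i] = norm.sf((2 / 3) * mu_maj - mu_min, scale=sd) \
            if sd > 0 else float(mu_min >= (2 / 3) * mu_maj)
    return ChIPTruth(table=table, baseline=baseline,
                     score_slope=score_slope,
                     buffering_coef=buffering_coef, noise_sd=noise_sd,
                     buffering_probability=pd.Series(probs, index=site_ids))


# ----------------------------------------------------------------------
# Manifest and presets
# ----------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    seed: int
    preset: str
    genome: Optional[GenomeTruth] = None
    population: Optional[PopulationTruth] = None
    alignment: Optional[AlignmentTruth] = None
    chip: Optional[ChIPTruth] = None

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "preset": self.preset}
        if self.genome is not None:
            out["threshold"] = self.genome.threshold
            out["planted"] = [
                {"contig": p.contig, "start": p.start, "strand": p.strand,
                 "sequence": p.sequence, "score": p.score,
                 "region_id": p.region_id, "homotypic": p.homotypic}
                for p in self.genome.planted]
        if self.population is not None:
            out["expected_loads"] = self.population.expected_loads
            out["theta"] = self.population.theta
            out["selection_scale"] = self.population.selection_scale
        if self.alignment is not None:
            out["bls_targets"] = self.alignment.bls_targets
            out["true_bls"] = self.alignment.true_bls
        if self.chip is not None:
            out["chip_model"] = {
                "baseline": self.chip.baseline,
                "score_slope": self.chip.score_slope,
                "buffering_coef": self.chip.buffering_coef,
                "noise_sd": self.chip.noise_sd}
            out["buffering_probability"] = {
                k: (None if np.isnan(v) else float(v))
                for k, v in self.chip.buffering_probability.items()}
        return out

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


PRESETS = ("fly", "human", "ctcf")


def simulate(preset: str, out_dir, seed: int = 0) -> GroundTruthManifest:
    """Generate a full synthetic dataset for one preset.

    ``fly``: isogenic-panel mode (162 haploid lines, ~3% per-base
    variation) with genome, regions, PWM, DGRP-style table, VCF,
    alignments and tree.  ``human``: diploid cohort mode (60
    individuals, ~0.25% variation).  ``ctcf``: per-individual ChIP
    signal matrix with genotypes and per-site metadata.
    """
    from . import io_formats as io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(seed)
    s = [int(x) for x in rng.generate_state(8) % (2 ** 31)]
    manifest = GroundTruthManifest(seed=seed, preset=preset)

    if preset in ("fly", "human"):
        ic = [0.5, 1.2, 1.8, 1.9, 1.6, 1.9, 1.0, 0.4]
        pwm = make_pwm(8, ic, seed=s[0])
        genome = make_genome(pwm, n_instances=80, n_decoys=10,
                             homotypic_pair_fraction=0.2,
                             length=100_000, seed=s[1])
        manifest.genome = genome
        if preset == "fly":
            pop = make_population(genome, pwm, n_haplotypes=162,
                                  theta=0.03, selection_scale=1.0,
                                  seed=s[2], ploidy=1)
            io.write_dgrp_table(pop.sites, out / "variants.dgrp.tsv")
        else:
            pop = make_population(genome, pwm, n_haplotypes=60,
                                  theta=0.0025, selection_scale=1.0,
                                  seed=s[2], ploidy=2)
        manifest.population = pop
        tree = default_tree()
        aln = make_alignments(genome, tree, seed=s[3])
        manifest.alignment = aln
        io.write_fasta(genome.genome, out / "genome.fa")
        io.write_regions(genome.regions, out / "regions.bed")
        io.write_pwm(pwm, out / "motif.pwm")
        io.write_vcf(pop.sites, out / "variants.vcf",
                     contig_lengths={c: len(g)
                                     for c, g in genome.genome.items()})
        io.write_alignment(aln.blocks, out / "alignments.maf")
        (out / "tree.nwk").write_text(DEFAULT_TREE_NEWICK + "\n")
    elif preset == "ctcf":
        chip = make_chip_individuals(n_sites=500, n_individuals=12,
                                     seed=s[0])
        manifest.chip = chip
        chip.table.sites.rename_axis("site").reset_index().to_csv(
            out / "sites.tsv", sep="\t", index=False)
        chip.table.signals.rename_axis("site").reset_index().to_csv(
            out / "signals.tsv", sep="\t", index=False)
        chip.table.genotypes.rename_axis("site").reset_index().to_csv(
            out / "genotypes.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    manifest.save(out / "manifest.json")
    return manifest
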