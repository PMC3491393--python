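"""Position weight matrices, motif scanning and scrambled-motif nulls.

A PWM models the sequence preference of a transcription factor as a
per-position log-odds scoring matrix over the DNA alphabet.  A window of
sequence matches the motif when the sum of the looked-up log-odds cells
reaches the matrix's score threshold.  Scanning is performed on both
strands; mutually overlapping matches are resolved in favour of the
strongest one, so each locus reports at most one instance per factor.

Scrambled (column-order permuted) PWMs serve as matched null motifs for
position-wise variation analyses: they preserve the base composition and
per-column information of the real motif while destroying its positional
structure.  The permutation of each scramble is recorded so that values
measured at scrambled-motif positions can later be "de-reshuffled" back
onto the real motif's coordinate system.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ALPHABET = "ACGT"
#: integer code used for any non-ACGT character (never matches)
N_CODE = 4
#: score sentinel for windows containing ambiguous bases
NO_MATCH = float("-inf")

_ENC = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """Log-odds position weight matrix (log base 2, columns A,C,G,T).

    Parameters
    ----------
    name : transcription factor identifier.
    matrix : (K, 4) array of per-position, per-base log2-odds scores.
    background : background base frequencies (must sum to 1).
    threshold : minimum match score used by :func:`scan`; optional until
        scanning time.
    probs : (K, 4) per-position base probabilities, kept when the matrix
        was built from counts or frequencies (used for information
        content and for sampling motif-like sequences).
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    threshold: Optional[float] = None
    probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(
                f"PWM matrix must be (K, 4); got {self.matrix.shape}")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(
                self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be 4 frequencies summing to 1")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != self.matrix.shape:
                raise ValueError("probs shape must match matrix shape")
        if self.threshold is not None and self.threshold > self.max_score + 1e-9:
            raise ValueError(
                f"threshold {self.threshold} exceeds maximum achievable "
                f"score {self.max_score}")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray,
                    background: Optional[Sequence[float]] = None,
                    pseudocount: float = 0.5,
                    threshold: Optional[float] = None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at position {bad[0] + 1}, "
                f"base {ALPHABET[bad[1]]}")
        probs = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        return cls.from_probabilities(name, probs, background, threshold)

    @classmethod
    def from_probabilities(cls, name: str, probs: np.ndarray,
                           background: Optional[Sequence[float]] = None,
                           threshold: Optional[float] = None) -> "PWM":
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            j = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"probabilities at position {j + 1} sum to {sums[j]:.4g}")
        bg = np.full(4, 0.25) if background is None else np.asarray(
            background, dtype=float)
        with np.errstate(divide="ignore"):
            matrix = np.log2(probs / bg)
        return cls(name, matrix, bg, threshold, probs)

    # -- basic properties ---------------------------------------------
    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def probabilities(self) -> np.ndarray:
        """Per-position base probabilities implied by the matrix."""
        if self.probs is not None:
            return self.probs
        p = self.background * np.exp2(self.matrix)
        return p / p.sum(axis=1, keepdims=True)

    def score(self, window: str, strand: str = "+") -> float:
        return score_window(self, window, strand)


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits, 2 + sum_b p*log2(p).

    Uses the uniform-background convention (0..2 bits for DNA), matching
    the scale of standard sequence logos.
    """
    p = pwm.probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)


def score_window(pwm: PWM, window: str, strand: str = "+") -> float:
    """Log-odds score of one sequence window.

    The window is given in forward-genome orientation; for ``strand='-'``
    its reverse complement is scored.  Any ambiguous base yields the
    no-match sentinel (-inf).
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pwm.length}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        window = reverse_complement(window)
    code = encode(window)
    if np.any(code == N_CODE):
        return NO_MATCH
    return float(pwm.matrix[np.arange(pwm.length), code].sum())


@dataclass
class MotifInstance:
    """A located, stranded, scored motif match.

    Coordinates are 0-based half-open on the forward strand;
    ``matched_sequence`` is strand-oriented (reverse complemented for
    minus-strand instances).
    """

    contig: str
    start: int
    end: int
    strand: str
    matched_sequence: str
    score: float
    tf_name: str
    bound: bool = False
    tss_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.end - self.start != len(self.matched_sequence):
            raise ValueError("interval length != matched sequence length")

    @property
    def instance_id(self) -> str:
        return f"{self.tf_name}:{self.contig}:{self.start}:{self.strand}"


def _strand_scores(matrix: np.ndarray, code: np.ndarray) -> np.ndarray:
    """Score every window start for a (K,4) matrix over encoded sequence."""
    K = matrix.shape[0]
    n = code.size - K + 1
    if n <= 0:
        return np.empty(0)
    win = sliding_window_view(code, K)
    safe = np.where(win < 4, win, 0)
    scores = matrix[np.arange(K)[None, :], safe].sum(axis=1)
    scores[(win == N_CODE).any(axis=1)] = NO_MATCH
    return scores


def _resolve_overlaps(cands: list[tuple[float, int, str]], K: int
                      ) -> list[tuple[float, int, str]]:
    """Greedy strongest-first overlap resolution (ties: leftmost, then +)."""
    order = sorted(cands, key=lambda c: (-c[0], c[1], c[2] != "+"))
    kept_starts: list[int] = []
    kept = []
    for score, start, strand in order:
        i = bisect.bisect_left(kept_starts, start)
        if i > 0 and start - kept_starts[i - 1] < K:
            continue
        if i < len(kept_starts) and kept_starts[i] - start < K:
            continue
        kept_starts.insert(i, start)
        kept.append((score, start, strand))
    return kept


def scan(pwm: PWM, genome: dict[str, str],
         regions: Optional[Iterable] = None,
         threshold: Optional[float] = None) -> list[MotifInstance]:
    """Scan both strands of a genome for motif matches.

    Among mutually overlapping matches (across strands) only the
    strongest is retained; ties break leftmost, then forward strand.
    If ``regions`` (objects with contig/start/end) are given, instances
    overlapping any region by >= 1 bp are flagged ``bound``.
    """
    thr = pwm.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no score threshold set on PWM or passed to scan()")
    K = pwm.length
    rc_matrix = pwm.matrix[::-1, ::-1]
    instances: list[MotifInstance] = []
    for contig in sorted(genome):
        seq = genome[contig]
        code = encode(seq)
        fwd = _strand_scores(pwm.matrix, code)
        rev = _strand_scores(rc_matrix, code)
        cands: list[tuple[float, int, str]] = []
        for starts in np.nonzero(fwd >= thr)[0]:
            cands.append((float(fwd[starts]), int(starts), "+"))
        for starts in np.nonzero(rev >= thr)[0]:
            cands.append((float(rev[starts]), int(starts), "-"))
        for score, start, strand in sorted(
                _resolve_overlaps(cands, K), key=lambda c: c[1]):
            window = seq[start:start + K].upper()
            if strand == "-":
                window = reverse_complement(window)
            instances.append(MotifInstance(
                contig=contig, start=start, end=start + K, strand=strand,
                matched_sequence=window, score=score, tf_name=pwm.name))
    if regions is not None:
        flag_bound(instances, regions)
    return instances


def flag_bound(instances: Sequence[MotifInstance], regions: Iterable) -> None:
    """Set ``bound`` on instances overlapping >= 1 bp of any region."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append((r.start, r.end))
    for ivs in by_contig.values():
        ivs.sort()
    for inst in instances:
        inst.bound = any(
            inst.start < e and s < inst.end
            for s, e in by_contig.get(inst.contig, ()))


@dataclass
class ScrambleRecord:
    """A column-order permutation of a parent PWM.

    ``permutation[j]`` gives the parent column placed at scrambled
    position ``j``; applying the inverse permutation recovers the parent
    column order, which is how measurements at scrambled-motif positions
    are mapped back ("de-reshuffled") onto real motif positions.
    """

    permutation: np.ndarray
    pwm: PWM
    parent_name: str

    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(self.permutation.size)
        return inv


def scramble_pwm(pwm: PWM, n: int = 10,
                 seed: Optional[int] = None) -> list[ScrambleRecord]:
    """Generate ``n`` non-identity column-order permutations of a PWM.

    Scrambles inherit the parent's threshold and background, so they are
    detected at the same stringency as the real motif.
    """
    if pwm.length < 2:
        raise ValueError("cannot scramble a single-column PWM "
                         "(no non-identity permutation exists)")
    rng = np.random.default_rng(seed)
    records = []
    identity = np.arange(pwm.length)
    for i in range(n):
        perm = rng.permutation(pwm.length)
        while np.array_equal(perm, identity):
            perm = rng.permutation(pwm.length)
        scrambled = PWM(
            name=f"{pwm.name}~scramble{i}",
            matrix=pwm.matrix[perm],
            background=pwm.background,
            threshold=pwm.threshold,
            probs=None if pwm.probs is None else pwm.probs[perm])
        records.append(ScrambleRecord(perm, scrambled, pwm.name))
    return records


def proximity_windows(instances: Sequence[MotifInstance], flank: int = 200
                      ) -> dict[str, list[tuple[int, int]]]:
    """Merged (start, end) windows of instance loci +/- flank, per contig."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for inst in instances:
        by_contig.setdefault(inst.contig, []).append(
            (max(0, inst.start - flank), inst.end + flank))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    return merged


def scan_scrambled(scrambles: Sequence[ScrambleRecord], genome: dict[str, str],
                   real_instances: Sequence[MotifInstance], flank: int = 200,
                   threshold: Optional[float] = None
                   ) -> list[list[MotifInstance]]:
    """Scan each scrambled PWM within +/- ``flank`` bp of real instances.

    Returns one instance list per scramble, index-aligned with
    ``scrambles``; each scramble keeps the real motif's threshold.
    """
    windows = proximity_windows(real_instances, flank)
    results: list[list[MotifInstance]] = []
    for rec in scrambles:
        found: list[MotifInstance] = []
        for contig, ivs in windows.items():
            seq = genome.get(contig)
            if seq is None:
                continue
            for s, e in ivs:
                sub = {contig: seq[s:min(e, len(seq))]}
                for inst in scan(rec.pwm, sub, threshold=threshold):
                    inst.start += s
                    inst.end += s
                    found.append(inst)
        results.append(found)
    return results


def calibrated_scramble_scan(pwm: PWM, scrambles: Sequence[ScrambleRecord],
                             genome: dict[str, str],
                             real_instances: Sequence[MotifInstance],
                             flank: int = 200,
                             target_ratio: float = 1.5,
                             step: float = 0.25,
                             max_relax: float = 6.0
                             ) -> tuple[list[list[MotifInstance]], float]:
    """Scan scrambles near real sites, relaxing the threshold if sparse.

    Stringent thresholds can leave too few scrambled-motif matches to
    build a stable positional null; the threshold is lowered in
    ``step`` decrements (at most ``max_relax`` below the real one)
    until the scrambles together yield at least ``target_ratio`` times
    the number of real instances.  Returns the per-scramble instance
    lists and the threshold used.
    """
    if pwm.threshold is None:
        raise ValueError("PWM needs a threshold")
    target = target_ratio * len(real_instances)
    thr = pwm.threshold
    while True:
        results = scan_scrambled(scrambles, genome, real_instances,
                                 flank=flank, threshold=thr)
        if sum(len(r) for r in results) >= target:
            return results, thr
        if thr <= pwm.threshold - max_relax:
            return results, thr
        thr -= step
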