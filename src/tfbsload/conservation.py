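"""Branch length score (BLS) of motif instances.

The BLS of a motif instance is the fraction of total phylogenetic
branch length spanned by the species in which the motif is conserved.
A species conserves the instance when its aligned sequence, within a
window allowing the motif to move up to 50 bp either way along the
alignment, contains a match (on either strand) scoring no more than 1
point below the instance's own reference score.  The conserving
species, together with the reference species, define a minimal spanning
subtree of the phylogeny; BLS is the subtree's branch length divided by
the total tree length, so it lies in [0, 1].

The conservation criterion is relative to the instance's own score, not
to the detection threshold: a drop bound caps how much match quality a
species may lose while still counting as conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .pwm import PWM, MotifInstance, NO_MATCH, _strand_scores, encode

DEFAULT_MOVEMENT = 50
DEFAULT_MAX_DROP = 1.0


class PhyloTree:
    """A rooted phylogeny with branch lengths (substitutions/site).

    Thin wrapper over a dendropy tree that precomputes, for every edge,
    the set of leaf labels below it — the only structure needed for
    minimal-spanning-subtree length queries.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.edges: list[tuple[float, frozenset[str]]] = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length or 0.0
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter())
            self.edges.append((float(length), leaves))
        self.species = frozenset(
            lf.taxon.label for lf in tree.leaf_node_iter())
        self.total_length = float(sum(e[0] for e in self.edges))
        if self.total_length <= 0:
            raise ValueError("tree must have positive total branch length")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "PhyloTree":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick",
                                 preserve_underscores=True, **kwargs)
        return cls(tree)

    def subtree_length(self, species_set: Sequence[str],
                       reference: Optional[str] = None) -> float:
        """Branch length of the minimal subtree connecting a species set.

        The reference species, when given, is always included.  Species
        absent from the tree are ignored.  A singleton (or empty) set
        spans no branches and returns 0.
        """
        wanted = set(species_set) & self.species
        if reference is not None:
            if reference not in self.species:
                raise KeyError(f"reference species {reference!r} not in tree")
            wanted.add(reference)
        if len(wanted) < 2:
            return 0.0
        total = 0.0
        for length, below in self.edges:
            k = len(wanted & below)
            if 0 < k < len(wanted):
                total += length
        return total


@dataclass
class AlignmentBlock:
    """One multiple-alignment block, reference coordinates 0-based.

    ``sequences`` maps species to gapped rows of equal length; the
    reference species' row, with gaps removed, spans
    ``[ref_start, ref_start + ref_size)`` on ``ref_contig``.
    """

    ref_species: str
    ref_contig: str
    ref_start: int
    ref_size: int
    sequences: dict[str, str]
    strands: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("all gapped rows must have equal length")
        ref = self.sequences[self.ref_species]
        if len(ref.replace("-", "")) != self.ref_size:
            raise ValueError("reference ungapped length != declared size")
        if self.strands.get(self.ref_species, "+") != "+":
            raise ValueError("minus-strand reference rows are not supported")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_size

    def columns_for(self, start: int, end: int) -> tuple[int, int]:
        """Alignment column range covering reference bases [start, end)."""
        if not (self.ref_start <= start < end <= self.ref_end):
            raise ValueError("interval outside block")
        ref = self.sequences[self.ref_species]
        is_base = np.frombuffer(ref.encode(), dtype=np.uint8) != ord("-")
        cum = np.cumsum(is_base)  # bases up to and including each column
        c0 = int(np.searchsorted(cum, start - self.ref_start + 1))
        c1 = int(np.searchsorted(cum, end - self.ref_start)) + 1
        return c0, c1


def species_window(instance: MotifInstance, block: AlignmentBlock,
                   species: str,
                   movement: int = DEFAULT_MOVEMENT) -> str:
    """A species' ungapped sequence around the instance's columns.

    The window spans the alignment columns of the instance extended by
    ``movement`` reference columns either way (clipped at block edges);
    an empty string is returned when the species is absent.
    """
    row = block.sequences.get(species)
    if row is None:
        return ""
    lo = max(block.ref_start, instance.start - movement)
    hi = min(block.ref_end, instance.end + movement)
    c0, c1 = block.columns_for(lo, hi)
    return row[c0:c1].replace("-", "").upper()


def is_conserved(instance: MotifInstance, window: str, pwm: PWM,
                 max_drop: float = DEFAULT_MAX_DROP
                 ) -> tuple[bool, float]:
    """Does the window hold a match within ``max_drop`` of the instance?

    The best score over both strands and all offsets is compared with
    ``instance.score - max_drop``; an empty or too-short window never
    conserves.
    """
    if len(window) < pwm.length:
        return False, NO_MATCH
    code = encode(window)
    best = max(
        float(np.max(_strand_scores(pwm.matrix, code))),
        float(np.max(_strand_scores(pwm.matrix[::-1, ::-1], code))))
    return best >= instance.score - max_drop, best


@dataclass
class BLSRecord:
    """Per-instance conservation as a fraction of total tree length."""

    instance_id: str
    conserving_species: frozenset[str]
    bls: float
    best_scores: dict[str, float]
    unaligned: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.bls <= 1.0 + 1e-12):
            raise ValueError(f"bls {self.bls} outside [0, 1]")


def branch_length_score(instance: MotifInstance,
                        blocks: Sequence[AlignmentBlock],
                        tree: PhyloTree, pwm: PWM,
                        movement: int = DEFAULT_MOVEMENT,
                        max_drop: float = DEFAULT_MAX_DROP,
                        ref_species: Optional[str] = None) -> BLSRecord:
    """BLS of one instance over alignment blocks and a phylogeny.

    The reference species always counts as conserving (the instance
    exists in it by construction); species absent from the alignment do
    not conserve.  An instance covered by no block gets BLS 0 with the
    ``unaligned`` flag.
    """
    block = next(
        (b for b in blocks
         if b.ref_contig == instance.contig
         and b.ref_start <= instance.start and instance.end <= b.ref_end),
        None)
    if block is None:
        return BLSRecord(instance.instance_id, frozenset(), 0.0, {},
                         unaligned=True)
    ref = ref_species or block.ref_species
    conserving = {ref}
    best_scores: dict[str, float] = {}
    for sp in sorted(tree.species - {ref}):
        window = species_window(instance, block, sp, movement)
        ok, best = is_conserved(instance, window, pwm, max_drop)
        best_scores[sp] = best
        if ok:
            conserving.add(sp)
    bls = tree.subtree_length(conserving, reference=ref) / tree.total_length
    return BLSRecord(instance.instance_id, frozenset(conserving), bls,
                     best_scores)
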