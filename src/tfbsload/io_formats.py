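"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally: BED is native,
VCF positions and MAF block starts are converted on read.  Genomic
intervals always satisfy 0 <= start < end.  Output tables are
tab-separated with a commented header carrying the software version,
the run seed and any configuration, so every result file records how it
was produced.

Formats: FASTA (genome), plain-text PWM, VCF and a documented
DGRP-style TSV dialect (variants), BED with optional signal column
(ChIP regions), MAF (multiple alignments), newick (phylogeny),
bedGraph (per-base conservation scores), TSV (results).

The DGRP-style dialect is a stand-in for isogenic-panel SNP freezes,
whose exact layout varies between releases; its columns are
(chrom, pos[1-based], ref, alt[comma separated], eps,
allele_coverage[comma separated, reference first], median_coverage,
calls[string over strains: base letter, N = missing, H = heterozygous]).
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from . import __version__
from .conservation import AlignmentBlock, PhyloTree
from .pwm import ALPHABET, PWM, MotifInstance
from .variation import HET, MISSING, VariantSite

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Run-level configuration recorded in all output headers."""

    random_seed: int = 0
    n_permutations: int = 10_000
    pwm_threshold_mode: str = "absolute_score"
    paths: dict = field(default_factory=dict)
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.pwm_threshold_mode not in ("absolute_score", "score_pvalue"):
            raise ValueError(
                f"unknown threshold mode {self.pwm_threshold_mode!r}")

    def header_items(self) -> list[tuple[str, str]]:
        items = [("seed", str(self.random_seed)),
                 ("n_permutations", str(self.n_permutations)),
                 ("pwm_threshold_mode", self.pwm_threshold_mode)]
        items += [(f"path.{k}", str(v)) for k, v in sorted(
            self.paths.items())]
        return items


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], path: PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ----------------------------------------------------------------------
# PWM (plain text)
# ----------------------------------------------------------------------

def read_pwm(path: PathLike, pseudocount: float = 0.5) -> PWM:
    """Read a plain-text PWM.

    The file starts with a header line ``> key=value ...`` declaring at
    least ``name`` and ``kind`` (``counts``, ``frequencies`` or
    ``logodds``); optional keys: ``orient`` (``positions`` = K rows of
    4 columns, the default, or ``bases`` = 4 rows of K columns),
    ``background`` (4 comma-separated frequencies) and ``threshold``.
    Count/frequency matrices are converted to log-odds; counts receive
    the pseudocount.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{path}: missing '>' header line")
    meta = {}
    for tok in lines[0][1:].split():
        if "=" not in tok:
            raise ValueError(f"{path}: malformed header token {tok!r}")
        k, v = tok.split("=", 1)
        meta[k] = v
    kind = meta.get("kind")
    if kind not in ("counts", "frequencies", "logodds"):
        raise ValueError(f"{path}: header must declare "
                         f"kind=counts|frequencies|logodds (got {kind!r})")
    rows = []
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split()
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-numeric value in matrix row {i}: {exc}"
            ) from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged matrix rows (widths {widths})")
    mat = np.array(rows, dtype=float)
    if meta.get("orient", "positions") == "bases":
        if mat.shape[0] != 4:
            raise ValueError(
                f"{path}: orient=bases requires 4 rows, got {mat.shape[0]}")
        mat = mat.T
    elif mat.shape[1] != 4:
        raise ValueError(
            f"{path}: expected 4 columns (A,C,G,T), got {mat.shape[1]} "
            f"in row 1")
    background = None
    if "background" in meta:
        background = [float(x) for x in meta["background"].split(",")]
    threshold = float(meta["threshold"]) if "threshold" in meta else None
    name = meta.get("name", path.stem)
    if kind == "counts":
        if np.any(mat < 0):
            r, c = np.argwhere(mat < 0)[0]
            raise ValueError(f"{path}: negative count at position {r + 1}, "
                             f"base {ALPHABET[c]}")
        return PWM.from_counts(name, mat, background, pseudocount,
                               threshold)
    if kind == "frequencies":
        return PWM.from_probabilities(name, mat, background, threshold)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PWM(name, mat, bg, threshold)


def write_pwm(pwm: PWM, path: PathLike) -> None:
    """Write a PWM as a log-odds matrix (round-trips with read_pwm)."""
    with open(path, "w") as fh:
        header = f"> name={pwm.name} kind=logodds orient=positions"
        header += " background=" + ",".join(
            f"{b:.6g}" for b in pwm.background)
        if pwm.threshold is not None:
            header += f" threshold={pwm.threshold:.17g}"
        fh.write(header + "\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


# ----------------------------------------------------------------------
# Variants
# ----------------------------------------------------------------------

def read_variants(path: PathLike, dialect: str = "vcf"
                  ) -> list[VariantSite]:
    """Read variant sites in 0-based coordinates.

    ``dialect='vcf'`` parses genotypes with cyvcf2 (diploid cohorts or
    haploid panels); ``dialect='dgrp_table'`` parses the documented
    isogenic-panel TSV dialect with per-allele coverage and error
    fields, flagging heterozygous strain calls.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "dgrp_table":
        return _read_dgrp_table(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_vcf(path: PathLike) -> list[VariantSite]:
    from cyvcf2 import VCF

    sites = []
    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise ValueError(f"{path}: VCF has no genotype (sample) columns")
    for rec in vcf:
        gts = [g[:-1] for g in rec.genotypes]  # strip phased flag
        ploidy = max(len(g) for g in gts)
        calls = np.full((n_samples, ploidy), MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            for j, a in enumerate(g):
                calls[i, j] = MISSING if a is None or a < 0 else a
        if ploidy == 1:
            calls = calls[:, 0]
        sites.append(VariantSite(
            contig=rec.CHROM, pos=rec.POS - 1, ref=rec.REF,
            alts=tuple(rec.ALT), calls=calls, ploidy=ploidy))
    return sites


DGRP_COLUMNS = ["chrom", "pos", "ref", "alt", "eps", "allele_coverage",
                "median_coverage", "calls"]


def _read_dgrp_table(path: PathLike) -> list[VariantSite]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(DGRP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: dgrp_table missing columns {sorted(missing)}")
    sites = []
    for _, row in df.iterrows():
        ref = row["ref"]
        alts = tuple(row["alt"].split(","))
        base_to_idx = {b: i for i, b in enumerate((ref,) + alts)}
        calls = np.empty(len(row["calls"]), dtype=np.int8)
        for i, ch in enumerate(row["calls"]):
            if ch == "N":
                calls[i] = MISSING
            elif ch == "H":
                calls[i] = HET
            elif ch in base_to_idx:
                calls[i] = base_to_idx[ch]
            else:
                raise ValueError(
                    f"{path}: call character {ch!r} at "
                    f"{row['chrom']}:{row['pos']} matches no allele")
        sites.append(VariantSite(
            contig=row["chrom"], pos=int(row["pos"]) - 1, ref=ref,
            alts=alts, calls=calls, ploidy=1, eps=float(row["eps"]),
            allele_coverage=tuple(
                float(x) for x in row["allele_coverage"].split(",")),
            median_coverage=float(row["median_coverage"])))
    return sites


def write_dgrp_table(sites: Sequence[VariantSite], path: PathLike,
                     config: Optional[RunConfig] = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write("\t".join(DGRP_COLUMNS) + "\n")
        for s in sites:
            alleles = s.alleles
            call_str = "".join(
                "N" if c == MISSING else "H" if c == HET else alleles[c]
                for c in s.calls)
            fh.write("\t".join([
                s.contig, str(s.pos + 1), s.ref, ",".join(s.alts),
                f"{s.eps:.6g}",
                ",".join(f"{c:.6g}" for c in s.allele_coverage),
                f"{s.median_coverage:.6g}", call_str]) + "\n")


def write_vcf(sites: Sequence[VariantSite], path: PathLike,
              sample_names: Optional[Sequence[str]] = None,
              contig_lengths: Optional[dict[str, int]] = None) -> None:
    """Write sites as a minimal uncompressed VCF (GT only)."""
    if not sites:
        raise ValueError("no sites to write")
    n = sites[0].calls.shape[0]
    names = sample_names or [f"S{i:03d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=tfbsload {__version__}\n")
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for s in sorted(sites, key=lambda s: (s.contig, s.pos)):
            gts = []
            if s.ploidy == 1:
                for c in s.calls:
                    gts.append("." if c < 0 else str(int(c)))
            else:
                for a, b in s.calls:
                    ga = "." if a < 0 else str(int(a))
                    gb = "." if b < 0 else str(int(b))
                    gts.append(f"{ga}/{gb}")
            fh.write("\t".join([
                s.contig, str(s.pos + 1), ".", s.ref, ",".join(s.alts),
                ".", "PASS", ".", "GT"] + gts) + "\n")


# ----------------------------------------------------------------------
# Regions (BED)
# ----------------------------------------------------------------------

@dataclass
class ChIPRegion:
    """A TF-bound region, optionally with a binding signal."""

    contig: str
    start: int
    end: int
    name: Optional[str] = None
    signal: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}")


def read_regions(path: PathLike) -> list[ChIPRegion]:
    """Read BED3+ regions; the optional 5th column is a signal value."""
    regions = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: BED line with < 3 fields: {ln!r}")
            regions.append(ChIPRegion(
                contig=parts[0], start=int(parts[1]), end=int(parts[2]),
                name=parts[3] if len(parts) > 3 else None,
                signal=float(parts[4]) if len(parts) > 4 else None))
    return regions


def write_regions(regions: Sequence[ChIPRegion], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.contig, str(r.start), str(r.end)]
            if r.name is not None or r.signal is not None:
                fields.append(r.name if r.name is not None else ".")
            if r.signal is not None:
                fields.append(f"{r.signal:.6g}")
            fh.write("\t".join(fields) + "\n")


# ----------------------------------------------------------------------
# MAF, newick, bedGraph
# ----------------------------------------------------------------------

def read_alignment(path: PathLike) -> list[AlignmentBlock]:
    """Read MAF blocks; the first row of each block is the reference.

    Species names are the part of ``src`` before the first dot; strand
    and gap structure are preserved.
    """
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        sequences, strands = {}, {}
        ref = None
        for rec in aln:
            species, _, contig = rec.id.partition(".")
            sequences[species] = str(rec.seq)
            strands[species] = "+" if rec.annotations.get("strand", 1) == 1 \
                else "-"
            if ref is None:
                ref = (species, contig, int(rec.annotations["start"]),
                       int(rec.annotations["size"]))
        blocks.append(AlignmentBlock(
            ref_species=ref[0], ref_contig=ref[1], ref_start=ref[2],
            ref_size=ref[3], sequences=sequences, strands=strands))
    return blocks


def write_alignment(blocks: Sequence[AlignmentBlock],
                    path: PathLike) -> None:
    """Write blocks as MAF (reference row first)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            order = [b.ref_species] + sorted(
                set(b.sequences) - {b.ref_species})
            for sp in order:
                seq = b.sequences[sp]
                size = len(seq.replace("-", ""))
                start = b.ref_start if sp == b.ref_species else 0
                contig = b.ref_contig if sp == b.ref_species else "contig"
                strand = b.strands.get(sp, "+")
                src_size = b.ref_start + b.ref_size \
                    if sp == b.ref_species else size
                fh.write(f"s {sp}.{contig} {start} {size} {strand} "
                         f"{src_size} {seq}\n")
            fh.write("\n")


def read_tree(path: PathLike) -> PhyloTree:
    return PhyloTree.from_newick(str(path), is_path=True)


def read_bedgraph(path: PathLike,
                  contig_lengths: Optional[dict[str, int]] = None
                  ) -> dict[str, np.ndarray]:
    """Read a bedGraph of per-base scores into per-contig arrays.

    Positions not covered by any interval score 0.  Lengths default to
    the maximum end seen per contig.
    """
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track")):
                continue
            contig, start, end, value = ln.split("\t")[:4]
            intervals.append((contig, int(start), int(end), float(value)))
    lengths: dict[str, int] = dict(contig_lengths or {})
    for contig, _, end, _ in intervals:
        lengths[contig] = max(lengths.get(contig, 0), end)
    tracks = {c: np.zeros(n) for c, n in lengths.items()}
    for contig, start, end, value in intervals:
        tracks[contig][start:end] = value
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray], path: PathLike) -> None:
    with open(path, "w") as fh:
        for contig in sorted(tracks):
            vals = np.asarray(tracks[contig])
            # run-length encode constant stretches
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{vals[s]:.6g}\n")


# ----------------------------------------------------------------------
# Result tables
# ----------------------------------------------------------------------

#: output schema for per-instance tables: position, sequence, match
#: score, branch length score, mutational load, TSS distance and the
#: count/score of the alternative allele when one was detected
INSTANCE_TABLE_COLUMNS = [
    "contig", "start", "end", "strand", "tf", "sequence", "pwm_score",
    "bls", "load", "tss_distance", "alt_count", "alt_score"]


def _header_lines(config: Optional[RunConfig],
                  extra: Optional[dict] = None) -> list[str]:
    lines = [f"# tfbsload version={__version__}"]
    if config is not None:
        lines += [f"# {k}={v}" for k, v in config.header_items()]
    if extra:
        lines += [f"# {k}={v}" for k, v in sorted(extra.items())]
    return lines


def write_table(records, path: PathLike,
                config: Optional[RunConfig] = None,
                extra_header: Optional[dict] = None) -> None:
    """Write records as TSV with a commented provenance header.

    ``records`` may be a DataFrame or a sequence of dataclass
    instances; an empty sequence yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    buf = _io.StringIO()
    for line in _header_lines(config, extra_header):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_records_frame(records) -> pd.DataFrame:
    """Per-instance result table in the documented output schema."""
    rows = []
    for r in records:
        inst = r.instance
        rows.append({
            "contig": inst.contig, "start": inst.start, "end": inst.end,
            "strand": inst.strand, "tf": inst.tf_name,
            "sequence": inst.matched_sequence, "pwm_score": r.w0,
            "bls": r.bls, "load": r.load, "tss_distance": r.tss_distance,
            "alt_count": r.n_alleles - 1,
            "alt_score": r.w0 - r.max_score_drop
            if r.n_alleles > 1 else np.nan})
    return pd.DataFrame(rows, columns=INSTANCE_TABLE_COLUMNS)
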