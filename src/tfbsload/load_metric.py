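"""Per-instance mutational load of motif instances and its aggregations.

Mutational load adapts the classical genetic-load idea to binding
sites: the penetrance of a motif mutation (allele frequency) is
combined with the phenotypic consequence it is predicted to have (the
loss of PWM match score).  For an instance with major-allele score w0
and observed alleles with scores w_i at frequencies p_i,

    L = (w0 - sum_i w_i * p_i) / w0

floored at zero, so monomorphic instances and score-gaining variation
carry no load.  The reference point is the major allele rather than the
best-scoring one because only bound instances enter the analysis, which
biases against detecting sites whose major allele is the weaker one.

Aggregations use a trimmed mean that excludes a single maximal value to
limit the influence of outliers, and group instances by conservation
(branch length score), motif stringency (within-factor score rank),
distance from the transcription start site, genomic windows, or
homotypic context (singleton vs duplet motifs per bound region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pwm import MotifInstance
from .variation import InstanceAlleleSet

#: average-load threshold (per 100 kb window) calling a high-load hotspot
HOTSPOT_LOAD = 5e-3

#: default TSS-distance bin edges in bp (upper-open last bin)
TSS_BIN_EDGES = (0, 500, 1000, 2000, 5000, 10000, np.inf)

#: default BLS bin edges; BLS = 0 always gets its own dedicated bin
BLS_BIN_EDGES = (0.0, 0.2, 0.5, 1.0)


def mutational_load(allelesets) -> float:
    """Mutational load of one motif instance.

    Accepts a single :class:`InstanceAlleleSet` or a sequence of
    per-site sets from an unphased multi-variant instance, in which
    case the maximum per-site load is returned (conservative: the worst
    single variant determines the instance's load).
    """
    if isinstance(allelesets, InstanceAlleleSet):
        allelesets = [allelesets]
    if not allelesets:
        raise ValueError("need at least one allele set")
    return max(_single_load(a) for a in allelesets)


def _single_load(aset: InstanceAlleleSet) -> float:
    w0 = aset.major.score
    if w0 <= 0:
        raise ValueError(
            f"major-allele score {w0} <= 0 for {aset.instance.instance_id}; "
            "instance should not have passed the detection threshold "
            "(check threshold configuration)")
    expected = sum(a.score * a.frequency for a in aset.alleles)
    return max(0.0, (w0 - expected) / w0)


@dataclass
class LoadRecord:
    """Load and covariates of one motif instance."""

    instance: MotifInstance
    load: float
    w0: float
    n_alleles: int
    max_score_drop: float
    bls: Optional[float] = None
    tss_distance: Optional[float] = None
    region_id: Optional[str] = None

    @property
    def tf_name(self) -> str:
        return self.instance.tf_name


def make_load_record(instance: MotifInstance,
                     allelesets: Sequence[InstanceAlleleSet],
                     bls: Optional[float] = None,
                     region_id: Optional[str] = None) -> LoadRecord:
    L = mutational_load(allelesets)
    sets = ([allelesets] if isinstance(allelesets, InstanceAlleleSet)
            else list(allelesets))
    w0 = sets[0].major.score
    n_alleles = sum(len(s.alleles) for s in sets) - (len(sets) - 1)
    drops = [s.major.score - a.score
             for s in sets for a in s.alleles]
    return LoadRecord(instance, L, w0, n_alleles, max(drops, default=0.0),
                      bls=bls, tss_distance=instance.tss_distance,
                      region_id=region_id)


def trimmed_mean_load(values: Iterable[float]) -> float:
    """Mean after excluding exactly one maximal value.

    A single value trims to nothing and is reported as 0 with a warning
    (so e.g. hotspot windows require at least two instances); an empty
    input is an error.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("trimmed mean of an empty set is undefined")
    if vals.size == 1:
        warnings.warn("trimmed mean of a single value is reported as 0")
        return 0.0
    return float((vals.sum() - vals.max()) / (vals.size - 1))


def annotate_tss_distance(instances: Sequence[MotifInstance],
                          tss: dict[str, Sequence[int]]) -> None:
    """Set unsigned distance from instance midpoint to the nearest TSS."""
    for inst in instances:
        positions = np.asarray(tss.get(inst.contig, ()), dtype=float)
        if positions.size == 0:
            inst.tss_distance = None
            continue
        mid = (inst.start + inst.end) / 2
        inst.tss_distance = float(np.abs(positions - mid).min())


def windowed_load(records: Sequence[LoadRecord],
                  window: int = 100_000,
                  hotspot_threshold: float = HOTSPOT_LOAD) -> pd.DataFrame:
    """Trimmed-mean load per fixed genomic window, with hotspot flags."""
    if not records:
        return pd.DataFrame(columns=["contig", "window_start", "window_end",
                                     "n", "mean_load", "hotspot"])
    rows = []
    keyed: dict[tuple[str, int], list[float]] = {}
    for r in records:
        key = (r.instance.contig, r.instance.start // window)
        keyed.setdefault(key, []).append(r.load)
    for (contig, w), loads in sorted(keyed.items()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = trimmed_mean_load(loads)
        rows.append({"contig": contig, "window_start": w * window,
                     "window_end": (w + 1) * window, "n": len(loads),
                     "mean_load": m, "hotspot": m > hotspot_threshold})
    return pd.DataFrame(rows)


def _bls_bins(bls: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Bin labels with a dedicated bin for BLS exactly 0."""
    labels = np.empty(bls.size, dtype=object)
    labels[bls == 0] = "BLS=0"
    nz = bls > 0
    cut = pd.cut(bls[nz], bins=list(edges), include_lowest=False,
                 right=True)
    labels[nz] = cut.astype(str)
    return labels


def _score_quintiles(records: Sequence[LoadRecord], n_bins: int = 5
                     ) -> np.ndarray:
    """Within-TF score ranks scaled to [0, 1], cut into equal ranges."""
    tf = np.array([r.tf_name for r in records])
    score = np.array([r.w0 for r in records], dtype=float)
    scaled = np.empty(score.size)
    for t in np.unique(tf):
        idx = np.nonzero(tf == t)[0]
        ranks = sps.rankdata(score[idx], method="average")
        scaled[idx] = (ranks - 1) / max(len(idx) - 1, 1)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.searchsorted(edges, scaled, side="right") - 1,
                    0, n_bins - 1)
    return np.array([f"Q{i + 1}" for i in which])


def _tss_bins(dist: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    labels = np.empty(dist.size, dtype=object)
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        mask = (dist >= lo) & (dist < hi)
        hi_txt = "inf" if np.isinf(hi) else f"{int(hi)}"
        labels[mask] = f"[{int(lo)},{hi_txt})"
    return labels


def aggregate_load(records: Sequence[LoadRecord], covariate: str,
                   bins: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Per-group trimmed-mean load table for one grouping covariate.

    ``covariate`` is one of ``bls`` (dedicated BLS = 0 bin plus ranges),
    ``score`` (within-TF rank quintiles) or ``tss`` (distance ranges).
    """
    if not records:
        raise ValueError("no records to aggregate")
    if covariate == "bls":
        vals = np.array([r.bls for r in records], dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError("all records need a BLS for bls aggregation")
        labels = _bls_bins(vals, bins or BLS_BIN_EDGES)
        order = ["BLS=0"] + [str(iv) for iv in pd.cut(
            np.array([]), bins=list(bins or BLS_BIN_EDGES)).categories]
    elif covariate == "score":
        labels = _score_quintiles(records)
        order = [f"Q{i + 1}" for i in range(5)]
    elif covariate == "tss":
        vals = np.array([r.tss_distance for r in records], dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError("all records need a TSS distance")
        edges = bins or TSS_BIN_EDGES
        labels = _tss_bins(vals, edges)
        order = [f"[{int(edges[i])},"
                 f"{'inf' if np.isinf(edges[i + 1]) else int(edges[i + 1])})"
                 for i in range(len(edges) - 1)]
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    loads = np.array([r.load for r in records], dtype=float)
    rows = []
    for g in order:
        sel = loads[labels == g]
        if sel.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append({"group": g, "n": sel.size,
                         "mean_load": trimmed_mean_load(sel)})
    return pd.DataFrame(rows)


def aggregate_trend_test(records: Sequence[LoadRecord], covariate: str,
                         n_perm: int = 10_000, seed: Optional[int] = None,
                         alternative: str = "two-sided",
                         bins: Optional[Sequence[float]] = None):
    """Permutation trend test over ordered covariate groups.

    Load values are permuted within each TF (covariates stay fixed),
    and the trend statistic is recomputed on the vector of per-group
    trimmed means; see :mod:`tfbsload.stats` for the statistic.
    """
    from . import stats

    if covariate == "bls":
        vals = np.array([r.bls for r in records], dtype=float)
        labels = _bls_bins(vals, bins or BLS_BIN_EDGES)
    elif covariate == "score":
        labels = _score_quintiles(records)
    elif covariate == "tss":
        vals = np.array([r.tss_distance for r in records], dtype=float)
        labels = _tss_bins(vals, bins or TSS_BIN_EDGES)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    loads = np.array([r.load for r in records], dtype=float)
    tf = np.array([r.tf_name for r in records])
    uniq = list(dict.fromkeys(sorted(set(labels))))
    lab_idx = {g: i for i, g in enumerate(uniq)}
    codes = np.array([lab_idx[g] for g in labels])

    def group_mean_trend(x: np.ndarray) -> float:
        means = np.empty(len(uniq))
        for i in range(len(uniq)):
            sel = x[codes == i]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                means[i] = trimmed_mean_load(sel) if sel.size else np.nan
        means = means[~np.isnan(means)]
        return stats.trend_statistic(means)

    return stats.permutation_test(loads, groups=tf,
                                  statistic=group_mean_trend,
                                  n_perm=n_perm, seed=seed,
                                  alternative=alternative)


# ----------------------------------------------------------------------
# Homotypic-context analyses
# ----------------------------------------------------------------------

def _records_by_region(records: Sequence[LoadRecord]
                       ) -> dict[tuple[str, str], list[LoadRecord]]:
    out: dict[tuple[str, str], list[LoadRecord]] = {}
    for r in records:
        if r.region_id is None:
            continue
        out.setdefault((r.tf_name, r.region_id), []).append(r)
    return out


def singleton_duplet_comparison(records: Sequence[LoadRecord],
                                n_draws: int = 100,
                                seed: Optional[int] = None,
                                n_perm: int = 1000,
                                bls_edges: Sequence[float] = BLS_BIN_EDGES):
    """Singleton vs duplet trimmed-mean load per BLS range.

    Bound regions with a single motif are "singletons"; regions with
    exactly two homotypic motifs are "duplets", from which one motif is
    drawn at random per region, repeated ``n_draws`` times.  Regions
    with three or more motifs are excluded.  The test statistic is the
    sum over BLS ranges of (mean singleton load - mean duplet load),
    averaged over draws; significance comes from permuting the
    singleton/duplet region labels within each TF.

    Returns ``(table, PermutationResult)``.
    """
    from . import stats

    rng = np.random.default_rng(seed)
    grouped = _records_by_region(records)
    singletons = [rs[0] for rs in grouped.values() if len(rs) == 1]
    duplets = [rs for rs in grouped.values() if len(rs) == 2]
    if not singletons or not duplets:
        raise ValueError("need both singleton and duplet regions")

    def bin_of(r: LoadRecord) -> str:
        return _bls_bins(np.array([r.bls], dtype=float), bls_edges)[0]

    ranges = sorted({bin_of(r) for r in singletons}
                    | {bin_of(r) for rs in duplets for r in rs})

    def statistic(single: list[LoadRecord],
                  dup: list[list[LoadRecord]],
                  draw_rng: np.random.Generator) -> tuple[float, pd.DataFrame]:
        per_draw = []
        rows = []
        draws = draw_rng.integers(0, 2, size=(n_draws, len(dup)))
        for d in range(n_draws):
            chosen = [dup[i][draws[d, i]] for i in range(len(dup))]
            total = 0.0
            for g in ranges:
                s_loads = [r.load for r in single if bin_of(r) == g]
                d_loads = [r.load for r in chosen if bin_of(r) == g]
                if not s_loads or not d_loads:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ms = trimmed_mean_load(s_loads)
                    md = trimmed_mean_load(d_loads)
                total += ms - md
                if d == 0:
                    rows.append({"bls_range": g, "n_singleton": len(s_loads),
                                 "n_duplet": len(d_loads),
                                 "mean_singleton": ms, "mean_duplet": md})
            per_draw.append(total)
        return float(np.mean(per_draw)), pd.DataFrame(rows)

    observed, table = statistic(singletons, duplets, rng)

    # null: represent each duplet region by one drawn motif, then permute
    # the singleton/duplet region labels within each TF
    reps = list(singletons) + [
        rs[rng.integers(2)] for rs in duplets]
    tfs = np.array([r.tf_name for r in reps])
    is_single = np.array([True] * len(singletons)
                         + [False] * len(duplets))
    rep_bins = np.array([bin_of(r) for r in reps])
    rep_loads = np.array([r.load for r in reps])

    def label_statistic(labels: np.ndarray) -> float:
        total = 0.0
        for g in ranges:
            s_sel = rep_loads[labels & (rep_bins == g)]
            d_sel = rep_loads[~labels & (rep_bins == g)]
            if s_sel.size == 0 or d_sel.size == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                total += trimmed_mean_load(s_sel) - trimmed_mean_load(d_sel)
        return total

    null = np.empty(n_perm)
    for b in range(n_perm):
        labels = is_single.copy()
        for t in np.unique(tfs):
            idx = np.nonzero(tfs == t)[0]
            labels[idx] = rng.permutation(labels[idx])
        null[b] = label_statistic(labels)
    p = stats.empirical_p(observed, null, alternative="two-sided")
    result = stats.PermutationResult(observed=observed, null=null,
                                     p_value=p, n_perm=n_perm, seed=seed,
                                     groups="tf", alternative="two-sided")
    return table, result


def load_vs_motif_count(records: Sequence[LoadRecord]
                        ) -> tuple[pd.DataFrame, float, float]:
    """Per-TF trimmed-mean load vs mean motifs per bound region.

    Returns ``(table, pearson_r, p)``; r is NA when either variable is
    constant.
    """
    rows = []
    by_tf: dict[str, list[LoadRecord]] = {}
    for r in records:
        by_tf.setdefault(r.tf_name, []).append(r)
    for tf, rs in sorted(by_tf.items()):
        regions: dict[str, int] = {}
        for r in rs:
            if r.region_id is not None:
                regions[r.region_id] = regions.get(r.region_id, 0) + 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = trimmed_mean_load([r.load for r in rs])
        rows.append({"tf": tf, "mean_load": m,
                     "mean_motifs_per_region":
                         float(np.mean(list(regions.values())))
                         if regions else np.nan})
    table = pd.DataFrame(rows)
    x = table["mean_load"].to_numpy()
    y = table["mean_motifs_per_region"].to_numpy()
    if len(table) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return table, float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return table, float(r), float(p)


def variable_vs_constant_scores(records: Sequence[LoadRecord],
                                seed: Optional[int] = None
                                ) -> tuple[pd.DataFrame, float, float]:
    """Score of the highest-load motif vs a zero-load motif per region.

    For each bound region holding at least one varying (load > 0) and
    one constant (load = 0) homotypic motif, the paired score
    difference (variable - constant) is reported together with a
    random-pair control; the p-value is a signed-rank test of the
    paired differences against zero.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (tf, region), rs in _records_by_region(records).items():
        if len(rs) < 2:
            continue
        variable = max(rs, key=lambda r: r.load)
        constants = [r for r in rs if r.load == 0.0 and r is not variable]
        if variable.load <= 0 or not constants:
            continue
        constant = constants[rng.integers(len(constants))]
        a, b = rng.choice(len(rs), size=2, replace=False)
        rows.append({"tf": tf, "region_id": region,
                     "score_variable": variable.w0,
                     "score_constant": constant.w0,
                     "difference": variable.w0 - constant.w0,
                     "random_difference": rs[a].w0 - rs[b].w0})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, float("nan"), float("nan")
    diffs = table["difference"].to_numpy()
    if np.all(diffs == 0):
        return table, 0.0, 1.0
    stat, p = sps.wilcoxon(diffs)
    return table, float(np.median(diffs)), float(p)
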