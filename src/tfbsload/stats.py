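"""Permutation machinery and standard-test wrappers.

Load distributions over binding sites are strongly zero-inflated (most
instances carry no detected variation), which breaks the assumptions of
conventional parametric tests.  Significance is therefore assessed by
permutation: values are shuffled within each transcription factor, so
that factor-specific properties (motif length, threshold, instance
count) cannot generate spurious global trends, and the statistic is
recomputed on the combined vector.

The trend statistic is the dot product of the normalised data vector
with the index vector (1, ..., N); normalisation is mean-centering
followed by unit-L2 scaling, isolated in :func:`normalize_vector` since
other normalisations exist in the literature.  P-values use the add-one
rule (1 + #{null at least as extreme}) / (1 + n_perm), which can never
report zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

MIN_PERMUTATIONS = 100


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: Optional[int]
    groups: Optional[str]
    alternative: str


def normalize_vector(x: np.ndarray) -> np.ndarray:
    """Mean-center then scale to unit L2 norm (zero vector stays zero)."""
    x = np.asarray(x, dtype=float)
    c = x - x.mean()
    norm = np.linalg.norm(c)
    return c / norm if norm > 0 else c


def trend_statistic(x: Sequence[float]) -> float:
    """Dot product of the normalised data vector with (1, ..., N).

    Positive for increasing trends, negative for decreasing, zero for a
    constant vector; invariant under adding a constant and under
    positive rescaling of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("trend statistic needs at least 2 values")
    idx = np.arange(1, x.size + 1, dtype=float)
    return float(normalize_vector(x) @ idx)


def _trend_rows(mat: np.ndarray) -> np.ndarray:
    """Vectorised trend statistic over rows of a matrix."""
    c = mat - mat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    idx = np.arange(1, mat.shape[1] + 1, dtype=float)
    return (c / norm) @ idx


def empirical_p(observed: float, null: np.ndarray,
                alternative: str = "greater") -> float:
    """Add-one permutation p-value, never exactly zero."""
    null = np.asarray(null, dtype=float)
    n = null.size
    if alternative == "greater":
        hits = np.sum(null >= observed)
    elif alternative == "less":
        hits = np.sum(null <= observed)
    elif alternative == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + hits) / (1 + n))


def _permute_within_groups(values: np.ndarray, groups: Optional[np.ndarray],
                           n_perm: int, rng: np.random.Generator
                           ) -> np.ndarray:
    """(n_perm, N) matrix of within-group permutations of ``values``."""
    N = values.size
    out = np.empty((n_perm, N))
    if groups is None:
        idx = np.argsort(rng.random((n_perm, N)), axis=1)
        return values[idx]
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = np.nonzero(groups == g)[0]
        idx = np.argsort(rng.random((n_perm, sel.size)), axis=1)
        out[:, sel] = values[sel][idx]
    return out


def permutation_test(values: Sequence[float],
                     groups: Optional[Sequence] = None,
                     statistic: Union[str, Callable] = "trend",
                     n_perm: int = 10_000,
                     seed: Optional[int] = None,
                     alternative: str = "two-sided") -> PermutationResult:
    """Within-group permutation test of a statistic on the combined vector.

    Each permutation shuffles values independently within each group
    (a single group reduces to an unrestricted permutation test).
    ``statistic`` is either the built-in ``"trend"`` (vectorised) or a
    callable on a 1-D value vector.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_perm = {n_perm} < {MIN_PERMUTATIONS}: p-value floor too "
            "unstable for inference")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    grp = None if groups is None else np.asarray(groups)
    perms = _permute_within_groups(values, grp, n_perm, rng)
    if statistic == "trend":
        observed = trend_statistic(values)
        null = _trend_rows(perms)
    else:
        observed = float(statistic(values))
        null = np.array([statistic(perms[i]) for i in range(n_perm)])
    p = empirical_p(observed, null, alternative)
    return PermutationResult(observed=observed, null=null, p_value=p,
                             n_perm=n_perm, seed=seed,
                             groups=None if groups is None else "supplied",
                             alternative=alternative)


def positionwise_null_test(real_freqs: np.ndarray,
                           null_freqs: np.ndarray,
                           n_perm: int = 2000,
                           seed: Optional[int] = None,
                           chunk: int = 200) -> np.ndarray:
    """Per-position p-values for reduced diversity vs a scrambled null.

    ``real_freqs`` is (n_real, K, 4) per-instance base frequencies of
    the real motif; ``null_freqs`` is (n_null, K, 4) for de-reshuffled
    scrambled instances.  The per-position statistic is the mean over
    instances of per-instance Nei diversity; the null distribution is
    built by resampling instance labels (each permutation draws
    ``n_real`` instances from the combined pool).  One-sided p
    (diversity as small as observed), add-one corrected.
    """
    from .variation import per_instance_diversity

    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm = {n_perm} < {MIN_PERMUTATIONS}")
    real_freqs = np.asarray(real_freqs, dtype=float)
    null_freqs = np.asarray(null_freqs, dtype=float)
    n_real, K, _ = real_freqs.shape
    d_all = np.concatenate([per_instance_diversity(real_freqs),
                            per_instance_diversity(null_freqs)], axis=0)
    n_tot = d_all.shape[0]
    rng = np.random.default_rng(seed)
    obs = d_all[:n_real].mean(axis=0)
    hits = np.zeros(K, dtype=int)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # first n_real entries of each random permutation of labels
        idx = np.argsort(rng.random((b, n_tot)), axis=1)[:, :n_real]
        d = d_all[idx].mean(axis=1)
        hits += (d <= obs[None, :] + 1e-12).sum(axis=0)
        done += b
    return (1 + hits) / (1 + n_perm)


# ----------------------------------------------------------------------
# Standard tests (thin wrappers)
# ----------------------------------------------------------------------

def fisher_test(table: np.ndarray, alternative: str = "two-sided"
                ) -> tuple[float, float]:
    """Exact Fisher test on a 2x2 contingency table -> (odds ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table), alternative=alternative)
    return float(odds), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> float:
    """Two-sample Wilcoxon (Mann-Whitney), normal approximation with
    ties correction; identical samples give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x[:, None] == y[None, :]):
        return 1.0
    _, p = sps.mannwhitneyu(x, y, alternative=alternative,
                            method="asymptotic")
    return float(min(p, 1.0))


def wilcoxon_signed_rank(diffs: Sequence[float],
                         alternative: str = "two-sided") -> float:
    """One-sample signed-rank test of paired differences against zero."""
    diffs = np.asarray(diffs, dtype=float)
    if np.all(diffs == 0):
        return 1.0
    _, p = sps.wilcoxon(diffs, alternative=alternative)
    return float(p)


def kruskal_wallis(*groups: Sequence[float]) -> float:
    """Kruskal-Wallis test across groups; all-identical data give p = 1."""
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 1.0
    _, p = sps.kruskal(*groups)
    return float(p)
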