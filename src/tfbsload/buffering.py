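"""Per-individual ChIP analysis of motif variants ("buffering").

Given genotype-resolved binding signals across individuals at
polymorphic binding sites, this module asks how much binding signal a
score-reducing motif mutation actually costs.  A homozygous polymorphic
site is "buffered" when individuals carrying the minor variant retain
at least two-thirds of the major variant's mean signal.  Interaction
models then test whether interspecies conservation (branch length
score) dampens the effect of motif mutations: a negative interaction
between score change and BLS means mutations at conserved sites perturb
binding less.

Signals from different individuals are made comparable by quantile
normalization (each individual's signal distribution is replaced by the
rank-wise mean distribution), implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import stats as _stats

#: a minor variant retaining at least this fraction of signal is buffered
BUFFERING_RATIO = 2.0 / 3.0

GENOTYPES = ("major", "minor", "het")


@dataclass
class IndividualBindingTable:
    """Site x individual ChIP signals with per-individual genotypes.

    ``signals`` and ``genotypes`` are DataFrames indexed by site id with
    one column per individual; genotype entries are ``"major"``,
    ``"minor"``, ``"het"`` or NA.  ``sites`` carries per-site metadata:
    ``score_major``, ``score_minor`` (PWM scores of the two variants)
    and ``bls``.
    """

    sites: pd.DataFrame
    signals: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.signals.index.equals(self.genotypes.index):
            raise ValueError("signals and genotypes must share site index")
        if list(self.signals.columns) != list(self.genotypes.columns):
            raise ValueError("signals and genotypes must share individuals")
        bad = set(self.genotypes.stack().dropna()) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")


def quantile_normalize(matrix) -> pd.DataFrame:
    """Quantile-normalize columns (individuals) of a signal matrix.

    Every column is mapped onto the same reference distribution — the
    row-wise mean of the sorted columns — with tied values receiving
    the average of the reference values at their tied ranks.
    """
    df = pd.DataFrame(matrix)
    values = df.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = sps.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def genotype_signal_summary(table: IndividualBindingTable) -> pd.DataFrame:
    """Mean signal per (site, genotype class); absent classes are absent.

    Individuals with the same genotype at a site are summarised by the
    mean of their signals.
    """
    rows = []
    for site in table.signals.index:
        gt = table.genotypes.loc[site]
        sig = table.signals.loc[site]
        for g in GENOTYPES:
            sel = sig[gt == g].dropna()
            if len(sel):
                rows.append({"site": site, "genotype": g,
                             "mean_signal": float(sel.mean()),
                             "n_individuals": int(len(sel))})
    return pd.DataFrame(rows)


def classify_buffered(major_signal: float, minor_signal: float,
                      ratio: float = BUFFERING_RATIO) -> bool:
    """Buffered iff the minor variant retains >= 2/3 of the major's
    signal (inclusive at exactly the threshold)."""
    if major_signal <= 0:
        raise ValueError("major-variant signal must be positive")
    return minor_signal >= ratio * major_signal


def site_buffering_table(table: IndividualBindingTable,
                         ratio: float = BUFFERING_RATIO) -> pd.DataFrame:
    """Per-site buffering call at homozygous polymorphic sites.

    Sites lacking either homozygote class are skipped (heterozygous
    individuals never enter the classification).
    """
    summary = genotype_signal_summary(table)
    wide = summary.pivot(index="site", columns="genotype",
                         values="mean_signal")
    rows = []
    for site, r in wide.iterrows():
        if "major" not in r or "minor" not in r or \
                pd.isna(r.get("major")) or pd.isna(r.get("minor")):
            continue
        rows.append({
            "site": site,
            "signal_major": r["major"],
            "signal_minor": r["minor"],
            "bls": float(table.sites.loc[site, "bls"]),
            "buffered": classify_buffered(r["major"], r["minor"], ratio)})
    if not rows:
        return pd.DataFrame(columns=["signal_major", "signal_minor",
                                     "bls", "buffered"],
                            index=pd.Index([], name="site"))
    return pd.DataFrame(rows).set_index("site")


def buffering_by_conservation(site_table: pd.DataFrame,
                              bls_split: float = 0.5
                              ) -> tuple[pd.DataFrame, float, float]:
    """Buffered x conservation 2x2 table with Fisher p.

    Strata are BLS < ``bls_split`` (less conserved) and BLS >=
    ``bls_split``; an empty stratum is an error.  Returns
    ``(table, odds_ratio, p)``; the odds ratio is NA when a margin is
    degenerate (e.g. every site buffered).
    """
    hi = site_table[site_table["bls"] >= bls_split]
    lo = site_table[site_table["bls"] < bls_split]
    if hi.empty or lo.empty:
        raise ValueError(
            f"empty conservation stratum at BLS split {bls_split}")
    counts = pd.DataFrame(
        {"buffered": [int(lo["buffered"].sum()), int(hi["buffered"].sum())],
         "not_buffered": [int((~lo["buffered"]).sum()),
                          int((~hi["buffered"]).sum())]},
        index=[f"BLS<{bls_split}", f"BLS>={bls_split}"])
    odds, p = _stats.fisher_test(counts.to_numpy())
    if not np.isfinite(odds):
        odds = float("nan")
    return counts, odds, p


# ----------------------------------------------------------------------
# Delta records and interaction models
# ----------------------------------------------------------------------

def delta_records(table: IndividualBindingTable) -> pd.DataFrame:
    """Per-site score and signal changes between variants.

    ``delta_score`` is score(minor) - score(major); ``delta_chip`` is
    the minor-vs-major difference in mean signal, sign-adjusted so that
    a signal change concordant with the score change is positive.
    Restricted to homozygous polymorphic sites.
    """
    site_tab = site_buffering_table(table)
    out = []
    for site, r in site_tab.iterrows():
        d_score = float(table.sites.loc[site, "score_minor"]
                        - table.sites.loc[site, "score_major"])
        raw = r["signal_minor"] - r["signal_major"]
        out.append({"site": site, "delta_score": d_score,
                    "delta_chip": sign_adjust(raw, d_score),
                    "bls": r["bls"],
                    "signal_major": r["signal_major"],
                    "signal_minor": r["signal_minor"]})
    return pd.DataFrame(out).set_index("site")


def sign_adjust(delta_chip: float, delta_score: float) -> float:
    """Orient a signal change relative to the direction of score change:
    concordant loss (or gain) becomes positive."""
    return float(np.sign(delta_score) * delta_chip) if delta_score else 0.0


def delta_analysis(records: pd.DataFrame, score_split: float = 1.0,
                   bls_split: Optional[float] = None) -> pd.DataFrame:
    """Grouped sign-adjusted signal changes at low vs high score disparity.

    Sites split by |delta score| strictly below / strictly above
    ``score_split``; a site exactly at the split belongs to neither
    group.  With ``bls_split`` the contrast is run within each
    conservation stratum.  Wilcoxon rank-sum p compares the low and
    high groups' delta-ChIP distributions.
    """
    absd = records["delta_score"].abs()
    strata = ([("all", records)] if bls_split is None else
              [(f"BLS<{bls_split}", records[records["bls"] < bls_split]),
               (f"BLS>={bls_split}", records[records["bls"] >= bls_split])])
    rows = []
    for name, sub in strata:
        lo = sub[absd.reindex(sub.index) < score_split]["delta_chip"]
        hi = sub[absd.reindex(sub.index) > score_split]["delta_chip"]
        p = (_stats.wilcoxon_rank_sum(lo, hi)
             if len(lo) and len(hi) else float("nan"))
        rows.append({"stratum": name, "n_low": len(lo), "n_high": len(hi),
                     "median_low": float(lo.median()) if len(lo) else np.nan,
                     "median_high": float(hi.median()) if len(hi) else np.nan,
                     "wilcoxon_p": p})
    return pd.DataFrame(rows)


@dataclass
class InteractionFit:
    """OLS fit of response on x, BLS and their interaction."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    condition_number: float
    model: object

    @property
    def interaction(self) -> float:
        return float(self.params["x:bls"])

    @property
    def interaction_p(self) -> float:
        return float(self.pvalues["x:bls"])

    def effect_curve(self, bls: float,
                     x_values: Sequence[float]) -> np.ndarray:
        """Predicted response over ``x_values`` at a fixed BLS."""
        x = np.asarray(x_values, dtype=float)
        b = self.params
        return (b["const"] + b["x"] * x + b["bls"] * bls
                + b["x:bls"] * x * bls)


def interaction_model(x: Sequence[float], bls: Sequence[float],
                      response: Sequence[float],
                      rank_response: bool = False,
                      max_condition: float = 1e8) -> InteractionFit:
    """OLS of response on x, BLS, and x*BLS.

    ``x`` is the score change (or motif score); with ``rank_response``
    the response is rank-transformed over the pooled observations
    first.  A negative interaction coefficient means conservation
    reduces the effect of x on the response.  Collinear predictors
    raise with the design matrix's condition number.
    """
    x = np.asarray(x, dtype=float)
    b = np.asarray(bls, dtype=float)
    y = np.asarray(response, dtype=float)
    if rank_response:
        y = sps.rankdata(y, method="average")
    X = pd.DataFrame({"x": x, "bls": b, "x:bls": x * b})
    X = sm.add_constant(X)
    cond = float(np.linalg.cond(X.to_numpy()))
    if cond > max_condition:
        raise ValueError(
            f"collinear predictors: design matrix condition number "
            f"{cond:.3g} exceeds {max_condition:.3g}")
    fit = sm.OLS(y, X).fit()
    return InteractionFit(params=fit.params, bse=fit.bse,
                          pvalues=fit.pvalues, condition_number=cond,
                          model=fit)


def mutation_effect_model(records: pd.DataFrame) -> InteractionFit:
    """Does conservation reduce the effect of motif mutations on binding?

    Response: sign-adjusted delta ChIP; predictors: |delta score|, BLS
    and their interaction.
    """
    return interaction_model(records["delta_score"].abs(),
                             records["bls"], records["delta_chip"])


def stringency_effect_model(scores: Sequence[float], bls: Sequence[float],
                            signals: Sequence[float]) -> InteractionFit:
    """Does conservation reduce the effect of motif stringency on the
    (pooled rank-transformed) binding signal?"""
    return interaction_model(scores, bls, signals, rank_response=True)
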