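"""Study statistics: normality screen, Friedman, post-hoc pairs, correlation.

The analysis route mirrors a small repeated-measures gait study:
Shapiro-Wilk normality screening per region x condition; on non-normal
cells a Friedman test across the walking conditions (participants as
blocks, per-participant medians as values); Wilcoxon signed-rank
post-hoc pairs with a Bonferroni correction; and Spearman correlation of
peak strain against peak plantar pressure for the flat condition, with
the conventional interpretation bands (weak < 0.4, moderate 0.4-0.69,
strong >= 0.7; significance requires p < 0.05).

The Friedman statistic uses mid-ranks and the tie-corrected chi-square
form with k-1 degrees of freedom; an exact permutation p-value
(enumerating all within-block orderings) is available for verification
at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientPairs
from .regions import ALL_LABELS

__all__ = [
    "FriedmanResult",
    "friedman_test",
    "friedman_exact_p",
    "bonferroni_adjust",
    "posthoc_pairs",
    "strain_pressure_correlation",
    "normality_screen",
    "correlation_band",
    "condition_comparison",
]


@dataclass
class FriedmanResult:
    statistic: float
    pvalue: float
    n_blocks: int
    k: int
    n_dropped: int = 0


def friedman_test(block_matrix: np.ndarray) -> FriedmanResult:
    """Friedman test on a participants x conditions value matrix.

    Blocks (rows) containing NaN are dropped listwise and counted in
    ``n_dropped``.  Mid-ranks handle ties; the statistic is the
    tie-corrected chi-square with k-1 degrees of freedom (identical
    blocks give statistic 0 and p = 1).
    """
    X = np.atleast_2d(np.asarray(block_matrix, dtype=float))
    complete = np.all(np.isfinite(X), axis=1)
    dropped = int(np.count_nonzero(~complete))
    X = X[complete]
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 conditions and >= 2 complete blocks")
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    col = ranks.sum(axis=0)
    num = n * (k - 1) * np.sum((col / n - (k + 1) / 2.0) ** 2)
    den = (np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0) / n
    if den <= 0:
        return FriedmanResult(0.0, 1.0, n, k, dropped)
    stat = float(num / den)
    p = float(sps.chi2.sf(stat, k - 1))
    return FriedmanResult(stat, p, n, k, dropped)


def friedman_exact_p(block_matrix: np.ndarray, max_perms: int = 400_000) -> float:
    """Exact permutation p-value: enumerate all within-block orderings.

    Feasible for k! ** n up to ``max_perms`` (e.g. 6^5 = 7776 for three
    conditions and five blocks).  The p-value is the fraction of
    permuted statistics >= the observed one.
    """
    X = np.atleast_2d(np.asarray(block_matrix, dtype=float))
    X = X[np.all(np.isfinite(X), axis=1)]
    n, k = X.shape
    import math
    n_perms = math.factorial(k) ** n
    if n_perms > max_perms:
        raise ValueError(f"exact enumeration infeasible: {n_perms} permutations")
    obs = friedman_test(X).statistic
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        Xp = np.stack([X[i, list(pi)] for i, pi in enumerate(combo)])
        total += 1
        if friedman_test(Xp).statistic >= obs - 1e-12:
            count += 1
    return count / total


def bonferroni_adjust(p_raw, n_comparisons: int) -> np.ndarray:
    """``min(1, p * m)`` family-wise adjustment."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_comparisons)


def posthoc_pairs(block_matrix: np.ndarray, labels=None, alpha: float = 0.05,
                  method: str = "wilcoxon") -> pd.DataFrame:
    """Pairwise post-hoc tests between conditions with Bonferroni correction.

    ``method='wilcoxon'`` runs the Wilcoxon signed-rank test per pair
    (exact distribution at n <= 25), ``'sign'`` the sign test.  A pair
    whose differences are all zero is degenerate: p = 1 with a note.
    Returns a frame with raw and adjusted p-values and significance
    flags at ``alpha``.
    """
    X = np.atleast_2d(np.asarray(block_matrix, dtype=float))
    X = X[np.all(np.isfinite(X), axis=1)]
    k = X.shape[1]
    labels = list(labels) if labels is not None else [f"c{i}" for i in range(k)]
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        d = X[:, i] - X[:, j]
        note = ""
        if np.all(d == 0):
            p_raw, stat = 1.0, 0.0
            note = "degenerate: all differences zero"
        elif method == "wilcoxon":
            mode = "exact" if len(d) <= 25 else "approx"
            res = sps.wilcoxon(X[:, i], X[:, j], zero_method="wilcox",
                               method=mode)
            stat, p_raw = float(res.statistic), float(res.pvalue)
        elif method == "sign":
            nz = d[d != 0]
            stat = float(np.sum(nz > 0))
            p_raw = float(sps.binomtest(int(stat), len(nz), 0.5).pvalue) if len(nz) \
                else 1.0
            if not len(nz):
                note = "degenerate: all differences zero"
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        rows.append((labels[i], labels[j], stat, p_raw, note))
    df = pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                     "statistic", "p_raw", "note"])
    df["p_adjusted"] = bonferroni_adjust(df["p_raw"].values, len(pairs))
    df["significant"] = df["p_adjusted"] < alpha
    return df


def correlation_band(rho: float) -> str:
    """Conventional interpretation band for a correlation coefficient."""
    r = abs(rho)
    if r < 0.4:
        return "weak"
    if r < 0.7:
        return "moderate"
    return "strong"


@dataclass
class CorrelationResult:
    rho: float
    pvalue: float
    n_pairs: int
    band: str
    significant: bool
    per_participant: pd.DataFrame = field(default_factory=pd.DataFrame)


def strain_pressure_correlation(table: pd.DataFrame, condition: str = "flat",
                                strain_col: str = "peak_smag_pct",
                                pressure_col: str = "ppp_kpa") -> CorrelationResult:
    """Spearman correlation of regional peak strain vs peak plantar pressure.

    Pairs are participant x region cells of the given condition with both
    measures present, each averaged (mean) across repeats.  The cohort
    rho pools all cells; per-participant rhos are also reported.  In-shoe
    pressure systems cannot follow compound curvature, so the comparison
    is meaningful only for the flat condition — the default.

    Raises
    ------
    InsufficientPairs
        With fewer than 3 paired points.
    """
    sub = table[table.condition == condition]
    m = (sub.groupby(["participant", "region"], sort=False)[[strain_col, pressure_col]]
         .mean().dropna().reset_index())
    if len(m) < 3:
        raise InsufficientPairs("insufficient pairs for correlation")
    rho, p = sps.spearmanr(m[strain_col], m[pressure_col])
    per = []
    for pid, g in m.groupby("participant", sort=False):
        if len(g) >= 3:
            r2, p2 = sps.spearmanr(g[strain_col], g[pressure_col])
            per.append((pid, float(r2), float(p2), len(g), correlation_band(r2)))
    per_df = pd.DataFrame(per, columns=["participant", "rho", "pvalue", "n", "band"])
    rho, p = float(rho), float(p)
    return CorrelationResult(rho=rho, pvalue=p, n_pairs=len(m),
                             band=correlation_band(rho),
                             significant=bool(p < 0.05),
                             per_participant=per_df)


def normality_screen(table: pd.DataFrame, value_col: str = "peak_smag_pct",
                     alpha: float = 0.05) -> tuple[pd.DataFrame, str]:
    """Shapiro-Wilk per region x condition on per-participant medians.

    Constant cells are undefined for the test and flagged non-normal by
    convention (with a note).  The recommendation is ``nonparametric``
    when any cell rejects at ``alpha`` — the route that leads to the
    Friedman test.
    """
    per = (table.dropna(subset=[value_col])
           .groupby(["region", "condition", "participant"], sort=False)[value_col]
           .median().reset_index())
    rows = []
    any_reject = False
    for (region, cond), g in per.groupby(["region", "condition"], sort=False):
        x = g[value_col].values
        if len(x) < 3:
            rows.append((region, cond, np.nan, len(x), "too few values"))
            continue
        if np.ptp(x) == 0:
            rows.append((region, cond, 0.0, len(x), "degenerate: constant sample"))
            any_reject = True
            continue
        stat, p = sps.shapiro(x)
        rows.append((region, cond, float(p), len(x), ""))
        if p < alpha:
            any_reject = True
    df = pd.DataFrame(rows, columns=["region", "condition", "shapiro_p", "n", "note"])
    return df, ("nonparametric" if any_reject else "parametric")


def condition_comparison(table: pd.DataFrame, value_col: str = "peak_smag_pct",
                         alpha: float = 0.05, gate_on_friedman: bool = True,
                         use_medians: bool = True) -> pd.DataFrame:
    """Per-region Friedman across conditions + Bonferroni post-hoc pairs.

    Values entering the block matrix are per-participant medians across
    repeats (``use_medians=True``, consistent with the median-based
    summary) or individual repeats with participant x repeat blocks.
    Post-hoc pairs run only when Friedman rejects, unless
    ``gate_on_friedman=False``.
    """
    conditions = list(dict.fromkeys(table.condition))
    regions = [r for r in ALL_LABELS if r in set(table.region)]
    rows = []
    for region in regions:
        sub = table[table.region == region]
        if use_medians:
            piv = (sub.groupby(["participant", "condition"], sort=False)[value_col]
                   .median().unstack("condition").reindex(columns=conditions))
        else:
            piv = sub.pivot_table(index=["participant", "repeat"],
                                  columns="condition", values=value_col
                                  ).reindex(columns=conditions)
        X = piv.values
        try:
            fr = friedman_test(X)
        except ValueError:
            continue
        row = {"region": region, "friedman_stat": fr.statistic,
               "friedman_p": fr.pvalue, "n_blocks": fr.n_blocks,
               "n_dropped": fr.n_dropped}
        if (not gate_on_friedman) or fr.pvalue < alpha:
            ph = posthoc_pairs(X, labels=conditions, alpha=alpha)
            for _, r in ph.iterrows():
                key = f"{r.condition_a}_vs_{r.condition_b}"
                row[f"p_adj[{key}]"] = r.p_adjusted
                row[f"sig[{key}]"] = bool(r.significant)
        rows.append(row)
    return pd.DataFrame(rows)
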