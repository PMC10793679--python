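"""Nonparametric group-comparison statistics and FDR control.

Rank-sum (Mann-Whitney/Wilcoxon two-sample), Wilcoxon signed-rank,
Kruskal-Wallis and Benjamini-Hochberg FDR are implemented directly:
small instances are handled by exact enumeration of the permutation
distribution (all rank assignments / sign patterns), larger ones by the
standard normal or chi-square approximations with tie correction.  The
per-taxon differential-abundance test applies the appropriate rank test
to per-sample fractions and corrects the family with BH.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .tables_io import CountTable, CountTableError, aggregate_taxa, to_relative

log = logging.getLogger(__name__)

EXACT_LIMIT = 12  # total observations at or below which tests enumerate exactly


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "chi_square" | "degenerate"


def _rank(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_test(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for two
    independent samples.

    Exact enumeration of all C(n1+n2, n1) rank assignments when the
    pooled size is at most 12, else the normal approximation with tie
    and continuity corrections.  The statistic is the rank sum of the
    first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    n1, n = a.size, a.size + b.size
    ranks = _rank(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    if np.all(pooled == pooled[0]):
        log.warning("rank_sum_test: all values tied; p = 1")
        return TestResult(w_obs, 1.0, "degenerate")
    if n <= EXACT_LIMIT:
        dev = abs(w_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
                hits += 1
        return TestResult(w_obs, hits / total, "exact")
    n2 = n - n1
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    z = (w_obs - mu - math.copysign(0.5, w_obs - mu)) / math.sqrt(var) if w_obs != mu else 0.0
    return TestResult(w_obs, float(min(1.0, 2.0 * norm.sf(abs(z)))), "normal_approx")


def signed_rank_test(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Exact enumeration of all 2^n sign
    patterns when n <= 12, else the normal approximation with tie and
    continuity corrections.  The statistic is W+, the positive rank sum.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        log.warning("signed_rank_test: all differences zero; p = 1")
        return TestResult(0.0, 1.0, "degenerate")
    if d.size < 2:
        raise ValueError("need at least 2 nonzero differences")
    n = d.size
    ranks = _rank(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_LIMIT:
        dev = abs(w_obs - mu)
        hits = 0
        for mask in range(1 << n):
            w = sum(ranks[i] for i in range(n) if mask >> i & 1)
            if abs(w - mu) >= dev - 1e-12:
                hits += 1
        return TestResult(w_obs, hits / (1 << n), "exact")
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    z = (w_obs - mu - math.copysign(0.5, w_obs - mu)) / math.sqrt(var) if w_obs != mu else 0.0
    return TestResult(w_obs, float(min(1.0, 2.0 * norm.sf(abs(z)))), "normal_approx")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        log.warning("kruskal_wallis: all values identical; H = 0, p = 1")
        return TestResult(0.0, 1.0, "degenerate")
    ranks = _rank(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h /= correction
    df = len(groups) - 1
    return TestResult(float(h), float(chi2.sf(h, df)), "chi_square")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def taxon_group_test(
    table: CountTable,
    meta: pd.DataFrame,
    rank: str | None,
    grouping: str,
    min_prevalence: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon differential abundance between metadata groups.

    Aggregates to ``rank`` (None = as-is), converts to per-sample
    fractions, drops taxa below ``min_prevalence`` (fraction of samples
    with any reads), then applies the rank-sum test (two groups) or
    Kruskal-Wallis (more) per taxon, with a BH-corrected q over the
    tested family.  Log2 fold change compares the first two groups' mean
    fractions with a pseudo-fraction of half the smallest nonzero value.
    Samples with a missing grouping value are dropped with a log line.
    """
    agg = aggregate_taxa(table, rank) if rank is not None else table
    samples = [s for s in agg.samples if s in meta.index]
    labels = meta.loc[samples, grouping]
    keep = labels.notna() & (labels.astype(str) != "")
    if (~keep).any():
        log.info("taxon_group_test: dropping %d sample(s) with missing %r", int((~keep).sum()), grouping)
    samples = [s for s, k in zip(samples, keep) if k]
    labels = labels[keep]
    group_names = sorted(labels.unique(), key=str)
    if len(group_names) < 2:
        raise CountTableError(f"grouping {grouping!r} defines fewer than 2 groups")
    members = {g: [s for s in samples if labels[s] == g] for g in group_names}
    empty = [str(g) for g, ss in members.items() if len(ss) < 2]
    if empty:
        raise CountTableError(f"group(s) with fewer than 2 samples: {empty}")

    sub = agg.subset_samples(samples)
    rel = to_relative(sub)
    prevalence = (sub.counts > 0).sum(axis=1) / len(samples)
    tested = [t for t in sub.taxa if prevalence[t] >= min_prevalence]
    if not tested:
        raise CountTableError("no taxa pass the prevalence filter")
    nonzero = rel.to_numpy()[rel.to_numpy() > 0]
    pseudo = nonzero.min() / 2.0 if nonzero.size else 0.5

    rows = []
    for t in tested:
        vecs = [rel.loc[t, members[g]].to_numpy() for g in group_names]
        if len(group_names) == 2:
            res = rank_sum_test(vecs[0], vecs[1])
        else:
            res = kruskal_wallis(vecs)
        means = {f"mean_{g}": float(v.mean()) for g, v in zip(group_names, vecs)}
        lfc = math.log2((vecs[0].mean() + pseudo) / (vecs[1].mean() + pseudo))
        rows.append(
            {"taxon": t, **means, "log2_fold_change": lfc,
             "statistic": res.statistic, "p_value": res.p_value, "method": res.method}
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["p_value"] < 0.05) & (out["q_value"] < 0.05)
    return out.sort_values("q_value", kind="mergesort").reset_index(drop=True)
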