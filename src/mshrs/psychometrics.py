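"""Psychometric validation of the costing model.

Implements the validation battery for a resource-use costing instrument:

* test-retest reliability of total quarterly cost in a *stable* subgroup,
  via the one-way random-effects intraclass correlation ICC(1,1);
* internal-consistency lower bounds (Guttman lambda-2 / lambda-6) over the
  standardized monetised cost components, excluding DMT cost;
* known-group validity: costs across predefined EDSS severity bins, with a
  Kruskal-Wallis omnibus test and Bonferroni-adjusted pairwise
  Mann-Whitney U tests;
* convergent / discriminant validity: Spearman correlations between total
  cost and PRO summary scores;
* completer vs non-completer contrasts to check for selection bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: EDSS severity bins used for known-group analysis (inclusive ranges).
DEFAULT_EDSS_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 1.0),
    (1.5, 2.5),
    (3.0, 4.0),
    (4.5, 5.5),
)

ICC_BAND_CUTOFFS = (0.5, 0.75, 0.9)  # poor / moderate / good / excellent


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


def icc_band(icc: float) -> str:
    """Interpretation band for an ICC estimate (cutoffs 0.5 / 0.75 / 0.9)."""
    if icc < ICC_BAND_CUTOFFS[0]:
        return "poor"
    if icc < ICC_BAND_CUTOFFS[1]:
        return "moderate"
    if icc < ICC_BAND_CUTOFFS[2]:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ReliabilityReport:
    n_stable: int
    icc: float
    icc_band: str
    lambda2: float | None = None
    lambda6: float | None = None


@dataclass(frozen=True)
class RetestRecord:
    """Paired-wave observation with the history needed to judge stability.

    ``edss_pre`` is the EDSS three months before the baseline assessment;
    relapse counts cover the pre-baseline window and the retest window.
    """

    respondent_id: str
    total_cost_w1: float
    total_cost_w2: float
    edss_pre: float | None = None
    edss_w1: float | None = None
    edss_w2: float | None = None
    relapses_pre_window: int | None = None
    relapses_retest_window: int | None = None


def filter_stable(records: Iterable[RetestRecord]) -> list[RetestRecord]:
    """Retain clinically stable respondents for the retest analysis.

    Stable means no relapse in either three-month window and no EDSS
    increase across pre-window -> baseline -> retest.  Records with missing
    history are excluded with a logged reason, never an error.
    """
    stable: list[RetestRecord] = []
    for rec in records:
        history = (
            rec.edss_pre,
            rec.edss_w1,
            rec.edss_w2,
            rec.relapses_pre_window,
            rec.relapses_retest_window,
        )
        if any(v is None for v in history):
            logger.info("excluding %s: incomplete stability history", rec.respondent_id)
            continue
        if rec.relapses_pre_window > 0 or rec.relapses_retest_window > 0:
            continue
        if rec.edss_w2 > rec.edss_w1 or rec.edss_w1 > rec.edss_pre:
            continue
        stable.append(rec)
    return stable


def icc_oneway_random(pairs: Sequence[tuple[float, float]]) -> float:
    """ICC(1,1): one-way random-effects intraclass correlation, k = 2.

    Computed from the one-way ANOVA variance components as
    (MS_between - MS_within) / (MS_between + (k-1) MS_within).
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of per-subject measurements")
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    grand = data.mean()
    subject_means = data.mean(axis=1)
    ss_between = k * np.sum((subject_means - grand) ** 2)
    ss_within = np.sum((data - subject_means[:, None]) ** 2)
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    denom = ms_between + (k - 1) * ms_within
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: no variance in the measurements")
    return float(min(1.0, (ms_between - ms_within) / denom))


def _item_covariance(item_matrix: np.ndarray, standardize: bool) -> np.ndarray:
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item matrix must be respondents x items with >= 2 items")
    if x.shape[0] < 3:
        raise ValueError("item matrix needs at least 3 respondents")
    sds = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise UndefinedStatisticError(
            f"zero-variance item(s) at column(s) {zero.tolist()}"
        )
    if standardize:
        x = (x - x.mean(axis=0)) / sds
    return np.cov(x, rowvar=False, ddof=1)


def guttman_lambda2(item_matrix: np.ndarray, standardize: bool = True) -> float:
    """Guttman's lambda-2 reliability lower bound.

    lambda2 = [sum_{i!=j} c_ij + sqrt(k/(k-1) * sum_{i!=j} c_ij^2)] / V_total
    with c_ij the item covariances and V_total the variance of the sum
    score.  Items are standardized first by default (the instrument's
    monetised components have wildly different scales).
    """
    cov = _item_covariance(item_matrix, standardize)
    k = cov.shape[0]
    off = cov - np.diag(np.diag(cov))
    c_sum = off.sum()
    c2_sum = (off**2).sum()
    v_total = cov.sum()
    if v_total <= 0:
        raise UndefinedStatisticError("total variance of the sum score is not positive")
    return float((c_sum + np.sqrt(k / (k - 1) * c2_sum)) / v_total)


def guttman_lambda6(item_matrix: np.ndarray, standardize: bool = True) -> float:
    """Guttman's lambda-6: 1 - sum of item error variances / V_total.

    The error variance of item i is its residual variance when regressed
    on all other items, obtained from the inverse covariance matrix as
    1 / (C^-1)_ii (equivalently (1 - R^2_i) * Var_i).
    """
    cov = _item_covariance(item_matrix, standardize)
    try:
        precision = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise UndefinedStatisticError("singular item covariance matrix") from exc
    error_vars = 1.0 / np.diag(precision)
    v_total = cov.sum()
    if v_total <= 0:
        raise UndefinedStatisticError("total variance of the sum score is not positive")
    return float(1.0 - error_vars.sum() / v_total)


def reliability_report(
    retest_records: Iterable[RetestRecord],
    item_matrix: np.ndarray | None = None,
) -> ReliabilityReport:
    """Full reliability analysis: stability filter, ICC(1,1), lambdas."""
    stable = filter_stable(retest_records)
    if len(stable) < 3:
        raise UndefinedStatisticError(
            f"only {len(stable)} stable respondents; reliability undefined"
        )
    pairs = [(r.total_cost_w1, r.total_cost_w2) for r in stable]
    icc = icc_oneway_random(pairs)
    lam2 = guttman_lambda2(item_matrix) if item_matrix is not None else None
    lam6 = guttman_lambda6(item_matrix) if item_matrix is not None else None
    return ReliabilityReport(
        n_stable=len(stable), icc=icc, icc_band=icc_band(icc), lambda2=lam2, lambda6=lam6
    )


# ---------------------------------------------------------------------------
# known-group validity


@dataclass(frozen=True)
class KnownGroupReport:
    bins: tuple[tuple[float, float], ...]
    group_summaries: pd.DataFrame  # one row per bin: n, mean, sd, median
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # bin_a, bin_b, u, p_raw, p_bonferroni
    n_excluded: int = 0


def assign_edss_bin(
    edss: float, bins: Sequence[tuple[float, float]] = DEFAULT_EDSS_BINS
) -> int | None:
    """Index of the severity bin containing ``edss``; None if outside all."""
    for i, (lo, hi) in enumerate(bins):
        if lo <= edss <= hi:
            return i
    return None


def _assignments(indices: Sequence[int], sizes: Sequence[int]):
    """All distinct splits of ``indices`` into ordered groups of ``sizes``."""
    from itertools import combinations as _comb

    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for head in _comb(indices, sizes[0]):
        rest = [i for i in indices if i not in set(head)]
        for tail in _assignments(rest, sizes[1:]):
            yield (head,) + tail


def _kruskal_h(groups: Sequence[np.ndarray]) -> float:
    """Kruskal-Wallis H with midrank tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else np.nan


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)


def exact_kruskal_p(groups: Sequence[np.ndarray]) -> float:
    """Exact permutation p for the Kruskal-Wallis H (tiny samples only)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = _kruskal_h(groups)
    hits = total = 0
    for split in _assignments(range(len(pooled)), sizes):
        perm = [pooled[list(idx)] for idx in split]
        if _kruskal_h(perm) >= h_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def exact_mannwhitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided permutation p for the Mann-Whitney U statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = _mw_u(a, b)
    extreme_obs = min(u_obs, n1 * len(b) - u_obs)
    hits = total = 0
    for split in _assignments(range(len(pooled)), [n1, len(b)]):
        pa = pooled[list(split[0])]
        pb = pooled[list(split[1])]
        u = _mw_u(pa, pb)
        if min(u, n1 * len(pb) - u) <= extreme_obs + 1e-12:
            hits += 1
        total += 1
    return hits / total


def known_group_analysis(
    costs: Sequence[float],
    edss: Sequence[float],
    bins: Sequence[tuple[float, float]] = DEFAULT_EDSS_BINS,
    exact: bool = False,
) -> KnownGroupReport:
    """Cost contrasts across EDSS severity bins.

    Kruskal-Wallis across all bins, then all pairwise Mann-Whitney U tests
    with Bonferroni adjustment over the pairwise family.  Records whose
    EDSS falls between or outside the bins are excluded and counted.
    With ``exact=True`` p-values come from exhaustive permutation
    enumeration (feasible only for very small samples); the default uses
    the standard midrank/tie-corrected large-sample tests.
    """
    costs = np.asarray(costs, dtype=float)
    edss = np.asarray(edss, dtype=float)
    if costs.shape != edss.shape:
        raise ValueError("costs and EDSS must be aligned")
    groups: list[np.ndarray] = []
    n_excluded = 0
    assignments = [assign_edss_bin(e, bins) for e in edss]
    for i in range(len(bins)):
        members = costs[[a == i for a in assignments]]
        groups.append(members)
    n_excluded = sum(1 for a in assignments if a is None)
    empty = [i for i, g in enumerate(groups) if len(g) == 0]
    if empty:
        labels = [f"{bins[i][0]}-{bins[i][1]}" for i in empty]
        raise ValueError(f"empty EDSS bin(s): {', '.join(labels)}")

    summaries = pd.DataFrame(
        {
            "bin_low": [b[0] for b in bins],
            "bin_high": [b[1] for b in bins],
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "sd": [float(np.std(g, ddof=1)) if len(g) > 1 else np.nan for g in groups],
            "median": [float(np.median(g)) for g in groups],
        }
    )

    if exact:
        h = _kruskal_h(groups)
        p = exact_kruskal_p(groups)
    else:
        h, p = stats.kruskal(*groups)
    n_pairs = len(list(combinations(range(len(bins)), 2)))
    rows = []
    for i, j in combinations(range(len(bins)), 2):
        if exact:
            u = _mw_u(groups[i], groups[j])
            p_raw = exact_mannwhitney_p(groups[i], groups[j])
        else:
            u, p_raw = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        rows.append(
            {
                "bin_a": i,
                "bin_b": j,
                "u": float(u),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * n_pairs)),
            }
        )
    return KnownGroupReport(
        bins=tuple(tuple(b) for b in bins),
        group_summaries=summaries,
        kruskal_h=float(h),
        kruskal_p=float(p),
        pairwise=pd.DataFrame(rows),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# convergent / discriminant validity


def convergent_discriminant(
    costs: Sequence[float],
    pro_scores: Mapping[str, Sequence[float]],
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman rank correlation of total cost with each PRO instrument.

    Pairwise-complete: for each instrument only respondents with both a
    cost and a score enter.  Convergent instruments are expected to exceed
    |r| = 0.40, discriminant ones to stay clearly below 0.3.
    """
    costs = np.asarray(costs, dtype=float)
    rows = []
    for name, scores in pro_scores.items():
        scores = np.asarray(scores, dtype=float)
        if scores.shape != costs.shape:
            raise ValueError(f"scores for {name} not aligned with costs")
        mask = ~(np.isnan(costs) | np.isnan(scores))
        x, y = costs[mask], scores[mask]
        if len(x) < min_pairs:
            raise ValueError(f"instrument {name}: only {len(x)} complete pairs")
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise UndefinedStatisticError(
                f"instrument {name}: constant vector, correlation undefined"
            )
        r, p = stats.spearmanr(x, y)
        rows.append({"instrument": name, "n": int(len(x)), "spearman_r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# completer comparison


def completer_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Contrast completers vs non-completers on demographics.

    Continuous variables (age, EDSS, disease duration) use Mann-Whitney U;
    sex uses a chi-square contingency test.  Expects columns
    ``completed_survey``, ``age``, ``sex``, ``edss``,
    ``disease_duration_years``.
    """
    comp = records[records["completed_survey"].astype(bool)]
    nonc = records[~records["completed_survey"].astype(bool)]
    if len(comp) == 0 or len(nonc) == 0:
        raise ValueError("both completer and non-completer groups must be nonempty")
    rows = []
    for var in ("age", "edss", "disease_duration_years"):
        a = pd.to_numeric(comp[var], errors="coerce").dropna()
        b = pd.to_numeric(nonc[var], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"variable": var, "test": "mann-whitney", "p": np.nan,
                 "completers_mean": a.mean(), "noncompleters_mean": b.mean(),
                 "degenerate": True}
            )
            continue
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"variable": var, "test": "mann-whitney", "p": float(p),
             "completers_mean": float(a.mean()), "noncompleters_mean": float(b.mean()),
             "degenerate": False}
        )
    table = pd.crosstab(records["completed_survey"].astype(bool), records["sex"])
    if table.shape[1] >= 2 and (table.values > 0).all():
        _, p, _, _ = stats.chi2_contingency(table)
        degenerate = False
    else:
        p, degenerate = np.nan, True
    rows.append(
        {"variable": "sex", "test": "chi-square", "p": float(p) if p == p else np.nan,
         "completers_mean": np.nan, "noncompleters_mean": np.nan, "degenerate": degenerate}
    )
    return pd.DataFrame(rows)
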