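"""Evaluation of predicted model quality scores.

Covers the three layers on which quality predictors are judged:

* regression accuracy — RMSE, mean absolute error ("ABS") and Pearson
  correlation between predicted and real GDT-TS;
* model selection — per target, pick the model with the highest predicted
  score (top-1) and sum the *real* GDT-TS of the picks;
* method comparison — paired two-sided t-test and exact Wilcoxon
  signed-rank test on per-target score pairs.

Two-sided tests are the conservative default.  The Wilcoxon test drops
zero differences (Wilcoxon's original procedure), uses midranks for tied
absolute differences, and computes the exact two-sided p-value from the
permutation distribution of the positive-rank sum for up to 25 non-zero
pairs, switching to a normal approximation with continuity and tie
correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "RankingResult",
    "PairedTestResult",
    "regression_metrics",
    "rank_models",
    "paired_t_test",
    "wilcoxon_signed_rank",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class EvalReport:
    rmse: float
    abs_err: float
    pearson: float | None  # None when either vector is constant
    n: int


@dataclass(frozen=True)
class RankingResult:
    """Top-1 selection per target and the total real score of the picks."""

    per_target: tuple[tuple[str, str, float, float], ...]  # (target, record, pred, real)
    total_real: float


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    method: str  # "t" | "wilcoxon"


def regression_metrics(predicted, real) -> EvalReport:
    """RMSE, mean absolute error and Pearson correlation of predictions."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(real, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    err = p - r
    rmse = float(np.sqrt(np.mean(err**2)))
    abs_err = float(np.mean(np.abs(err)))
    if p.size < 2 or np.ptp(p) == 0 or np.ptp(r) == 0:
        pearson = None
    else:
        pearson = float(stats.pearsonr(p, r).statistic)
    return EvalReport(rmse=rmse, abs_err=abs_err, pearson=pearson, n=int(p.size))


def rank_models(
    predictions: list[tuple[str, str, float]],
    reals: dict[str, float],
) -> RankingResult:
    """Select the top-1 model per target by predicted score.

    ``predictions`` holds ``(target_id, record_id, predicted)``; ``reals``
    maps record_id to the real GDT-TS.  Predicted-score ties are broken by
    the lexicographically smallest record_id so runs are reproducible.
    """
    by_target: dict[str, tuple[str, float]] = {}
    for target_id, record_id, pred in predictions:
        cur = by_target.get(target_id)
        if cur is None or (-pred, record_id) < (-cur[1], cur[0]):
            by_target[target_id] = (record_id, pred)
    rows = []
    for target_id in sorted(by_target):
        record_id, pred = by_target[target_id]
        if record_id not in reals:
            raise KeyError(f"no real score for selected record {record_id!r}")
        rows.append((target_id, record_id, float(pred), float(reals[record_id])))
    return RankingResult(
        per_target=tuple(rows),
        total_real=float(sum(row[3] for row in rows)),
    )


def _paired_diffs(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    return a - b


def paired_t_test(a, b) -> PairedTestResult:
    """Paired two-sided t-test on per-target score pairs."""
    d = _paired_diffs(a, b)
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("degenerate: zero variance of differences")
    n = d.size
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(statistic=t, p_value=p, n_pairs=n, method="t")


def _exact_positive_rank_sum_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p for the positive-rank sum via its full null distribution.

    Each of the 2^m equiprobable sign assignments contributes its ranks to
    the positive sum; the distribution is built by dynamic programming
    over doubled ranks (midranks are multiples of 1/2, so doubling makes
    them integers), which is equivalent to full enumeration.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_obs))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2 * min(lower, upper)))


def wilcoxon_signed_rank(a, b) -> PairedTestResult:
    """Paired two-sided Wilcoxon signed-rank test; exact for m <= 25 non-zero pairs."""
    d = _paired_diffs(a, b)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    m = d.size
    if m <= EXACT_WILCOXON_MAX_N:
        p = _exact_positive_rank_sum_p(ranks, w)
    else:
        mean = m * (m + 1) / 4
        # variance with midrank tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
        z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return PairedTestResult(statistic=w, p_value=p, n_pairs=m, method="wilcoxon")
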