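"""Confirmatory analyses for trait-connectivity relationships.

* split-half verification: the sample is randomly split into two halves and a
  relationship is confirmed iff the Pearson correlation in both halves shares
  the full-sample sign;
* permutation test: the score vector is shuffled against the fixed connection
  strengths (default 5000 pairings); the p-value is the empirical tail
  fraction of null correlations at least as extreme as the observed one, in
  the pre-specified direction of the primary-analysis effect, floored at
  1/(n_perm + 1) so it is never exactly zero (an observed r ranked at the
  97.5th percentile of its null therefore yields p = 1 - 0.975 = 0.025);
* Kendall's W concordance between statistic maps or rank vectors, with
  mid-rank tie handling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["split_half_verify", "permutation_test", "percentile_pvalue",
           "kendalls_w", "PermutationResult", "SplitHalfResult"]


@dataclass
class SplitHalfResult:
    r_full: float
    r_half1: float
    r_half2: float
    confirmed: bool


@dataclass
class PermutationResult:
    observed_r: float
    null_r: np.ndarray
    p_value: float
    rng_seed: int
    direction: str


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom < 1e-300:
        return np.nan
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def split_half_verify(strengths: np.ndarray, scores: np.ndarray,
                      rng_seed: int) -> SplitHalfResult:
    """Random equal split (odd n: sizes differ by one); confirmed iff both
    halves' correlations share the full-sample sign."""
    strengths = np.asarray(strengths, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = len(strengths)
    if len(scores) != n:
        raise ValueError("strengths and scores must have equal length")
    if n < 8:
        raise ValueError(f"split-half verification needs n >= 8, got {n}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    half1, half2 = perm[: n // 2], perm[n // 2:]
    r_full = _pearson(strengths, scores)
    r1 = _pearson(strengths[half1], scores[half1])
    r2 = _pearson(strengths[half2], scores[half2])
    if np.isnan(r1) or np.isnan(r2) or np.isnan(r_full):
        logger.warning("zero-variance half in split-half verification; not confirmed")
        confirmed = False
    else:
        confirmed = bool(np.sign(r1) == np.sign(r_full) and np.sign(r2) == np.sign(r_full))
    return SplitHalfResult(r_full=r_full, r_half1=r1, r_half2=r2, confirmed=confirmed)


def percentile_pvalue(observed: float, null_values: np.ndarray,
                      direction: str = "positive") -> float:
    """One-sided empirical-tail p-value with a 1/(n+1) floor.

    ``positive``: fraction of null values >= observed; ``negative``: fraction
    <= observed.  The floor keeps p > 0 when the observed value exceeds every
    null value.
    """
    null_values = np.asarray(null_values, dtype=float)
    n = len(null_values)
    if direction == "positive":
        count = int((null_values >= observed).sum())
    elif direction == "negative":
        count = int((null_values <= observed).sum())
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    return max(count / n, 1.0 / (n + 1))


def permutation_test(strengths: np.ndarray, scores: np.ndarray,
                     n_perm: int = 5000, rng_seed: int = 0,
                     direction: str = "auto") -> PermutationResult:
    """Permutation null for the strength/score Pearson correlation.

    ``direction`` should be the a priori sign of the primary-analysis effect
    ('positive'/'negative'); 'auto' uses the sign of the observed r (a
    convenience for exploratory use — under the null it halves the effective
    test direction and p is no longer uniform on (0, 1)).
    """
    strengths = np.asarray(strengths, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = len(strengths)
    if len(scores) != n:
        raise ValueError("strengths and scores must have equal length")
    if n < 5:
        raise ValueError(f"permutation test needs n >= 5, got {n}")
    if scores.std() == 0:
        raise ValueError("constant scores: correlation undefined")
    if n_perm < 100:
        logger.warning("n_perm = %d is very small; p-value resolution is coarse", n_perm)

    observed = _pearson(strengths, scores)
    rng = np.random.default_rng(rng_seed)
    # vectorized: all permutations of the score vector at once
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    S = scores[perms]
    Sc = S - S.mean(axis=1, keepdims=True)
    xc = strengths - strengths.mean()
    with np.errstate(invalid="ignore"):
        null = (Sc @ xc) / (np.linalg.norm(Sc, axis=1) * np.linalg.norm(xc))
    null = np.clip(np.nan_to_num(null), -1.0, 1.0)
    if direction == "auto":
        direction = "positive" if observed >= 0 else "negative"
    p = percentile_pvalue(observed, null, direction)
    return PermutationResult(observed_r=observed, null_r=null, p_value=p,
                             rng_seed=rng_seed, direction=direction)


def kendalls_w(judgments: np.ndarray) -> float:
    """Kendall's coefficient of concordance among m judges ranking n items.

    ``judgments`` is (m, n): raw values per judge are converted to mid-ranks,
    and the standard tie correction is applied:

        W = 12 S / (m^2 (n^3 - n) - m T),   T = sum_j sum_ties (t^3 - t).
    """
    J = np.asarray(judgments, dtype=float)
    if J.ndim != 2:
        raise ValueError("judgments must be a 2D (judges x items) array")
    m, n = J.shape
    if m < 2 or n < 2:
        raise ValueError(f"need at least 2 judges and 2 items, got {J.shape}")
    ranks = np.vstack([stats.rankdata(row) for row in J])
    T = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        T += float((counts ** 3 - counts).sum())
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - m * (n + 1) / 2.0) ** 2).sum())
    denom = m ** 2 * (n ** 3 - n) - m * T
    if denom <= 0:
        raise ValueError("degenerate rankings (all judges constant); W undefined")
    return 12.0 * S / denom
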