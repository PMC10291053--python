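"""Genre comparisons, feature-rating correlations with per-channel FDR
correction, and the within-subject median split of film ratings.

Conventions: Cohen's d for the paired design is the mean difference divided by
the SD of the differences (equivalently t / sqrt(n)); trialwise correlations
pool all subject x film observations; Benjamini-Hochberg adjustment is applied
within each channel's family of correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedComparison:
    t: float
    df: int
    p: float
    d: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


@dataclass
class CorrelationResult:
    feature: str
    r: float
    n: int
    p: float
    q: float | None = None
    channel: str | None = None


def paired_test(a, b) -> PairedComparison:
    """Paired t-test with Cohen's d = mean(diff) / SD(diff) (sample SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedComparison(
        t=float(t), df=n - 1, p=float(p), d=float(diff.mean() / sd),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
    )


def correlate(x, y, feature: str = "", channel: str | None = None) -> CorrelationResult:
    """Pearson correlation with the exact t-based two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(feature=feature, r=float(r), n=len(x), p=float(p), channel=channel)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_per_channel(results: list[CorrelationResult]) -> list[CorrelationResult]:
    """Apply BH within each channel's family (channel None = its own family)."""
    groups: dict = {}
    for i, res in enumerate(results):
        groups.setdefault(res.channel, []).append(i)
    for idxs in groups.values():
        q = bh_adjust([results[i].p for i in idxs])
        for i, qi in zip(idxs, q):
            results[i].q = float(qi)
    return results


def median_split(ratings, seed: int = 0) -> np.ndarray:
    """Label one subject's films 'low'/'high' by the within-subject rating
    ranking; boundary ties are broken by a seeded random draw."""
    ratings = np.asarray(ratings, dtype=float)
    n = len(ratings)
    if n < 2:
        raise ValueError("need at least 2 films")
    rng = np.random.default_rng(seed)
    if np.all(ratings == ratings[0]):
        warnings.warn("all ratings identical; low/high labels assigned by seeded draw")
    jitter = rng.uniform(-1e-9, 1e-9, size=n)
    order = np.argsort(ratings + jitter, kind="stable")
    labels = np.empty(n, dtype=object)
    half = n // 2
    labels[order[:half]] = "low"
    labels[order[half:]] = "high"
    return labels.astype(str)


def genre_comparison(matrix: pd.DataFrame, feature: str) -> PairedComparison:
    """Paired comedy-vs-drama test on per-subject genre means of a feature."""
    agg = matrix.groupby(["subject_id", "genre"])[feature].mean().unstack("genre")
    return paired_test(agg["comedy"].to_numpy(), agg["drama"].to_numpy())


def correlation_analysis(
    matrix: pd.DataFrame,
    feature_channels: dict,
    rating_col: str = "rating",
) -> pd.DataFrame:
    """Correlate each feature with ratings; BH per channel.

    ``feature_channels`` maps feature column -> channel label (or None for
    scalar/peripheral features, each adjusted as its own family).
    """
    results = []
    y = matrix[rating_col].to_numpy(dtype=float)
    for feat, ch in feature_channels.items():
        x = matrix[feat].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4 or x[ok].std() == 0:
            continue
        results.append(correlate(x[ok], y[ok], feature=feat, channel=ch))
    adjust_per_channel(results)
    return pd.DataFrame(
        [
            {"feature": r.feature, "channel": r.channel, "r": r.r, "n": r.n,
             "p": r.p, "q": r.q}
            for r in results
        ]
    )
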