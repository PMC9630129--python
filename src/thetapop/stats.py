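"""Estimation statistics: permutation tests, bootstrap effect sizes,
the Watson–Wheeler circular test, and the novelty-preference index.

All tests are two-sided.  Permutation tests enumerate the full arrangement
set when it is small (≤ 2¹⁵ arrangements) and otherwise fall back to
Monte-Carlo with an add-one correction, p = (b + 1)/(m + 1), so p is never
exactly zero.  Effect sizes are reported as mean/median (or paired-mean)
differences with percentile 95% confidence intervals from bootstrap
resampling (default 5,000 resamples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2

from .core import ValidationError

__all__ = [
    "EffectSize",
    "permutation_test",
    "bootstrap_effect",
    "watson_wheeler",
    "novelty_preference",
    "benjamini_hochberg",
]

EXACT_LIMIT = 2**15
N_BOOT = 5000


def _stat_fn(statistic: str):
    if statistic == "mean_diff":
        return lambda a, b: np.mean(a) - np.mean(b)
    if statistic == "median_diff":
        return lambda a, b: np.median(a) - np.median(b)
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(a, b, paired: bool = False, statistic: str = "mean_diff",
                     n_perm: int = 10000, rng: np.random.Generator | None = None) -> float:
    """Two-sided permutation p-value for the difference between two samples.

    Paired mode flips the signs of per-pair differences; unpaired mode
    reassigns group labels.  Exact enumeration is used when the number of
    arrangements is at most 2¹⁵, otherwise Monte-Carlo with the add-one
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("permutation test needs at least 2 observations per sample")
    if rng is None:
        rng = np.random.default_rng(0)
    tol = 1e-12

    if paired:
        if a.size != b.size:
            raise ValidationError("paired samples must have equal length")
        d = a - b
        obs = abs(float(np.mean(d)) if statistic == "mean_diff" else float(np.median(d)))
        red = np.median if statistic == "median_diff" else np.mean
        n = d.size
        if 2**n <= EXACT_LIMIT:
            signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n), indexing="ij")).reshape(n, -1).T
            stats = np.abs(red(signs * d, axis=1))
            return float(np.mean(stats >= obs - tol))
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
        stats = np.abs(red(signs * d, axis=1))
        return float((np.sum(stats >= obs - tol) + 1) / (n_perm + 1))

    fn = _stat_fn(statistic)
    obs = abs(float(fn(a, b)))
    pooled = np.r_[a, b]
    n_a, n_tot = a.size, a.size + b.size
    if math.comb(n_tot, n_a) <= EXACT_LIMIT:
        count = 0
        total = 0
        idx_all = np.arange(n_tot)
        for idx in combinations(range(n_tot), n_a):
            idx = np.asarray(idx)
            mask = np.zeros(n_tot, dtype=bool)
            mask[idx] = True
            stat = abs(float(fn(pooled[mask], pooled[~mask])))
            count += stat >= obs - tol
            total += 1
        return count / total
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(float(fn(perm[:n_a], perm[n_a:])))
        count += stat >= obs - tol
    return float((count + 1) / (n_perm + 1))


@dataclass
class EffectSize:
    """Point difference with a percentile bootstrap 95% CI."""

    point: float
    ci_low: float
    ci_high: float
    n_resamples: int
    kind: str


def bootstrap_effect(a, b, kind: str = "mean_diff", n: int = N_BOOT,
                     ci: float = 0.95, rng: np.random.Generator | None = None) -> EffectSize:
    """Bootstrap-coupled estimation of a two-sample (or paired) difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("bootstrap requires non-empty samples")
    if rng is None:
        rng = np.random.default_rng(0)
    alpha = (1.0 - ci) / 2.0

    if kind == "paired_mean_diff":
        if a.size != b.size:
            raise ValidationError("paired samples must have equal length")
        d = a - b
        point = float(np.mean(d))
        idx = rng.integers(0, d.size, size=(n, d.size))
        boots = np.mean(d[idx], axis=1)
    elif kind in ("mean_diff", "median_diff"):
        fn = _stat_fn(kind)
        point = float(fn(a, b))
        ia = rng.integers(0, a.size, size=(n, a.size))
        ib = rng.integers(0, b.size, size=(n, b.size))
        red = np.median if kind == "median_diff" else np.mean
        boots = red(a[ia], axis=1) - red(b[ib], axis=1)
    else:
        raise ValueError(f"unknown effect kind {kind!r}")
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    if not (lo <= point <= hi):
        warnings.warn("bootstrap CI does not bracket the point estimate (resampling pathology)")
    return EffectSize(point=point, ci_low=float(lo), ci_high=float(hi), n_resamples=n, kind=kind)


def watson_wheeler(groups, deg: bool = True):
    """Watson–Wheeler (uniform-scores) test for homogeneity of circular samples.

    Pooled observations are ranked around the circle and mapped to uniform
    scores β_r = 2πr/N; with per-group resultants (C_g, S_g),

        W = 2 Σ_g (C_g² + S_g²) / n_g

    is referred to a χ² distribution with 2(k−1) degrees of freedom.
    Groups of fewer than 10 observations trigger a small-sample warning;
    ties are broken by stable ordering (with a warning).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValidationError("Watson–Wheeler needs at least 2 groups")
    sizes = [g.size for g in arrays]
    if min(sizes) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if min(sizes) < 10:
        warnings.warn("Watson–Wheeler chi-squared approximation is poor for n < 10")
    if deg:
        arrays = [np.radians(g) for g in arrays]
    pooled = np.concatenate(arrays)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(arrays)])
    wrapped = np.mod(pooled, 2 * np.pi)
    if np.unique(wrapped).size < wrapped.size:
        warnings.warn("ties in circular data broken by stable ordering")
    order = np.argsort(wrapped, kind="stable")
    n_tot = pooled.size
    beta = 2.0 * np.pi * (np.arange(1, n_tot + 1)) / n_tot
    w = 0.0
    for i, n_g in enumerate(sizes):
        sel = labels[order] == i
        c = float(np.sum(np.cos(beta[sel])))
        s = float(np.sum(np.sin(beta[sel])))
        w += (c * c + s * s) / n_g
    w *= 2.0
    p = float(chi2.sf(w, df=2 * (k - 1)))
    return w, p


def novelty_preference(exploration_times: dict, novel_id) -> float:
    """Percentage of object-exploration time spent on the novel object.

    Chance level is 100/n_objects (25% with four objects).
    """
    if len(exploration_times) < 2:
        raise ValidationError("novelty preference needs at least 2 objects")
    if novel_id not in exploration_times:
        raise ValidationError(f"novel object {novel_id!r} not in exploration table")
    total = float(sum(exploration_times.values()))
    if total <= 0:
        raise ValidationError("zero total exploration time")
    return 100.0 * float(exploration_times[novel_id]) / total


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """Benjamini–Hochberg adjusted p-values (helper; off by default in the
    pipeline, which reports per-comparison tests)."""
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                        alpha=alpha, method="fdr_bh")
    return reject, p_adj
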