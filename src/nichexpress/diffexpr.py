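"""Empirical-Bayes moderated t-tests with FDR adjustment.

The per-gene residual variance s2 is shrunk toward a prior variance s0_2
estimated by moment matching on log s2 (digamma/trigamma matching of the
scaled-F model), the classical moderated-t formulation:

    s_tilde2 = (d0 * s0_2 + df * s2) / (d0 + df)
    t_mod    = effect / sqrt(s_tilde2 / n_eff)

with two-sided p-values from the t distribution on d0 + df degrees of
freedom (standard normal when the prior degrees of freedom d0 are
infinite).  Two designs are supported: a two-color single-sample design
(replicate M values; n_eff = n) and a two-group comparison of log2
intensities (pooled variance; n_eff = (1/n1 + 1/n2)^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm as normal_dist
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .normalize import MATable
from .synthdata import SingleChannelSet

# Below this bound a residual variance is treated as exactly zero (float
# dust from arithmetically identical replicates).
_DEGENERATE_S2 = 1e-12
# Effects below this bound are treated as null in the all-degenerate
# (zero-noise) limit.
_DEGENERATE_EFFECT = 1e-8


@dataclass
class PriorEstimate:
    """Hyperparameters of the variance prior: prior degrees of freedom d0
    (possibly infinite) and prior variance s0_2.

    ``estimate_prior`` always returns d0 > 0; d0 = 0 is tolerated here so
    the no-moderation limit (ordinary gene-wise t) can be expressed.
    """

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_2 > 0):
            raise ValueError(f"s0_2 must be > 0, got {self.s0_2}")


def genewise_stats_two_color(ma: MATable) -> pd.DataFrame:
    """Gene-wise layer for the two-color single-sample design.

    effect = mean orientation-corrected M, s2 = sample variance of the
    replicate Ms, df = n - 1.  Per-group mean log2 intensities (germarium,
    testis channels) are recorded for the downstream intensity gate.
    """
    n = ma.n_replicates
    if n < 2:
        raise ValueError(f"need >= 2 replicates, got {n}")
    effect = ma.M.mean(axis=1)
    s2 = ma.M.var(axis=1, ddof=1)
    stats = pd.DataFrame(
        {
            "effect": effect,
            "s2": s2,
            "df": n - 1,
            "a_mean": ma.A.mean(axis=1),
            "mean_group1": ma.log2_germarium().mean(axis=1),
            "mean_group2": ma.log2_testis().mean(axis=1),
        }
    )
    stats.attrs["n_eff"] = float(n)
    stats.attrs["groups"] = ("germarium", "testis")
    return stats


def genewise_stats_two_group(
    matrix: pd.DataFrame, group_labels: Sequence[str], positive_group: Optional[str] = None
) -> pd.DataFrame:
    """Gene-wise layer for a two-group design on log2 intensities.

    effect = mean(group1) - mean(group2), s2 = pooled within-group
    variance, df = n1 + n2 - 2.  ``positive_group`` selects group 1 (the
    first label in column order by default).
    """
    labels = pd.Series(list(group_labels), index=matrix.columns)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    if positive_group is not None:
        if positive_group not in groups:
            raise ValueError(f"positive_group {positive_group!r} not in {groups}")
        groups = [positive_group] + [g for g in groups if g != positive_group]
    g1, g2 = groups
    x1 = matrix.loc[:, labels.values == g1]
    x2 = matrix.loc[:, labels.values == g2]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples, got {g1}:{n1}, {g2}:{n2}")
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    s2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    stats = pd.DataFrame(
        {
            "effect": m1 - m2,
            "s2": s2,
            "df": n1 + n2 - 2,
            "a_mean": matrix.mean(axis=1),
            "mean_group1": m1,
            "mean_group2": m2,
        }
    )
    stats.attrs["n_eff"] = 1.0 / (1.0 / n1 + 1.0 / n2)
    stats.attrs["groups"] = (g1, g2)
    return stats


def genewise_stats(
    data: Union[MATable, SingleChannelSet, pd.DataFrame],
    design: Optional[Sequence[str]] = None,
    positive_group: Optional[str] = None,
) -> pd.DataFrame:
    """Dispatch to the two-color or two-group gene-wise layer."""
    if isinstance(data, MATable):
        return genewise_stats_two_color(data)
    if isinstance(data, SingleChannelSet):
        # raw intensity sets are taken to the log2 scale; pre-normalized
        # log2 matrices should be passed as plain DataFrames
        return genewise_stats_two_group(
            np.log2(data.matrix), data.group_labels, positive_group
        )
    if design is None:
        raise ValueError("a group design is required for a plain matrix")
    return genewise_stats_two_group(data, design, positive_group)


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x, with the asymptotic branches of
    # the standard moment-matching estimator.
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_prior(s2: Union[pd.Series, np.ndarray], df: Union[int, float, np.ndarray]) -> PriorEstimate:
    """Moment-matching estimate of the variance prior (d0, s0_2).

    Matches the empirical mean and variance of log s2 against the
    theoretical moments of a scaled F / log chi-square model.  When the
    empirical spread of log s2 does not exceed the sampling minimum
    trigamma(df/2), the variances are consistent with a single common value
    and d0 is reported infinite with s0_2 equal to the mean variance.
    """
    x = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), x.shape).copy()
    ok = np.isfinite(x) & (x > -1e-15) & np.isfinite(df_arr) & (df_arr > 1e-15)
    x = x[ok]
    df_arr = df_arr[ok]
    if (x > 0).sum() < 20:
        raise ValueError(
            "prior estimation needs >= 20 genes with positive residual variance "
            "(degenerate simulation?)"
        )
    x = np.maximum(x, 0.0)
    m = np.median(x)
    if m == 0:
        warnings.warn("more than half of residual variances are exactly zero")
        m = 1.0
    x = np.maximum(x, 1e-5 * m)
    z = np.log(x)
    e = z - digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df_arr / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(x.mean())
    return PriorEstimate(d0=float(d0), s0_2=s0_2)


def moderated_t(
    effect: Union[float, np.ndarray],
    s2: Union[float, np.ndarray],
    df: Union[float, np.ndarray],
    prior: PriorEstimate,
    n_eff: float,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Moderated t statistics and two-sided p-values.

    Returns (t_mod, p, df_total).  d0 = 0 is accepted as the no-moderation
    limit (ordinary gene-wise t); d0 = inf gives the common-variance z-test.
    """
    effect = np.atleast_1d(np.asarray(effect, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    df = float(np.atleast_1d(np.asarray(df, dtype=float))[0])
    if np.isinf(prior.d0):
        s_tilde2 = np.full_like(s2, prior.s0_2)
        df_total = np.inf
    else:
        s_tilde2 = (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    if np.any(s_tilde2 <= 0):
        raise ValueError("nonpositive posterior variance; cannot form t statistic")
    t = effect / np.sqrt(s_tilde2 / n_eff)
    if np.isinf(df_total):
        p = 2.0 * normal_dist.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    return t, p, df_total


def bh_adjust(p: Union[pd.Series, np.ndarray]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _degenerate_results(stats: pd.DataFrame) -> pd.DataFrame:
    # Zero-noise limit: every gene's replicates agree exactly, so any
    # nonzero effect is infinitely significant and any null effect is not.
    effect = stats["effect"].values
    nonnull = np.abs(effect) > _DEGENERATE_EFFECT
    t = np.zeros_like(effect)
    t[nonnull] = np.sign(effect[nonnull]) * np.inf
    p = np.where(nonnull, 0.0, 1.0)
    out = stats.copy()
    out["t_mod"] = t
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    return out


class _ModeratedTTestBase(BaseEstimator):
    """Shared fitting logic; subclasses provide the gene-wise layer."""

    def _finish(self, stats: pd.DataFrame) -> None:
        self.n_eff_ = stats.attrs["n_eff"]
        self.groups_ = stats.attrs["groups"]
        self.df_residual_ = float(stats["df"].iloc[0])
        if np.all(stats["s2"].values <= _DEGENERATE_S2):
            self.prior_d0_ = np.inf
            self.prior_s0_2_ = 0.0
            self.df_total_ = np.inf
            results = _degenerate_results(stats)
        else:
            prior = estimate_prior(stats["s2"], stats["df"])
            t, p, df_total = moderated_t(
                stats["effect"].values,
                stats["s2"].values,
                self.df_residual_,
                prior,
                self.n_eff_,
            )
            self.prior_d0_ = prior.d0
            self.prior_s0_2_ = prior.s0_2
            self.df_total_ = df_total
            results = stats.copy()
            results["t_mod"] = t
            results["p"] = p
            results["p_adj"] = bh_adjust(p)
        results = results.rename(columns={"effect": "M", "a_mean": "A"})
        self.results_ = results[
            ["M", "A", "t_mod", "p", "p_adj", "mean_group1", "mean_group2"]
        ]


class TwoColorModeratedTTest(_ModeratedTTestBase):
    """Moderated one-sample t-test on replicate two-color M values.

    Fitted attributes: ``results_`` (per-gene M, A, t_mod, p, p_adj and
    per-channel mean log2 intensities), ``prior_d0_``, ``prior_s0_2_``,
    ``df_residual_``, ``df_total_``, ``n_eff_``.
    """

    def fit(self, X: MATable, y=None) -> "TwoColorModeratedTTest":
        self._finish(genewise_stats_two_color(X))
        return self


class TwoGroupModeratedTTest(_ModeratedTTestBase):
    """Moderated two-group t-test on log2 intensities.

    Follows the scikit-learn orientation: ``X`` has samples in rows and
    genes in columns, ``y`` holds the per-sample group labels.  A
    ``SingleChannelSet`` (genes x samples) may be passed directly instead.
    """

    def __init__(self, positive_group: Optional[str] = None) -> None:
        self.positive_group = positive_group

    def fit(self, X, y: Optional[Sequence[str]] = None) -> "TwoGroupModeratedTTest":
        if isinstance(X, SingleChannelSet):
            stats = genewise_stats_two_group(
                np.log2(X.matrix), X.group_labels, self.positive_group
            )
        else:
            if y is None:
                raise ValueError("group labels y are required")
            matrix = X.T if isinstance(X, pd.DataFrame) else pd.DataFrame(X).T
            stats = genewise_stats_two_group(matrix, list(y), self.positive_group)
        self._finish(stats)
        return self
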