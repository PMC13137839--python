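"""Nonparametric inference used across the pipeline: cluster-based permutation
tests for time-series group contrasts and the logistic GLM predicting IPIS
occurrence from preceding NAc gamma power."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ClusterTestResult",
    "GlmResult",
    "cluster_permutation",
    "glm_ipis",
    "mean_difference",
]


@dataclass(frozen=True)
class ClusterTestResult:
    clusters: tuple[tuple[int, int, float, float], ...]  # (start idx, end idx excl, mass, p)
    n_perm: int
    alpha: float
    stat_trace: np.ndarray
    threshold: float

    def significant(self, alpha: float | None = None) -> list[tuple[int, int, float, float]]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c[3] < a]


def _t_two_group(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sps.ttest_ind(a, b, axis=0).statistic


def _t_paired(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sps.ttest_rel(a, b, axis=0).statistic


def _clusters(stat: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    above = np.abs(stat) > thr
    out: list[tuple[int, int, float]] = []
    i = 0
    while i < stat.size:
        if above[i]:
            j = i
            while j + 1 < stat.size and above[j + 1] and np.sign(stat[j + 1]) == np.sign(stat[i]):
                j += 1
            out.append((i, j + 1, float(np.sum(np.abs(stat[i : j + 1])))))
            i = j + 1
        else:
            i += 1
    return out


def cluster_permutation(
    group_a: np.ndarray,
    group_b: np.ndarray | Sequence[np.ndarray],
    scheme: str = "two_group",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> ClusterTestResult:
    """Cluster-based permutation test on equal-length traces.

    Schemes: ``two_group`` (independent samples), ``paired`` (matched rows),
    ``one_vs_others`` (``group_b`` is a list of other groups pooled).  The
    pointwise statistic is a t value thresholded at two-sided p < 0.05;
    contiguous same-sign supra-threshold samples form clusters scored by mass
    (summed |t|); cluster p values come from the maximal-cluster-mass
    distribution over label permutations.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    if scheme == "one_vs_others":
        others = [np.atleast_2d(np.asarray(g, float)) for g in group_b]
        b = np.concatenate(others, axis=0)
        scheme = "two_group"
    else:
        b = np.atleast_2d(np.asarray(group_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("traces must have equal length")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 traces per group")
    if n_perm < 1.0 / alpha:
        warnings.warn("fewer permutations than 1/alpha; p values cannot reach alpha")

    rng = np.random.default_rng(seed)
    if scheme == "two_group":
        stat = _t_two_group(a, b)
        df = a.shape[0] + b.shape[0] - 2
        thr = sps.t.ppf(1 - 0.025, df)
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        null_max = np.zeros(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            pa, pb = pooled[perm[:na]], pooled[perm[na:]]
            cl = _clusters(_t_two_group(pa, pb), thr)
            if cl:
                null_max[k] = max(c[2] for c in cl)
    elif scheme == "paired":
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired scheme needs matched rows")
        stat = _t_paired(a, b)
        df = a.shape[0] - 1
        thr = sps.t.ppf(1 - 0.025, df)
        diff = a - b
        null_max = np.zeros(n_perm)
        for k in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=(diff.shape[0], 1))
            d = diff * flips
            t = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(d.shape[0]))
            cl = _clusters(t, thr)
            if cl:
                null_max[k] = max(c[2] for c in cl)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    clusters = []
    for i, j, mass in _clusters(stat, thr):
        p = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
        clusters.append((i, j, mass, float(p)))
    return ClusterTestResult(
        clusters=tuple(clusters),
        n_perm=n_perm,
        alpha=alpha,
        stat_trace=stat,
        threshold=float(thr),
    )


@dataclass(frozen=True)
class GlmResult:
    exp_coefficient: float  # exponentiated logistic slope per 1 SD of gamma power
    ci95: tuple[float, float]
    p: float
    n_events: int
    penalized: bool = False


def glm_ipis(
    ipis_indicator: np.ndarray,
    gamma_power: np.ndarray,
    covariates: np.ndarray | None = None,
) -> GlmResult:
    """Logistic regression of per-window IPIS occurrence on the NAc gamma
    power of the window 50 ms earlier (predictor standardized before the fit).

    An exponentiated coefficient > 1 means preceding gamma raises the odds of
    an IPIS.  On complete separation the fit falls back to an L2-penalized
    likelihood and the result is flagged.
    """
    import statsmodels.api as sm

    y = np.asarray(ipis_indicator, float)
    g = np.asarray(gamma_power, float)
    if y.size != g.size:
        raise ValueError("outcome and predictor must have equal length")
    sd = g.std()
    if sd == 0:
        raise ValueError("constant predictor")
    gz = (g - g.mean()) / sd
    X = gz[:, None] if covariates is None else np.column_stack([gz, covariates])
    X = sm.add_constant(X)
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError, Exception):
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0, maxiter=500)
            penalized = True
    beta = float(fit.params[1])
    if penalized or not np.all(np.isfinite(getattr(fit, "bse", [np.nan]))):
        se = float("nan")
        ci = (float("nan"), float("nan"))
        p = float("nan")
    else:
        se = float(fit.bse[1])
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        p = float(fit.pvalues[1])
    return GlmResult(
        exp_coefficient=float(np.exp(beta)),
        ci95=ci,
        p=p,
        n_events=int(y.sum()),
        penalized=penalized,
    )


def mean_difference(a_mean: float, b_mean: float) -> float:
    """Difference of two reported group means (e.g. sham minus active severity
    score, giving the mean symptom reduction)."""
    return a_mean - b_mean
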