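"""Group-level frequentist and Bayesian statistics.

Paired and one-sample t tests with small-sample-corrected effect sizes
(Hedges' g on difference scores; g1 for one-sample contrasts), the 2x2
within-subject ANOVA expressed through its single-df contrasts (so F = t^2
holds by construction), directional JZS Bayes factors for paired designs
with prior-width robustness sweeps, and Pearson correlations with a
stretched-beta-prior Bayes factor.

Bayes factor conventions: BF01 > 1 favours the null. The paired-design
alternative places a Cauchy(0, prior_scale) prior on the standardized effect
size, truncated to the caller-specified direction; the default scale 0.707
follows common Bayesian t-test software. The correlation alternative uses a
stretched Beta(1/w, 1/w) prior on rho with default width w = 1 (uniform).
Both marginals are computed by adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, hyp2f1

__all__ = [
    "TestResult",
    "BayesFactorResult",
    "DegenerateVarianceError",
    "paired_contrast",
    "one_sample_test",
    "rm_anova_2x2",
    "jzs_bf01_directional",
    "bf_robustness",
    "pearson_with_bf",
    "bonferroni",
]

DEFAULT_PRIOR_SCALE = 0.707
SUBSTANTIAL_BF = 3.0


class DegenerateVarianceError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    effect_size: float
    effect_label: str


@dataclass(frozen=True)
class BayesFactorResult:
    bf01: float
    prior_scale: float
    robustness_curve: list | None = None
    min_scale_substantial: float | None = None


def hedges_correction(n: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4(n-1) - 1)."""
    return 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)


def one_sample_test(x, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t test with Hedges-corrected effect size g1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("zero variance: t statistic undefined")
    t = (x.mean() - mu0) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    g1 = (x.mean() - mu0) / sd * hedges_correction(n)
    return TestResult(statistic=float(t), df=n - 1, p_value=float(p),
                      effect_size=float(g1), effect_label="hedges_g1")


def paired_contrast(a, b) -> TestResult:
    """Paired t test on a - b with Hedges' g on the difference scores.

    Identical inputs (all differences exactly zero) carry no evidence either
    way and return t = 0, p = 1; a constant non-zero difference is degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("missing or non-finite pairs")
    d = a - b
    if np.all(d == 0):
        return TestResult(statistic=0.0, df=n - 1, p_value=1.0,
                          effect_size=0.0, effect_label="hedges_g")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("constant non-zero differences: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    g = d.mean() / sd * hedges_correction(n)
    return TestResult(statistic=float(t), df=n - 1, p_value=float(p),
                      effect_size=float(g), effect_label="hedges_g")


# within-observer contrast weights, cells ordered
# (A present, B disgust), (present, anger), (absent, disgust), (absent, anger)
_CONTRASTS = {
    "factor_a": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
    "factor_b": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
}


def rm_anova_2x2(cells) -> dict[str, TestResult]:
    """2x2 repeated-measures ANOVA via single-df within-observer contrasts.

    ``cells`` is (n_observers, 4) with columns ordered (present, disgust),
    (present, anger), (absent, disgust), (absent, anger). Each effect is the
    one-sample t test of the corresponding contrast scores; F = t^2 with
    df = (1, n-1). Zero-variance, zero-mean contrasts give F = 0.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 2 or cells.shape[1] != 4:
        raise ValueError("cells must be an (n_observers, 4) array")
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 observers")
    if np.any(~np.isfinite(cells)):
        raise ValueError("incomplete cells: non-finite values present")
    out = {}
    scale = max(1.0, float(np.abs(cells).max()))
    for name, w in _CONTRASTS.items():
        scores = cells @ w
        if np.all(np.abs(scores) <= 1e-12 * scale):
            out[name] = TestResult(statistic=0.0, df=(1, cells.shape[0] - 1),
                                   p_value=1.0, effect_size=0.0,
                                   effect_label="hedges_g1")
            continue
        t_res = one_sample_test(scores, 0.0)
        out[name] = TestResult(statistic=t_res.statistic ** 2,
                               df=(1, cells.shape[0] - 1),
                               p_value=t_res.p_value,
                               effect_size=t_res.effect_size,
                               effect_label=t_res.effect_label)
    return out


def _jzs_marginal_directional(t: float, n: int, scale: float) -> float:
    """Marginal likelihood of t under a half-Cauchy(scale) prior on delta > 0.

    Substituting delta = scale*tan(u) turns the truncated-Cauchy mixture of
    noncentral-t densities into a smooth integral over (0, pi/2).
    """
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(u):
        delta = scale * math.tan(u)
        return stats.nct.pdf(t, nu, delta * sqrt_n)

    val, _ = integrate.quad(integrand, 0.0, math.pi / 2.0, epsabs=0, epsrel=1e-9,
                            limit=200)
    return (2.0 / math.pi) * val


def jzs_bf01_directional(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE,
                         direction: int = 1) -> float:
    """BF01 for a directional JZS (Cauchy-prior) paired/one-sample t test.

    ``direction`` (+1 or -1) gives the sign of the effect under the
    alternative; the prior is the Cauchy(0, prior_scale) on the standardized
    effect size truncated to that side. BF01 > 1 favours the null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    t_signed = t * direction  # fold so the alternative predicts positive t
    m1 = _jzs_marginal_directional(t_signed, n, prior_scale)
    m0 = stats.t.pdf(t_signed, n - 1)
    if not (m1 > 0 and math.isfinite(m1)):
        raise FloatingPointError(
            f"JZS marginal likelihood did not converge (m1={m1}, t={t}, n={n}, scale={prior_scale})"
        )
    return m0 / m1


def bf_robustness(t: float, n: int, scales, direction: int = 1) -> BayesFactorResult:
    """BF01 across a grid of prior scales ("prior widths").

    ``min_scale_substantial`` is the smallest tested scale at which the data
    provide substantial evidence for the null (BF01 >= 3).
    """
    scales = list(scales)
    if not scales:
        raise ValueError("scales must be a non-empty sorted list")
    if any(s <= 0 for s in scales) or sorted(scales) != scales:
        raise ValueError("scales must be positive and sorted increasing")
    curve = [(s, jzs_bf01_directional(t, n, s, direction)) for s in scales]
    substantial = [s for s, bf in curve if bf >= SUBSTANTIAL_BF]
    default_bf = jzs_bf01_directional(t, n, DEFAULT_PRIOR_SCALE, direction)
    return BayesFactorResult(bf01=default_bf, prior_scale=DEFAULT_PRIOR_SCALE,
                             robustness_curve=curve,
                             min_scale_substantial=min(substantial) if substantial else None)


def _corr_log_likelihood_ratio(rho: float, r: float, n: int) -> float:
    """log f(r | rho, n) - log f(r | 0, n), exact sampling density of r."""
    if abs(rho) >= 1.0:
        return -math.inf
    lr = ((n - 1) / 2.0) * math.log1p(-rho * rho) \
        - (n - 1.5) * math.log1p(-rho * r) \
        + math.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
    l0 = math.log(hyp2f1(0.5, 0.5, n - 0.5, 0.5))  # rho = 0
    return lr - l0


def _pearson_bf10(r: float, n: int, width: float) -> float:
    """BF10 for rho != 0 with a stretched Beta(1/width, 1/width) prior."""
    a = 1.0 / width

    def integrand(rho):
        # stretched-beta density on (-1, 1)
        log_prior = ((a - 1.0) * (math.log1p(rho) + math.log1p(-rho))
                     - (2.0 * a - 1.0) * math.log(2.0) - betaln(a, a))
        return math.exp(_corr_log_likelihood_ratio(rho, r, n) + log_prior)

    val, _ = integrate.quad(integrand, -1.0, 1.0, epsabs=0, epsrel=1e-9,
                            limit=200, points=[r])
    return val


def pearson_with_bf(x, y, beta_prior_width: float = 1.0) -> tuple[float, float, float]:
    """Pearson r, two-sided p, and BF01 against a stretched-beta alternative."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateVarianceError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
        bf01 = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        bf10 = _pearson_bf10(r, n, beta_prior_width)
        if not (bf10 > 0 and math.isfinite(bf10)):
            raise FloatingPointError(f"correlation marginal did not converge (bf10={bf10})")
        bf01 = 1.0 / bf10
    return r, float(p), float(bf01)


def bonferroni(p_values, m: int | None = None):
    """m-fold Bonferroni correction (off by default in all reports)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(p * m, 1.0)
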