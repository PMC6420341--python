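"""Cumulative-Gaussian psychometric model for 2AFC expression judgements.

The morph axis runs from 0 (fully disgusted) to 1 (fully angry); the target
response is "anger", so the psychometric function gives P(anger | morph level).
Fitting follows the standard fixed-asymptote convention: guess rate ``gamma``
and lapse rate ``lam`` are held fixed (defaults 0 and 0.03) while the point of
subjective equality ``alpha`` and the spread ``sigma`` (reported slope is
1/sigma) are estimated by maximum likelihood on binned binomial counts.
Model adequacy is screened with a parametric-bootstrap deviance test; a fit
with bootstrap p < 0.05 is flagged for exclusion from downstream aftereffect
analyses.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

__all__ = [
    "PsychometricParams",
    "BinnedResponses",
    "FitResult",
    "AftereffectResult",
    "ParameterDomainError",
    "NonIdentifiableError",
    "ExcludedFitError",
    "pf_eval",
    "fit_mle",
    "gof_bootstrap",
    "aftereffect",
]

# Fit bounds: PSEs slightly outside the morph range are allowed, but not
# unbounded drift; sigma below 0.01 is indistinguishable from a step at the
# candidate spacing used here.
ALPHA_BOUNDS = (-0.5, 1.5)
SIGMA_BOUNDS = (0.01, 1.0)

GOF_EXCLUSION_P = 0.05


class ParameterDomainError(ValueError):
    """Psychometric parameters outside their domain."""


class NonIdentifiableError(ValueError):
    """Response pattern carries no information about (alpha, sigma)."""


class ExcludedFitError(ValueError):
    """A fit flagged by the goodness-of-fit screen was used downstream."""


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of gamma + (1 - gamma - lam) * Phi((x - alpha) / sigma)."""

    alpha: float
    sigma: float
    gamma: float = 0.0
    lam: float = 0.03

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ParameterDomainError("alpha must be finite")
        if not (self.sigma > 0):
            raise ParameterDomainError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.gamma < 1 and 0 <= self.lam < 1):
            raise ParameterDomainError("gamma and lam must lie in [0, 1)")
        if self.gamma + self.lam >= 1:
            raise ParameterDomainError("gamma + lam must be < 1")

    @property
    def slope(self) -> float:
        """Reported sensitivity index (1/sigma)."""
        return 1.0 / self.sigma


def pf_eval(params: PsychometricParams, x):
    """P(target response | morph level x) under a cumulative Gaussian.

    Vectorised over ``x``; returns values in [gamma, 1 - lam].
    """
    z = (np.asarray(x, dtype=float) - params.alpha) / params.sigma
    return params.gamma + (1.0 - params.gamma - params.lam) * ndtr(z)


@dataclass(frozen=True)
class BinnedResponses:
    """Per-level binomial counts of target ("anger") responses.

    Levels are sorted and duplicates merged on construction.
    """

    levels: np.ndarray
    n_trials: np.ndarray
    n_target: np.ndarray

    def __init__(self, levels, n_trials, n_target):
        levels = np.asarray(levels, dtype=float)
        n_trials = np.asarray(n_trials, dtype=np.int64)
        n_target = np.asarray(n_target, dtype=np.int64)
        if not (levels.shape == n_trials.shape == n_target.shape):
            raise ValueError("levels, n_trials, n_target must have equal length")
        if np.any(n_trials < 0) or np.any(n_target < 0):
            raise ValueError("counts must be non-negative")
        if np.any(n_target > n_trials):
            raise ValueError("n_target cannot exceed n_trials")
        # merge duplicate levels
        uniq, inv = np.unique(levels, return_inverse=True)
        if uniq.size != levels.size:
            n_trials = np.bincount(inv, weights=n_trials).astype(np.int64)
            n_target = np.bincount(inv, weights=n_target).astype(np.int64)
            levels = uniq
        else:
            order = np.argsort(levels)
            levels, n_trials, n_target = levels[order], n_trials[order], n_target[order]
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n_trials", n_trials)
        object.__setattr__(self, "n_target", n_target)

    @classmethod
    def from_trials(cls, stimulus_level: Sequence[float], response: Sequence[int]) -> "BinnedResponses":
        df = pd.DataFrame({"level": np.asarray(stimulus_level, dtype=float),
                           "r": np.asarray(response, dtype=np.int64)})
        g = df.groupby("level")["r"].agg(["count", "sum"])
        return cls(g.index.to_numpy(), g["count"].to_numpy(), g["sum"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "BinnedResponses":
        df = pd.read_csv(path)
        missing = {"level", "n_trials", "n_target"} - set(df.columns)
        if missing:
            raise ValueError(f"binned-response CSV missing columns: {sorted(missing)}")
        return cls(df["level"].to_numpy(), df["n_trials"].to_numpy(), df["n_target"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"level": self.levels, "n_trials": self.n_trials,
                      "n_target": self.n_target}).to_csv(path, index=False)

    @property
    def total_trials(self) -> int:
        return int(self.n_trials.sum())


@dataclass(frozen=True)
class FitResult:
    params: PsychometricParams
    loglik: float
    deviance: float
    converged: bool
    gof_p: float | None = None
    excluded: bool = False
    psi_alpha: float | None = None  # interim Psi posterior mean, if available
    psi_sigma: float | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.params.alpha, "sigma": self.params.sigma,
            "gamma": self.params.gamma, "lam": self.params.lam,
            "loglik": self.loglik, "deviance": self.deviance,
            "gof_p": self.gof_p, "converged": self.converged,
            "excluded": self.excluded,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _binomial_loglik(k, n, p):
    """Binomial log-likelihood without the constant term; 0*log(0) := 0."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _saturated_loglik(data: BinnedResponses) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = data.n_target / data.n_trials
        terms = np.where(data.n_target > 0, data.n_target * np.log(np.where(phat > 0, phat, 1.0)), 0.0)
        terms = terms + np.where(
            data.n_trials - data.n_target > 0,
            (data.n_trials - data.n_target) * np.log(np.where(phat < 1, 1 - phat, 1.0)),
            0.0,
        )
    return float(terms.sum())


def _nll(theta, levels, n, k, gamma, lam):
    alpha, log_sigma = theta
    p = gamma + (1 - gamma - lam) * ndtr((levels - alpha) / math.exp(log_sigma))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_mle(data: BinnedResponses, gamma: float = 0.0, lam: float = 0.03) -> FitResult:
    """Maximum-likelihood (alpha, sigma) with fixed asymptotes.

    Deterministic: a coarse 10x10 grid over the bounds seeds a bounded
    quasi-Newton polish on (alpha, log sigma).
    """
    live = data.n_trials > 0
    levels = data.levels[live]
    n = data.n_trials[live]
    k = data.n_target[live]
    if levels.size < 2:
        raise NonIdentifiableError(
            f"need >= 2 stimulus levels with trials, got {levels.size}"
        )
    if np.all(k == 0) or np.all(k == n):
        pattern = "all-target" if np.all(k == n) else "all-nontarget"
        raise NonIdentifiableError(
            f"responses are {pattern} at every level; alpha and sigma are not identifiable"
        )
    if n.sum() < 20:
        warnings.warn(f"only {int(n.sum())} trials; fit may be unstable", stacklevel=2)

    alphas = np.linspace(*ALPHA_BOUNDS, 10)
    log_sigmas = np.linspace(math.log(SIGMA_BOUNDS[0]), math.log(SIGMA_BOUNDS[1]), 10)
    # vectorised coarse grid
    A, S = np.meshgrid(alphas, np.exp(log_sigmas), indexing="ij")
    P = gamma + (1 - gamma - lam) * ndtr((levels[None, None, :] - A[..., None]) / S[..., None])
    P = np.clip(P, 1e-12, 1 - 1e-12)
    LL = np.sum(k * np.log(P) + (n - k) * np.log1p(-P), axis=-1)
    i, j = np.unravel_index(np.argmax(LL), LL.shape)
    x0 = np.array([alphas[i], log_sigmas[j]])

    bounds = [ALPHA_BOUNDS, (math.log(SIGMA_BOUNDS[0]), math.log(SIGMA_BOUNDS[1]))]
    res = minimize(_nll, x0, args=(levels, n, k, gamma, lam), method="L-BFGS-B", bounds=bounds)
    alpha_hat = float(res.x[0])
    sigma_hat = float(math.exp(res.x[1]))

    at_bound = (
        alpha_hat <= ALPHA_BOUNDS[0] + 1e-9 or alpha_hat >= ALPHA_BOUNDS[1] - 1e-9
        or sigma_hat <= SIGMA_BOUNDS[0] * (1 + 1e-9) or sigma_hat >= SIGMA_BOUNDS[1] * (1 - 1e-9)
    )
    converged = bool(res.success) and not at_bound
    if at_bound:
        warnings.warn(
            f"optimizer at parameter bound (alpha={alpha_hat:.3f}, sigma={sigma_hat:.3f})",
            stacklevel=2,
        )

    loglik = -float(res.fun)
    deviance = 2.0 * (_saturated_loglik(BinnedResponses(levels, n, k)) - loglik)
    deviance = max(deviance, 0.0) if deviance > -1e-9 else deviance
    params = PsychometricParams(alpha_hat, sigma_hat, gamma, lam)
    return FitResult(params=params, loglik=loglik, deviance=deviance, converged=converged)


def deviance_of(params: PsychometricParams, data: BinnedResponses) -> float:
    """Deviance of a given parameter vector against binned data."""
    ll = _binomial_loglik(data.n_target, data.n_trials, pf_eval(params, data.levels))
    return 2.0 * (_saturated_loglik(data) - ll)


def gof_bootstrap(fit: FitResult, data: BinnedResponses, n_sim: int = 400,
                  seed: int | None = None) -> FitResult:
    """Parametric-bootstrap deviance test of the fitted model.

    Simulates ``n_sim`` datasets from the fitted parameters at the observed
    stimulus placements, refits each, and compares simulated deviances with
    the observed one. Returns a copy of ``fit`` with ``gof_p`` set to the
    smoothed p-value (1 + #{D_sim >= D_obs}) / (n_kept + 1) and ``excluded``
    set by the p < 0.05 rule.
    """
    if not fit.converged:
        raise ValueError("goodness-of-fit screen requires a converged fit")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    p_model = np.clip(pf_eval(fit.params, data.levels), 0.0, 1.0)
    gamma, lam = fit.params.gamma, fit.params.lam
    d_sims = []
    failures = 0
    for _ in range(n_sim):
        k_sim = rng.binomial(data.n_trials, p_model)
        sim = BinnedResponses(data.levels, data.n_trials, k_sim)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_mle(sim, gamma=gamma, lam=lam)
            d_sims.append(refit.deviance)
        except NonIdentifiableError:
            failures += 1
    if failures > 0.10 * n_sim:
        raise RuntimeError(
            f"goodness-of-fit bootstrap unstable: {failures}/{n_sim} refits failed"
        )
    d_sims = np.asarray(d_sims)
    p = (1.0 + int(np.sum(d_sims >= fit.deviance - 1e-12))) / (d_sims.size + 1.0)
    return replace(fit, gof_p=p, excluded=p < GOF_EXCLUSION_P)


@dataclass(frozen=True)
class AftereffectResult:
    """Signed PSE shifts (baseline - adapted) per adapted condition."""

    pse_baseline: float
    pse_adapted: dict = field(default_factory=dict)

    @property
    def aftereffect(self) -> dict:
        return {c: self.pse_baseline - p for c, p in self.pse_adapted.items()}


def aftereffect(pse_baseline, pse_adapted) -> float:
    """PSE difference score, baseline minus adapted.

    On the 0=disgust .. 1=anger morph axis, positive values indicate
    adaptation to disgust (targets perceived as more angry). Accepts raw PSE
    values or ``FitResult`` objects; fits flagged by the goodness-of-fit
    screen are refused.
    """
    vals = []
    for obj, label in ((pse_baseline, "baseline"), (pse_adapted, "adapted")):
        if isinstance(obj, FitResult):
            if obj.excluded:
                raise ExcludedFitError(
                    f"{label} fit excluded by goodness-of-fit screen (p={obj.gof_p})"
                )
            vals.append(obj.params.alpha)
        else:
            vals.append(float(obj))
    return vals[0] - vals[1]
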