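"""Psi adaptive procedure for 2AFC psychometric estimation.

Each trial's morph level is chosen to minimise the expected Shannon entropy
of the posterior over a (PSE, spread) grid, the response updates the
posterior by Bayes' rule, and posterior means provide running estimates.
Entropy is computed in natural log; the base does not affect the argmin.

The selection step uses the identity p*H(w/p) = p*log(p) - sum(w*log(w))
with per-candidate likelihood tables precomputed at initialisation, so a
144-trial session runs in milliseconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometric import PsychometricParams, pf_eval

__all__ = [
    "PsiState",
    "PsiConfigError",
    "psi_init",
    "default_psi_state",
    "psi_select",
    "psi_update",
    "psi_estimate",
    "posterior_entropy",
    "run_psi_session",
]

_TIE_TOL = 1e-12
_FLOOR = 1e-300


class PsiConfigError(ValueError):
    """Invalid Psi grid, candidate set, or prior."""


@dataclass
class PsiState:
    """Posterior over a (alpha, sigma) grid plus the candidate stimulus set.

    ``posterior`` is flat with alpha varying slowest (shape A*S); ``history``
    records the (stimulus, response) pairs applied so far. ``_like1`` caches
    P(response=1 | candidate, grid cell) and ``_xlogx1`` its x*log(x)
    transform (likewise ``_like0``/``_xlogx0``); the caches are shared across
    the states an update chain produces.
    """

    alpha_grid: np.ndarray
    sigma_grid: np.ndarray
    posterior: np.ndarray
    candidates: np.ndarray
    gamma: float
    lam: float
    history: list = field(default_factory=list)
    _like1: np.ndarray | None = None
    _like0: np.ndarray | None = None
    _xlogx1: np.ndarray | None = None
    _xlogx0: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.alpha_grid.size * self.sigma_grid.size


def _likelihood_tables(alpha_grid, sigma_grid, candidates, gamma, lam):
    A, S = np.meshgrid(alpha_grid, sigma_grid, indexing="ij")
    alpha_flat, sigma_flat = A.ravel(), S.ravel()
    from scipy.special import ndtr

    z = (candidates[:, None] - alpha_flat[None, :]) / sigma_flat[None, :]
    like1 = gamma + (1 - gamma - lam) * ndtr(z)
    like1 = np.clip(like1, _FLOOR, 1.0)
    like0 = np.clip(1.0 - like1, _FLOOR, 1.0)
    xlogx1 = like1 * np.log(like1)
    xlogx0 = like0 * np.log(like0)
    return like1, like0, xlogx1, xlogx0


def psi_init(alpha_grid, sigma_grid, candidates, gamma: float = 0.0,
             lam: float = 0.03, prior=None) -> PsiState:
    """Fresh Psi state with a normalised (default uniform) prior."""
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if alpha_grid.size == 0 or sigma_grid.size == 0:
        raise PsiConfigError("parameter grids must be non-empty")
    if candidates.size == 0:
        raise PsiConfigError("candidate set must be non-empty")
    if np.any(sigma_grid <= 0):
        raise PsiConfigError("sigma grid must be positive")
    if np.any((candidates < 0) | (candidates > 1)):
        raise PsiConfigError("candidates must lie in [0, 1]")
    n = alpha_grid.size * sigma_grid.size
    if prior is None:
        posterior = np.full(n, 1.0 / n)
    else:
        prior = np.asarray(prior, dtype=float).ravel()
        if prior.size != n:
            raise PsiConfigError(f"prior has {prior.size} weights, grid has {n} cells")
        if np.any(prior < 0) or prior.sum() <= 0:
            raise PsiConfigError("prior must be non-negative and not all zero")
        posterior = prior / prior.sum()
    like1, like0, xlogx1, xlogx0 = _likelihood_tables(
        alpha_grid, sigma_grid, candidates, gamma, lam
    )
    return PsiState(alpha_grid=alpha_grid, sigma_grid=sigma_grid,
                    posterior=posterior, candidates=candidates,
                    gamma=gamma, lam=lam, history=[],
                    _like1=like1, _like0=like0, _xlogx1=xlogx1, _xlogx0=xlogx0)


def default_psi_state(gamma: float = 0.0, lam: float = 0.03) -> PsiState:
    """Default grids: 41 PSEs on [0,1], 21 log-spaced spreads on [0.02, 0.5],
    41 candidate morph levels on [0,1], uniform prior."""
    return psi_init(
        alpha_grid=np.linspace(0.0, 1.0, 41),
        sigma_grid=np.geomspace(0.02, 0.5, 21),
        candidates=np.linspace(0.0, 1.0, 41),
        gamma=gamma, lam=lam,
    )


def expected_entropies(state: PsiState) -> np.ndarray:
    """Expected posterior entropy E[H] for each candidate stimulus."""
    post = state.posterior
    with np.errstate(divide="ignore", invalid="ignore"):
        logpost = np.where(post > 0, np.log(np.where(post > 0, post, 1.0)), 0.0)
    t = post * logpost  # p*log(p), 0 at zero cells
    # per candidate: p_r = sum_cell post*like_r ; s_r = sum_cell w*log(w)
    p1 = state._like1 @ post
    p0 = state._like0 @ post
    s1 = state._like1 @ t + state._xlogx1 @ post
    s0 = state._like0 @ t + state._xlogx0 @ post
    with np.errstate(divide="ignore", invalid="ignore"):
        eh = (np.where(p1 > 0, p1 * np.log(np.where(p1 > 0, p1, 1.0)), 0.0) - s1
              + np.where(p0 > 0, p0 * np.log(np.where(p0 > 0, p0, 1.0)), 0.0) - s0)
    return eh


def psi_select(state: PsiState) -> float:
    """Candidate morph level minimising expected posterior entropy.

    Ties (within 1e-12) break toward the lowest candidate value.
    """
    eh = expected_entropies(state)
    idx = int(np.flatnonzero(eh <= eh.min() + _TIE_TOL)[0])
    return float(state.candidates[idx])


def psi_update(state: PsiState, x: float, response: int) -> PsiState:
    """Bayes update of the posterior after observing ``response`` at ``x``."""
    if response not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {response!r}")
    ix = np.searchsorted(state.candidates, x)
    if ix < state.candidates.size and abs(state.candidates[ix] - x) < 1e-12:
        like = state._like1[ix] if response else state._like0[ix]
    else:
        warnings.warn(f"stimulus {x} not in the candidate set", stacklevel=2)
        p1 = np.asarray([_pf_grid(state, x)]).ravel()
        like = p1 if response else 1.0 - p1
    post = state.posterior * like
    post = np.maximum(post, 0.0)
    total = post.sum()
    if total <= 0:
        raise FloatingPointError("posterior underflow: all updated weights are zero")
    post /= total
    return PsiState(alpha_grid=state.alpha_grid, sigma_grid=state.sigma_grid,
                    posterior=post, candidates=state.candidates,
                    gamma=state.gamma, lam=state.lam,
                    history=state.history + [(float(x), int(response))],
                    _like1=state._like1, _like0=state._like0,
                    _xlogx1=state._xlogx1, _xlogx0=state._xlogx0)


def _pf_grid(state: PsiState, x: float) -> np.ndarray:
    from scipy.special import ndtr
    A, S = np.meshgrid(state.alpha_grid, state.sigma_grid, indexing="ij")
    z = (x - A.ravel()) / S.ravel()
    return np.clip(state.gamma + (1 - state.gamma - state.lam) * ndtr(z), _FLOOR, 1.0)


def psi_estimate(state: PsiState) -> tuple[float, float]:
    """Marginal posterior means of alpha and sigma."""
    if not state.history:
        warnings.warn("psi_estimate called before any update", stacklevel=2)
    post = state.posterior.reshape(state.alpha_grid.size, state.sigma_grid.size)
    alpha_hat = float(post.sum(axis=1) @ state.alpha_grid)
    sigma_hat = float(post.sum(axis=0) @ state.sigma_grid)
    return alpha_hat, sigma_hat


def posterior_entropy(state: PsiState) -> float:
    """Shannon entropy (nats) of the current posterior."""
    p = state.posterior[state.posterior > 0]
    return float(-(p * np.log(p)).sum())


def run_psi_session(respond, n_trials: int, state: PsiState | None = None) -> tuple[PsiState, pd.DataFrame]:
    """Run ``n_trials`` of the adaptive procedure against a responder.

    ``respond(x) -> 0/1`` supplies the observer's answer at morph level x
    (for simulated observers, a seeded Bernoulli draw from their true
    psychometric function). Returns the final state and the per-trial trace
    (`trial,stimulus_level,response,alpha_hat,sigma_hat,posterior_entropy`).
    """
    if state is None:
        state = default_psi_state()
    rows = []
    for t in range(1, n_trials + 1):
        x = psi_select(state)
        r = int(respond(x))
        state = psi_update(state, x, r)
        a_hat, s_hat = psi_estimate(state)
        rows.append((t, x, r, a_hat, s_hat, posterior_entropy(state)))
    trace = pd.DataFrame(rows, columns=["trial", "stimulus_level", "response",
                                        "alpha_hat", "sigma_hat", "posterior_entropy"])
    return state, trace


def bernoulli_responder(params: PsychometricParams, rng: np.random.Generator):
    """Simulated observer answering by Bernoulli(pf(x))."""
    def respond(x: float) -> int:
        return int(rng.random() < pf_eval(params, x))
    return respond
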