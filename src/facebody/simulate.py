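"""Synthetic observers for face-body context integration experiments.

Two generative hypotheses about where face and body signals merge:

* ``late`` integration — adaptation acts on face representations upstream of
  the face-body merge, so the aftereffect magnitude follows the physical
  facial expression of the adaptor regardless of body context.
* ``early`` integration — adaptation acts on the integrated percept, so the
  effective shift is weighted by the probability q that the adaptor face is
  perceived as its physical emotion in that body context:
  delta_eff = delta * (2q - 1). With q from the bias construction (q = 1 in
  the congruent context, 1 - kappa in the incongruent one, 1 - kappa/2 for
  the weaker off-pair fear/sad contexts), a full contextual reversal
  (kappa = 1) predicts an equal-magnitude opposite aftereffect.

Categorization responses are multinomial draws from the observer's base
rates with a fraction kappa of the face-emotion mass reassigned to the body
emotion in incongruent contexts (kappa/2 for fear/sad). Adaptation sessions
answer Psi-selected morph levels by Bernoulli draws from the observer's true
psychometric function, with the PSE shifted by the signed effective
adaptation magnitude on the 0 = disgust, 1 = anger morph axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .psychometric import PsychometricParams, pf_eval
from .psi import PsiState, default_psi_state, psi_estimate, psi_select, psi_update, posterior_entropy

__all__ = [
    "ObserverModel",
    "CohortConfig",
    "ParamDist",
    "effective_shift",
    "categorization_probs",
    "simulate_categorization",
    "simulate_adaptation_session",
    "draw_observers",
    "generate_cohort",
]

EMOTIONS = ("disgust", "anger", "fear", "sad")
PAIR = ("disgust", "anger")
HYPOTHESES = ("early", "late")

# Condition labels used in trial files: baseline has no adaptor; face
# conditions pair the physical face emotion with a body-context emotion;
# "none" faces are blurred-face body-only adaptors.
BASELINE = "baseline"


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth latent parameters of one simulated observer."""

    alpha0: float = 0.5
    sigma_true: float = 0.12
    lam_true: float = 0.03
    gamma_true: float = 0.0
    delta: float = 0.08
    kappa: float = 0.5
    base_rates: tuple = (0.75, 0.15, 0.07, 0.03)  # P(response) to the face emotion, congruent context
    hypothesis: str = "late"
    seed: int = 0

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if abs(sum(self.base_rates) - 1.0) > 1e-9:
            raise ValueError("base_rates must sum to 1")

    def true_params(self, pse: float | None = None) -> PsychometricParams:
        return PsychometricParams(self.alpha0 if pse is None else pse,
                                  self.sigma_true, self.gamma_true, self.lam_true)


def percept_probability(obs: ObserverModel, face_emotion: str, context: str) -> float:
    """q: probability the face is perceived as its physical emotion in context.

    Defined by the bias construction itself (baseline response confusion is
    treated as response noise, not a percept change): q = 1 when the body is
    congruent, 1 - kappa when it shows the other pair emotion, 1 - kappa/2
    for the weaker off-pair (fear/sad) contexts.
    """
    if context == face_emotion:
        return 1.0
    if context in PAIR:
        return 1.0 - obs.kappa
    return 1.0 - obs.kappa / 2.0


def effective_shift(obs: ObserverModel, adaptor_face: str, adaptor_context: str) -> float:
    """Signed PSE displacement of the adapted state on the morph axis.

    Disgust adaptation biases perception toward anger, i.e. lowers the PSE;
    anger adaptation raises it. Body-only adaptors (face "none") do not
    shift the PSE. Under the late hypothesis the magnitude is delta
    regardless of context; under early it is delta * (2q - 1).
    """
    if adaptor_face == "none":
        return 0.0
    if adaptor_face not in PAIR:
        raise ValueError(f"adaptor_face must be in {PAIR} or 'none'")
    if adaptor_context not in PAIR:
        raise ValueError(f"adaptor_context must be in {PAIR}")
    if obs.hypothesis == "late":
        magnitude = obs.delta
    else:
        q = percept_probability(obs, adaptor_face, adaptor_context)
        magnitude = obs.delta * (2.0 * q - 1.0)
    sign = -1.0 if adaptor_face == "disgust" else 1.0
    return sign * magnitude


def categorization_probs(obs: ObserverModel, face_emotion: str, context: str) -> np.ndarray:
    """Response probabilities over (disgust, anger, fear, sad) for one context."""
    if context not in EMOTIONS:
        raise ValueError(f"context must be one of {EMOTIONS}, got {context!r}")
    rates = dict(zip(_rate_order(face_emotion), obs.base_rates))
    probs = np.array([rates[e] for e in EMOTIONS], dtype=float)
    if context != face_emotion:
        frac = obs.kappa if context in PAIR else obs.kappa / 2.0
        i_face = EMOTIONS.index(face_emotion)
        i_body = EMOTIONS.index(context)
        moved = frac * probs[i_face]
        probs[i_face] -= moved
        probs[i_body] += moved
    return probs


def _rate_order(face_emotion: str) -> tuple:
    """base_rates are ordered (face emotion, other pair emotion, fear, sad)."""
    other = PAIR[1 - PAIR.index(face_emotion)]
    return (face_emotion, other, "fear", "sad")


def simulate_categorization(obs: ObserverModel, context: str, n_trials: int,
                            face_emotion: str | None = None,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Multinomial 4-alternative categorization trials for one context."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    face = face_emotion or "disgust"
    rng = rng if rng is not None else np.random.default_rng(obs.seed)
    probs = categorization_probs(obs, face, context)
    draws = rng.choice(len(EMOTIONS), size=n_trials, p=probs)
    return pd.DataFrame({
        "context": context,
        "face_emotion": face,
        "response": [EMOTIONS[i] for i in draws],
    })


def simulate_adaptation_session(obs: ObserverModel, adaptor_face: str,
                                adaptor_context: str, n_test: int = 144,
                                psi: PsiState | None = None,
                                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One Psi-driven 2AFC session (baseline when adaptor_face is 'none' and
    adaptor_context is 'baseline'-coded by the caller).

    Returns the trial trace with Psi running estimates; response 1 codes an
    "anger" judgement of the morph target.
    """
    rng = rng if rng is not None else np.random.default_rng(obs.seed)
    state = psi if psi is not None else default_psi_state(gamma=obs.gamma_true, lam=obs.lam_true)
    if adaptor_face == "none" and adaptor_context == BASELINE:
        shift = 0.0
    else:
        shift = effective_shift(obs, adaptor_face, adaptor_context)
    params = obs.true_params(pse=obs.alpha0 + shift)
    rows = []
    for t in range(1, n_test + 1):
        x = psi_select(state)
        r = int(rng.random() < pf_eval(params, x))
        state = psi_update(state, x, r)
        a_hat, s_hat = psi_estimate(state)
        rows.append((t, x, r, a_hat, s_hat, posterior_entropy(state)))
    return pd.DataFrame(rows, columns=["trial", "stimulus_level", "response",
                                       "alpha_hat", "sigma_hat", "posterior_entropy"])


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal specification for one latent observer parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(10_000):
            v = rng.normal(self.mean, self.sd)
            if self.lo <= v <= self.hi:
                return float(v)
        raise RuntimeError("truncated-normal rejection sampling failed")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the experimental protocol: 24 observers, 144 baseline
    and 144 adapted test trials per condition after 24 adaptation trials,
    48 categorization trials per body context, disgust faces, and adapted
    conditions pairing the face with a congruent and an incongruent body.
    """

    n_observers: int = 24
    hypothesis: str = "late"
    face_emotion: str = "disgust"
    n_test: int = 144
    n_adaptation: int = 24
    n_baseline: int = 144
    n_categorization: int = 48  # per body context
    alpha0: ParamDist = ParamDist(0.5, 0.05, 0.3, 0.7)
    sigma: ParamDist = ParamDist(0.12, 0.03, 0.04, 0.4)
    delta: ParamDist = ParamDist(0.08, 0.02, 0.0, 0.3)
    kappa: ParamDist = ParamDist(0.5, 0.2, 0.0, 1.0)
    lam_true: float = 0.03
    gamma_true: float = 0.0
    base_rates: tuple = (0.75, 0.15, 0.07, 0.03)
    include_body_only: bool = False
    contexts: tuple = EMOTIONS
    seed: int = 0

    def __post_init__(self):
        if self.n_observers < 0:
            raise ValueError("n_observers must be >= 0")
        if min(self.n_test, self.n_adaptation, self.n_baseline, self.n_categorization) < 1:
            raise ValueError("trial counts must be positive")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")

    def conditions(self) -> list[tuple[str, str]]:
        """(adaptor_face, adaptor_context) pairs, baseline first."""
        face = self.face_emotion
        other = PAIR[1 - PAIR.index(face)]
        conds = [("none", BASELINE), (face, face), (face, other)]
        if self.include_body_only:
            conds += [("none", face), ("none", other)]
        return conds


def _observer_rng(seed: int, obs_idx: int, stream: int) -> np.random.Generator:
    # counter-based fan-out: each observer/stream pair gets an independent
    # substream, stable under partial regeneration
    return np.random.default_rng([seed, obs_idx, stream])


def draw_observers(config: CohortConfig) -> list[ObserverModel]:
    """Draw the cohort's latent parameters from the configured distributions."""
    observers = []
    for i in range(config.n_observers):
        rng = _observer_rng(config.seed, i, 0)
        observers.append(ObserverModel(
            alpha0=config.alpha0.draw(rng),
            sigma_true=config.sigma.draw(rng),
            lam_true=config.lam_true,
            gamma_true=config.gamma_true,
            delta=config.delta.draw(rng),
            kappa=config.kappa.draw(rng),
            base_rates=config.base_rates,
            hypothesis=config.hypothesis,
            seed=int(np.random.default_rng([config.seed, i, 1]).integers(2**31)),
        ))
    return observers


def generate_cohort(config: CohortConfig, out_dir=None):
    """Simulate a full cohort: categorization + baseline/adapted Psi sessions.

    Returns (adaptation_trials, categorization_trials, manifest); when
    ``out_dir`` is given also writes ``adaptation_trials.csv``,
    ``categorization_trials.csv`` and ``ground_truth.json`` there.
    Fully reproducible from ``config.seed``.
    """
    observers = draw_observers(config)
    if config.n_observers == 0:
        warnings.warn("n_observers = 0: empty cohort", stacklevel=2)
    adapt_frames, cat_frames, manifest_obs = [], [], []
    for i, obs in enumerate(observers):
        # categorization: one stream per context
        for j, ctx in enumerate(config.contexts):
            rng = _observer_rng(config.seed, i, 10 + j)
            df = simulate_categorization(obs, ctx, config.n_categorization,
                                         face_emotion=config.face_emotion, rng=rng)
            df.insert(0, "observer_id", i)
            cat_frames.append(df)
        # adaptation: one stream per condition
        for k, (face, ctx) in enumerate(config.conditions()):
            rng = _observer_rng(config.seed, i, 100 + k)
            n = config.n_baseline if ctx == BASELINE else config.n_test
            trace = simulate_adaptation_session(obs, face, ctx, n_test=n, rng=rng)
            trace.insert(0, "observer_id", i)
            trace.insert(1, "phase", "baseline" if ctx == BASELINE else "adapted")
            trace.insert(2, "adaptor_face", face)
            trace.insert(3, "adaptor_context", ctx)
            adapt_frames.append(trace)
        record = asdict(obs)
        record["observer_id"] = i
        record["effective_shifts"] = {
            f"{face}:{ctx}": effective_shift(obs, face, ctx)
            for face, ctx in config.conditions() if ctx != BASELINE
        }
        manifest_obs.append(record)

    cols = ["observer_id", "phase", "adaptor_face", "adaptor_context",
            "trial", "stimulus_level", "response"]
    if adapt_frames:
        adaptation = pd.concat(adapt_frames, ignore_index=True)[cols]
        categorization = pd.concat(cat_frames, ignore_index=True)
    else:
        adaptation = pd.DataFrame(columns=cols)
        categorization = pd.DataFrame(columns=["observer_id", "context", "face_emotion", "response"])
    manifest = {
        "seed": config.seed,
        "hypothesis": config.hypothesis,
        "face_emotion": config.face_emotion,
        "n_observers": config.n_observers,
        "conditions": [list(c) for c in config.conditions()],
        "observers": manifest_obs,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        adaptation.to_csv(out / "adaptation_trials.csv", index=False)
        categorization.to_csv(out / "categorization_trials.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return adaptation, categorization, manifest
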