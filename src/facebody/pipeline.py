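"""End-to-end study orchestration.

simulate -> run Psi sessions -> bin -> MLE fit -> bootstrap GOF screen ->
aftereffect scores -> bias indices -> group statistics. Observers with a
failed goodness-of-fit screen in any condition are dropped from the
adaptation analyses but retained in the exclusion log; the bias-index vs
aftereffect-difference correlation uses only non-excluded observers with
defined indices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import ConfusionTable, compute_bias_indices
from .psychometric import BinnedResponses, fit_mle, gof_bootstrap
from .simulate import BASELINE, PAIR, CohortConfig, ParamDist, generate_cohort
from .stats import (
    DEFAULT_PRIOR_SCALE,
    DegenerateVarianceError,
    bf_robustness,
    one_sample_test,
    paired_contrast,
    pearson_with_bf,
    rm_anova_2x2,
)

__all__ = [
    "StudyConfig",
    "TrialParseError",
    "run_study",
    "read_trials",
    "read_categorization",
    "write_report",
    "analyze_trials",
]

log = logging.getLogger("facebody")

SCHEMA_VERSION = 1

ADAPT_COLUMNS = ["observer_id", "phase", "adaptor_face", "adaptor_context",
                 "trial", "stimulus_level", "response"]
CAT_COLUMNS = ["observer_id", "context", "face_emotion", "response"]
VALID_RESPONSES = {"0", "1", "disgust", "anger", "fear", "sad", "none"}


class TrialParseError(ValueError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulated study (YAML-serialisable)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gamma: float = 0.0
    lam: float = 0.03
    n_sim_gof: int = 400
    prior_scale: float = DEFAULT_PRIOR_SCALE
    robustness_scales: tuple = (0.1, 0.2, 0.35, 0.5, 0.707, 1.0, 1.414)
    bonferroni_m: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"config schema_version must be {SCHEMA_VERSION}, got {version!r}")
        cohort_raw = raw.pop("cohort", {})
        known_cohort = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = set(cohort_raw) - known_cohort
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
        for key in ("alpha0", "sigma", "delta", "kappa"):
            if key in cohort_raw:
                cohort_raw[key] = ParamDist(**cohort_raw[key])
        if "base_rates" in cohort_raw:
            cohort_raw["base_rates"] = tuple(cohort_raw["base_rates"])
        if "contexts" in cohort_raw:
            cohort_raw["contexts"] = tuple(cohort_raw["contexts"])
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "robustness_scales" in raw:
            raw["robustness_scales"] = tuple(raw["robustness_scales"])
        seed = raw.get("seed", 0)
        cohort_raw.setdefault("seed", seed)
        return cls(cohort=CohortConfig(**cohort_raw), **raw)

    def with_overrides(self, seed: int | None = None, n_sim_gof: int | None = None) -> "StudyConfig":
        cfg = self
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed,
                                      cohort=dataclasses.replace(cfg.cohort, seed=seed))
        if n_sim_gof is not None:
            cfg = dataclasses.replace(cfg, n_sim_gof=n_sim_gof)
        return cfg


def read_trials(path) -> pd.DataFrame:
    """Read an adaptation/baseline trial CSV, validating the dialect."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ADAPT_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    bad = df.loc[~df["response"].isin({"0", "1"})]
    if len(bad):
        line = int(bad.index[0]) + 2  # header is line 1
        raise TrialParseError(
            f"{path}: line {line}: response {bad['response'].iloc[0]!r} not in {{0,1}}"
        )
    out = df.copy()
    for col, typ in (("observer_id", int), ("trial", int),
                     ("stimulus_level", float), ("response", int)):
        try:
            out[col] = out[col].astype(typ)
        except ValueError as exc:
            raise TrialParseError(f"{path}: column {col!r}: {exc}") from exc
    return out[ADAPT_COLUMNS]


def read_categorization(path) -> pd.DataFrame:
    """Read a categorization trial CSV, validating the dialect."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CAT_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    bad = df.loc[~df["response"].isin(VALID_RESPONSES)]
    if len(bad):
        line = int(bad.index[0]) + 2
        raise TrialParseError(
            f"{path}: line {line}: response {bad['response'].iloc[0]!r} invalid"
        )
    df = df.copy()
    df["observer_id"] = df["observer_id"].astype(int)
    return df[CAT_COLUMNS]


def _fit_session(trials: pd.DataFrame, gamma: float, lam: float,
                 n_sim_gof: int, seed) -> dict:
    binned = BinnedResponses.from_trials(trials["stimulus_level"], trials["response"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_mle(binned, gamma=gamma, lam=lam)
        if fit.converged and n_sim_gof > 0:
            fit = gof_bootstrap(fit, binned, n_sim=n_sim_gof, seed=seed)
    return {
        "alpha": fit.params.alpha, "sigma": fit.params.sigma,
        "loglik": fit.loglik, "deviance": fit.deviance,
        "gof_p": fit.gof_p, "converged": fit.converged,
        "excluded": bool(fit.excluded or not fit.converged),
    }


def analyze_trials(adaptation: pd.DataFrame, categorization: pd.DataFrame,
                   config: StudyConfig) -> dict:
    """Fit, screen, score and test an already-simulated (or loaded) study."""
    face = categorization["face_emotion"].iloc[0] if len(categorization) else "disgust"
    incongruent_ctx = PAIR[1 - PAIR.index(face)]
    congruent_key = f"{face}:{face}"
    incongruent_key = f"{face}:{incongruent_ctx}"

    per_observer = {}
    exclusion_log = []
    for obs_id, obs_trials in adaptation.groupby("observer_id"):
        fits = {}
        for (phase, a_face, a_ctx), sess in obs_trials.groupby(
                ["phase", "adaptor_face", "adaptor_context"]):
            key = BASELINE if phase == "baseline" else f"{a_face}:{a_ctx}"
            gof_seed = np.random.default_rng(
                [config.seed, int(obs_id), zlib.crc32(key.encode()) % (2**16)]).integers(2**31)
            fits[key] = _fit_session(sess, config.gamma, config.lam,
                                     config.n_sim_gof, int(gof_seed))
            log.info("observer %s condition %s: alpha=%.3f gof_p=%s",
                     obs_id, key, fits[key]["alpha"], fits[key]["gof_p"])
        excluded = any(f["excluded"] for f in fits.values())
        if excluded:
            reasons = [k for k, f in fits.items() if f["excluded"]]
            exclusion_log.append({"observer_id": int(obs_id), "conditions": reasons})
            log.info("observer %s excluded (conditions: %s)", obs_id, reasons)
        baseline_alpha = fits.get(BASELINE, {}).get("alpha")
        aftereffects = {
            k: baseline_alpha - f["alpha"]
            for k, f in fits.items() if k != BASELINE and baseline_alpha is not None
        }
        per_observer[int(obs_id)] = {
            "fits": fits, "aftereffects": aftereffects, "excluded": excluded,
        }

    # bias indices per observer
    for obs_id, obs_cat in categorization.groupby("observer_id"):
        table = ConfusionTable.from_trials(obs_cat, face_emotion=face)
        entry = per_observer.setdefault(int(obs_id), {"fits": {}, "aftereffects": {},
                                                      "excluded": False})
        try:
            bi = compute_bias_indices(table)
            entry["bias_indices"] = dataclasses.asdict(bi)
        except ValueError as exc:
            entry["bias_indices"] = None
            log.info("observer %s: bias indices undefined (%s)", obs_id, exc)

    included = {i: o for i, o in per_observer.items()
                if not o["excluded"] and o["aftereffects"]}
    group: dict = {"n_simulated": len(per_observer), "n_included": len(included),
                   "n_excluded": len(per_observer) - len(included)}

    def _column(key):
        return np.array([o["aftereffects"][key] for o in included.values()
                         if key in o["aftereffects"]])

    con = _column(congruent_key)
    incon = _column(incongruent_key)
    if con.size >= 2 and con.size == incon.size:
        group["aftereffect_congruent"] = _test_dict(one_sample_test, con)
        group["aftereffect_incongruent"] = _test_dict(one_sample_test, incon)
        group["aftereffect_congruent_mean"] = float(con.mean())
        group["aftereffect_incongruent_mean"] = float(incon.mean())
        paired = _test_dict(paired_contrast, con, incon)
        group["congruent_vs_incongruent"] = paired
        if paired is not None:
            # directional alternative: early integration predicts a larger
            # aftereffect in the congruent than the incongruent context
            bf = bf_robustness(paired["statistic"], con.size,
                               sorted(set(config.robustness_scales + (config.prior_scale,))),
                               direction=1)
            group["bf01_congruent_vs_incongruent"] = bf.bf01
            group["bf_prior_scale"] = bf.prior_scale
            group["bf_robustness_curve"] = bf.robustness_curve
            group["bf_min_scale_substantial"] = bf.min_scale_substantial
        # 2x2 ANOVA (face present/absent x body context) when body-only
        # adaptor conditions exist
        body_keys = (f"none:{face}", f"none:{incongruent_ctx}")
        if all(any(k in o["aftereffects"] for o in included.values()) for k in body_keys):
            cells = np.array([
                [o["aftereffects"][congruent_key], o["aftereffects"][incongruent_key],
                 o["aftereffects"][body_keys[0]], o["aftereffects"][body_keys[1]]]
                for o in included.values()
                if all(k in o["aftereffects"] for k in
                       (congruent_key, incongruent_key, *body_keys))
            ])
            if cells.shape[0] >= 2:
                group["anova_2x2"] = {
                    name: {"F": r.statistic, "df": list(np.atleast_1d(r.df)),
                           "p": r.p_value}
                    for name, r in rm_anova_2x2(cells).items()
                }
        # correlation of bias indices with the aftereffect difference
        diffs, idx1, idx2 = [], [], []
        for o in included.values():
            bi = o.get("bias_indices")
            if bi is None or congruent_key not in o["aftereffects"]:
                continue
            d = o["aftereffects"][congruent_key] - o["aftereffects"][incongruent_key]
            diffs.append(d)
            idx1.append(bi["index1"])
            idx2.append(bi["index2"])
        for label, vals in (("bias_index_1", idx1), ("bias_index_2", idx2)):
            pairs = [(v, d) for v, d in zip(vals, diffs) if v is not None]
            if len(pairs) >= 3:
                v, d = map(np.asarray, zip(*pairs))
                try:
                    r, p, bf01 = pearson_with_bf(v, d)
                    group[f"correlation_{label}"] = {"r": r, "p": p, "bf01": bf01, "n": len(pairs)}
                except DegenerateVarianceError:
                    group[f"correlation_{label}"] = None

    return {
        "facebody_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "metadata": {
            "bf_prior": f"Cauchy(0, {config.prior_scale}) on standardized effect size, directional",
            "bias_index_adjustment_N": "disgust+anger responses in the context (proportion denominator)",
            "baseline_aggregation": "mean of available baseline sessions",
            "n_sim_gof": config.n_sim_gof,
        },
        "per_observer": per_observer,
        "exclusion_log": exclusion_log,
        "group": group,
    }


def _test_dict(fn, *args):
    try:
        r = fn(*args)
    except (DegenerateVarianceError, ValueError):
        return None
    return {"statistic": r.statistic, "df": r.df, "p": r.p_value,
            "effect_size": r.effect_size, "effect_label": r.effect_label}


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Simulate a cohort and run the full analysis; optionally write outputs."""
    adaptation, categorization, manifest = generate_cohort(config.cohort, out_dir=out_dir)
    report = analyze_trials(adaptation, categorization, config)
    report["ground_truth_hypothesis"] = manifest["hypothesis"]
    if out_dir is not None:
        write_report(report, Path(out_dir) / "study_report.json")
        _write_exclusion_log(report, Path(out_dir) / "exclusions.log")
    return report


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_exclusion_log(report: dict, path) -> None:
    lines = [f"observer {e['observer_id']}: excluded (conditions: {', '.join(e['conditions'])})"
             for e in report["exclusion_log"]]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
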