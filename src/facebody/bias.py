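"""Categorization bias indices from 4-alternative confusion tables.

Both indices restrict to disgust and anger responses within the disgust and
anger body contexts. Writing p_c for the proportion of face-congruent
("correct") responses among disgust+anger responses in context c:

* Bias Index 1 = p_con / p_incon, a ratio measure (> 1 indicates a bias
  toward the body emotion in the incongruent context).
* Bias Index 2 = z(p_con) - z(p_incon), a d'-style difference of standard
  scores; extreme proportions of 0 or 1 are first adjusted to 1/N and
  1 - 1/N, with N the disgust+anger response count in that context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.special import ndtri

__all__ = [
    "ConfusionTable",
    "BiasIndices",
    "UndefinedProportionError",
    "UndefinedRatioError",
    "context_proportions",
    "bias_index_1",
    "bias_index_2",
    "compute_bias_indices",
]

RESPONSES = ("disgust", "anger", "fear", "sad", "no_response")
PAIR = ("disgust", "anger")


class UndefinedProportionError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of 4-alternative responses by body context for one observer.

    ``counts`` maps context label -> {response -> count}; ``face_emotion``
    (disgust or anger) defines the congruent context, the other member of
    the disgust/anger pair the incongruent one.
    """

    face_emotion: str
    counts: dict

    def __post_init__(self):
        if self.face_emotion not in PAIR:
            raise ValueError(f"face_emotion must be one of {PAIR}")
        for ctx, row in self.counts.items():
            for resp, c in row.items():
                if resp not in RESPONSES:
                    raise ValueError(f"unknown response label {resp!r} in context {ctx!r}")
                if int(c) != c or c < 0:
                    raise ValueError(f"counts must be non-negative integers, got {c!r}")

    @property
    def congruent(self) -> str:
        return self.face_emotion

    @property
    def incongruent(self) -> str:
        return PAIR[1 - PAIR.index(self.face_emotion)]

    @classmethod
    def from_trials(cls, df: pd.DataFrame, face_emotion: str) -> "ConfusionTable":
        """Build from a trial table with ``context`` and ``response`` columns.

        Responses coded "none" are tabulated as no_response.
        """
        counts: dict = {}
        for ctx, grp in df.groupby("context"):
            row = dict.fromkeys(RESPONSES, 0)
            for resp, n in grp["response"].value_counts().items():
                key = "no_response" if resp == "none" else str(resp)
                if key not in RESPONSES:
                    raise ValueError(f"unknown response label {resp!r}")
                row[key] = int(n)
            counts[str(ctx)] = row
        return cls(face_emotion=face_emotion, counts=counts)

    def to_json(self, path=None) -> str:
        text = json.dumps({"face_emotion": self.face_emotion, "counts": self.counts}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class BiasIndices:
    index1: float | None
    index2: float
    p_con: float
    p_incon: float
    adjusted: bool


def context_proportions(table: ConfusionTable) -> tuple[float, float, int, int]:
    """(p_con, p_incon, N_con, N_incon) restricted to disgust/anger responses.

    p_c = face-congruent responses / (disgust + anger responses) in context c;
    fear, sad and no_response trials enter neither numerator nor denominator.
    """
    out = []
    for ctx in (table.congruent, table.incongruent):
        if ctx not in table.counts:
            raise UndefinedProportionError(f"no trials recorded for context {ctx!r}")
        row = table.counts[ctx]
        n_pair = row.get("disgust", 0) + row.get("anger", 0)
        if n_pair == 0:
            raise UndefinedProportionError(
                f"no disgust/anger responses in context {ctx!r}; proportion undefined"
            )
        out.append((row.get(table.face_emotion, 0) / n_pair, n_pair))
    (p_con, n_con), (p_incon, n_incon) = out
    return p_con, p_incon, n_con, n_incon


def bias_index_1(p_con: float, p_incon: float) -> float:
    """Ratio of congruent to incongruent correct-response proportions."""
    if p_incon == 0:
        raise UndefinedRatioError(
            "incongruent proportion is 0; the ratio index is undefined "
            "(a ratio could skew the analysis) — use bias_index_2"
        )
    return p_con / p_incon


def _adjust_extreme(p: float, n: int) -> tuple[float, bool]:
    if n < 1:
        raise UndefinedProportionError("context has no disgust/anger responses")
    if p == 0.0:
        return 1.0 / n, True
    if p == 1.0:
        return 1.0 - 1.0 / n, True
    return p, False


def bias_index_2(p_con: float, p_incon: float, n_con: int, n_incon: int) -> tuple[float, bool]:
    """d'-style index z(p_con) - z(p_incon) with the 1/N extreme adjustment.

    Returns (index, adjusted) where ``adjusted`` flags whether either
    proportion was moved off 0 or 1.
    """
    pc, adj_c = _adjust_extreme(p_con, n_con)
    pi, adj_i = _adjust_extreme(p_incon, n_incon)
    return float(ndtri(pc) - ndtri(pi)), adj_c or adj_i


def compute_bias_indices(table: ConfusionTable) -> BiasIndices:
    """Both bias indices for one observer's confusion table."""
    p_con, p_incon, n_con, n_incon = context_proportions(table)
    try:
        idx1 = bias_index_1(p_con, p_incon)
    except UndefinedRatioError:
        idx1 = None
    idx2, adjusted = bias_index_2(p_con, p_incon, n_con, n_incon)
    return BiasIndices(index1=idx1, index2=idx2, p_con=p_con, p_incon=p_incon,
                       adjusted=adjusted)
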