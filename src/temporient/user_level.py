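"""User-level aggregation of tweet predictions and correlation analysis.

For each user the per-class tweet fractions are computed for temporal
orientation (past/present/future) and emotion (joy/sadness/anger/fear),
plus a 4x4 emotion-by-intensity-bin table: intensity is stratified into
VLI [0, 0.25), LI [0.25, 0.5), MI [0.5, 0.75) and HI [0.75, 1]. Associations
between orientation and emotion fractions across users are quantified with
Pearson's r and a two-sided t-test (n - 2 degrees of freedom) at alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from temporient.corpus_io import EMOTION_CLASS_NAMES, TEMPORAL_CLASS_NAMES

BIN_NAMES = ("VLI", "LI", "MI", "HI")
_BIN_EDGES = (0.25, 0.5, 0.75)


def bin_intensity(score: float) -> str:
    """Assign an intensity score to its half-open bin.

    Boundaries are closed on the left (0.25 -> LI, 0.5 -> MI, 0.75 -> HI);
    the top bin absorbs score 1.0 so the bins cover all of [0, 1].
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"intensity {score} outside [0, 1]")
    for name, edge in zip(BIN_NAMES, _BIN_EDGES):
        if score < edge:
            return name
    return "HI"


@dataclass
class UserAggregate:
    """Per-user fractions over temporal classes, emotions and intensity bins."""

    user_id: str
    n_tweets: int
    orientation_frac: np.ndarray          # (3,) past, present, future
    emotion_frac: np.ndarray              # (4,) joy, sadness, anger, fear
    emo_intensity_frac: np.ndarray        # (4, 4) emotion x bin

    def __post_init__(self) -> None:
        if self.n_tweets < 1:
            raise ValueError("a user aggregate needs at least one tweet")
        for name, arr, total in (("orientation", self.orientation_frac, 1.0),
                                 ("emotion", self.emotion_frac, 1.0)):
            if abs(arr.sum() - total) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1")
        if np.max(np.abs(self.emo_intensity_frac.sum(axis=1) - self.emotion_frac)) > 1e-9:
            raise ValueError("bin fractions must sum to each emotion's fraction")


def aggregate_users(tweet_table: pd.DataFrame,
                    min_tweets: int = 1) -> list[UserAggregate]:
    """Aggregate per-tweet predictions to per-user fractions.

    ``tweet_table`` needs columns user_id, temporal (class name), emotion
    (class name) and intensity (real in [0, 1]). Users with fewer than
    ``min_tweets`` tweets are dropped.
    """
    required = {"user_id", "temporal", "emotion", "intensity"}
    missing = required - set(tweet_table.columns)
    if missing:
        raise ValueError(f"prediction table missing column(s) {sorted(missing)}")
    if tweet_table["user_id"].isna().any() or (tweet_table["user_id"] == "").any():
        raise ValueError("every tweet must carry a user_id")
    t_index = {c: i for i, c in enumerate(TEMPORAL_CLASS_NAMES)}
    e_index = {c: i for i, c in enumerate(EMOTION_CLASS_NAMES)}
    b_index = {b: i for i, b in enumerate(BIN_NAMES)}
    out = []
    for user_id, grp in tweet_table.groupby("user_id", sort=True):
        n = len(grp)
        if n < min_tweets:
            continue
        orient = np.zeros(3)
        emo = np.zeros(4)
        cells = np.zeros((4, 4))
        for _, row in grp.iterrows():
            orient[t_index[row["temporal"]]] += 1
            e = e_index[row["emotion"]]
            emo[e] += 1
            cells[e, b_index[bin_intensity(float(row["intensity"]))]] += 1
        out.append(UserAggregate(str(user_id), n, orient / n, emo / n, cells / n))
    return out


def users_to_frame(users: Sequence[UserAggregate]) -> pd.DataFrame:
    rows = []
    for u in users:
        row: dict = {"user_id": u.user_id, "n_tweets": u.n_tweets}
        row.update({f"frac_{c}": u.orientation_frac[i]
                    for i, c in enumerate(TEMPORAL_CLASS_NAMES)})
        row.update({f"frac_{c}": u.emotion_frac[i]
                    for i, c in enumerate(EMOTION_CLASS_NAMES)})
        for i, emo in enumerate(EMOTION_CLASS_NAMES):
            for j, b in enumerate(BIN_NAMES):
                row[f"frac_{emo}_{b}"] = u.emo_intensity_frac[i, j]
        rows.append(row)
    return pd.DataFrame(rows)


def write_user_aggregates(users: Sequence[UserAggregate], path: str | Path) -> None:
    users_to_frame(users).to_csv(Path(path), index=False)


def correlate(users: Sequence[UserAggregate] | pd.DataFrame,
              x_field: str, y_field: str) -> dict:
    """Pearson r between two per-user fraction columns, with its t-test p.

    Zero variance in either field gives a flagged undefined result rather
    than an exception.
    """
    frame = users if isinstance(users, pd.DataFrame) else users_to_frame(users)
    x = frame[x_field].to_numpy(dtype=float)
    y = frame[y_field].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs at least 3 users")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "p_value": None, "n": n, "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": n, "defined": True}


def correlation_matrix(users: Sequence[UserAggregate] | pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """All orientation-vs-emotion correlations across users.

    Rows cover the 3x4 orientation-emotion grid and the 3x16
    orientation-(emotion x intensity-bin) grid; each row carries r, p and a
    significance flag at ``alpha``.
    """
    frame = users if isinstance(users, pd.DataFrame) else users_to_frame(users)
    y_fields = [f"frac_{e}" for e in EMOTION_CLASS_NAMES]
    y_fields += [f"frac_{e}_{b}" for e in EMOTION_CLASS_NAMES for b in BIN_NAMES]
    rows = []
    for t in TEMPORAL_CLASS_NAMES:
        for y_field in y_fields:
            res = correlate(frame, f"frac_{t}", y_field)
            rows.append({"x": f"frac_{t}", "y": y_field, "r": res["r"],
                         "p": res["p_value"], "n": res["n"],
                         "significant": (res["defined"] and res["p_value"] < alpha)})
    return pd.DataFrame(rows)


def mcnemar_test(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> dict:
    """Exact McNemar test comparing two classifiers on the same items.

    This is the legitimate use of McNemar's test: paired correctness
    indicators, testing whether the two classifiers' error rates differ.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired correctness vectors must align")
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    n = n01 + n10
    if n == 0:
        return {"n01": 0, "n10": 0, "p_value": 1.0}
    p = min(1.0, 2.0 * stats.binom.cdf(min(n01, n10), n, 0.5))
    return {"n01": n01, "n10": n10, "p_value": float(p)}
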