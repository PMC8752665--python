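"""Synthetic corpora with known latent structure.

Three generators make the pipeline testable offline:

* :func:`simulate_lf_matrix` — labeling-function outputs with controlled
  accuracy, propensity (non-abstain rate) and planted pairwise agreement,
  the three dependency types the generative label model estimates;
* :func:`simulate_corpus` — users whose tweets carry latent temporal and
  emotion classes plus Beta-distributed intensities, rendered as marker
  tokens + filler so both heuristics and the neural model can learn them;
* :func:`planted_correlation` — a Monte-Carlo oracle for the user-level
  orientation-emotion correlations implied by the population parameters,
  computed on latent propensities alone (no text, no classifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from temporient.corpus_io import (
    EMOTION_CLASS_NAMES,
    TEMPORAL_CLASS_NAMES,
    EmotionRecord,
    Lexicon,
    Tweet,
)
from temporient.weak_labelers import LabelMatrix, keyword_lexicon

TEMPORAL_MARKERS = {
    "past": ["yesterday", "remembered", "nostalgia", "childhood", "ago"],
    "present": ["currently", "rightnow", "today", "moment", "nowadays"],
    "future": ["tomorrow", "someday", "upcoming", "eventually", "soon"],
}
EMOTION_MARKERS = {
    "joy": ["happy", "delighted", "yay", "smiling", "cheerful"],
    "sadness": ["sad", "tears", "gloomy", "heartbroken", "crying"],
    "anger": ["furious", "rage", "annoyed", "outraged", "livid"],
    "fear": ["scared", "terrified", "anxious", "dread", "panicking"],
}
FILLER_VOCAB = [
    "the", "a", "my", "friend", "coffee", "weather", "city", "music", "game",
    "phone", "dog", "cat", "work", "school", "home", "street", "book", "movie",
    "dinner", "morning", "train", "garden", "river", "photo", "shirt", "desk",
    "window", "cloud", "song", "party",
]

# planted association: past tweets skew sad, future tweets skew joyful
PLANTED_EMOTION_GIVEN_ORIENTATION = np.array([
    [0.10, 0.60, 0.15, 0.15],   # past
    [0.25, 0.25, 0.25, 0.25],   # present
    [0.60, 0.10, 0.15, 0.15],   # future
])
INDEPENDENT_EMOTION_GIVEN_ORIENTATION = np.full((3, 4), 0.25)


def marker_lexicon() -> Lexicon:
    """Fixture temporal lexicon built from all class-marker tokens."""
    return Lexicon({w: cls for cls, words in TEMPORAL_MARKERS.items() for w in words},
                   name="marker_lexicon")


def keyword30_fixture() -> Lexicon:
    """Stand-in 30-per-class keyword lists.

    Covers all five markers per class (as both published temporal word
    lists cover the common temporal words) plus inert padding tokens, so
    this labeler is heavily redundant with the marker lexicon — exactly the
    kind of dependent pair structure estimation should flag.
    """
    lists = {}
    for cls, markers in TEMPORAL_MARKERS.items():
        lists[cls] = markers + [f"{cls}_kw_{i:02d}" for i in range(25)]
    return keyword_lexicon(lists["past"], lists["present"], lists["future"])


@dataclass
class LFSpec:
    """Behavior of one simulated labeling function.

    ``accuracy`` is the chance of emitting the true class when labeling;
    ``propensity`` the chance of labeling at all; ``copy_of``/``agreement``
    plant a pairwise dependency: with probability ``agreement`` the LF
    copies the named earlier LF's output instead of drawing independently.
    """

    accuracy: float
    propensity: float = 1.0
    copy_of: int | None = None
    agreement: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError("accuracy must be in (0, 1]")
        if not 0.0 <= self.propensity <= 1.0:
            raise ValueError("propensity must be in [0, 1]")
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must be in [0, 1]")


def simulate_lf_matrix(truth: np.ndarray, specs: Sequence[LFSpec],
                       seed: int = 0) -> LabelMatrix:
    """Simulate a label matrix over latent classes ``truth`` (codes 1..K)."""
    if not specs:
        raise ValueError("at least one LFSpec is required")
    truth = np.asarray(truth, dtype=np.intp)
    K = 3
    M, L = len(truth), len(specs)
    rng = np.random.default_rng(seed)
    entries = np.zeros((M, L), dtype=np.intp)
    for q, spec in enumerate(specs):
        correct = rng.random(M) < spec.accuracy
        # uniformly wrong class: shift by 1 or 2 mod K
        shift = rng.integers(1, K, size=M)
        labels = np.where(correct, truth, (truth - 1 + shift) % K + 1)
        labels[rng.random(M) >= spec.propensity] = 0
        if spec.copy_of is not None:
            if not 0 <= spec.copy_of < q:
                raise ValueError("copy_of must reference an earlier LF index")
            copied = rng.random(M) < spec.agreement
            labels = np.where(copied, entries[:, spec.copy_of], labels)
        entries[:, q] = labels
    return LabelMatrix(entries, [f"lf_{q}" for q in range(L)])


@dataclass
class PopulationSpec:
    """Generative parameters for a synthetic user population."""

    n_users: int = 300
    tweets_per_user: int = 20
    orientation_dirichlet: tuple[float, float, float] = (1.5, 1.5, 1.5)
    emotion_given_orientation: np.ndarray = field(
        default_factory=lambda: PLANTED_EMOTION_GIVEN_ORIENTATION.copy())
    #: when set, users draw per-user emotion mixtures from this Dirichlet,
    #: independent of orientation (the zero-correlation population);
    #: emotion_given_orientation is then ignored
    emotion_dirichlet: tuple[float, float, float, float] | None = None
    intensity_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {e: (2.0, 2.0) for e in EMOTION_CLASS_NAMES})
    marker_prob: float = 0.9
    n_filler: tuple[int, int] = (4, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        self.emotion_given_orientation = np.asarray(self.emotion_given_orientation,
                                                    dtype=float)
        if self.emotion_given_orientation.shape != (3, 4):
            raise ValueError("emotion_given_orientation must be 3x4")
        if not np.allclose(self.emotion_given_orientation.sum(axis=1), 1.0):
            raise ValueError("emotion_given_orientation rows must sum to 1")
        if min(self.orientation_dirichlet) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


def simulate_corpus(spec: PopulationSpec) -> tuple[list[Tweet], pd.DataFrame]:
    """Generate tweets plus their latent truth table.

    Each user draws an orientation mixture from the Dirichlet; each tweet
    draws its temporal class from that mixture, its emotion from the
    orientation-conditional row (or from the user's own independent emotion
    mixture when ``emotion_dirichlet`` is set), its intensity from the
    emotion's Beta, and a token stream of class markers (injected with
    ``marker_prob``; the emotion-marker count grows with intensity) plus
    uniform filler.
    """
    rng = np.random.default_rng(spec.seed)
    tweets: list[Tweet] = []
    rows = []
    for u in range(spec.n_users):
        user_id = f"u{u:05d}"
        pi = rng.dirichlet(spec.orientation_dirichlet)
        emo_mix = (rng.dirichlet(spec.emotion_dirichlet)
                   if spec.emotion_dirichlet is not None else None)
        for j in range(spec.tweets_per_user):
            t_idx = rng.choice(3, p=pi)
            t_cls = TEMPORAL_CLASS_NAMES[t_idx]
            e_idx = rng.choice(4, p=(emo_mix if emo_mix is not None
                                     else spec.emotion_given_orientation[t_idx]))
            e_cls = EMOTION_CLASS_NAMES[e_idx]
            a, b = spec.intensity_beta[e_cls]
            intensity = float(rng.beta(a, b))
            tokens = rng.choice(FILLER_VOCAB,
                                size=rng.integers(*spec.n_filler)).tolist()
            if rng.random() < spec.marker_prob:
                tokens += rng.choice(TEMPORAL_MARKERS[t_cls],
                                     size=rng.integers(1, 3), replace=False).tolist()
            if rng.random() < spec.marker_prob:
                n_emo = 1 + int(round(2 * intensity))
                tokens += rng.choice(EMOTION_MARKERS[e_cls],
                                     size=n_emo, replace=True).tolist()
            rng.shuffle(tokens)
            tweet_id = f"t{u:05d}_{j:03d}"
            tweets.append(Tweet(id=tweet_id, text=" ".join(tokens), user_id=user_id))
            rows.append({"id": tweet_id, "user_id": user_id, "temporal": t_cls,
                         "emotion": e_cls, "intensity": intensity})
    return tweets, pd.DataFrame(rows)


def separable_fixture(n_per_task: int = 60, seed: int = 0
                      ) -> tuple[list, list]:
    """Small fully-separable training fixture for the multi-task model.

    Marker injection probability is 1, so every tweet carries its class
    markers and both tasks are learnable to perfection by construction.
    Returns (temporal records, emotion records), ``n_per_task`` each.
    """
    from temporient.corpus_io import TemporalRecord
    users = max(3, int(np.ceil(n_per_task / 10)))
    spec = PopulationSpec(n_users=users, tweets_per_user=20, marker_prob=1.0,
                          seed=seed)
    tweets, truth = simulate_corpus(spec)
    temporal = [TemporalRecord(t, truth.iloc[i]["temporal"])
                for i, t in enumerate(tweets[:n_per_task])]
    emotion = emotion_records_from_truth(tweets, truth, n_per_task, seed=seed + 1)
    return temporal, emotion


def emotion_records_from_truth(tweets: Sequence[Tweet], truth: pd.DataFrame,
                               n: int, seed: int = 0) -> list[EmotionRecord]:
    """Draw a class-balanced labeled emotion training set from a corpus."""
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in tweets}
    records: list[EmotionRecord] = []
    per_class = n // len(EMOTION_CLASS_NAMES)
    for emo in EMOTION_CLASS_NAMES:
        ids = truth.loc[truth["emotion"] == emo, "id"].to_numpy()
        if len(ids) < per_class:
            raise ValueError(f"not enough {emo} tweets for a balanced set of {n}")
        chosen = rng.choice(ids, size=per_class, replace=False)
        sub = truth.set_index("id").loc[chosen]
        records.extend(EmotionRecord(by_id[i], emo, float(row["intensity"]))
                       for i, row in sub.iterrows())
    return records


def planted_correlation(spec: PopulationSpec, n_mc_users: int = 100_000,
                        seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo oracle for the user-level orientation-emotion Pearson r.

    Samples latent per-user class fractions only (no text, no classifiers)
    at large n, so sampling error on each r is ~ 1/sqrt(n_mc_users).
    Returns a 3x4 orientation-by-emotion table of r.
    """
    rng = np.random.default_rng(seed)
    n = spec.tweets_per_user
    pis = rng.dirichlet(spec.orientation_dirichlet, size=n_mc_users)
    counts = rng.multinomial(n, pis)                            # (N, 3)
    if spec.emotion_dirichlet is not None:
        mixes = rng.dirichlet(spec.emotion_dirichlet, size=n_mc_users)
        emo_counts = rng.multinomial(n, mixes).astype(float)
    else:
        emo_counts = np.zeros((n_mc_users, 4))
        for o in range(3):
            emo_counts += rng.multinomial(counts[:, o],
                                          spec.emotion_given_orientation[o])
    orient_frac = counts / n
    emo_frac = emo_counts / n
    table = np.empty((3, 4))
    for i in range(3):
        for j in range(4):
            x, y = orient_frac[:, i], emo_frac[:, j]
            denom = x.std() * y.std()
            table[i, j] = (np.mean((x - x.mean()) * (y - y.mean())) / denom
                           if denom > 0 else np.nan)  # class never emitted
    return pd.DataFrame(table, index=list(TEMPORAL_CLASS_NAMES),
                        columns=list(EMOTION_CLASS_NAMES))
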