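"""Reproducible end-to-end studies on synthetic populations.

These functions chain the full method — weak labeling, generative label
fusion, balanced selection, multi-task training, prediction, user-level
aggregation and correlation — on corpora from :mod:`temporient.synthetic_data`,
so that correlation recovery can be validated against the Monte-Carlo oracle.

The study uses the three heuristic labeling functions. The trainable weak
models are deliberately left out of this particular validation chain: they
bootstrap from a small seed corpus and carry a fixed sample bias over
emotion-marker tokens that contaminates the recovered orientation-emotion
correlations without shrinking as the corpus grows (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from temporient import corpus_io as cio
from temporient import label_model as lm
from temporient import multitask_net as mt
from temporient import synthetic_data as sd
from temporient import user_level as ul
from temporient import weak_labelers as wl


@dataclass
class StudyConfig:
    """Desk-scale study sizes (see docs/methods.md for the rationale)."""

    balanced_fraction: float = 0.4   # share of the corpus selected for training
    n_emotion_train: int = 1600
    recurrent_units: int = 48
    conv_filters: int = 48
    shared_mlp_units: int = 96
    task_dense_units: int = 48
    embedding_dim: int = 32
    epochs: int = 25
    seed: int = 0


def heuristic_labeling_functions() -> list[tuple[str, object]]:
    """The three heuristic weak label sources over the fixture lexicons."""
    lexicon = sd.marker_lexicon()
    keywords = sd.keyword30_fixture()
    tagger = wl.RuleBasedTagger()
    return [
        ("lexicon", lambda t: wl.lf_lexicon(t, lexicon)),
        ("keyword30", lambda t: wl.lf_keyword30(t, keywords)),
        ("pos_verb", lambda t: wl.lf_pos_verb(tagger(t.tokens))),
    ]


def weak_supervision_labels(tweets, config: StudyConfig
                            ) -> tuple[list[cio.TemporalRecord], lm.PosteriorLabels]:
    """Weak label -> structure -> generative fit -> balanced selection."""
    matrix = wl.build_label_matrix(tweets, heuristic_labeling_functions())
    structure = lm.estimate_structure(matrix)
    weights = lm.fit_generative(matrix, structure)
    posterior = lm.posterior_labels(weights, matrix, structure)
    counts = np.bincount(posterior.hard, minlength=4)[1:]
    n_balanced = min(int(config.balanced_fraction * len(tweets)) // 3 * 3,
                     3 * int(counts.min()))
    selected = lm.select_balanced_training(posterior, tweets, n_balanced)
    return selected, posterior


def train_study_model(tweets, truth: pd.DataFrame,
                      config: StudyConfig) -> mt.MultiTaskModel:
    selected, _ = weak_supervision_labels(tweets, config)
    emotion = sd.emotion_records_from_truth(
        tweets, truth, config.n_emotion_train, seed=config.seed + 13)
    model_cfg = mt.ModelConfig(
        embedding_dim=config.embedding_dim,
        recurrent_units=config.recurrent_units,
        conv_filters=config.conv_filters,
        shared_mlp_units=config.shared_mlp_units,
        task_dense_units=config.task_dense_units,
        epochs=config.epochs,
        seed=config.seed,
    )
    return mt.train_multitask(selected, emotion, model_cfg)


def predictions_table(model: mt.MultiTaskModel, tweets,
                      truth: pd.DataFrame) -> pd.DataFrame:
    preds = model.predict(tweets)
    return pd.DataFrame({
        "id": preds.tweet_ids,
        "user_id": truth["user_id"].to_numpy(),
        "temporal": [wl.CLASS_NAMES[c] for c in preds.temporal_hard],
        "emotion": [cio.EMOTION_CLASS_NAMES[c] for c in preds.emotion_hard],
        "intensity": preds.intensity,
    })


def run_correlation_study(spec: sd.PopulationSpec,
                          config: StudyConfig | None = None) -> dict:
    """Full pipeline on one population; returns the user-level correlations.

    The result dict carries the per-tweet temporal/emotion accuracies of the
    discriminator, the 3x4 and full correlation tables, and the
    (future, joy) cell that the planted population is designed around.
    """
    config = config or StudyConfig()
    tweets, truth = sd.simulate_corpus(spec)
    model = train_study_model(tweets, truth, config)
    table = predictions_table(model, tweets, truth)
    t_codes = {"past": 1, "present": 2, "future": 3}
    e_codes = {e: i for i, e in enumerate(cio.EMOTION_CLASS_NAMES)}
    preds = model.predict(tweets)
    temporal_acc = float(np.mean(
        preds.temporal_hard == truth["temporal"].map(t_codes).to_numpy()))
    emotion_acc = float(np.mean(
        preds.emotion_hard == truth["emotion"].map(e_codes).to_numpy()))
    users = ul.aggregate_users(table)
    frame = ul.users_to_frame(users)
    matrix = ul.correlation_matrix(frame)
    base = matrix[matrix["y"].isin(
        [f"frac_{e}" for e in cio.EMOTION_CLASS_NAMES])]
    joy_future = ul.correlate(frame, "frac_future", "frac_joy")
    return {
        "temporal_accuracy": temporal_acc,
        "emotion_accuracy": emotion_acc,
        "n_users": len(users),
        "correlations": matrix,
        "max_abs_r_base": float(base["r"].abs().max()),
        "max_abs_r_all": float(matrix["r"].abs().max()),
        "joy_future_r": joy_future["r"],
        "joy_future_p": joy_future["p_value"],
    }


def planted_population(seed: int) -> sd.PopulationSpec:
    """300 users x 20 tweets with the planted joy-future association."""
    return sd.PopulationSpec(n_users=300, tweets_per_user=20, seed=seed)


def independent_population(seed: int) -> sd.PopulationSpec:
    """1000 users x 10 tweets with orientation-independent emotions."""
    return sd.PopulationSpec(
        n_users=1000, tweets_per_user=10,
        emotion_given_orientation=sd.INDEPENDENT_EMOTION_GIVEN_ORIENTATION,
        seed=seed)
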