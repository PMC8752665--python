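"""Hard-parameter-sharing multi-task network for tweets.

Architecture: token embeddings feed a bidirectional GRU and, in parallel, a
temporal convolution with global max pooling; the two summaries are
concatenated and passed through one shared dense (MLP) layer. Three heads
branch off the shared representation: a 3-way softmax for temporal
orientation, and an emotion-task dense layer carrying a 4-way emotion
softmax plus a sigmoid scalar for emotion intensity. Classification losses
are categorical cross-entropy; intensity uses squared error, added to the
emotion class loss with equal weight. Training alternates one mini-batch
per task so gradients from both tasks flow through the shared encoder.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from temporient import nn
from temporient.corpus_io import (
    EMOTION_CLASS_NAMES,
    EmotionRecord,
    TemporalRecord,
    Tweet,
    read_word_vectors,
)
from temporient.weak_labelers import CLASS_NAMES, build_vocab, encode_token_ids

logger = logging.getLogger(__name__)

EMOTION_INDEX = {name: i for i, name in enumerate(EMOTION_CLASS_NAMES)}


@dataclass
class ModelConfig:
    """Hyper-parameters; classification defaults follow the tuned values
    (batch 64, 100 epochs, rmsprop, conv filter width 7, dropout 0.2)."""

    embedding_dim: int = 200
    recurrent_units: int = 32
    conv_filters: int = 32
    conv_filter_size: int = 7
    shared_mlp_units: int = 64
    task_dense_units: int = 32
    dropout: float = 0.2
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 0.005
    optimizer: str = "rmsprop"
    max_len: int = 50
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("embedding_dim", "recurrent_units", "conv_filters",
                     "conv_filter_size", "shared_mlp_units", "task_dense_units",
                     "batch_size", "epochs", "max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def load_word_vectors(path: str | Path | None, vocab: dict[str, int],
                      dim: int, seed: int = 0) -> np.ndarray:
    """Build the embedding table for a vocabulary.

    Rows of in-vocabulary tokens are copied from the vector file;
    out-of-vocabulary rows (and the whole table, when no file is given) are
    drawn from seeded small-variance noise. The pad row is zero.
    """
    rng = np.random.default_rng(seed)
    table = rng.normal(0.0, 0.1, size=(len(vocab), dim))
    if "<pad>" in vocab:
        table[vocab["<pad>"]] = 0.0
    if path is not None:
        tokens, vectors = read_word_vectors(path)
        if vectors.shape[1] != dim:
            raise ValueError(
                f"word-vector file has dimension {vectors.shape[1]}, expected {dim}")
        for tok, row in tokens.items():
            if tok in vocab:
                table[vocab[tok]] = vectors[row]
    return table


@dataclass
class Predictions:
    """Per-tweet outputs of the three heads."""

    tweet_ids: list[str]
    temporal_probs: np.ndarray   # (N, 3)
    emotion_probs: np.ndarray    # (N, 4)
    intensity: np.ndarray        # (N,)

    @property
    def temporal_hard(self) -> np.ndarray:
        return self.temporal_probs.argmax(axis=1) + 1  # 1..3 class codes

    @property
    def emotion_hard(self) -> np.ndarray:
        return self.emotion_probs.argmax(axis=1)  # 0..3 indices

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"id": self.tweet_ids})
        df["temporal"] = [CLASS_NAMES[c] for c in self.temporal_hard]
        for i, cls in enumerate(("past", "present", "future")):
            df[f"p_{cls}"] = self.temporal_probs[:, i]
        df["emotion"] = [EMOTION_CLASS_NAMES[c] for c in self.emotion_hard]
        for i, emo in enumerate(EMOTION_CLASS_NAMES):
            df[f"p_{emo}"] = self.emotion_probs[:, i]
        df["intensity"] = self.intensity
        df.to_csv(Path(path), sep="\t", index=False)


class MultiTaskModel:
    """Shared encoder with temporal, emotion and intensity heads."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int],
                 embedding_table: np.ndarray | None = None,
                 single_task: bool = False):
        self.config = config
        self.vocab = vocab
        self.single_task = single_task
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        E, H, F = config.embedding_dim, config.recurrent_units, config.conv_filters
        if embedding_table is None:
            embedding_table = load_word_vectors(None, vocab, E, seed=config.seed)
        self.embed = nn.Tensor(embedding_table.copy(), requires_grad=True)
        self.gru_fwd = nn.GRUCell(rng, E, H)
        self.gru_bwd = nn.GRUCell(rng, E, H)
        self.conv = nn.Conv1D(rng, config.conv_filter_size, E, F)
        self.shared_mlp = nn.Dense(rng, 2 * H + F, config.shared_mlp_units)
        self.temporal_dense = nn.Dense(rng, config.shared_mlp_units, config.task_dense_units)
        self.temporal_head = nn.Dense(rng, config.task_dense_units, 3)
        self.emotion_dense = nn.Dense(rng, config.shared_mlp_units, config.task_dense_units)
        self.emotion_head = nn.Dense(rng, config.task_dense_units, 4)
        self.intensity_head = nn.Dense(rng, config.task_dense_units, 1)

    # -- parameter groups -----------------------------------------------------
    def shared_params(self) -> list[nn.Tensor]:
        return [self.embed, *self.gru_fwd.params(), *self.gru_bwd.params(),
                *self.conv.params(), *self.shared_mlp.params()]

    def temporal_params(self) -> list[nn.Tensor]:
        return [*self.temporal_dense.params(), *self.temporal_head.params()]

    def emotion_params(self) -> list[nn.Tensor]:
        return [*self.emotion_dense.params(), *self.emotion_head.params(),
                *self.intensity_head.params()]

    def all_params(self) -> list[nn.Tensor]:
        params = self.shared_params() + self.temporal_params()
        if not self.single_task:
            params += self.emotion_params()
        return params

    # -- forward passes -------------------------------------------------------
    def encode(self, token_lists: Sequence[Sequence[str]],
               train: bool = False) -> nn.Tensor:
        """Shared representation: [BiGRU summary | pooled conv] -> shared MLP."""
        if not token_lists:
            raise ValueError("empty batch")
        max_len = max(self.config.conv_filter_size,
                      min(self.config.max_len,
                          max((len(t) for t in token_lists), default=1)))
        idx, mask = encode_token_ids(token_lists, self.vocab, max_len)
        emb = nn.embedding(self.embed, idx)
        h_f = nn.run_recurrent(self.gru_fwd, emb, mask)
        h_b = nn.run_recurrent(self.gru_bwd, emb, mask, reverse=True)
        pooled = nn.max_pool_time(nn.relu(self.conv(emb)))
        shared = nn.relu(self.shared_mlp(nn.concat([h_f, h_b, pooled], axis=1)))
        return nn.dropout(shared, self.config.dropout, self._dropout_rng, train)

    def temporal_logits(self, shared: nn.Tensor) -> nn.Tensor:
        return self.temporal_head(nn.relu(self.temporal_dense(shared)))

    def emotion_outputs(self, shared: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        hidden = nn.relu(self.emotion_dense(shared))
        return self.emotion_head(hidden), nn.sigmoid(self.intensity_head(hidden))

    def predict(self, tweets: Sequence[Tweet], batch_size: int = 256) -> Predictions:
        t_probs, e_probs, intens = [], [], []
        for start in range(0, len(tweets), batch_size):
            chunk = tweets[start:start + batch_size]
            shared = self.encode([t.tokens for t in chunk], train=False)
            t_probs.append(nn.softmax(self.temporal_logits(shared).data))
            e_logits, e_int = self.emotion_outputs(shared)
            e_probs.append(nn.softmax(e_logits.data))
            intens.append(np.clip(e_int.data[:, 0], 0.0, 1.0))
        return Predictions([t.id for t in tweets], np.vstack(t_probs),
                           np.vstack(e_probs), np.concatenate(intens))

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {"params": [p.data for p in
                            self.shared_params() + self.temporal_params()
                            + self.emotion_params()],
                 "vocab": self.vocab, "single_task": self.single_task}
        with open(path, "wb") as fh:
            pickle.dump(state, fh)
        Path(str(path) + ".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultiTaskModel":
        path = Path(path)
        config = ModelConfig(**json.loads(Path(str(path) + ".json").read_text()))
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(config, state["vocab"], single_task=state["single_task"])
        targets = (model.shared_params() + model.temporal_params()
                   + model.emotion_params())
        for p, data in zip(targets, state["params"]):
            p.data = np.asarray(data)
        return model


def _split_validation(n: int, fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = int(round(n * fraction))
    return perm[n_val:], perm[:n_val]


def train_multitask(temporal_data: Sequence[TemporalRecord],
                    emotion_data: Sequence[EmotionRecord] | None,
                    config: ModelConfig,
                    embedding_path: str | Path | None = None,
                    vocab: dict[str, int] | None = None) -> MultiTaskModel:
    """Train the multi-task model by alternating one mini-batch per task.

    10% of each task's data is held out; the parameters with the best
    held-out loss over the epochs are returned. Passing ``emotion_data=None``
    trains the temporal single-task ablation with the same encoder.
    """
    if not temporal_data:
        raise ValueError("temporal training data is empty")
    single_task = emotion_data is None or len(emotion_data) == 0
    rng = np.random.default_rng(config.seed)

    all_tokens = [r.tweet.tokens for r in temporal_data]
    if not single_task:
        all_tokens += [r.tweet.tokens for r in emotion_data]
    if vocab is None:
        vocab = build_vocab(all_tokens)
    table = load_word_vectors(embedding_path, vocab, config.embedding_dim,
                              seed=config.seed)
    model = MultiTaskModel(config, vocab, table, single_task=single_task)
    opt = nn.RMSProp(model.all_params(), lr=config.learning_rate)

    t_tokens = [r.tweet.tokens for r in temporal_data]
    t_labels = np.array([{"past": 0, "present": 1, "future": 2}[r.temporal_class]
                         for r in temporal_data], dtype=np.intp)
    t_train, t_val = _split_validation(len(t_tokens), config.validation_fraction, rng)
    batch_t = min(config.batch_size, len(t_train))
    if batch_t < config.batch_size:
        logger.warning("temporal dataset smaller than one batch; batch size -> %d", batch_t)

    if not single_task:
        e_tokens = [r.tweet.tokens for r in emotion_data]
        e_labels = np.array([EMOTION_INDEX[r.emotion_class] for r in emotion_data],
                            dtype=np.intp)
        e_intensity = np.array([r.intensity for r in emotion_data])
        e_train, e_val = _split_validation(len(e_tokens), config.validation_fraction, rng)
        batch_e = min(config.batch_size, len(e_train))
        if batch_e < config.batch_size:
            logger.warning("emotion dataset smaller than one batch; batch size -> %d", batch_e)

    def temporal_loss(indices, train):
        shared = model.encode([t_tokens[i] for i in indices], train=train)
        return nn.softmax_cross_entropy(model.temporal_logits(shared), t_labels[indices])

    def emotion_loss(indices, train):
        shared = model.encode([e_tokens[i] for i in indices], train=train)
        logits, intensity = model.emotion_outputs(shared)
        return nn.add(nn.softmax_cross_entropy(logits, e_labels[indices]),
                      nn.mean_squared_error(intensity, e_intensity[indices][:, None]))

    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    loss_trace: list[float] = []
    for epoch in range(config.epochs):
        t_order = rng.permutation(t_train)
        e_order = rng.permutation(e_train) if not single_task else np.empty(0, np.intp)
        n_steps = max(int(np.ceil(len(t_order) / batch_t)),
                      int(np.ceil(len(e_order) / batch_e)) if not single_task else 0)
        epoch_loss = 0.0
        for step in range(n_steps):
            # temporal batch (cycled when this task's data runs short)
            lo = (step * batch_t) % len(t_order)
            idx = np.take(t_order, range(lo, lo + batch_t), mode="wrap")
            opt.zero_grad()
            loss = temporal_loss(idx, train=True)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            if single_task:
                continue
            lo = (step * batch_e) % len(e_order)
            idx = np.take(e_order, range(lo, lo + batch_e), mode="wrap")
            opt.zero_grad()
            loss = emotion_loss(idx, train=True)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        loss_trace.append(epoch_loss / max(n_steps, 1))

        val = 0.0
        if len(t_val):
            val += float(temporal_loss(t_val, train=False).data)
        if not single_task and len(e_val):
            val += float(emotion_loss(e_val, train=False).data)
        if not len(t_val) and (single_task or not len(e_val)):
            val = loss_trace[-1]  # no held-out data: fall back to training loss
        if val < best_val:
            best_val = val
            best_state = [p.data.copy() for p in model.all_params()]
    if best_state is not None:
        for p, data in zip(model.all_params(), best_state):
            p.data = data
    model.loss_trace = loss_trace  # type: ignore[attr-defined]
    return model


def evaluate(predictions: Predictions,
             gold_temporal: Sequence[str] | None = None,
             gold_emotion: Sequence[str] | None = None,
             gold_intensity: Sequence[float] | None = None) -> dict:
    """Accuracy, per-class precision/recall/F1, confusion matrices, and
    Pearson r between predicted and gold intensity."""
    out: dict = {}
    if gold_temporal is not None:
        codes = {"past": 1, "present": 2, "future": 3}
        out["temporal"] = _classification_report(
            np.array([codes[g] for g in gold_temporal]), predictions.temporal_hard,
            labels=[1, 2, 3], names=["past", "present", "future"])
    if gold_emotion is not None:
        out["emotion"] = _classification_report(
            np.array([EMOTION_INDEX[g] for g in gold_emotion]), predictions.emotion_hard,
            labels=[0, 1, 2, 3], names=list(EMOTION_CLASS_NAMES))
    if gold_intensity is not None:
        gold = np.asarray(gold_intensity, dtype=float)
        if np.ptp(gold) == 0 or np.ptp(predictions.intensity) == 0:
            out["intensity_pearson_r"] = None  # undefined: zero variance
        else:
            r, p = stats.pearsonr(predictions.intensity, gold)
            out["intensity_pearson_r"] = float(r)
            out["intensity_pearson_p"] = float(p)
    return out


def _classification_report(gold: np.ndarray, pred: np.ndarray,
                           labels: list[int], names: list[str]) -> dict:
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
    prec, rec, f1, _ = precision_recall_fscore_support(
        gold, pred, labels=labels, zero_division=0)
    return {
        "accuracy": float((gold == pred).mean()),
        "per_class": {name: {"precision": float(p), "recall": float(r), "f1": float(f)}
                      for name, p, r, f in zip(names, prec, rec, f1)},
        "confusion": confusion_matrix(gold, pred, labels=labels).tolist(),
    }
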