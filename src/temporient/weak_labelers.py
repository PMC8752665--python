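"""Weak temporal-orientation labelers and the label matrix they populate.

Five label sources feed the generative model downstream: two lexicon
heuristics, a part-of-speech verb heuristic, and two trainable weak
classifiers (a linear SVM on tf-idf and a bidirectional LSTM). Heuristics
may abstain (code 0); trained weak models always commit to a class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from temporient import nn
from temporient.corpus_io import Lexicon, TemporalRecord, Tweet

logger = logging.getLogger(__name__)

ABSTAIN = 0
TEMPORAL_CLASSES = {"past": 1, "present": 2, "future": 3}
CLASS_NAMES = {v: k for k, v in TEMPORAL_CLASSES.items()}
NUM_CLASSES = 3


@dataclass
class LabelMatrix:
    """M tweets x L labeling functions of weak labels (0 = abstain)."""

    entries: np.ndarray
    lf_names: list[str]
    num_classes: int = NUM_CLASSES

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.intp)
        if self.entries.ndim != 2 or min(self.entries.shape) < 1:
            raise ValueError("label matrix must be 2-D with M, L >= 1")
        if self.entries.shape[1] != len(self.lf_names):
            raise ValueError("lf_names must match the number of columns")
        if self.entries.min() < 0 or self.entries.max() > self.num_classes:
            raise ValueError(f"entries must lie in 0..{self.num_classes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def coverage(self) -> np.ndarray:
        """Per-LF fraction of non-abstain labels."""
        return (self.entries != ABSTAIN).mean(axis=0)

    def to_tsv(self, path: str | Path, tweet_ids: Sequence[str]) -> None:
        df = pd.DataFrame(self.entries, columns=self.lf_names)
        df.insert(0, "id", list(tweet_ids))
        df.to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> tuple["LabelMatrix", list[str]]:
        df = pd.read_csv(Path(path), sep="\t", dtype={"id": str})
        lf_names = [c for c in df.columns if c != "id"]
        return cls(df[lf_names].to_numpy(), lf_names), list(df["id"])


def _match_classes(tokens: Iterable[str], lookup: Callable[[str], str | None]) -> set[str]:
    return {cls for tok in tokens if (cls := lookup(tok)) is not None}


def lf_lexicon(tweet: Tweet, lexicon: Lexicon,
               conflict: Literal["abstain", "majority"] = "abstain") -> int:
    """Label by lexicon membership: one matching class wins, none abstains.

    When words of several temporal classes match, the default rule abstains
    (precision over coverage); ``majority`` votes by match count instead,
    abstaining on ties.
    """
    if not lexicon.entries:
        raise ValueError("lexicon is empty")
    if conflict == "abstain":
        classes = _match_classes(tweet.tokens, lexicon.lookup)
        if len(classes) == 1:
            return TEMPORAL_CLASSES[classes.pop()]
        return ABSTAIN
    counts: dict[str, int] = {}
    for tok in tweet.tokens:
        cls = lexicon.lookup(tok)
        if cls is not None:
            counts[cls] = counts.get(cls, 0) + 1
    if not counts:
        return ABSTAIN
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return TEMPORAL_CLASSES[winners[0]] if len(winners) == 1 else ABSTAIN


def keyword_lexicon(past: Sequence[str], present: Sequence[str],
                    future: Sequence[str]) -> Lexicon:
    """Build the 30-per-class keyword lexicon, rejecting overlapping lists."""
    sets = {"past": set(past), "present": set(present), "future": set(future)}
    for a in sets:
        for b in sets:
            if a < b and sets[a] & sets[b]:
                raise ValueError(f"keyword lists overlap between {a} and {b}: "
                                 f"{sorted(sets[a] & sets[b])}")
    entries = {w: cls for cls, words in sets.items() for w in words}
    return Lexicon(entries, name="keyword30")


def lf_keyword30(tweet: Tweet, keywords: Lexicon,
                 conflict: Literal["abstain", "majority"] = "abstain") -> int:
    """Same matching semantics as lf_lexicon, on the keyword lists."""
    return lf_lexicon(tweet, keywords, conflict=conflict)


# --- part-of-speech heuristic ------------------------------------------------

PAST_TAGS = {"VBD", "VBN"}
PRESENT_TAGS = {"VBP", "VBZ", "VBG"}
FUTURE_MODALS = {"will", "shall", "gonna", "'ll", "wo"}  # "wo" from "won't"


def lf_pos_verb(tags: Sequence[tuple[str, str]]) -> int:
    """Temporal label from verb morphology.

    Modal future ("will"/"shall"/"gonna") beats past tense beats present
    tense when several verb tags co-occur; no verb at all abstains. Unknown
    tags are treated as non-verbs.
    """
    has_future = any(tag == "MD" and tok.lower() in FUTURE_MODALS for tok, tag in tags)
    if has_future:
        return TEMPORAL_CLASSES["future"]
    if any(tag in PAST_TAGS for _, tag in tags):
        return TEMPORAL_CLASSES["past"]
    if any(tag in PRESENT_TAGS for _, tag in tags):
        return TEMPORAL_CLASSES["present"]
    return ABSTAIN


class RuleBasedTagger:
    """A miniature deterministic Penn-style tagger for tweets.

    Good enough to exercise the verb heuristic; a real tweet tagger can be
    injected anywhere a ``tagger(tokens) -> [(token, tag), ...]`` callable is
    accepted (an adapter just has to emit Penn-style verb tags).
    """

    _PRONOUNS = {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us", "them"}
    _MODALS = {"will", "shall", "can", "could", "would", "should", "may", "might", "must",
               "gonna", "'ll", "wo"}
    _BE_PAST = {"was", "were", "been", "did", "had"}
    _BE_PRESENT = {"is", "am", "are", "be", "do", "does", "has", "have"}
    _COMMON_VERBS = {"go", "see", "get", "make", "know", "think", "take", "come", "want",
                     "look", "use", "find", "give", "tell", "work", "feel", "try", "love",
                     "miss", "need", "like", "say", "hope", "plan", "wish", "remember"}
    _IRREGULAR_PAST = {"went", "saw", "got", "made", "knew", "thought", "took", "came",
                       "looked", "found", "gave", "told", "felt", "said", "ate", "wrote",
                       "met", "lost", "left", "kept", "held", "heard", "ran", "sat", "won"}

    def __call__(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        tags = []
        for tok in tokens:
            low = tok.lower()
            if re.fullmatch(r"[^\w\s]+", tok) or tok in ("<url>", "<user>"):
                tag = "."
            elif low in self._MODALS:
                tag = "MD"
            elif low in self._BE_PAST or low in self._IRREGULAR_PAST:
                tag = "VBD"
            elif low in self._BE_PRESENT:
                tag = "VBP"
            elif low.endswith("ed") and len(low) > 3:
                tag = "VBD"
            elif low.endswith("ing") and len(low) > 4:
                tag = "VBG"
            elif low in self._COMMON_VERBS:
                tag = "VB"
            elif low in self._PRONOUNS:
                tag = "PRP"
            elif low.isdigit():
                tag = "CD"
            else:
                tag = "NN"
            tags.append((tok, tag))
        return tags


# --- trainable weak models ---------------------------------------------------

class WeakModel:
    """A fitted full classifier over the three temporal classes (never abstains)."""

    def predict(self, tweet: Tweet) -> int:
        return self.predict_many([tweet])[0]

    def predict_many(self, tweets: Sequence[Tweet]) -> np.ndarray:
        raise NotImplementedError


class _SvmWeakModel(WeakModel):
    def __init__(self, vectorizer, clf):
        self._vectorizer = vectorizer
        self._clf = clf

    def predict_many(self, tweets: Sequence[Tweet]) -> np.ndarray:
        X = self._vectorizer.transform([" ".join(t.tokens) for t in tweets])
        return self._clf.predict(X).astype(np.intp)


class _BiLstmWeakModel(WeakModel):
    def __init__(self, vocab, embed, fwd, bwd, head, max_len):
        self._vocab = vocab
        self._embed = embed
        self._fwd, self._bwd = fwd, bwd
        self._head = head
        self._max_len = max_len

    def _encode(self, tweets: Sequence[Tweet]) -> nn.Tensor:
        idx, mask = encode_token_ids([t.tokens for t in tweets], self._vocab, self._max_len)
        emb = nn.embedding(self._embed, idx)
        h_f = nn.run_recurrent(self._fwd, emb, mask)
        h_b = nn.run_recurrent(self._bwd, emb, mask, reverse=True)
        return self._head(nn.concat([h_f, h_b], axis=1))

    def predict_many(self, tweets: Sequence[Tweet], batch_size: int = 512) -> np.ndarray:
        out = []
        for start in range(0, len(tweets), batch_size):
            logits = self._encode(tweets[start:start + batch_size]).data
            out.append(logits.argmax(axis=1).astype(np.intp) + 1)
        return np.concatenate(out)


def build_vocab(token_lists: Iterable[Sequence[str]],
                specials: Sequence[str] = ("<pad>", "<unk>")) -> dict[str, int]:
    vocab = {tok: i for i, tok in enumerate(specials)}
    for tokens in token_lists:
        for tok in tokens:
            vocab.setdefault(tok, len(vocab))
    return vocab


def encode_token_ids(token_lists: Sequence[Sequence[str]], vocab: dict[str, int],
                     max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad/right-truncate token sequences to (B, max_len) index + mask arrays."""
    B = len(token_lists)
    idx = np.zeros((B, max_len), dtype=np.intp)
    mask = np.zeros((B, max_len), dtype=np.float64)
    unk = vocab.get("<unk>", 0)
    for b, tokens in enumerate(token_lists):
        for t, tok in enumerate(tokens[:max_len]):
            idx[b, t] = vocab.get(tok, unk)
            mask[b, t] = 1.0
    return idx, mask


def train_weak_model(kind: Literal["svm", "bilstm"],
                     seed_corpus: Sequence[TemporalRecord],
                     config: dict | None = None) -> WeakModel:
    """Fit a weak full classifier on a small labeled seed corpus.

    ``svm`` is a linear SVM on tf-idf unigrams/bigrams; ``bilstm`` is a
    bidirectional LSTM over learned embeddings with a softmax head.
    """
    config = dict(config or {})
    present = {r.temporal_class for r in seed_corpus}
    missing = set(TEMPORAL_CLASSES) - present
    if missing:
        raise ValueError(f"seed corpus lacks class(es): {sorted(missing)}")
    y = np.array([TEMPORAL_CLASSES[r.temporal_class] for r in seed_corpus], dtype=np.intp)
    tweets = [r.tweet for r in seed_corpus]

    if kind == "svm":
        from sklearn.feature_extraction.text import TfidfVectorizer
        from sklearn.svm import LinearSVC
        vectorizer = TfidfVectorizer(ngram_range=(1, 2), token_pattern=r"\S+")
        X = vectorizer.fit_transform([" ".join(t.tokens) for t in tweets])
        clf = LinearSVC(C=config.get("C", 1.0), random_state=config.get("seed", 0))
        clf.fit(X, y)
        return _SvmWeakModel(vectorizer, clf)

    if kind == "bilstm":
        rng = np.random.default_rng(config.get("seed", 0))
        max_len = config.get("max_len", 50)
        embed_dim = config.get("embedding_dim", 32)
        hidden = config.get("recurrent_units", 16)
        epochs = config.get("epochs", 60)
        lr = config.get("learning_rate", 0.02)
        vocab = build_vocab([t.tokens for t in tweets])
        embed = nn.Tensor(rng.normal(0.0, 0.1, size=(len(vocab), embed_dim)),
                          requires_grad=True)
        fwd = nn.LSTMCell(rng, embed_dim, hidden)
        bwd = nn.LSTMCell(rng, embed_dim, hidden)
        head = nn.Dense(rng, 2 * hidden, NUM_CLASSES)
        model = _BiLstmWeakModel(vocab, embed, fwd, bwd, head, max_len)
        params = [embed, *fwd.params(), *bwd.params(), *head.params()]
        opt = nn.RMSProp(params, lr=lr)
        for _ in range(epochs):
            opt.zero_grad()
            loss = nn.softmax_cross_entropy(model._encode(tweets), y - 1)
            loss.backward()
            opt.step()
        return model

    raise ValueError(f"unknown weak-model kind {kind!r}")


def build_label_matrix(tweets: Sequence[Tweet],
                       labeling_functions: Sequence[tuple[str, Callable[[Tweet], int]]]
                       ) -> LabelMatrix:
    """Apply each labeling function to each tweet.

    An LF that raises on a tweet is recorded as an abstain and logged; the
    matrix is deterministic for deterministic LFs.
    """
    if not labeling_functions:
        raise ValueError("at least one labeling function is required")
    M, L = len(tweets), len(labeling_functions)
    entries = np.zeros((M, L), dtype=np.intp)
    for q, (name, lf) in enumerate(labeling_functions):
        many = getattr(lf, "predict_many", None) or getattr(
            getattr(lf, "__self__", None), "predict_many", None)
        if many is not None:  # weak models label whole batches at once
            try:
                entries[:, q] = many(tweets)
            except Exception:
                logger.warning("weak model %s failed; column abstains", name,
                               exc_info=True)
            continue
        for p, tweet in enumerate(tweets):
            try:
                entries[p, q] = lf(tweet)
            except Exception:  # noqa: BLE001 - LF failures degrade to abstain
                logger.warning("LF %s failed on tweet %s; recording abstain",
                               name, tweet.id, exc_info=True)
                entries[p, q] = ABSTAIN
    return LabelMatrix(entries, [name for name, _ in labeling_functions])
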