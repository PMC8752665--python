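"""Data model, tokenization and readers/writers for tweet corpora.

File formats are deliberately plain: TSV/JSONL tweet tables, TSV emotion
files (ordinal 0-3 or real [0,1] intensity), two-column temporal lexicons,
and GloVe-style word-vector text files.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

TEMPORAL_CLASS_NAMES = ("past", "present", "future")
EMOTION_CLASS_NAMES = ("joy", "sadness", "anger", "fear")

URL_TOKEN = "<url>"
MENTION_TOKEN = "<user>"

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#(\w+)")
# words (incl. apostrophes), placeholder tokens, or runs of punctuation
_TOKEN_RE = re.compile(r"<url>|<user>|[\w']+|[^\w\s]+")


@dataclass
class Tweet:
    """A single tweet with its deterministic token stream."""

    id: str
    text: str
    user_id: str | None = None
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("tweet id must be non-empty")
        if not self.tokens:
            self.tokens = preprocess(self.text)


@dataclass
class TemporalRecord:
    """A tweet paired with a temporal-orientation label."""

    tweet: Tweet
    temporal_class: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.temporal_class not in TEMPORAL_CLASS_NAMES:
            raise ValueError(f"unknown temporal class {self.temporal_class!r}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class EmotionRecord:
    """A tweet with an emotion class and a real-valued intensity in [0, 1]."""

    tweet: Tweet
    emotion_class: str
    intensity: float
    intensity_ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.emotion_class not in EMOTION_CLASS_NAMES:
            raise ValueError(f"unknown emotion class {self.emotion_class!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity {self.intensity} outside [0, 1]")
        if self.intensity_ordinal is not None:
            expected = convert_ordinal_intensity(self.intensity_ordinal)
            if abs(expected - self.intensity) > 1e-12:
                raise ValueError(
                    f"intensity {self.intensity} inconsistent with ordinal "
                    f"{self.intensity_ordinal} (expected {expected})"
                )


@dataclass
class Lexicon:
    """Case-insensitive token -> temporal-class map."""

    entries: dict[str, str]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        normalized = {}
        for token, cls in self.entries.items():
            if cls not in TEMPORAL_CLASS_NAMES:
                raise ValueError(f"lexicon {self.name!r}: bad class {cls!r} for {token!r}")
            normalized[token.lower()] = cls
        self.entries = normalized

    def lookup(self, token: str) -> str | None:
        return self.entries.get(token.lower())


def preprocess(text: str) -> list[str]:
    """Tokenize a raw tweet deterministically.

    Lowercases; replaces URLs with ``<url>`` and @-mentions with ``<user>``;
    strips the ``#`` of hashtags but keeps the word; keeps punctuation runs
    (and hence emoticons/emoji) as single tokens. Idempotent on re-joined
    already-normalized streams.
    """
    if not text:
        return []
    text = _URL_RE.sub(URL_TOKEN, text)
    text = _MENTION_RE.sub(MENTION_TOKEN, text)
    text = _HASHTAG_RE.sub(r"\1", text)
    return [t.lower() if t not in (URL_TOKEN, MENTION_TOKEN) else t
            for t in _TOKEN_RE.findall(text)]


def convert_ordinal_intensity(ei_oc: int) -> float:
    """Map an ordinal emotion-intensity annotation (0-3) to [0, 1].

    Uses the affine conversion ``ei_oc * 0.25 + 0.125``, placing each
    ordinal level at the midpoint of one of the four intensity bins.
    """
    if ei_oc not in (0, 1, 2, 3):
        raise ValueError(f"ordinal intensity must be in {{0,1,2,3}}, got {ei_oc!r}")
    return ei_oc * 0.25 + 0.125


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate tweet id {i!r}")
        seen.add(i)


def read_tweets(path: str | Path, format: Literal["tsv", "jsonl"] = "tsv") -> list[Tweet]:
    """Read a tweet table (columns: id, user_id, text)."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("id", "text"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        rows = df.to_dict("records")
    elif format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
                if "id" not in rec or "text" not in rec:
                    raise ValueError(f"{path}:{lineno}: missing required key 'id' or 'text'")
                rows.append(rec)
    else:
        raise ValueError(f"unknown tweet-table format {format!r}")
    _check_unique_ids([str(r["id"]) for r in rows])
    return [
        Tweet(id=str(r["id"]), text=str(r.get("text", "")),
              user_id=(str(r["user_id"]) if r.get("user_id") not in (None, "") else None))
        for r in rows
    ]


def write_tweets(tweets: Iterable[Tweet], path: str | Path,
                 format: Literal["tsv", "jsonl"] = "tsv") -> None:
    path = Path(path)
    recs = [{"id": t.id, "user_id": t.user_id or "", "text": t.text} for t in tweets]
    if format == "tsv":
        pd.DataFrame(recs, columns=["id", "user_id", "text"]).to_csv(path, sep="\t", index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in recs:
                fh.write(json.dumps(r) + "\n")
    else:
        raise ValueError(f"unknown tweet-table format {format!r}")


def read_emotion_file(path: str | Path,
                      dialect: Literal["ordinal", "real"] = "real") -> list[EmotionRecord]:
    """Read a TSV emotion file with columns id, text, emotion, intensity.

    In the ``ordinal`` dialect intensity is an integer 0-3 and each record
    carries both the ordinal value and its converted real intensity.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "text", "emotion", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    _check_unique_ids(list(df["id"]))
    records = []
    for _, row in df.iterrows():
        tweet = Tweet(id=row["id"], text=row["text"])
        emotion = row["emotion"].strip().lower()
        if emotion not in EMOTION_CLASS_NAMES:
            raise ValueError(f"{path}: unsupported emotion class {row['emotion']!r}")
        if dialect == "ordinal":
            ordinal = int(row["intensity"])
            rec = EmotionRecord(tweet, emotion,
                                convert_ordinal_intensity(ordinal), intensity_ordinal=ordinal)
        elif dialect == "real":
            rec = EmotionRecord(tweet, emotion, float(row["intensity"]))
        else:
            raise ValueError(f"unknown emotion-file dialect {dialect!r}")
        records.append(rec)
    return records


def write_emotion_file(records: Iterable[EmotionRecord], path: str | Path) -> None:
    rows = [{"id": r.tweet.id, "text": r.tweet.text,
             "emotion": r.emotion_class, "intensity": r.intensity} for r in records]
    pd.DataFrame(rows, columns=["id", "text", "emotion", "intensity"]).to_csv(
        Path(path), sep="\t", index=False)


def read_lexicon(path: str | Path, name: str | None = None) -> Lexicon:
    """Read a two-column TSV lexicon: token <tab> past|present|future."""
    path = Path(path)
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            entries[parts[0]] = parts[1]
    return Lexicon(entries, name=name or path.stem)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for token, cls in sorted(lexicon.entries.items()):
            fh.write(f"{token}\t{cls}\n")


def read_word_vectors(path: str | Path) -> tuple[dict[str, int], np.ndarray]:
    """Read a GloVe-style plain-text vector file.

    Returns (token -> row index, matrix). All lines must share one dimension.
    """
    tokens: dict[str, int] = {}
    vectors: list[np.ndarray] = []
    dim: int | None = None
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"{path}:{lineno}: vector dimension {vec.size} != {dim}")
            tokens[parts[0]] = len(vectors)
            vectors.append(vec)
    if dim is None:
        raise ValueError(f"{path}: empty word-vector file")
    return tokens, np.vstack(vectors)


def write_word_vectors(table: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for token, vec in table.items():
            fh.write(token + " " + " ".join(f"{x:.6g}" for x in np.asarray(vec)) + "\n")
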