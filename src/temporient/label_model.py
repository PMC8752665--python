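"""Factor-graph generative model over weak labels.

The model scores a label-matrix row Lambda_p together with a candidate true
class y through three indicator factor families:

* accuracy      phi^Acc_q  = 1{Lambda_pq = y}        (one weight per LF)
* propensity    phi^Lab_q  = 1{Lambda_pq != abstain} (one weight per LF)
* correlation   phi^Corr_qr = 1{Lambda_pq = Lambda_pr} for (q, r) in the
  dependency set S (one weight per pair)

with the joint ``rho_z(Lambda_p, y) = exp(w . phi_p) / U`` normalized exactly
over all (K+1)^L possible rows times K classes. Training minimizes the
negative log marginal likelihood of the observed matrix (the true classes are
latent and summed out); the posterior over classes given each observed row
supplies probabilistic training labels.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from temporient.corpus_io import TemporalRecord, Tweet
from temporient.weak_labelers import ABSTAIN, CLASS_NAMES, LabelMatrix

logger = logging.getLogger(__name__)

MAX_EXACT_L = 10  # (K+1)^L normalizer enumeration cap


@dataclass(frozen=True)
class CorrelationSet:
    """Unordered LF index pairs modeled as statistically dependent."""

    pairs: frozenset[tuple[int, int]] = frozenset()

    def __init__(self, pairs=()):  # accept any iterable, canonicalize order
        canon = set()
        for q, r in pairs:
            if q == r:
                raise ValueError(f"self-pair ({q}, {r}) not allowed")
            canon.add((min(q, r), max(q, r)))
        object.__setattr__(self, "pairs", frozenset(canon))

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FactorWeights:
    """Weights for the three dependency types (accuracy, propensity, correlation)."""

    acc: np.ndarray
    lab: np.ndarray
    corr: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=np.float64)
        self.lab = np.asarray(self.lab, dtype=np.float64)
        vals = np.concatenate([self.acc, self.lab, np.fromiter(self.corr.values(), float,
                                                               count=len(self.corr))])
        if not np.all(np.isfinite(vals)):
            raise ValueError("factor weights must be finite")

    @classmethod
    def zeros(cls, n_lfs: int, structure: CorrelationSet) -> "FactorWeights":
        return cls(np.zeros(n_lfs), np.zeros(n_lfs),
                   {pair: 0.0 for pair in structure.sorted_pairs()})

    def as_vector(self, structure: CorrelationSet) -> np.ndarray:
        return np.concatenate([self.acc, self.lab,
                               [self.corr[p] for p in structure.sorted_pairs()]])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_lfs: int,
                    structure: CorrelationSet) -> "FactorWeights":
        pairs = structure.sorted_pairs()
        return cls(vec[:n_lfs], vec[n_lfs:2 * n_lfs],
                   dict(zip(pairs, vec[2 * n_lfs:].tolist())))

    def to_json(self, path: str | Path, structure: CorrelationSet) -> None:
        payload = {
            "acc": self.acc.tolist(),
            "lab": self.lab.tolist(),
            "corr": {f"{q},{r}": w for (q, r), w in sorted(self.corr.items())},
            "structure": structure.sorted_pairs(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["FactorWeights", "CorrelationSet"]:
        payload = json.loads(Path(path).read_text())
        corr = {tuple(int(x) for x in k.split(",")): v for k, v in payload["corr"].items()}
        return (cls(payload["acc"], payload["lab"], corr),
                CorrelationSet(tuple(p) for p in payload["structure"]))


@dataclass
class PosteriorLabels:
    """Row-stochastic posterior class probabilities plus argmax hard labels."""

    probs: np.ndarray
    hard: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    def to_tsv(self, path: str | Path, tweet_ids: Sequence[str]) -> None:
        df = pd.DataFrame(self.probs, columns=["p_past", "p_present", "p_future"])
        df.insert(0, "id", list(tweet_ids))
        df["hard_label"] = [CLASS_NAMES[h] for h in self.hard]
        df.to_csv(Path(path), sep="\t", index=False)


def factor_features(row: np.ndarray, y: int, structure: CorrelationSet) -> np.ndarray:
    """Concatenated indicator features [acc | lab | corr] for one row and class y."""
    row = np.asarray(row)
    if not 1 <= y:
        raise ValueError(f"candidate class must be >= 1, got {y}")
    acc = (row == y).astype(np.float64)
    lab = (row != ABSTAIN).astype(np.float64)
    corr = np.array([1.0 if row[q] == row[r] else 0.0
                     for q, r in structure.sorted_pairs()])
    return np.concatenate([acc, lab, corr])


def _feature_tensor(rows: np.ndarray, structure: CorrelationSet,
                    num_classes: int) -> np.ndarray:
    """Features for every (row, y): shape (n_rows, K, 2L + |S|), vectorized."""
    rows = np.asarray(rows)
    n, L = rows.shape
    K = num_classes
    feats = np.empty((n, K, 2 * L + len(structure)))
    for y in range(1, K + 1):
        feats[:, y - 1, :L] = rows == y
    feats[:, :, L:2 * L] = (rows != ABSTAIN)[:, None, :]
    for j, (q, r) in enumerate(structure.sorted_pairs()):
        feats[:, :, 2 * L + j] = (rows[:, q] == rows[:, r])[:, None]
    return feats


def _all_rows(L: int, num_classes: int) -> np.ndarray:
    """Every possible label-matrix row: (K+1)^L x L."""
    if L > MAX_EXACT_L:
        raise ValueError(
            f"exact normalizer enumeration capped at L <= {MAX_EXACT_L}, got L = {L}")
    return np.array(list(itertools.product(range(num_classes + 1), repeat=L)),
                    dtype=np.intp)


def _log_partition_terms(weights: FactorWeights, structure: CorrelationSet,
                         L: int, K: int) -> tuple[np.ndarray, np.ndarray]:
    """(scores over all rows x K, feature tensor) for the exact normalizer."""
    all_rows = _all_rows(L, K)
    feats = _feature_tensor(all_rows, structure, K)
    w = weights.as_vector(structure)
    return feats @ w, feats


def _logsumexp(a: np.ndarray, axis=None) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    out = np.log(np.exp(a - m).sum(axis=axis, keepdims=True)) + m
    return np.squeeze(out, axis=axis) if axis is not None else out.reshape(())


def neg_log_marginal_likelihood(weights: FactorWeights, matrix: LabelMatrix,
                                structure: CorrelationSet | None = None) -> float:
    """Exact negative log marginal likelihood of the observed label matrix.

    The true class of each tweet is latent and summed out; rows are
    independent, so the joint marginal factorizes per tweet with a shared
    single-row normalizer.
    """
    structure = structure or CorrelationSet()
    M, L = matrix.shape
    K = matrix.num_classes
    obs_feats = _feature_tensor(matrix.entries, structure, K)
    w = weights.as_vector(structure)
    obs_scores = obs_feats @ w                      # (M, K)
    norm_scores, _ = _log_partition_terms(weights, structure, L, K)
    log_u = _logsumexp(norm_scores.ravel())
    return float(M * log_u - _logsumexp(obs_scores, axis=1).sum())


def _nll_and_grad(w: np.ndarray, obs_feats: np.ndarray, norm_feats: np.ndarray,
                  l2: float) -> tuple[float, np.ndarray]:
    M = obs_feats.shape[0]
    obs_scores = obs_feats @ w
    obs_ls = _logsumexp(obs_scores, axis=1)
    post = np.exp(obs_scores - obs_ls[:, None])
    e_obs = np.einsum("mk,mkf->f", post, obs_feats)

    flat = norm_feats.reshape(-1, norm_feats.shape[-1])
    scores = flat @ w
    log_u = _logsumexp(scores)
    model_p = np.exp(scores - log_u)
    e_model = model_p @ flat

    nll = M * log_u - obs_ls.sum() + 0.5 * l2 * (w @ w)
    grad = M * (e_model) - e_obs + l2 * w
    return float(nll), grad


def fit_generative(matrix: LabelMatrix, structure: CorrelationSet | None = None,
                   opt_config: dict | None = None) -> FactorWeights:
    """Fit factor weights by full-batch gradient descent on the exact NLL.

    Deterministic (zero initialization); raises if the objective keeps
    increasing for a full patience window, which indicates a too-large step.
    """
    structure = structure or CorrelationSet()
    cfg = {"learning_rate": 0.05, "iterations": 500, "l2": 1e-4,
           "patience": 20, "seed": 0}
    cfg.update(opt_config or {})
    if not np.any(matrix.entries != ABSTAIN):
        raise ValueError("label matrix contains no non-abstain entries")
    M, L = matrix.shape
    K = matrix.num_classes
    obs_feats = _feature_tensor(matrix.entries, structure, K)
    norm_feats = _feature_tensor(_all_rows(L, K), structure, K)
    w = FactorWeights.zeros(L, structure).as_vector(structure)

    lr = cfg["learning_rate"] / max(M, 1)  # step scale invariant to corpus size
    best_nll = np.inf
    bad_steps = 0
    nll_trace = []
    for it in range(cfg["iterations"]):
        nll, grad = _nll_and_grad(w, obs_feats, norm_feats, cfg["l2"])
        nll_trace.append(nll)
        if nll < best_nll - 1e-12:
            best_nll = nll
            bad_steps = 0
        else:
            bad_steps += 1
            if bad_steps > cfg["patience"]:
                raise RuntimeError(
                    "generative-model NLL failed to decrease for "
                    f"{cfg['patience']} consecutive iterations (at iter {it}); "
                    "try a smaller learning_rate")
        w = w - lr * grad
    logger.info("fit_generative: NLL %0.4f -> %0.4f over %d iterations",
                nll_trace[0], nll_trace[-1], len(nll_trace))
    weights = FactorWeights.from_vector(w, L, structure)
    weights.nll_trace = nll_trace  # type: ignore[attr-defined]
    return weights


def posterior_labels(weights: FactorWeights, matrix: LabelMatrix,
                     structure: CorrelationSet | None = None) -> PosteriorLabels:
    """Posterior class probabilities per row, softmax of the factor scores.

    All-abstain rows get the uniform posterior. Hard labels are the row
    argmax; exact ties break by class order past < present < future.
    """
    structure = structure or CorrelationSet()
    feats = _feature_tensor(matrix.entries, structure, matrix.num_classes)
    scores = feats @ weights.as_vector(structure)
    probs = np.exp(scores - _logsumexp(scores, axis=1)[:, None])
    probs /= probs.sum(axis=1, keepdims=True)
    return PosteriorLabels(probs, probs.argmax(axis=1) + 1)


def _emission_probs(weights: FactorWeights, K: int) -> np.ndarray:
    """Per-LF conditional emission p(value | true class) implied by an
    independent (accuracy + propensity only) factor model: (L, K, K+1)."""
    L = len(weights.acc)
    probs = np.empty((L, K, K + 1))
    for q in range(L):
        for y in range(K):
            row = np.full(K + 1, np.exp(weights.lab[q]))
            row[0] = 1.0  # abstain carries no factor
            row[y + 1] = np.exp(weights.acc[q] + weights.lab[q])
            probs[q, y] = row / row.sum()
    return probs


def estimate_structure(matrix: LabelMatrix, config: dict | None = None) -> CorrelationSet:
    """Select dependent LF pairs by agreement lift over an independent fit.

    A dependency-free model (accuracy and propensity factors only) is fitted
    first; conditioned on the latent class it makes all LFs independent, so
    it predicts a pairwise agreement rate from the fitted weights alone. A
    pair (q, r) enters S when its observed agreement rate, over rows where
    both LFs commit, exceeds that prediction by more than ``threshold``
    (default 0.15) — agreement the shared latent class cannot explain.
    Matrices with fewer than ``min_rows`` rows (default 20) yield the empty
    set with a warning, as the empirical rates are too noisy.
    """
    cfg = {"threshold": 0.15, "min_rows": 20, "fit": {}}
    cfg.update(config or {})
    M, L = matrix.shape
    if M < cfg["min_rows"]:
        logger.warning("estimate_structure: only %d rows (< %d); returning empty set",
                       M, cfg["min_rows"])
        return CorrelationSet()
    entries = matrix.entries
    if not np.any(entries != ABSTAIN) or L < 2:
        return CorrelationSet()
    K = matrix.num_classes
    indep = fit_generative(matrix, CorrelationSet(), cfg["fit"])
    emission = _emission_probs(indep, K)
    pairs = []
    for q in range(L):
        for r in range(q + 1, L):
            both = (entries[:, q] != ABSTAIN) & (entries[:, r] != ABSTAIN)
            if both.sum() < cfg["min_rows"]:
                continue
            observed = (entries[both, q] == entries[both, r]).mean()
            # model-implied agreement, conditional on both labeling
            agree = both_label = 0.0
            for y in range(K):
                pq, pr = emission[q, y], emission[r, y]
                agree += (pq[1:] @ pr[1:]) / K
                both_label += (1.0 - pq[0]) * (1.0 - pr[0]) / K
            expected = agree / both_label if both_label > 0 else 0.0
            if observed - expected > cfg["threshold"]:
                pairs.append((q, r))
    return CorrelationSet(pairs)


def select_balanced_training(posterior: PosteriorLabels, tweets: Sequence[Tweet],
                             n: int) -> list[TemporalRecord]:
    """Pick the n highest-confidence tweets, class-balanced.

    Per-class quotas split n evenly; any remainder goes to the earlier
    classes in the order past, present, future. Within a class, tweets are
    ranked by posterior probability of that class; all-abstain rows (exactly
    uniform posteriors) are excluded.
    """
    if len(tweets) != posterior.probs.shape[0]:
        raise ValueError("tweets and posterior rows must align")
    K = posterior.probs.shape[1]
    base, rem = divmod(n, K)
    quotas = [base + (1 if k < rem else 0) for k in range(K)]
    uniform = np.all(np.abs(posterior.probs - 1.0 / K) < 1e-12, axis=1)
    records: list[TemporalRecord] = []
    for k, quota in enumerate(quotas):
        cls = k + 1
        members = np.where((posterior.hard == cls) & ~uniform)[0]
        if len(members) < quota:
            achievable = K * min(
                np.sum((posterior.hard == c + 1) & ~uniform) for c in range(K))
            raise ValueError(
                f"class {CLASS_NAMES[cls]!r} has only {len(members)} candidates "
                f"for a quota of {quota}; largest achievable balanced n is {achievable}")
        conf = posterior.probs[members, k]
        order = members[np.argsort(-conf, kind="stable")][:quota]
        records.extend(
            TemporalRecord(tweets[i], CLASS_NAMES[cls],
                           confidence=float(posterior.probs[i, k]))
            for i in order)
    return records
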