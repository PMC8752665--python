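"""Independent brute-force oracles shared by the label-model tests.

These deliberately use naive python loops over explicit enumerations so
they share no code path with the vectorized implementation they check.
"""

import itertools

import numpy as np

from temporient import label_model as lm
from temporient.weak_labelers import LabelMatrix


def brute_force_nll(weights, matrix, structure, K=3):
    """-log sum_Y rho(Lambda, Y) by enumerating all K^M joint assignments."""
    M, L = matrix.shape
    w = weights.as_vector(structure)
    U = 0.0
    for row in itertools.product(range(K + 1), repeat=L):
        for y in range(1, K + 1):
            U += np.exp(w @ lm.factor_features(np.array(row), y, structure))
    total = 0.0
    for assignment in itertools.product(range(1, K + 1), repeat=M):
        score = sum(w @ lm.factor_features(matrix.entries[p], y, structure)
                    for p, y in enumerate(assignment))
        total += np.exp(score) / U ** M
    return -np.log(total)


def brute_force_posterior(weights, matrix, structure, K=3):
    """Per-row softmax over the K per-class feature scores."""
    w = weights.as_vector(structure)
    out = np.empty((matrix.shape[0], K))
    for p in range(matrix.shape[0]):
        scores = [w @ lm.factor_features(matrix.entries[p], y, structure)
                  for y in range(1, K + 1)]
        e = np.exp(np.array(scores) - max(scores))
        out[p] = e / e.sum()
    return out


def random_instance(rng, max_m=5, max_l=4):
    M = int(rng.integers(1, max_m + 1))
    L = int(rng.integers(1, max_l + 1))
    matrix = LabelMatrix(rng.integers(0, 4, size=(M, L)),
                         [f"lf{q}" for q in range(L)])
    pairs = []
    if L >= 2 and rng.random() < 0.5:
        pairs = [(0, 1)]
    structure = lm.CorrelationSet(pairs)
    weights = lm.FactorWeights(
        rng.normal(0, 0.7, L), rng.normal(0, 0.7, L),
        {p: float(rng.normal(0, 0.7)) for p in structure.sorted_pairs()})
    return matrix, structure, weights


def majority_vote(entries, K=3):
    votes = np.stack([(entries == y).sum(axis=1) for y in range(1, K + 1)], axis=1)
    return votes.argmax(axis=1) + 1
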