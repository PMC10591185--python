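"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the textbook definition of the quantity, with
plain Python loops and no reuse of the package's code paths.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

import numpy as np


def amip_oracle(seq: str, k: int) -> float:
    """Mutual information (bits) of the lag-k ordered pair distribution.

    Double sum over the 16 ordered nucleotide pairs, with marginals taken
    from the same lag-k joint; empty cells contribute zero.
    """
    pairs = [(seq[i], seq[i + k]) for i in range(len(seq) - k)]
    n = len(pairs)
    joint = Counter(pairs)
    px = Counter(x for x, _ in pairs)
    py = Counter(y for _, y in pairs)
    mi = 0.0
    for x in "ACGT":
        for y in "ACGT":
            c = joint.get((x, y), 0)
            if c == 0:
                continue
            p = c / n
            mi += p * math.log2(p / ((px[x] / n) * (py[y] / n)))
    return mi


def majority_oracle(votes: Sequence[int]) -> bool:
    """True iff strictly more than half of the votes are positive."""
    return sum(votes) > len(votes) / 2


def auc_oracle(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: fraction of positive/negative pairs ranked
    correctly, ties counted one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def mcc_oracle(labels: Sequence[int], calls: Sequence[int]) -> float:
    """MCC as the Pearson correlation between the two binary vectors."""
    y = np.asarray(labels, dtype=float)
    c = np.asarray(calls, dtype=float)
    if y.std() == 0 or c.std() == 0:
        return 0.0
    return float(np.corrcoef(y, c)[0, 1])


def topsis_oracle(matrix: np.ndarray, weights: Sequence[float],
                  directions: Sequence[str]) -> np.ndarray:
    """Closeness coefficients by the textbook TOPSIS steps, loop by loop."""
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    V = np.zeros_like(X)
    for j in range(m):
        norm = math.sqrt(sum(X[i, j] ** 2 for i in range(n)))
        if norm > 0:
            for i in range(n):
                V[i, j] = X[i, j] / norm * w[j]
    ideal = [max(V[:, j]) if directions[j] == "benefit" else min(V[:, j])
             for j in range(m)]
    anti = [min(V[:, j]) if directions[j] == "benefit" else max(V[:, j])
            for j in range(m)]
    scores = np.empty(n)
    for i in range(n):
        d_plus = math.sqrt(sum((V[i, j] - ideal[j]) ** 2 for j in range(m)))
        d_minus = math.sqrt(sum((V[i, j] - anti[j]) ** 2 for j in range(m)))
        scores[i] = d_minus / (d_plus + d_minus) if d_plus + d_minus else 0.5
    return scores
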