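"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written the naive way (explicit loops, third-party
estimators) and deliberately shares no code with the library path it
checks.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import mutual_info_score

from dbpred.sequence_io import AMINO_ACIDS


def naive_autocovariance(track: np.ndarray, lg_max: int) -> np.ndarray:
    """AC by explicit double loop over position pairs."""
    track = np.asarray(track, dtype=float)
    L = len(track)
    mean = sum(track) / L
    out = []
    for lg in range(1, lg_max + 1):
        acc = 0.0
        for j in range(L - lg):
            acc += (track[j] - mean) * (track[j + lg] - mean)
        out.append(acc / (L - lg))
    return np.array(out)


def brute_force_dpc(seq: str) -> np.ndarray:
    """Skip-dipeptide frequencies by enumerating every position pair."""
    L = len(seq)
    aa_pos = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    out = np.zeros((3, 20, 20))
    for s in (0, 1, 2):
        for p in range(L):
            q = p + s + 1
            if q < L:
                out[s, aa_pos[seq[p]], aa_pos[seq[q]]] += 1
    return (out / (L - 1)).reshape(-1)


def mi_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information in bits via scikit-learn's estimator."""
    return mutual_info_score(x, y) / np.log(2)


def mi_table_oracle(table: np.ndarray) -> float:
    """MI in bits of a contingency table, by expanding it into label vectors."""
    xs, ys = [], []
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            xs.extend([i] * int(table[i, j]))
            ys.extend([j] * int(table[i, j]))
    if not xs:
        return 0.0
    return mi_oracle(np.array(xs), np.array(ys))


def greedy_mid_oracle(states: np.ndarray, y: np.ndarray, top_k: int) -> list[int]:
    """Exhaustive greedy MID ranking on pre-discretized states.

    At each step every remaining feature's score is evaluated explicitly:
    relevance minus mean MI against all selected features; ties go to the
    smaller index.
    """
    d = states.shape[1]
    selected: list[int] = []
    remaining = list(range(d))
    for _ in range(top_k):
        best_j, best_score = None, None
        for j in remaining:
            rel = mi_oracle(states[:, j], y)
            red = (
                np.mean([mi_oracle(states[:, j], states[:, s]) for s in selected])
                if selected
                else 0.0
            )
            score = rel - red
            if best_score is None or score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def vote_oracle(votes, threshold: int = 6) -> int:
    """Count-and-compare majority rule."""
    return 1 if list(votes).count(1) > threshold else 0


def confusion_oracle(y_true, y_pred) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) by explicit iteration."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def auc_pair_oracle(y_true, scores) -> float:
    """AUC as the fraction of (positive, negative) pairs correctly ordered,
    counting ties as half."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    total = correct = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                correct += 1
            elif p == n:
                correct += 0.5
    return correct / total


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
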