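"""Independent reference implementations used only for cross-checking."""

import itertools

import numpy as np


def brute_force_matching(cost: np.ndarray) -> set:
    """Min-cost bipartite matching by permutation enumeration (n <= 6)."""
    n_rows, n_cols = cost.shape
    k = min(n_rows, n_cols)
    best, best_cost = None, np.inf
    for row_subset in itertools.permutations(range(n_rows), k):
        for col_subset in itertools.permutations(range(n_cols), k):
            total = sum(cost[r, c] for r, c in zip(row_subset, col_subset))
            if total < best_cost - 1e-12:
                best_cost = total
                best = set(zip(row_subset, col_subset))
    return best


def greedy_oracle(scores: np.ndarray) -> dict:
    """Literal step-by-step re-simulation of the printed 6-step role
    assignment: retrieve probabilities, take the global maximum, assign,
    remove the role from everyone else, renormalize, repeat."""
    probs = {
        t: {r: scores[t, r] for r in range(scores.shape[1])}
        for t in range(len(scores))
    }
    assignment = {}
    while probs and any(len(p) for p in probs.values()):
        best_t, best_r, best_v = None, None, -1.0
        for t in sorted(probs):
            for r in sorted(probs[t]):
                if probs[t][r] > best_v + 1e-15:
                    best_t, best_r, best_v = t, r, probs[t][r]
        assignment[best_t] = best_r
        del probs[best_t]
        for t in probs:
            probs[t].pop(best_r, None)
            total = sum(probs[t].values())
            if total > 0:
                probs[t] = {r: v / total for r, v in probs[t].items()}
    return assignment
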