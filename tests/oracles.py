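"""Independent brute-force oracles used only by the test suite.

Each re-derives a quantity by exhaustive enumeration or direct formula
evaluation, without sharing code paths with the package implementation.
"""

import itertools
import math

import numpy as np


def brute_force_concepts(incidence: np.ndarray) -> set[tuple[frozenset, frozenset]]:
    """All concepts as (extent-row-set, intent-col-set): close every attribute subset."""
    incidence = np.asarray(incidence, dtype=bool)
    n_obj, n_attr = incidence.shape
    concepts = set()
    for size in range(n_attr + 1):
        for subset in itertools.combinations(range(n_attr), size):
            extent = [i for i in range(n_obj) if all(incidence[i, j] for j in subset)]
            intent = [j for j in range(n_attr) if all(incidence[i, j] for i in extent)]
            concepts.add((frozenset(extent), frozenset(intent)))
    return concepts


def naive_connectivity(X: np.ndarray, labels: np.ndarray, L: int) -> float:
    """Direct neighbour enumeration with (distance, index) sorting."""
    m = len(X)
    total = 0.0
    for i in range(m):
        dists = sorted(
            (math.dist(X[i], X[j]), j) for j in range(m) if j != i
        )
        for rank, (_, j) in enumerate(dists[:L], start=1):
            if labels[i] != labels[j]:
                total += 1.0 / rank
    return total


def naive_silhouette(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Per-gene evaluation of (b - a)/max(a, b) with singleton -> 0."""
    m = len(X)
    s = []
    for i in range(m):
        own = [j for j in range(m) if labels[j] == labels[i] and j != i]
        if not own:
            s.append(0.0)
            continue
        a = sum(math.dist(X[i], X[j]) for j in own) / len(own)
        b = math.inf
        for c in range(k):
            if c == labels[i]:
                continue
            members = [j for j in range(m) if labels[j] == c]
            if members:
                b = min(b, sum(math.dist(X[i], X[j]) for j in members) / len(members))
        s.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(s))


def best_label_permutation_agreement(labels_ref, labels_other, k: int) -> int:
    """Max label agreement over all k! relabellings of labels_other."""
    best = -1
    for perm in itertools.permutations(range(k)):
        mapped = [perm[l] for l in labels_other]
        best = max(best, sum(int(a == b) for a, b in zip(labels_ref, mapped)))
    return best


def set_overlap_pct(a: set, b: set) -> float:
    return 100.0 * len(set(a) & set(b)) / max(len(a), len(b))
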