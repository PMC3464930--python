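"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in plain Python loops with math/Fraction
arithmetic, deliberately avoiding the package's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

from drem2.model_core import DremModel, SplitClassifier, StateNode


def naive_path_loglik(model: DremModel, X, feats) -> np.ndarray:
    """Per-gene, per-path joint log-likelihood by explicit enumeration."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    paths = model.paths()
    out = np.zeros((X.shape[0], len(paths)))
    for g in range(X.shape[0]):
        for li, path in enumerate(paths):
            ll = 0.0
            for node in path:
                x = X[g, node.t]
                if not math.isnan(x):
                    ll += -0.5 * math.log(2 * math.pi * node.var)
                    ll += -((x - node.mean) ** 2) / (2 * node.var)
            for parent, child in zip(path, path[1:]):
                if len(parent.children) > 1:
                    fvec = np.asarray(feats[child.t])[:, g]
                    scores = [
                        float(np.dot(w, fvec)) + float(b)
                        for w, b in zip(
                            parent.classifier.weights, parent.classifier.intercepts
                        )
                    ]
                    mx = max(scores)
                    denom = sum(math.exp(s - mx) for s in scores)
                    k = parent.children.index(child)
                    ll += scores[k] - mx - math.log(denom)
            out[g, li] = ll
    return out


def naive_posteriors(model: DremModel, X, feats) -> np.ndarray:
    L = naive_path_loglik(model, X, feats)
    out = np.zeros_like(L)
    for g in range(L.shape[0]):
        mx = L[g].max()
        w = np.exp(L[g] - mx)
        out[g] = w / w.sum()
    return out


def random_tree_model(rng: np.random.Generator, n_times=4, n_tfs=3, k_max=3):
    """A random tree-structured model with <= k_max children per node."""

    def grow(t: int) -> StateNode:
        node = StateNode(
            t, float(rng.normal(0, 2)), float(rng.uniform(0.3, 2.0))
        )
        if t < n_times - 1:
            k = int(rng.choice([1, 1, 2, 2, 3])) if k_max >= 3 else int(rng.choice([1, 2]))
            node.children = [grow(t + 1) for _ in range(k)]
            if k > 1:
                w = rng.normal(0, 1, size=(k, n_tfs))
                b = rng.normal(0, 1, size=k)
                w[0] = 0.0
                b[0] = 0.0
                node.classifier = SplitClassifier(w, b)
        return node

    root = grow(0)
    tf_ids = [f"TF{i}" for i in range(n_tfs)]
    return DremModel(root=root, tf_ids=tf_ids, n_times=n_times)


def hypergeom_upper_enum(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration of all n-subsets of [N]."""
    population = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)
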