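"""The tree-structured input-output HMM.

States form a tree with one level per time point: every root-to-leaf path is
a candidate expression trajectory, each state emits a univariate Gaussian
over the log2 ratio at its time point, and a node with several children (a
split) routes genes to the children through a multiclass logistic-regression
classifier over the gene's TF binding features for the transition into the
children's time point.  Child 0 of every split is the zero-weight softmax
reference class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, log_softmax

#: lower bound on every state variance (log2-ratio scale)
VAR_FLOOR = 1e-4

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class SplitClassifier:
    """Multiclass logistic regression routing genes to a split's children.

    ``weights`` is (n_children, n_features) and ``intercepts`` (n_children,);
    row 0 is identically zero (reference class).  P(child k | x) is the
    softmax of w_k . x + w_k0.
    """

    weights: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.weights.shape[0] != self.intercepts.shape[0]:
            raise ValueError("one weight vector and intercept per child required")

    @property
    def n_children(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def logits(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_children) matrix of linear scores."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != classifier's {self.n_features}"
            )
        return X @ self.weights.T + self.intercepts

    def log_probs(self, X: np.ndarray) -> np.ndarray:
        return log_softmax(self.logits(X), axis=1)

    def probs(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.log_probs(X))


def transition_probs(
    classifier: SplitClassifier | None, features: np.ndarray
) -> np.ndarray:
    """Probability over children for one gene's feature vector.

    Non-split nodes (no classifier) return the degenerate distribution (1.0).
    """
    if classifier is None:
        return np.ones(1)
    return classifier.probs(np.atleast_2d(features))[0]


@dataclass
class StateNode:
    """One hidden state: Gaussian emission at time ``t`` plus children."""

    t: int
    mean: float
    var: float
    children: list["StateNode"] = field(default_factory=list)
    classifier: SplitClassifier | None = None

    def __post_init__(self) -> None:
        if self.var < VAR_FLOOR:
            self.var = VAR_FLOOR

    @property
    def is_split(self) -> bool:
        return len(self.children) > 1

    def validate(self) -> None:
        if self.is_split and self.classifier is None:
            raise ValueError(f"split node at t={self.t} lacks a classifier")
        if self.is_split and self.classifier.n_children != len(self.children):
            raise ValueError("classifier arity != out-degree")
        if not self.is_split and self.classifier is not None:
            raise ValueError("non-split node carries a classifier")
        for c in self.children:
            if c.t != self.t + 1:
                raise ValueError("child time index must be parent's + 1")
            c.validate()


def emission_loglik(node: StateNode, x) -> np.ndarray:
    """Gaussian log density of observation(s) x under the state.

    Missing observations (NaN) are marginalized out and contribute 0.
    """
    x = np.asarray(x, dtype=float)
    out = -0.5 * (_LOG_2PI + math.log(node.var) + (x - node.mean) ** 2 / node.var)
    out = np.where(np.isnan(x), 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class DremModel:
    """A trained (or in-training) tree model.

    ``tf_ids`` fixes the feature order every split classifier is expressed
    in.  Leaves are ordered by depth-first traversal with children visited
    in index order; this ordering defines path/leaf indices everywhere.
    """

    root: StateNode
    tf_ids: list[str] = field(default_factory=list)
    n_times: int = 0
    config: dict = field(default_factory=dict)
    train_loglik: float | None = None
    trained: bool = False
    gene_ids: list[str] = field(default_factory=list)
    assignments: list[int] | None = None  # per-gene Viterbi leaf indices

    def __post_init__(self) -> None:
        if self.n_times == 0:
            self.n_times = 1 + max(n.t for n in self.states())
        self.root.validate()
        for leaf in self.leaves():
            if leaf.t != self.n_times - 1:
                raise ValueError("every leaf must sit at the last time point")

    # -- traversal ---------------------------------------------------------

    def states(self) -> list[StateNode]:
        out: list[StateNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    @property
    def n_states(self) -> int:
        return len(self.states())

    def leaves(self) -> list[StateNode]:
        return [n for n in self.states() if not n.children]

    def paths(self) -> list[list[StateNode]]:
        """Root-to-leaf node sequences, in leaf order."""
        out: list[list[StateNode]] = []

        def walk(node: StateNode, prefix: list[StateNode]) -> None:
            prefix = prefix + [node]
            if not node.children:
                out.append(prefix)
            else:
                for c in node.children:
                    walk(c, prefix)

        walk(self.root, [])
        return out

    def splits(self) -> list[StateNode]:
        """Split nodes in DFS order."""
        return [n for n in self.states() if n.is_split]

    def split_id(self, node: StateNode) -> str:
        """Stable identifier 't<time>.s<rank among splits at that time>'."""
        same_t = [s for s in self.splits() if s.t == node.t]
        return f"t{node.t}.s{same_t.index(node)}"

    # -- inference ---------------------------------------------------------

    def path_loglik(
        self, X: np.ndarray, features_by_time: dict[int, np.ndarray] | None
    ) -> np.ndarray:
        """(n_genes, n_leaves) matrix of per-path joint log likelihoods.

        ``X`` is genes x time points (NaN = missing); ``features_by_time``
        maps transition time t (1-based into the series) to the TF x gene
        feature matrix driving the classifiers of splits whose children sit
        at t.  Computed by a single pass down the tree, accumulating
        emission log densities and log transition probabilities.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_genes = X.shape[0]
        if X.shape[1] != self.n_times:
            raise ValueError(f"trajectories must have {self.n_times} time points")
        cols: list[np.ndarray] = []

        def walk(node: StateNode, acc: np.ndarray) -> None:
            acc = acc + emission_loglik(node, X[:, node.t])
            if not node.children:
                cols.append(acc)
                return
            if node.is_split:
                feats = self._features_at(features_by_time, node.t + 1, n_genes)
                logp = node.classifier.log_probs(feats)  # genes x children
                for k, child in enumerate(node.children):
                    walk(child, acc + logp[:, k])
            else:
                walk(node.children[0], acc)

        walk(self.root, np.zeros(n_genes))
        return np.column_stack(cols)

    def _features_at(
        self, features_by_time: dict[int, np.ndarray] | None, t: int, n_genes: int
    ) -> np.ndarray:
        d = len(self.tf_ids)
        if features_by_time is None or t not in features_by_time:
            if d == 0:
                return np.zeros((n_genes, 0))
            raise ValueError(f"no feature matrix for transition into time {t}")
        F = np.asarray(features_by_time[t], dtype=float)
        if F.shape != (d, n_genes):
            raise ValueError(
                f"feature matrix for t={t} has shape {F.shape}, "
                f"expected ({d}, {n_genes})"
            )
        return F.T  # genes x TFs

    def gene_loglik(
        self, X: np.ndarray, features_by_time: dict[int, np.ndarray] | None
    ) -> np.ndarray:
        """Total per-gene log likelihood: logsumexp over leaves."""
        return logsumexp(self.path_loglik(X, features_by_time), axis=1)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        ids: dict[int, int] = {}
        for i, n in enumerate(self.states()):
            ids[id(n)] = i
        for n in self.states():
            rec: dict = {
                "id": ids[id(n)],
                "t": n.t,
                "mean": n.mean,
                "var": n.var,
                "children": [ids[id(c)] for c in n.children],
            }
            if n.classifier is not None:
                rec["classifier"] = {
                    "weights": n.classifier.weights.tolist(),
                    "intercepts": n.classifier.intercepts.tolist(),
                }
            nodes.append(rec)
        return {
            "format": "drem2-model/1",
            "n_times": self.n_times,
            "tf_ids": list(self.tf_ids),
            "nodes": nodes,
            "train_loglik": self.train_loglik,
            "config": self.config,
            "gene_ids": list(self.gene_ids),
            "assignments": self.assignments,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DremModel":
        recs = {r["id"]: r for r in payload["nodes"]}
        built: dict[int, StateNode] = {}

        def build(i: int) -> StateNode:
            if i in built:
                return built[i]
            r = recs[i]
            node = StateNode(
                t=r["t"],
                mean=r["mean"],
                var=r["var"],
                children=[build(c) for c in r["children"]],
            )
            if "classifier" in r:
                node.classifier = SplitClassifier(
                    np.asarray(r["classifier"]["weights"]),
                    np.asarray(r["classifier"]["intercepts"]),
                )
            built[i] = node
            return node

        root = build(0)
        return cls(
            root=root,
            tf_ids=list(payload["tf_ids"]),
            n_times=payload["n_times"],
            config=payload.get("config", {}),
            train_loglik=payload.get("train_loglik"),
            trained=True,
            gene_ids=list(payload.get("gene_ids") or []),
            assignments=payload.get("assignments"),
        )


def chain_model(
    means: list[float], variances: list[float], tf_ids: list[str] | None = None
) -> DremModel:
    """Single-path model with one state per time point (no splits)."""
    nodes = [StateNode(t, m, v) for t, (m, v) in enumerate(zip(means, variances))]
    for a, b in zip(nodes, nodes[1:]):
        a.children = [b]
    return DremModel(root=nodes[0], tf_ids=list(tf_ids or []), n_times=len(nodes))
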