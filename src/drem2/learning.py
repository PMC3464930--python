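"""Model fitting: EM for parameters, greedy structure search for split
placement, and Viterbi gene-to-path assignment.

The E-step enumerates root-to-leaf paths exactly (trees here have few
leaves), the M-step re-estimates state means/variances by posterior-weighted
moments and refits each split's classifier by posterior-weighted, L2-
penalized maximum likelihood (a convex problem solved with L-BFGS, warm-
started from the current weights so the penalized likelihood never
decreases).  Structure search grows the tree greedily from the single-path
chain, one extra child at a time, scoring proposals by penalized training
likelihood.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_softmax, logsumexp, softmax

from drem2.model_core import (
    VAR_FLOOR,
    DremModel,
    SplitClassifier,
    StateNode,
    chain_model,
)

logger = logging.getLogger(__name__)

#: a state whose total posterior weight falls below this is degenerate
DEGENERATE_WEIGHT = 1e-8
#: quantiles used to initialize the new child chain of a split proposal
_PROPOSAL_QUANTILES = (0.25, 0.75)


@dataclass
class LearnConfig:
    """Fitting hyperparameters.

    ``structure_penalty`` (kappa) is the per-parameter cost subtracted from
    the training log-likelihood when scoring a topology (each state
    contributes its mean and variance, each split the weight vectors and
    intercepts of its non-reference children); ``None`` selects the BIC
    default 0.5*log(n_genes).  ``l2_penalty`` regularizes every split
    classifier's weight vectors (not intercepts).  ``min_path_genes``
    rejects splits that would leave a child with fewer Viterbi genes.
    """

    k_max: int = 3
    em_tol: float = 1e-3
    em_max_iter: int = 100
    l2_penalty: float = 1.0
    structure_penalty: float | None = None
    min_path_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.em_tol <= 0:
            raise ValueError("em_tol must be > 0")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")
        if self.k_max < 2:
            raise ValueError("k_max must allow binary splits")

    def kappa(self, n_genes: int) -> float:
        if self.structure_penalty is not None:
            return self.structure_penalty
        return 0.5 * math.log(max(n_genes, 2))


@dataclass
class TrainingTrace:
    """Per-iteration penalized log-likelihoods and structure-search events."""

    logliks: list[float] = field(default_factory=list)
    proposals: list[dict] = field(default_factory=list)


@dataclass
class PathAssignment:
    """Viterbi gene-to-leaf assignment."""

    leaf_indices: np.ndarray
    n_leaves: int
    gene_ids: list[str] | None = None

    def counts(self) -> np.ndarray:
        return np.bincount(self.leaf_indices, minlength=self.n_leaves)

    def genes_on_path(self, leaf: int) -> list[str]:
        if self.gene_ids is None:
            raise ValueError("assignment carries no gene ids")
        return [g for g, l in zip(self.gene_ids, self.leaf_indices) if l == leaf]


# ---------------------------------------------------------------------------
# weighted soft-label multiclass logistic regression
# ---------------------------------------------------------------------------


def fit_weighted_multiclass_logistic(
    X: np.ndarray,
    soft_labels: np.ndarray,
    l2_penalty: float,
    init: SplitClassifier | None = None,
) -> SplitClassifier:
    """Maximize sum_g sum_k q_gk * log softmax_k(x_g) - l2*||w||^2.

    ``soft_labels`` holds nonnegative per-gene masses over children (E-step
    posteriors; rows need not sum to 1 — the row sum acts as the gene's
    weight).  Child 0 is the fixed zero-weight reference, so only classes
    1..K-1 are parameterized; the problem is convex and solved to a gradient
    norm of about 1e-6.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = np.atleast_2d(np.asarray(soft_labels, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("non-finite classifier features")
    if np.any(M < 0):
        raise ValueError("soft labels must be nonnegative")
    n, d = X.shape
    K = M.shape[1]
    if K < 2:
        return SplitClassifier(np.zeros((1, d)), np.zeros(1))
    r = M.sum(axis=1)  # per-gene total mass
    Xb = np.hstack([X, np.ones((n, 1))])  # intercept column last

    def unpack(theta: np.ndarray) -> np.ndarray:
        # full (K, d+1) parameter block, row 0 zero
        full = np.zeros((K, d + 1))
        full[1:] = theta.reshape(K - 1, d + 1)
        return full

    def objective(theta: np.ndarray):
        full = unpack(theta)
        logits = Xb @ full.T  # n x K
        logp = log_softmax(logits, axis=1)
        ll = float(np.sum(M * logp))
        pen = l2_penalty * float(np.sum(full[1:, :d] ** 2))
        p = np.exp(logp)
        resid = r[:, None] * p - M  # n x K
        grad_full = resid.T @ Xb  # K x (d+1)
        grad_full[1:, :d] += 2.0 * l2_penalty * full[1:, :d]
        return -(ll - pen), grad_full[1:].ravel()

    if init is not None and init.weights.shape == (K, d):
        theta0 = np.hstack([init.weights[1:], init.intercepts[1:, None]]).ravel()
    else:
        theta0 = np.zeros((K - 1) * (d + 1))
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "gtol": 1e-6, "ftol": 1e-14},
    )
    full = unpack(res.x)
    return SplitClassifier(full[:, :d].copy(), full[:, d].copy())


def classifier_penalty(model: DremModel, l2_penalty: float) -> float:
    return l2_penalty * sum(
        float(np.sum(s.classifier.weights**2)) for s in model.splits()
    )


def n_parameters(model: DremModel) -> int:
    """Free parameters: (mean, var) per state plus each split's classifier
    rows for its non-reference children (weights and intercept)."""
    d = len(model.tf_ids)
    n = 2 * model.n_states
    for s in model.splits():
        n += (len(s.children) - 1) * (d + 1)
    return n


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _leaf_membership(model: DremModel) -> dict[int, list[int]]:
    """id(node) -> indices of leaves whose path passes through the node."""
    member: dict[int, list[int]] = {}
    for leaf_idx, path in enumerate(model.paths()):
        for node in path:
            member.setdefault(id(node), []).append(leaf_idx)
    return member


def em_fit(
    model: DremModel,
    X: np.ndarray,
    features_by_time: dict[int, np.ndarray] | None,
    cfg: LearnConfig,
) -> tuple[DremModel, TrainingTrace]:
    """Fit the parameters of a fixed tree structure by EM (in place).

    Stops when the penalized log-likelihood gain drops below ``em_tol`` or
    after ``em_max_iter`` iterations.  Deterministic: no randomness enters
    the updates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_genes = X.shape[0]
    if n_genes == 0:
        raise ValueError("empty gene set")
    trace = TrainingTrace()
    prev = -np.inf
    for _it in range(cfg.em_max_iter):
        L = model.path_loglik(X, features_by_time)  # n x leaves
        ll = float(np.sum(logsumexp(L, axis=1)))
        pen_ll = ll - classifier_penalty(model, cfg.l2_penalty)
        trace.logliks.append(pen_ll)
        model.train_loglik = ll
        if pen_ll - prev < cfg.em_tol and _it > 0:
            break
        prev = pen_ll
        P = softmax(L, axis=1)  # leaf posteriors
        member = _leaf_membership(model)

        for node in model.states():
            gamma = P[:, member[id(node)]].sum(axis=1)
            x_t = X[:, node.t]
            obs = ~np.isnan(x_t)
            w = gamma[obs]
            total = float(w.sum())
            if total < DEGENERATE_WEIGHT:
                logger.warning(
                    "degenerate state at t=%d (weight %.2e); variance floored",
                    node.t, total,
                )
                node.var = max(node.var, VAR_FLOOR)
                continue
            mu = float(np.dot(w, x_t[obs]) / total)
            var = float(np.dot(w, (x_t[obs] - mu) ** 2) / total)
            node.mean = mu
            node.var = max(var, VAR_FLOOR)

        for split in model.splits():
            masses = np.column_stack(
                [P[:, member[id(c)]].sum(axis=1) for c in split.children]
            )
            feats = model._features_at(features_by_time, split.t + 1, n_genes)
            split.classifier = fit_weighted_multiclass_logistic(
                feats, masses, cfg.l2_penalty, init=split.classifier
            )
    model.trained = True
    return model, trace


# ---------------------------------------------------------------------------
# Viterbi assignment
# ---------------------------------------------------------------------------


def viterbi_assign(
    model: DremModel,
    X: np.ndarray,
    features_by_time: dict[int, np.ndarray] | None,
    gene_ids: list[str] | None = None,
) -> PathAssignment:
    """Assign each gene to the leaf maximizing its path log-likelihood.

    Ties go to the smallest leaf index (np.argmax's first-maximum rule).
    """
    L = model.path_loglik(X, features_by_time)
    return PathAssignment(
        leaf_indices=np.argmax(L, axis=1),
        n_leaves=L.shape[1],
        gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------------
# greedy structure search
# ---------------------------------------------------------------------------


def _passing_genes(model: DremModel, node: StateNode, assignment: PathAssignment) -> np.ndarray:
    member = _leaf_membership(model)
    leaves = set(member[id(node)])
    return np.isin(assignment.leaf_indices, list(leaves))


def _propose_child(
    model: DremModel,
    node_index: int,
    quantile: float,
    X: np.ndarray,
    assignment: PathAssignment,
) -> DremModel | None:
    """Clone the model and append a fresh chain child to states()[node_index].

    The new chain's means are initialized at the given quantile of the
    values (per time point) of genes currently routed through the node, its
    variances at their empirical variance; the split classifier starts at
    (or is extended by) zero weights for the new child.
    """
    passing = _passing_genes(model, model.states()[node_index], assignment)
    if passing.sum() < 2:
        return None
    cand = copy.deepcopy(model)
    node = cand.states()[node_index]
    T = cand.n_times
    sub = X[passing][:, node.t + 1 : T]
    with np.errstate(all="ignore"):
        q_means = np.nanquantile(sub, quantile, axis=0)
        q_vars = np.nanvar(sub, axis=0)
    if np.any(np.isnan(q_means)):
        return None
    chain: list[StateNode] = []
    for off, (m, v) in enumerate(zip(q_means, q_vars)):
        chain.append(StateNode(node.t + 1 + off, float(m), float(max(v, VAR_FLOOR))))
    for a, b in zip(chain, chain[1:]):
        a.children = [b]
    node.children = node.children + [chain[0]]
    d = len(cand.tf_ids)
    if node.classifier is None:
        node.classifier = SplitClassifier(np.zeros((2, d)), np.zeros(2))
    else:
        node.classifier = SplitClassifier(
            np.vstack([node.classifier.weights, np.zeros(d)]),
            np.append(node.classifier.intercepts, 0.0),
        )
    return cand


def structure_search(
    X: np.ndarray,
    features_by_time: dict[int, np.ndarray] | None,
    cfg: LearnConfig,
    tf_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[DremModel, TrainingTrace]:
    """Greedy split placement starting from the single-path chain.

    Every node below the last time point with out-degree < k_max is a
    candidate for gaining one more child (binary splits first, then
    ternary); each proposal is refit by EM and scored by penalized
    log-likelihood minus kappa per model parameter.  The best improving
    proposal is
    accepted; search stops when none improves the score or a new child
    would receive fewer than ``min_path_genes`` Viterbi genes.
    Deterministic: proposals are enumerated in DFS node order and at fixed
    initialization quantiles.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_genes, T = X.shape
    kappa = cfg.kappa(n_genes)

    means = [float(np.nanmean(X[:, t])) for t in range(T)]
    variances = [float(max(np.nanvar(X[:, t]), VAR_FLOOR)) for t in range(T)]
    model = chain_model(means, variances, tf_ids)
    model, trace = em_fit(model, X, features_by_time, cfg)
    pen = trace.logliks[-1]
    score = pen - kappa * n_parameters(model)
    search_trace = TrainingTrace(logliks=list(trace.logliks))

    while True:
        best: tuple[float, DremModel, TrainingTrace, dict] | None = None
        assignment = viterbi_assign(model, X, features_by_time)
        for node_index, node in enumerate(model.states()):
            if node.t >= T - 1 or len(node.children) >= cfg.k_max:
                continue
            for q in _PROPOSAL_QUANTILES:
                cand = _propose_child(model, node_index, q, X, assignment)
                if cand is None:
                    continue
                cand, cand_trace = em_fit(cand, X, features_by_time, cfg)
                cand_assign = viterbi_assign(cand, X, features_by_time)
                split = cand.states()[node_index]
                child_counts = _child_viterbi_counts(cand, split, cand_assign)
                event = {
                    "split_time": node.t + 1,
                    "quantile": q,
                    "score": cand_trace.logliks[-1] - kappa * n_parameters(cand),
                    "child_counts": child_counts,
                    "accepted": False,
                }
                search_trace.proposals.append(event)
                if min(child_counts) < cfg.min_path_genes:
                    continue
                cand_score = event["score"]
                if best is None or cand_score > best[0]:
                    best = (cand_score, cand, cand_trace, event)
        if best is None or best[0] <= score + 1e-9:
            break
        score, model, trace, event = best
        event["accepted"] = True
        search_trace.logliks.extend(trace.logliks)

    model.config = {
        "k_max": cfg.k_max,
        "em_tol": cfg.em_tol,
        "em_max_iter": cfg.em_max_iter,
        "l2_penalty": cfg.l2_penalty,
        "structure_penalty": kappa,
        "min_path_genes": cfg.min_path_genes,
        "seed": cfg.seed,
    }
    model.gene_ids = list(gene_ids or [])
    assignment = viterbi_assign(model, X, features_by_time, gene_ids)
    model.assignments = [int(i) for i in assignment.leaf_indices]
    model.trained = True
    return model, search_trace


def _child_viterbi_counts(
    model: DremModel, split: StateNode, assignment: PathAssignment
) -> list[int]:
    member = _leaf_membership(model)
    counts = []
    for child in split.children:
        leaves = set(member[id(child)])
        counts.append(int(np.isin(assignment.leaf_indices, list(leaves)).sum()))
    return counts


def split_times(model: DremModel) -> list[int]:
    """Divergence times (children's time index) of the model's splits."""
    return sorted(s.t + 1 for s in model.splits())
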