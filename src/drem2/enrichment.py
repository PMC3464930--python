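"""Model annotation: per-split TF enrichment ("split tables"), per-path GO
enrichment with Bonferroni correction, TF up/down flags, and gene-set export
for external discriminative motif finders.

All enrichment tests are one-sided upper-tail hypergeometric tests, computed
by exact summation in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from drem2.io_formats import GoAnnotation
from drem2.learning import PathAssignment, _leaf_membership
from drem2.model_core import DremModel, StateNode

#: default display threshold for attaching a TF to a split node
SPLIT_P_THRESHOLD = 5e-5
#: default significance level on Bonferroni-corrected GO p-values
GO_ALPHA = 0.05


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail
# ---------------------------------------------------------------------------


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Exact log-space summation of the pmf over the upper tail; the result is
    clipped into (0, 1].
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        if k > min(K, n):
            raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
        raise ValueError(f"k={k} negative")
    if k == 0:
        return 1.0
    hi = min(K, n)
    i = np.arange(k, hi + 1)
    log_pmf = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    p = float(np.exp(logsumexp(log_pmf)))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


# ---------------------------------------------------------------------------
# split tables
# ---------------------------------------------------------------------------


@dataclass
class SplitTableRow:
    tf_id: str
    path_index: int  # child index within the split
    n_path: int
    k_path: int
    n_split: int
    k_split: int
    p_conditional: float
    p_overall: float


@dataclass
class SplitTable:
    """Per-TF, per-outgoing-path enrichment at one split node."""

    split_id: str
    split_time: int  # time of the diverging children
    rows: list[SplitTableRow]
    n_split: int
    annotated_tfs: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "split": self.split_id,
                    "tf": r.tf_id,
                    "path": r.path_index,
                    "n_path": r.n_path,
                    "k_path": r.k_path,
                    "n_split": r.n_split,
                    "k_split": r.k_split,
                    "p_conditional": r.p_conditional,
                    "p_overall": r.p_overall,
                }
                for r in self.rows
            ]
        )


def _genes_by_node(
    model: DremModel, assignment: PathAssignment
) -> dict[int, np.ndarray]:
    member = _leaf_membership(model)
    out = {}
    for node in model.states():
        leaves = member[id(node)]
        out[id(node)] = np.isin(assignment.leaf_indices, leaves)
    return out


def build_split_table(
    model: DremModel,
    assignment: PathAssignment,
    features_by_time: dict[int, np.ndarray],
    target_threshold: float = 0.0,
    display_threshold: float = SPLIT_P_THRESHOLD,
) -> list[SplitTable]:
    """One enrichment table per split node.

    A TF "targets" a gene when the absolute effective feature value at the
    split's transition exceeds ``target_threshold`` (default: any nonzero
    value, which reads +-1 for three-state encodings).  ``p_conditional``
    tests the path's target count against the genes entering the split;
    ``p_overall`` uses all model genes as background.  TFs reaching
    ``display_threshold`` on some path are attached to the split.
    """
    in_node = _genes_by_node(model, assignment)
    n_genes = len(assignment.leaf_indices)
    tables: list[SplitTable] = []
    for split in model.splits():
        t = split.t + 1
        feats = np.asarray(features_by_time[t])  # TF x gene
        targets = np.abs(feats) > target_threshold
        entering = in_node[id(split)]
        n_split = int(entering.sum())
        rows: list[SplitTableRow] = []
        annotated: list[str] = []
        for ti, tf in enumerate(model.tf_ids):
            tgt = targets[ti]
            k_split = int((tgt & entering).sum())
            k_all = int(tgt.sum())
            best_p = 1.0
            for ci, child in enumerate(split.children):
                on_path = in_node[id(child)]
                n_path = int(on_path.sum())
                k_path = int((tgt & on_path).sum())
                p_cond = hypergeom_upper(k_path, k_split, n_path, n_split)
                p_over = hypergeom_upper(k_path, k_all, n_path, n_genes)
                rows.append(
                    SplitTableRow(tf, ci, n_path, k_path, n_split, k_split, p_cond, p_over)
                )
                best_p = min(best_p, p_cond)
            if best_p <= display_threshold:
                annotated.append(tf)
        tables.append(
            SplitTable(model.split_id(split), t, rows, n_split, annotated)
        )
    return tables


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------


@dataclass
class GoResult:
    path_index: int
    term_id: str
    term_name: str
    k_path: int
    n_path: int
    k_background: int
    n_background: int
    p_raw: float
    p_corrected: float


def go_enrich(
    path_genes: list[str],
    background_genes: list[str],
    annotation: GoAnnotation,
    path_index: int = 0,
) -> list[GoResult]:
    """Hypergeometric GO enrichment of one path against the model background.

    Tests every term annotating at least one path gene; Bonferroni-corrects
    over the number of tested terms; sorted by corrected then raw p-value.
    """
    if not path_genes:
        raise ValueError("empty path")
    bg = {g.strip().lower() for g in background_genes}
    path = {g.strip().lower() for g in path_genes}
    if not path <= bg:
        raise ValueError("background must contain every path gene")
    term_path_count: dict[str, int] = {}
    term_bg_count: dict[str, int] = {}
    for g in bg:
        terms = annotation.gene_to_terms.get(g, frozenset())
        for term in terms:
            term_bg_count[term] = term_bg_count.get(term, 0) + 1
            if g in path:
                term_path_count[term] = term_path_count.get(term, 0) + 1
    tested = sorted(term_path_count)
    n_tested = len(tested)
    results = []
    for term in tested:
        k, K = term_path_count[term], term_bg_count[term]
        p = hypergeom_upper(k, K, len(path), len(bg))
        results.append(
            GoResult(
                path_index,
                term,
                annotation.term_names.get(term, term),
                k,
                len(path),
                K,
                len(bg),
                p,
                min(1.0, p * n_tested),
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term_id))
    return results


def model_go_enrichment(
    model: DremModel,
    assignment: PathAssignment,
    annotation: GoAnnotation,
) -> list[GoResult]:
    """GO enrichment of every path of the model against the model's genes."""
    if assignment.gene_ids is None:
        raise ValueError("assignment must carry gene ids for GO enrichment")
    background = list(assignment.gene_ids)
    out: list[GoResult] = []
    for leaf in range(assignment.n_leaves):
        genes = assignment.genes_on_path(leaf)
        if genes:
            out.extend(go_enrich(genes, background, annotation, path_index=leaf))
    return out


def significant_terms(results: list[GoResult], alpha: float = GO_ALPHA) -> set[str]:
    """Terms significant on any path after Bonferroni correction."""
    return {r.term_id for r in results if r.p_corrected < alpha}


def count_significant_terms(
    per_model_results: dict[str, list[GoResult]], alpha: float = GO_ALPHA
) -> dict:
    """Significant-term counts and pairwise set differences across models."""
    sets = {name: significant_terms(res, alpha) for name, res in per_model_results.items()}
    names = list(sets)
    report = {
        "counts": {name: len(s) for name, s in sets.items()},
        "terms": {name: sorted(s) for name, s in sets.items()},
        "pairwise": {},
    }
    for a in names:
        for b in names:
            if a >= b:
                continue
            report["pairwise"][f"{a} vs {b}"] = {
                "shared": len(sets[a] & sets[b]),
                f"only {a}": sorted(sets[a] - sets[b]),
                f"only {b}": sorted(sets[b] - sets[a]),
            }
    return report


# ---------------------------------------------------------------------------
# TF activity flags
# ---------------------------------------------------------------------------


@dataclass
class TfActivityFlag:
    tf_id: str
    split_id: str
    direction: str  # up | down | none


def flag_tf_direction(
    tf_id: str,
    split: StateNode,
    tf_expression: dict[str, np.ndarray],
    split_id: str,
    delta: float = 0.5,
) -> TfActivityFlag:
    """Up/down flag from the TF's own log2 ratio at the split's time."""
    lookup = {k.strip().lower(): v for k, v in tf_expression.items()}
    traj = lookup.get(tf_id.strip().lower())
    t = split.t + 1
    if traj is None or t >= len(traj) or np.isnan(traj[t]):
        return TfActivityFlag(tf_id, split_id, "none")
    e = float(traj[t])
    if e >= delta:
        return TfActivityFlag(tf_id, split_id, "up")
    if e <= -delta:
        return TfActivityFlag(tf_id, split_id, "down")
    return TfActivityFlag(tf_id, split_id, "none")


# ---------------------------------------------------------------------------
# gene-set export for discriminative motif search
# ---------------------------------------------------------------------------


def export_split_genesets(
    model: DremModel,
    assignment: PathAssignment,
    split_id: str,
    out_dir: str | Path,
) -> list[tuple[Path, Path]]:
    """Write foreground/background id lists for each path-vs-rest contrast.

    A split with k outgoing paths yields k contrasts; within each, the
    foreground (genes on the path) and background (genes on the split's
    other paths) partition the genes entering the split.  Returns the list
    of (foreground, background) file pairs.
    """
    if assignment.gene_ids is None:
        raise ValueError("assignment must carry gene ids")
    split = next((s for s in model.splits() if model.split_id(s) == split_id), None)
    if split is None:
        raise KeyError(f"unknown split id {split_id!r}")
    in_node = _genes_by_node(model, assignment)
    entering = in_node[id(split)]
    genes = np.asarray(assignment.gene_ids, dtype=object)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs: list[tuple[Path, Path]] = []
    for ci, child in enumerate(split.children):
        fg_mask = in_node[id(child)]
        bg_mask = entering & ~fg_mask
        fg = out_dir / f"{split_id}.path{ci}.foreground.txt"
        bg = out_dir / f"{split_id}.path{ci}.background.txt"
        fg.write_text("\n".join(genes[fg_mask]) + "\n", encoding="utf-8")
        bg.write_text("\n".join(genes[bg_mask]) + "\n", encoding="utf-8")
        pairs.append((fg, bg))
    return pairs
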