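"""Fully synthetic expression + binding datasets from a known planted model.

The generator is the inverse of the model: it plants a tree (by default a
single binary bifurcation), draws TF-gene binding first (the signal TF binds
most of the genes destined for its path and few others), routes each gene
through the planted softmax over its binding features, and samples its
trajectory from the path's Gaussian states.  Everything is reproducible from
the scenario seed, and the emitted files use the package's exact dialects so
the whole pipeline can be exercised end to end without external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from drem2.io_formats import (
    BindingMatrix,
    DynamicBindingSet,
    ExpressionTable,
    align,
    write_gaf,
    write_obo,
)
from drem2.learning import split_times
from drem2.model_core import DremModel, SplitClassifier, StateNode


@dataclass
class SimScenario:
    """Study conditions for one simulated dataset.

    ``split_time`` is the time point at which the planted paths diverge
    (``None`` plants a chain); children are separated by ``delta_mu`` at
    every time from the split onward.  The signal TF binds
    ``bind_rate_signal`` of the genes destined for the up path and
    ``bind_rate_offpath`` of the rest; decoy TFs bind ``bind_rate_offpath``
    of all genes.  Continuous binding values are Uniform(1, 5).
    """

    n_times: int = 5
    n_genes: int = 500
    n_tfs: int = 10
    split_time: int | None = 2
    out_degree: int = 2
    delta_mu: float = 3.0
    sigma: float = 0.5
    signal_tf: int = 0
    planted_weight: float = 2.0
    bind_rate_signal: float = 0.8
    bind_rate_offpath: float = 0.1
    binding_mode: str = "continuous"  # three_state | continuous | dynamic | mixed
    tf_expression_coupled: bool = False
    tf_noise_sd: float = 0.1
    tf_coupled_level: float = 1.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.binding_mode not in ("three_state", "continuous", "dynamic", "mixed"):
            raise ValueError(f"unknown binding_mode {self.binding_mode!r}")
        if self.split_time is not None:
            if not 1 <= self.split_time <= self.n_times - 1:
                raise ValueError("split_time must lie in 1..n_times-1")
            if not 2 <= self.out_degree <= 3:
                raise ValueError("planted out-degree must be 2 or 3")
        if not 0 <= self.signal_tf < self.n_tfs:
            raise ValueError("signal_tf out of range")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _tf_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"TF{i:0{width}d}" for i in range(1, n + 1)]


def _planted_model(scn: SimScenario, tf_ids: list[str]) -> DremModel:
    T = scn.n_times
    if scn.split_time is None:
        nodes = [StateNode(t, 0.0, scn.sigma**2) for t in range(T)]
        for a, b in zip(nodes, nodes[1:]):
            a.children = [b]
        return DremModel(root=nodes[0], tf_ids=list(tf_ids), n_times=T)
    K = scn.out_degree
    trunk = [StateNode(t, 0.0, scn.sigma**2) for t in range(scn.split_time)]
    for a, b in zip(trunk, trunk[1:]):
        a.children = [b]
    offsets = [(k - (K - 1) / 2.0) * scn.delta_mu for k in range(K)]
    branches = []
    for off in offsets:
        chain = [StateNode(t, off, scn.sigma**2) for t in range(scn.split_time, T)]
        for a, b in zip(chain, chain[1:]):
            a.children = [b]
        branches.append(chain[0])
    trunk[-1].children = branches
    weights = np.zeros((K, len(tf_ids)))
    weights[K - 1, scn.signal_tf] = scn.planted_weight  # up path is the last child
    trunk[-1].classifier = SplitClassifier(weights, np.zeros(K))
    return DremModel(root=trunk[0], tf_ids=list(tf_ids), n_times=T)


def _draw_binding(
    scn: SimScenario, destined_up: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """TF x gene binding matrix; the signal TF tracks the destined-up genes."""
    n, m = scn.n_tfs, scn.n_genes
    bound = rng.random((n, m)) < scn.bind_rate_offpath
    sig = scn.signal_tf
    bound[sig] = np.where(
        destined_up,
        rng.random(m) < scn.bind_rate_signal,
        rng.random(m) < scn.bind_rate_offpath,
    )
    if scn.binding_mode == "three_state":
        values = bound.astype(float)
    else:
        values = bound * rng.uniform(1.0, 5.0, size=(n, m))
    return values


def simulate(
    scn: SimScenario,
) -> tuple[ExpressionTable, DynamicBindingSet, dict]:
    """Draw one dataset; returns (expression, binding set, ground truth).

    The expression table contains the target genes followed by the TF rows
    (regulators are genes too).  The truth dict carries the planted model,
    the per-target-gene path labels and softmax path probabilities, the
    target gene ids and the signal TF's id.
    """
    rng = np.random.default_rng(scn.seed)
    gene_ids = _gene_ids(scn.n_genes)
    tf_ids = _tf_ids(scn.n_tfs)
    model = _planted_model(scn, tf_ids)
    T = scn.n_times
    K = scn.out_degree if scn.split_time is not None else 1

    destined = rng.integers(0, K, size=scn.n_genes)
    binding = _draw_binding(scn, destined == K - 1, rng)

    if scn.split_time is None:
        labels = np.zeros(scn.n_genes, dtype=int)
        probs = np.ones((scn.n_genes, 1))
    else:
        clf = model.splits()[0].classifier
        # balance the marginal: center the up-path logit on its mean feature
        intercepts = clf.intercepts.copy()
        intercepts[K - 1] = -scn.planted_weight * float(
            np.mean(binding[scn.signal_tf])
        )
        clf.intercepts = intercepts
        probs = clf.probs(binding.T)
        cum = np.cumsum(probs, axis=1)
        labels = (rng.random(scn.n_genes)[:, None] >= cum).sum(axis=1)

    paths = model.paths()
    means = np.array([[n.mean for n in paths[l]] for l in labels])
    X = rng.normal(means, scn.sigma)

    tf_X = rng.normal(0.0, scn.tf_noise_sd, size=(scn.n_tfs, T))
    if scn.tf_expression_coupled and scn.split_time is not None:
        # the signal TF rises one time point before its split
        tf_X[scn.signal_tf, scn.split_time - 1 :] += scn.tf_coupled_level

    table = ExpressionTable(
        gene_ids + tf_ids,
        [str(t) for t in range(T)],
        np.vstack([X, tf_X]),
        list(range(T)),
        "log2",
    )
    dyn = _binding_set(scn, binding, tf_ids, gene_ids, rng)
    truth = {
        "model": model,
        "labels": labels,
        "path_probs": probs,
        "gene_ids": gene_ids,
        "tf_ids": tf_ids,
        "signal_tf_id": tf_ids[scn.signal_tf],
        "up_child": K - 1,
        "scenario": scn,
    }
    return table, dyn, truth


def _binding_set(
    scn: SimScenario,
    binding: np.ndarray,
    tf_ids: list[str],
    gene_ids: list[str],
    rng: np.random.Generator,
) -> DynamicBindingSet:
    encoding = "three_state" if scn.binding_mode == "three_state" else "continuous"
    grid = BindingMatrix(list(tf_ids), list(gene_ids), binding, encoding)
    if scn.binding_mode in ("three_state", "continuous"):
        return align(DynamicBindingSet(static_part=grid))
    st = scn.split_time if scn.split_time is not None else 1
    if scn.binding_mode == "dynamic":
        # informative grid at the split transition, decoy grids elsewhere
        parts = {}
        for t in range(1, scn.n_times):
            if t == st:
                parts[t] = grid
            else:
                decoy = rng.random(binding.shape) < scn.bind_rate_offpath
                vals = decoy * rng.uniform(1.0, 5.0, size=binding.shape)
                parts[t] = BindingMatrix(
                    list(tf_ids), list(gene_ids), vals, "continuous"
                )
        return align(DynamicBindingSet(dynamic_parts=parts))
    # mixed: decoy TFs static, the signal TF dynamic at the split transition
    sig = scn.signal_tf
    static_vals = binding.copy()
    static_vals[sig] = 0.0
    static = BindingMatrix(list(tf_ids), list(gene_ids), static_vals, encoding)
    dyn_grid = BindingMatrix(
        [tf_ids[sig]], list(gene_ids), binding[sig : sig + 1], encoding
    )
    return align(DynamicBindingSet(static_part=static, dynamic_parts={st: dyn_grid}))


# ---------------------------------------------------------------------------
# synthetic GO annotation
# ---------------------------------------------------------------------------


def make_go_files(
    obo_path: str | Path,
    gaf_path: str | Path,
    path_groups: list[list[str]],
    all_genes: list[str],
    seed: int = 0,
    terms_per_group: int = 4,
    n_background_terms: int = 6,
    coverage: tuple[float, float] = (0.5, 0.9),
    leak: float = 0.05,
) -> None:
    """Write a toy OBO/GAF pair whose terms track the planted path groups.

    Each group gets ``terms_per_group`` terms annotating a random fraction
    (``coverage``) of its genes plus a ``leak`` fraction of the others;
    background terms annotate random genes irrespective of group.  All terms
    hang off a single root by is_a.
    """
    rng = np.random.default_rng(seed)
    root = "GO:0000001"
    terms: list[tuple[str, str, list[str]]] = [(root, "biological_process", [])]
    annotations: list[tuple[str, str]] = []
    counter = 2

    def next_term(name: str) -> str:
        nonlocal counter
        tid = f"GO:{counter:07d}"
        counter += 1
        terms.append((tid, name, [root]))
        return tid

    all_set = list(all_genes)
    for gi, group in enumerate(path_groups):
        others = [g for g in all_set if g not in set(group)]
        for ti in range(terms_per_group):
            tid = next_term(f"path{gi} program {ti}")
            cov = rng.uniform(*coverage)
            chosen = [g for g in group if rng.random() < cov]
            leaked = [g for g in others if rng.random() < leak]
            for g in chosen + leaked:
                annotations.append((g, tid))
    for ti in range(n_background_terms):
        tid = next_term(f"background process {ti}")
        for g in all_set:
            if rng.random() < 0.1:
                annotations.append((g, tid))
    write_obo(obo_path, terms)
    write_gaf(gaf_path, annotations)


# ---------------------------------------------------------------------------
# dataset export and recovery metrics
# ---------------------------------------------------------------------------


def simulate_to_dir(scn: SimScenario, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write every input file in the package's dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, dyn, truth = simulate(scn)
    paths: dict[str, Path] = {}
    paths["expression"] = out_dir / "expression.tsv"
    table.write(paths["expression"])
    manifest_lines: list[str] = []
    if dyn.static_part is not None:
        p = out_dir / "binding.static.tsv"
        dyn.static_part.write(p)
        manifest_lines.append("static: binding.static.tsv")
        paths["static"] = p
    for t, grid in sorted(dyn.dynamic_parts.items()):
        p = out_dir / f"binding.t{t}.tsv"
        grid.write(p)
        manifest_lines.append(f"timepoint {t}: binding.t{t}.tsv")
        paths[f"dynamic.{t}"] = p
    paths["manifest"] = out_dir / "binding.manifest"
    paths["manifest"].write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")
    paths["scenario"] = out_dir / "scenario.yaml"
    paths["scenario"].write_text(
        yaml.safe_dump(asdict(scn), sort_keys=True), encoding="utf-8"
    )
    paths["truth_labels"] = out_dir / "truth_labels.tsv"
    with open(paths["truth_labels"], "w", encoding="utf-8") as fh:
        fh.write("gene\tpath\n")
        for g, l in zip(truth["gene_ids"], truth["labels"]):
            fh.write(f"{g}\t{l}\n")
    return paths


def load_scenario(path: str | Path) -> SimScenario:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return SimScenario(**raw)


def recovery_report(truth: dict, model: DremModel, assignment) -> dict:
    """Score a learned model against the planted truth.

    Reports split-time recovery, adjusted Rand index between true and
    Viterbi path partitions, the max absolute state-mean error over matched
    states (NaN when the topologies differ), and whether the planted signal
    TF's classifier weight points toward the up path.
    """
    tm: DremModel = truth["model"]
    labels = np.asarray(truth["labels"])
    learned_assign = np.asarray(assignment.leaf_indices)[: len(labels)]
    true_times = split_times(tm)
    learned_times = split_times(model)

    report = {
        "true_split_times": true_times,
        "learned_split_times": learned_times,
        "split_time_exact": learned_times == true_times,
        "ari": float(adjusted_rand_score(labels, learned_assign)),
        "max_mean_error": _max_mean_error(tm, model),
        "signal_weight_positive": _signal_weight_positive(
            model, truth["signal_tf_id"]
        ),
    }
    return report


def _max_mean_error(truth: DremModel, model: DremModel) -> float:
    by_t_truth: dict[int, list[float]] = {}
    by_t_model: dict[int, list[float]] = {}
    for n in truth.states():
        by_t_truth.setdefault(n.t, []).append(n.mean)
    for n in model.states():
        by_t_model.setdefault(n.t, []).append(n.mean)
    worst = 0.0
    for t, tmeans in by_t_truth.items():
        mmeans = by_t_model.get(t, [])
        if len(mmeans) != len(tmeans):
            return float("nan")
        diffs = np.abs(np.sort(tmeans) - np.sort(mmeans))
        worst = max(worst, float(diffs.max()))
    return worst


def _signal_weight_positive(model: DremModel, signal_tf_id: str) -> bool | None:
    """Does the learned classifier push the signal TF's targets up?"""
    if signal_tf_id not in model.tf_ids:
        return None
    idx = model.tf_ids.index(signal_tf_id)
    verdicts = []
    for split in model.splits():
        w = split.classifier.weights[:, idx]
        child_means = [c.mean for c in split.children]
        up = int(np.argmax(child_means))
        others = [w[k] for k in range(len(w)) if k != up]
        verdicts.append(w[up] - float(np.mean(others)) > 0)
    if not verdicts:
        return None
    return all(verdicts)


def default_scenario(seed: int = 1, **overrides) -> SimScenario:
    """The reference study condition: T=5, one binary split at t=2,
    delta_mu=3, sigma=0.5, 500 genes."""
    return replace(SimScenario(seed=seed), **overrides)
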