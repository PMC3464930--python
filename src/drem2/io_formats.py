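"""Readers and writers for every external file the engine touches.

File dialects (normative for this package):

* expression table — tab-delimited, UTF-8; header row of time-point labels
  (repeated labels denote replicate columns), first column gene ids, cells
  are log2 ratios (or raw ratios, to be transformed downstream);
* binding grid — tab-delimited; header of TF names, first column gene ids,
  numeric cells; three-state {-1, 0, 1} or continuous nonnegative values,
  auto-detected from the cell-value set;
* dynamic manifest — plain text, lines ``static: <grid>`` and
  ``timepoint <t>: <grid>`` with paths relative to the manifest;
* GO — standard OBO 1.2 ontology plus GAF 2.x association file;
* model JSON — round-trippable serialization of a trained model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

MISSING_TOKEN_DEFAULT = ""
#: genes missing strictly more than this fraction of time points are dropped
MAX_MISSING_FRACTION = 0.5


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


def _norm_id(s: str) -> str:
    return s.strip().lower()


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Genes x columns matrix of expression ratios with replicate provenance.

    ``values`` has one column per input column; ``replicate_map[j]`` gives the
    index into ``time_labels`` that column ``j`` measures.  Missing values are
    NaN, never silently zero.  ``dialect`` is ``"log2"`` or ``"ratio"``.
    """

    gene_ids: list[str]
    time_labels: list[str]
    values: np.ndarray
    replicate_map: list[int]
    dialect: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.replicate_map)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.replicate_map)} columns"
            )
        if len(self.time_labels) < 2:
            raise FormatError("an expression table needs at least 2 time points")
        norm = [_norm_id(g) for g in self.gene_ids]
        if len(set(norm)) != len(norm):
            seen: set[str] = set()
            for g, n in zip(self.gene_ids, norm):
                if n in seen:
                    raise FormatError(f"duplicate gene id {g!r}")
                seen.add(n)
        if self.dialect not in ("log2", "ratio"):
            raise FormatError(f"unknown dialect {self.dialect!r}")
        bad = [j for j in self.replicate_map if not 0 <= j < len(self.time_labels)]
        if bad:
            raise FormatError(f"replicate_map entries out of range: {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_labels)

    @property
    def is_collapsed(self) -> bool:
        return self.replicate_map == list(range(self.n_times))

    def index_of(self, gene_id: str) -> int | None:
        if not hasattr(self, "_idx"):
            self._idx = {_norm_id(g): i for i, g in enumerate(self.gene_ids)}
        return self._idx.get(_norm_id(gene_id))

    def trajectory(self, gene_id: str) -> np.ndarray | None:
        """Per-time-point values for one gene; requires a collapsed table."""
        i = self.index_of(gene_id)
        if i is None:
            return None
        if not self.is_collapsed:
            raise FormatError("trajectory() requires one column per time point")
        return self.values[i]

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            labels = [self.time_labels[j] for j in self.replicate_map]
            fh.write("Gene\t" + "\t".join(labels) + "\n")
            for g, row in zip(self.gene_ids, self.values):
                cells = ["" if math.isnan(v) else format(v, ".10g") for v in row]
                fh.write(g + "\t" + "\t".join(cells) + "\n")


def read_expression(
    path: str | Path,
    dialect: str = "log2",
    missing_token: str = MISSING_TOKEN_DEFAULT,
    drop_sparse_genes: bool = True,
) -> ExpressionTable:
    """Parse a tab-delimited expression table.

    Repeated header labels map their columns to a single time point.  Genes
    missing more than half of the time points (all replicates of a time point
    NaN) are dropped with a warning.
    """
    rows = _read_tab_rows(path)
    if len(rows) < 2:
        raise FormatError(f"{path}: expected a header and at least one gene row")
    header = rows[0]
    col_labels = [c.strip() for c in header[1:]]
    if not col_labels:
        raise FormatError(f"{path}: header has no time-point columns")
    time_labels: list[str] = []
    replicate_map: list[int] = []
    for lab in col_labels:
        if lab not in time_labels:
            time_labels.append(lab)
        replicate_map.append(time_labels.index(lab))

    gene_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(col_labels)))
    for r, cells in enumerate(rows[1:], start=2):
        if len(cells) != len(col_labels) + 1:
            raise FormatError(
                f"{path}: line {r}: expected {len(col_labels) + 1} fields, "
                f"got {len(cells)}"
            )
        gene_ids.append(cells[0].strip())
        for j, cell in enumerate(cells[1:]):
            cell = cell.strip()
            if cell == missing_token:
                data[r - 2, j] = np.nan
                continue
            try:
                data[r - 2, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {r}: non-numeric cell {cell!r} "
                    f"(missing token is {missing_token!r})"
                ) from None

    table = ExpressionTable(gene_ids, time_labels, data, replicate_map, dialect)
    if drop_sparse_genes:
        table = _drop_sparse_genes(table, path)
    return table


def _drop_sparse_genes(table: ExpressionTable, path: str | Path) -> ExpressionTable:
    rep = np.asarray(table.replicate_map)
    # a time point is missing for a gene when all its replicate columns are NaN
    tp_missing = np.stack(
        [np.all(np.isnan(table.values[:, rep == t]), axis=1) for t in range(table.n_times)],
        axis=1,
    )
    frac = tp_missing.mean(axis=1)
    keep = frac <= MAX_MISSING_FRACTION
    if keep.all():
        return table
    dropped = [g for g, k in zip(table.gene_ids, keep) if not k]
    logger.warning(
        "%s: dropping %d gene(s) missing >%.0f%% of time points: %s",
        path, len(dropped), 100 * MAX_MISSING_FRACTION,
        ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
    )
    return ExpressionTable(
        [g for g, k in zip(table.gene_ids, keep) if k],
        table.time_labels,
        table.values[keep],
        table.replicate_map,
        table.dialect,
    )


def _read_tab_rows(path: str | Path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            rows.append(line.split("\t"))
    return rows


# ---------------------------------------------------------------------------
# binding grids
# ---------------------------------------------------------------------------


@dataclass
class BindingMatrix:
    """TF x gene matrix of binding evidence.

    ``encoding`` is ``"three_state"`` (cells in {-1, 0, 1}: repressor / no
    evidence / activator) or ``"continuous"`` (nonnegative values, e.g.
    b = -log10 of a ChIP peak p-value).  Absent pairs are 0.  A third
    encoding, ``"signed"``, never appears in input files: it marks derived
    matrices (e.g. expression-scaled three-state rows) whose magnitudes are
    continuous but whose signs still carry the activator/repressor reading.
    """

    tf_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    encoding: str = "three_state"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise FormatError(
                f"binding matrix shape {self.values.shape} does not match "
                f"{len(self.tf_ids)} TFs x {len(self.gene_ids)} genes"
            )
        for name, ids in (("TF", self.tf_ids), ("gene", self.gene_ids)):
            norm = [_norm_id(x) for x in ids]
            if len(set(norm)) != len(norm):
                dup = sorted({n for n in norm if norm.count(n) > 1})
                raise FormatError(f"duplicate {name} id(s): {dup}")
        if self.encoding == "three_state":
            if not np.isin(self.values, (-1.0, 0.0, 1.0)).all():
                raise FormatError("three_state matrix has values outside {-1,0,1}")
        elif self.encoding == "continuous":
            if np.any(self.values < 0):
                raise FormatError("continuous binding values must be >= 0")
        elif self.encoding != "signed":
            raise FormatError(f"unknown encoding {self.encoding!r}")

    def row(self, tf_id: str) -> np.ndarray:
        return self.values[self.tf_ids.index(tf_id)]

    def write(self, path: str | Path) -> None:
        # file layout is gene rows x TF columns (transposed from memory)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Gene\t" + "\t".join(self.tf_ids) + "\n")
            for j, g in enumerate(self.gene_ids):
                cells = [format(v, ".10g") for v in self.values[:, j]]
                fh.write(g + "\t" + "\t".join(cells) + "\n")


def read_binding_grid(path: str | Path) -> BindingMatrix:
    """Parse a gene x TF grid; encoding auto-detected from the cell values."""
    rows = _read_tab_rows(path)
    if len(rows) < 2 or len(rows[0]) < 2:
        raise FormatError(f"{path}: empty binding grid")
    tf_ids = [c.strip() for c in rows[0][1:]]
    gene_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(tf_ids)))
    for r, cells in enumerate(rows[1:], start=2):
        if len(cells) != len(tf_ids) + 1:
            raise FormatError(
                f"{path}: line {r}: expected {len(tf_ids) + 1} fields, got {len(cells)}"
            )
        gene_ids.append(cells[0].strip())
        for j, cell in enumerate(cells[1:]):
            try:
                data[r - 2, j] = float(cell)
            except ValueError:
                raise FormatError(f"{path}: line {r}: non-numeric cell {cell!r}") from None
    values = data.T  # TF x gene
    three_state = bool(np.isin(values, (-1.0, 0.0, 1.0)).all())
    if not three_state and np.any(values < 0):
        i, j = map(int, np.argwhere(values < 0)[0])
        raise FormatError(
            f"{path}: negative continuous binding value {values[i, j]} "
            f"for TF {tf_ids[i]!r}, gene {gene_ids[j]!r}"
        )
    return BindingMatrix(
        tf_ids, gene_ids, values, "three_state" if three_state else "continuous"
    )


@dataclass
class DynamicBindingSet:
    """A static binding matrix, per-time-point matrices, or a mix of both.

    After :func:`align`, all member matrices share the same TF and gene
    universes (sorted unions, zero-filled), so downstream results do not
    depend on the declaration order of the input grids.
    """

    static_part: BindingMatrix | None = None
    dynamic_parts: dict[int, BindingMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.static_part is None and not self.dynamic_parts:
            raise FormatError("dynamic binding set needs a static or dynamic part")

    @property
    def parts(self) -> list[BindingMatrix]:
        out = [] if self.static_part is None else [self.static_part]
        return out + [self.dynamic_parts[t] for t in sorted(self.dynamic_parts)]

    @property
    def tf_ids(self) -> list[str]:
        return self.parts[0].tf_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.parts[0].gene_ids

    def is_aligned(self) -> bool:
        ref = self.parts[0]
        return all(
            p.tf_ids == ref.tf_ids and p.gene_ids == ref.gene_ids for p in self.parts
        )


def align(dyn: DynamicBindingSet, gene_ids: list[str] | None = None) -> DynamicBindingSet:
    """Project all member matrices onto shared, sorted TF/gene universes.

    ``gene_ids``, when given (normally the expression table's genes), fixes
    the gene universe and its order; grid genes outside it are dropped.
    Missing entries are zero (no evidence).
    """
    parts = dyn.parts
    tf_union = sorted({t for p in parts for t in p.tf_ids}, key=_norm_id)
    if gene_ids is None:
        gene_union = sorted({g for p in parts for g in p.gene_ids}, key=_norm_id)
    else:
        gene_union = list(gene_ids)
    gpos = {_norm_id(g): j for j, g in enumerate(gene_union)}
    tpos = {_norm_id(t): i for i, t in enumerate(tf_union)}

    def project(m: BindingMatrix) -> BindingMatrix:
        out = np.zeros((len(tf_union), len(gene_union)))
        gcols = [gpos.get(_norm_id(g)) for g in m.gene_ids]
        for i, tf in enumerate(m.tf_ids):
            ti = tpos[_norm_id(tf)]
            for j, gc in enumerate(gcols):
                if gc is not None:
                    out[ti, gc] = m.values[i, j]
        return BindingMatrix(list(tf_union), list(gene_union), out, m.encoding)

    static = None if dyn.static_part is None else project(dyn.static_part)
    dynamic = {t: project(m) for t, m in dyn.dynamic_parts.items()}
    return DynamicBindingSet(static, dynamic)


def read_dynamic_manifest(path: str | Path) -> DynamicBindingSet:
    """Parse a static/dynamic manifest and load + align every listed grid.

    Time-point indices are 0-based positions in the expression table's
    ordered time labels; index t's grid drives the classifier of the
    transition INTO time point t.
    """
    path = Path(path)
    static: BindingMatrix | None = None
    dynamic: dict[int, BindingMatrix] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"{path}: line {lineno}: expected 'key: grid-path'")
            key, _, grid = line.partition(":")
            key, grid = key.strip(), grid.strip()
            grid_path = path.parent / grid
            if not grid_path.exists():
                raise FormatError(f"{path}: line {lineno}: no such grid file {grid!r}")
            if key == "static":
                if static is not None:
                    raise FormatError(f"{path}: line {lineno}: duplicate static entry")
                static = read_binding_grid(grid_path)
            elif key.startswith("timepoint"):
                try:
                    t = int(key.split()[1])
                except (IndexError, ValueError):
                    raise FormatError(
                        f"{path}: line {lineno}: expected 'timepoint <index>'"
                    ) from None
                if t < 0:
                    raise FormatError(f"{path}: line {lineno}: negative time index")
                if t in dynamic:
                    raise FormatError(f"{path}: line {lineno}: duplicate time point {t}")
                dynamic[t] = read_binding_grid(grid_path)
            else:
                raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
    if static is None and not dynamic:
        raise FormatError(f"{path}: manifest lists no grids")
    return align(DynamicBindingSet(static, dynamic))


# ---------------------------------------------------------------------------
# Gene Ontology
# ---------------------------------------------------------------------------


@dataclass
class GoAnnotation:
    """A GO DAG plus gene -> term annotations propagated to all ancestors."""

    term_ids: list[str]
    term_names: dict[str, str]
    term_parents: dict[str, set[str]]
    gene_to_terms: dict[str, frozenset[str]]

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}


def read_go(obo_path: str | Path, gaf_path: str | Path) -> GoAnnotation:
    """Load an OBO 1.2 ontology and a GAF 2.x file; propagate annotations.

    Annotation is by exact (case-insensitive) id against GAF column 3
    (DB Object Symbol); NOT-qualified and obsolete-term rows are dropped.
    Each gene-term pair is counted once regardless of how many annotation
    lines or descendant terms support it.
    """
    graph = obonet.read_obo(obo_path)
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise FormatError(f"is_a cycle in ontology: {cycle}")
    term_ids = sorted(dag.nodes)
    term_names = {t: graph.nodes[t].get("name", t) for t in term_ids}
    parents = {t: set(dag.successors(t)) for t in term_ids}
    ancestors = {t: nx.descendants(dag, t) for t in term_ids}

    gene_terms: dict[str, set[str]] = {}
    with open(gaf_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise FormatError(f"{gaf_path}: GAF line with <5 columns: {line!r}")
            symbol, qualifier, term = cols[2], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            if term not in dag.nodes:  # unknown or obsolete term
                continue
            key = _norm_id(symbol)
            terms = gene_terms.setdefault(key, set())
            terms.add(term)
            terms.update(ancestors[term])
    return GoAnnotation(
        term_ids,
        term_names,
        parents,
        {g: frozenset(ts) for g, ts in gene_terms.items()},
    )


def write_obo(path: str | Path, terms: list[tuple[str, str, list[str]]]) -> None:
    """Write a minimal OBO 1.2 file from (id, name, is_a parents) triples."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for tid, name, parents in terms:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            for p in parents:
                fh.write(f"is_a: {p}\n")


def write_gaf(path: str | Path, annotations: list[tuple[str, str]]) -> None:
    """Write a minimal GAF 2.2 file from (gene symbol, term id) pairs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene, term in annotations:
            cols = ["DB", gene, gene, "", term, "REF", "IEA", "", "P",
                    "", "", "protein", "taxon:0000", "20120816", "DB", "", ""]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------


def write_model_json(model, path: str | Path) -> None:
    """Serialize a trained model (round-trippable, byte-deterministic).

    Nodes carry time index, mean and variance; split nodes carry their
    classifier weight matrix (one row per child, child 0 the zero-weight
    reference).  Gene-to-path assignments and the run configuration are
    embedded so a run is reproducible from the file alone.
    """
    from drem2.model_core import DremModel  # local import to avoid a cycle

    if not isinstance(model, DremModel):
        raise TypeError("write_model_json expects a DremModel")
    if not model.trained:
        raise ValueError("refusing to serialize an untrained model")
    payload = model.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path: str | Path):
    from drem2.model_core import DremModel

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return DremModel.from_dict(payload)
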