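"""Expression preprocessing: log transform, replicate collapse, change
filtering and first-time-point anchoring.

The pipeline order is fixed: log -> collapse -> filter -> anchor.  Each stage
is idempotent on its own output, so running the pipeline twice is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from drem2.io_formats import ExpressionTable


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing pipeline.

    ``min_abs_change`` drops genes whose absolute log2 ratio never reaches
    the threshold at any time point; genes exactly at the threshold are kept.
    ``anchor_at_zero`` prepends a synthetic all-zero time point 0 when the
    data was expressed as fold change against a baseline, so every gene
    starts co-expressed at ratio 0.
    """

    take_log2: bool = False
    replicate_collapse: str = "mean"
    min_abs_change: float = 0.0
    anchor_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.min_abs_change < 0:
            raise ValueError("min_abs_change must be >= 0")
        if self.replicate_collapse not in ("mean", "median"):
            raise ValueError("replicate_collapse must be 'mean' or 'median'")


def log_transform(table: ExpressionTable) -> ExpressionTable:
    """log2-transform a ratio-dialect table; identity on log2 tables."""
    if table.dialect == "log2":
        return table
    finite = ~np.isnan(table.values)
    if np.any(table.values[finite] <= 0):
        i, j = map(int, np.argwhere(finite & (table.values <= 0))[0])
        raise ValueError(
            f"nonpositive ratio {table.values[i, j]} for gene "
            f"{table.gene_ids[i]!r}, column {j} — cannot take log2"
        )
    return ExpressionTable(
        list(table.gene_ids),
        list(table.time_labels),
        np.log2(table.values),
        list(table.replicate_map),
        "log2",
    )


def collapse_replicates(
    table: ExpressionTable, cfg: PreprocessConfig | None = None
) -> ExpressionTable:
    """Combine replicate columns into one column per time point.

    Missing values are skipped; a time point missing in all replicates of a
    gene stays missing.  With a single replicate per time point this is the
    identity (up to column order).
    """
    cfg = cfg or PreprocessConfig()
    if table.is_collapsed:
        return table
    rep = np.asarray(table.replicate_map)
    reduce = np.nanmean if cfg.replicate_collapse == "mean" else np.nanmedian
    out = np.full((table.n_genes, table.n_times), np.nan)
    for t in range(table.n_times):
        cols = table.values[:, rep == t]
        any_obs = ~np.all(np.isnan(cols), axis=1)
        if any_obs.any():
            out[any_obs, t] = reduce(cols[any_obs], axis=1)
    return ExpressionTable(
        list(table.gene_ids),
        list(table.time_labels),
        out,
        list(range(table.n_times)),
        table.dialect,
    )


def filter_min_change(table: ExpressionTable, threshold: float) -> ExpressionTable:
    """Drop genes whose max |log2 ratio| over time is strictly below threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if table.dialect != "log2":
        raise ValueError("filter_min_change requires log2 dialect")
    if threshold == 0:
        out = table
        out.n_removed = 0
        return out
    with np.errstate(invalid="ignore"):
        max_abs = np.nanmax(np.abs(table.values), axis=1)
    max_abs = np.where(np.isnan(max_abs), 0.0, max_abs)
    keep = max_abs >= threshold
    out = ExpressionTable(
        [g for g, k in zip(table.gene_ids, keep) if k],
        list(table.time_labels),
        table.values[keep],
        list(table.replicate_map),
        table.dialect,
    )
    out.n_removed = int((~keep).sum())
    return out


def anchor_first_timepoint(table: ExpressionTable) -> ExpressionTable:
    """Prepend an all-zero time point 0 unless the first column already is one.

    Requires a collapsed, log2-dialect table: the model assumes all genes
    start co-expressed at ratio 0 at the root state.
    """
    if table.dialect != "log2":
        raise ValueError("anchor_first_timepoint requires log2 dialect")
    if not table.is_collapsed:
        raise ValueError("collapse replicates before anchoring")
    first = table.values[:, 0]
    if np.all(np.isnan(first) | (first == 0.0)) and not np.all(np.isnan(first)):
        return table
    zeros = np.zeros((table.n_genes, 1))
    return ExpressionTable(
        list(table.gene_ids),
        ["0"] + list(table.time_labels),
        np.hstack([zeros, table.values]),
        list(range(table.n_times + 1)),
        table.dialect,
    )


def preprocess(table: ExpressionTable, cfg: PreprocessConfig) -> ExpressionTable:
    """Full pipeline: log -> collapse -> filter -> anchor."""
    if cfg.take_log2 or table.dialect == "ratio":
        table = log_transform(table)
    table = collapse_replicates(table, cfg)
    table = filter_min_change(table, cfg.min_abs_change)
    if cfg.anchor_at_zero:
        table = anchor_first_timepoint(table)
    return table
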