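"""Classifier feature assembly from binding data.

Three concerns live here:

* converting ChIP p-values to nonnegative binding values, b = -log10(p);
* elevating or depressing a TF's binding prior from its own expression via
  the logistic multiplier m(e) = 2*sigma(w*e), where sigma is the standard
  logistic function and w the expression scaling weight (m(0) = 1, bounded
  in (0, 2), strictly increasing in e);
* selecting, for the transition into each time point, the effective TF x
  gene feature matrix from a mixed static/dynamic binding set (a dynamic
  grid for time t overrides a TF's static row at that transition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from drem2.io_formats import BindingMatrix, DynamicBindingSet, ExpressionTable


@dataclass
class ScalingConfig:
    """TF-expression prior scaling: m(e) = 2*sigma(weight*e)."""

    enabled: bool = False
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("expression scaling weight must be >= 0")


def pvalue_to_binding(p):
    """b = -log10(p) for p in (0, 1]; vectorized."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    b = -np.log10(p)
    return float(b) if b.ndim == 0 else b


def binding_to_pvalue(b):
    """Inverse of :func:`pvalue_to_binding`: p = 10**(-b)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("binding values must be >= 0")
    p = np.power(10.0, -b)
    return float(p) if p.ndim == 0 else p


def expression_multiplier(e, cfg: ScalingConfig):
    """Prior multiplier from a TF's log2 expression ratio.

    Equals 1 at e=0 or weight=0; tends to 2 as the TF is strongly
    up-regulated and to 0 as it is strongly repressed.
    """
    e = np.asarray(e, dtype=float)
    m = 2.0 / (1.0 + np.exp(-cfg.weight * e))
    return float(m) if m.ndim == 0 else m


def scale_binding(
    binding: BindingMatrix,
    tf_expression: dict[str, np.ndarray] | None,
    t: int,
    cfg: ScalingConfig,
) -> BindingMatrix:
    """Multiply each TF's row by its expression multiplier at time t.

    The magnitude is scaled and the sign preserved, so three-state rows keep
    their activator/repressor reading; zeros stay zero.  TFs without an
    expression trajectory (or a missing value at t) are left unchanged.
    """
    if not cfg.enabled or cfg.weight == 0 or not tf_expression:
        return binding
    values = binding.values.copy()
    lookup = {k.strip().lower(): v for k, v in tf_expression.items()}
    for i, tf in enumerate(binding.tf_ids):
        traj = lookup.get(tf.strip().lower())
        if traj is None or t >= len(traj):
            continue
        e = traj[t]
        if np.isnan(e):
            continue
        m = expression_multiplier(e, cfg)
        values[i] = np.sign(values[i]) * np.abs(values[i]) * m
    # scaled magnitudes are no longer three-state and may keep repressor signs
    return BindingMatrix(
        list(binding.tf_ids), list(binding.gene_ids), values, "signed"
    )


def tf_trajectories(
    table: ExpressionTable, tf_ids: list[str]
) -> dict[str, np.ndarray]:
    """Extract the expression trajectories of the TFs present in the table."""
    out: dict[str, np.ndarray] = {}
    for tf in tf_ids:
        traj = table.trajectory(tf)
        if traj is not None:
            out[tf] = traj
    return out


def features_for_transition(
    dyn: DynamicBindingSet,
    t: int,
    n_times: int,
    cfg: ScalingConfig | None = None,
    tf_expression: dict[str, np.ndarray] | None = None,
) -> BindingMatrix:
    """Effective TF x gene feature matrix for the transition into time t.

    With a static-only set the same (scaled) matrix serves every transition;
    with dynamic grids, the grid registered for t supplies the rows of its
    TFs and static-only TFs fall back to their static rows (dynamic
    overrides static on collision).
    """
    if not 1 <= t < n_times:
        raise ValueError(f"transition time {t} out of range 1..{n_times - 1}")
    if not dyn.is_aligned():
        raise ValueError("align the binding set before feature assembly")
    cfg = cfg or ScalingConfig()

    static = dyn.static_part
    dynamic = dyn.dynamic_parts.get(t)
    if dynamic is None:
        if static is None:
            # fully dynamic set with no grid for this transition: no evidence
            ref = dyn.parts[0]
            base = BindingMatrix(
                list(ref.tf_ids),
                list(ref.gene_ids),
                np.zeros_like(ref.values),
                "continuous",
            )
        else:
            base = static
    elif static is None:
        base = dynamic
    else:
        values = static.values.copy()
        dyn_tfs = {
            i for i, tf in enumerate(dynamic.tf_ids)
            if np.any(dynamic.values[i] != 0)
        }
        for i in dyn_tfs:
            values[i] = dynamic.values[i]
        if static.encoding == dynamic.encoding == "three_state":
            encoding = "three_state"
        elif np.all(values >= 0):
            encoding = "continuous"
        else:
            encoding = "signed"
        base = BindingMatrix(list(static.tf_ids), list(static.gene_ids), values, encoding)
    return scale_binding(base, tf_expression, t, cfg)


def feature_matrices(
    dyn: DynamicBindingSet,
    n_times: int,
    cfg: ScalingConfig | None = None,
    tf_expression: dict[str, np.ndarray] | None = None,
) -> dict[int, np.ndarray]:
    """TF x gene feature matrix for every transition t = 1..n_times-1."""
    return {
        t: features_for_transition(dyn, t, n_times, cfg, tf_expression).values
        for t in range(1, n_times)
    }
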