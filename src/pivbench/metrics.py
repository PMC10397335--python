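"""Agreement statistics between agent ground truth and PIV output.

Global order parameter

    v_a(t) = | (1/N) sum_i v_i / |v_i| |          in [0, 1]

(1 = perfect global alignment, 0 = disorder); its local analogue
v_a^{x_j,R} over the agents within minimum-image distance R of a circle
center x_j, and the mean v_a^R over all non-empty circles.  The circles are
centered on the PIV-vector anchors, so the same formula applied to the
(unit-normalized) PIV vectors yields v_a^{R,PIV} and the coherence
difference D^R = |v_a^{R,SPP} - v_a^{R,PIV}|.

The alignment score

    A^R(t) = (1/M) sum_j (1/N_j^R) sum_{i: |x_j - x_i| <= R}
             cos(angle(v_j, w_i))                  in [-1, 1]

averages, over the M valid PIV vectors with at least one enclosed agent,
the cosine between the vector and the velocities of the nearby agents —
1 when PIV reproduces the local motion, 0 for no relation, -1 for
anti-alignment.

Characteristic scales: gamma0(N) = Gamma/sqrt(N) is the grid side holding
one agent on average; R0(N) = gamma0/sqrt(pi) the analogous circle radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .piv import PIVField
from .vicsek import AgentState, VicsekParams

__all__ = [
    "MetricUndefinedError",
    "MetricSeries",
    "order_parameter",
    "local_order",
    "local_order_piv",
    "alignment_score",
    "coherence_difference",
    "gamma0",
    "r0",
    "characteristic_radius",
]


class MetricUndefinedError(ValueError):
    """Raised when a metric has an empty averaging set."""


@dataclass
class MetricSeries:
    """Time-indexed values of one metric at one evaluation radius."""

    metric_name: str                  # one of {v_a, v_a^R, A^R, D^R}
    times: np.ndarray
    values: np.ndarray
    R_px: float | None = None         # absent for v_a
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times, "metric": self.metric_name,
                           "value": self.values})
        df["R_px"] = self.R_px if self.R_px is not None else np.nan
        for k, v in self.provenance.items():
            df[k] = v
        return df


def _unit(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    return vectors / norms


def order_parameter(state: AgentState, v0: float | None = None) -> float:
    """Magnitude of the mean unit-velocity vector over all agents."""
    if state.n < 1:
        raise MetricUndefinedError("order parameter undefined for empty state")
    if v0 is not None and v0 == 0:
        raise MetricUndefinedError("order parameter undefined at zero speed")
    h = state.heading_vectors()
    return float(np.linalg.norm(h.mean(axis=0)))


def _min_image_dist2(centers_px: np.ndarray, points_px: np.ndarray,
                     period_px: float) -> np.ndarray:
    """(C, P) squared minimum-image distances in pixel space."""
    d = centers_px[:, None, :] - points_px[None, :, :]
    d -= period_px * np.round(d / period_px)
    return np.einsum("cpk,cpk->cp", d, d)


def _local_va(centers_px: np.ndarray, points_px: np.ndarray,
              units: np.ndarray, R_px: float,
              period_px: float) -> tuple[np.ndarray, float]:
    """Per-center |mean unit vector| over enclosed points; nan when empty."""
    within = _min_image_dist2(centers_px, points_px, period_px) <= R_px * R_px
    counts = within.sum(axis=1)
    sums = within.astype(float) @ units
    per_center = np.full(len(centers_px), np.nan)
    nz = counts > 0
    if not np.any(nz):
        raise MetricUndefinedError("no center encloses any point at this radius")
    per_center[nz] = np.linalg.norm(sums[nz], axis=1) / counts[nz]
    return per_center, float(np.nanmean(per_center))


def local_order(state: AgentState, centers_px: np.ndarray, R_px: float,
                params: VicsekParams) -> tuple[np.ndarray, float]:
    """Local order v_a^{x_j,R} per center plus their mean v_a^R.

    Agent positions are converted to pixels; distances use the periodic
    minimum-image rule with period L * px_per_unit.  Centers enclosing no
    agent are nan and excluded from the mean.
    """
    if params.v0 == 0:
        raise MetricUndefinedError("local order undefined at zero speed")
    centers_px = np.atleast_2d(np.asarray(centers_px, dtype=float))
    period = params.L * params.px_per_unit
    return _local_va(centers_px, state.pos * params.px_per_unit,
                     state.heading_vectors(), R_px, period)


def local_order_piv(field: PIVField, R_px: float,
                    period_px: float,
                    centers_px: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """v_a^{R,PIV}: the local-order formula applied to valid PIV vectors.

    Vectors are unit-normalized (zero-magnitude vectors have no direction
    and are dropped).  Default centers are the valid-vector anchors.
    """
    keep = field.valid & (np.linalg.norm(field.vectors, axis=1) > 0)
    if not np.any(keep):
        raise MetricUndefinedError("no valid PIV vectors")
    if centers_px is None:
        centers_px = field.anchors[keep]
    return _local_va(np.atleast_2d(centers_px), field.anchors[keep],
                     _unit(field.vectors[keep]), R_px, period_px)


def alignment_score(field: PIVField, state: AgentState, R_px: float,
                    params: VicsekParams) -> float:
    """A^R: mean cosine between each valid PIV vector and the velocities of
    agents within R of its anchor, averaged over the M participating vectors.

    The state must be the one at the earlier frame of the PIV pair.  Vectors
    enclosing no agent, and zero-magnitude vectors, are excluded from M.
    """
    if field.t != state.t:
        raise ValueError(
            f"field (t={field.t}) and state (t={state.t}) must share the "
            "time index of the earlier frame"
        )
    if params.v0 == 0:
        raise MetricUndefinedError("alignment score undefined at zero speed")
    keep = field.valid & (np.linalg.norm(field.vectors, axis=1) > 0)
    if not np.any(keep):
        raise MetricUndefinedError("no valid PIV vectors")
    anchors = field.anchors[keep]
    vunit = _unit(field.vectors[keep])
    period = params.L * params.px_per_unit
    within = _min_image_dist2(anchors, state.pos * params.px_per_unit,
                              period) <= R_px * R_px
    counts = within.sum(axis=1)
    participating = counts > 0
    if not np.any(participating):
        raise MetricUndefinedError("no PIV vector encloses any agent (M = 0)")
    cosines = vunit @ state.heading_vectors().T          # (M_keep, N)
    inner = (cosines * within)[participating].sum(axis=1) / counts[participating]
    return float(inner.mean())


def coherence_difference(state: AgentState, field: PIVField, R_px: float,
                         params: VicsekParams) -> float:
    """D^R = |v_a^{R,SPP} - v_a^{R,PIV}| with circles centered on the
    anchors of the valid PIV vectors."""
    keep = field.valid & (np.linalg.norm(field.vectors, axis=1) > 0)
    if not np.any(keep):
        raise MetricUndefinedError("no valid PIV vectors")
    centers = field.anchors[keep]
    _, va_spp = local_order(state, centers, R_px, params)
    period = params.L * params.px_per_unit
    _, va_piv = local_order_piv(field, R_px, period, centers_px=centers)
    return float(abs(va_spp - va_piv))


def gamma0(N: int, Gamma: float) -> float:
    """Grid side containing a single agent on average: Gamma / sqrt(N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if Gamma <= 0:
        raise ValueError("Gamma must be positive")
    return float(Gamma / np.sqrt(N))


def r0(N: int, Gamma: float) -> float:
    """Circle radius containing a single agent on average (uniform law):
    gamma0(N) / sqrt(pi) = Gamma / sqrt(pi * N)."""
    return gamma0(N, Gamma) / float(np.sqrt(np.pi))


def characteristic_radius(N: int, Gamma: float,
                          convention: str = "formula") -> float:
    """R0 under either convention.

    'formula': the defining relation R0 = gamma0/sqrt(pi).  'grid': R0 =
    gamma0, the alternative normalization in which R/R0 = 1 matches the grid
    side (both conventions appear in the literature for N = 300, Gamma = 615:
    20.0 px vs 35.5 px).  Experiments record which convention was active.
    """
    if convention == "formula":
        return r0(N, Gamma)
    if convention == "grid":
        return gamma0(N, Gamma)
    raise ValueError(f"unknown r0 convention {convention!r}")
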