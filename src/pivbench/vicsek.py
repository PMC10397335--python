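"""Discrete-time Vicsek model of self-propelled particles.

N point agents move at constant speed v0 in a periodic square box of side L.
At every step each agent adopts the mean heading of all agents within the
interaction radius r (itself included) plus an independent uniform angular
perturbation in [-eta0/2, eta0/2]:

    r_i(t+1) = r_i(t) + v0 * (cos theta_i(t), sin theta_i(t)) * dt
    theta_i(t+1) = atan2( sum_j sin theta_j(t), sum_j cos theta_j(t) ) + dtheta_i

with j running over the neighbor set of i at time t (minimum-image distance
<= r).  The update is synchronous: both rules read the complete time-t
configuration.  The noise amplitude eta0 is the temperature-like control
parameter of the order-disorder transition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VicsekParams",
    "AgentState",
    "Trajectory",
    "init_state",
    "mean_neighbor_angle",
    "mean_neighbor_angles",
    "neighbor_adjacency",
    "step",
    "simulate",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class VicsekParams:
    """Simulation parameters.

    Defaults reproduce the study conditions: a box of L = 5 arbitrary units
    imaged at 123 px/unit (615 x 615 px), N = 300 agents, speed 0.03
    units/step (3.7 px/frame) and interaction radius 0.5 units (61.5 px).
    """

    L: float = 5.0
    px_per_unit: float = 123.0
    N: int = 300
    v0: float = 0.03
    r: float = 0.5
    eta0: float = np.pi / 6
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("box side L must be positive")
        if self.v0 < 0:
            raise ValueError("speed v0 must be non-negative")
        if not (0 < self.r <= self.L):
            raise ValueError("interaction radius r must satisfy 0 < r <= L")
        if self.N < 0 or int(self.N) != self.N:
            raise ValueError("agent count N must be a non-negative integer")
        if not (0.0 <= self.eta0 <= TWO_PI):
            raise ValueError("noise amplitude eta0 must lie in [0, 2*pi]")
        if self.gamma_img <= 0:
            raise ValueError("image side L*px_per_unit must round to a positive integer")

    @property
    def gamma_img(self) -> int:
        """Image side Gamma in pixels."""
        return int(round(self.L * self.px_per_unit))

    @property
    def v0_px(self) -> float:
        """Speed in pixels per simulation step."""
        return self.v0 * self.px_per_unit


@dataclass
class AgentState:
    """Positions and headings of all agents at one time step.

    pos is (N, 2) with columns (x, y) in box units, each in [0, L);
    theta is (N,) in radians, each in [0, 2*pi).  Agent identity is the
    positional index.  The implied velocity of agent i is
    v0 * (cos theta_i, sin theta_i).
    """

    t: int
    pos: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(-1, 2)
        self.theta = np.asarray(self.theta, dtype=float).reshape(-1)
        if self.pos.shape[0] != self.theta.shape[0]:
            raise ValueError("pos and theta must describe the same number of agents")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def heading_vectors(self) -> np.ndarray:
        """(N, 2) unit vectors (cos theta, sin theta)."""
        return np.column_stack([np.cos(self.theta), np.sin(self.theta)])

    def copy(self) -> "AgentState":
        return AgentState(self.t, self.pos.copy(), self.theta.copy())


@dataclass
class Trajectory:
    """Time-ordered sequence of AgentStates with constant membership."""

    states: list[AgentState]
    params: VicsekParams
    seed: int

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, t: int) -> AgentState:
        return self.states[t]

    def __iter__(self) -> Iterator[AgentState]:
        return iter(self.states)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for s in self.states:
            frames.append(
                pd.DataFrame(
                    {
                        "t": s.t,
                        "agent_id": np.arange(s.n),
                        "x_units": s.pos[:, 0],
                        "y_units": s.pos[:, 1],
                        "theta_rad": s.theta,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    return np.mod(theta, TWO_PI)


def min_image(delta: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image displacement for a periodic box of side L."""
    return delta - L * np.round(delta / L)


def _adjacency_brute(pos: np.ndarray, r: float, L: float) -> np.ndarray:
    d = pos[:, None, :] - pos[None, :, :]
    d = min_image(d, L)
    return np.einsum("ijk,ijk->ij", d, d) <= r * r


def _adjacency_cells(pos: np.ndarray, r: float, L: float) -> np.ndarray:
    """Cell-list neighbor search; cell size >= r, 3x3 neighborhood scan.

    Produces the identical boolean adjacency matrix as the brute-force path
    (same distance rule), so downstream angle sums are bitwise equal.
    """
    n = pos.shape[0]
    nc = int(L // r)
    if nc < 3:  # box too small for a meaningful cell decomposition
        return _adjacency_brute(pos, r, L)
    cell = L / nc
    ix = np.minimum((pos[:, 0] / cell).astype(int), nc - 1)
    iy = np.minimum((pos[:, 1] / cell).astype(int), nc - 1)
    cell_of = ix * nc + iy
    order = np.argsort(cell_of, kind="stable")
    sorted_cells = cell_of[order]
    starts = np.searchsorted(sorted_cells, np.arange(nc * nc))
    ends = np.searchsorted(sorted_cells, np.arange(nc * nc), side="right")

    adj = np.zeros((n, n), dtype=bool)
    r2 = r * r
    for i in range(n):
        cands = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                c = ((ix[i] + dx) % nc) * nc + (iy[i] + dy) % nc
                cands.append(order[starts[c]:ends[c]])
        cand = np.concatenate(cands)
        d = min_image(pos[cand] - pos[i], L)
        adj[i, cand[(d * d).sum(axis=1) <= r2]] = True
    return adj


def neighbor_adjacency(pos: np.ndarray, r: float, L: float,
                       method: str = "auto") -> np.ndarray:
    """Boolean N x N matrix: adj[i, j] iff minimum-image dist(i, j) <= r.

    method: 'brute' (O(N^2) distance matrix), 'cells' (cell list), or 'auto'
    (brute below ~600 agents).  Both paths return identical matrices.
    """
    if method == "auto":
        method = "brute" if pos.shape[0] <= 600 else "cells"
    if method == "brute":
        return _adjacency_brute(pos, r, L)
    if method == "cells":
        return _adjacency_cells(pos, r, L)
    raise ValueError(f"unknown neighbor search method {method!r}")


def mean_neighbor_angles(state: AgentState, params: VicsekParams,
                         method: str = "auto") -> np.ndarray:
    """Mean neighbor heading for every agent, quadrant-correct.

    atan2 of the summed sines and cosines over the neighbor set (self
    included) mapped to [0, 2*pi).  If both sums are exactly zero
    (measure-zero cancellation) the agent keeps its current heading.
    """
    adj = neighbor_adjacency(state.pos, params.r, params.L, method=method)
    s = adj @ np.sin(state.theta)
    c = adj @ np.cos(state.theta)
    ang = _wrap_angle(np.arctan2(s, c))
    degenerate = (s == 0.0) & (c == 0.0)
    if np.any(degenerate):
        ang = np.where(degenerate, state.theta, ang)
    return ang


def mean_neighbor_angle(state: AgentState, i: int, r: float, L: float) -> float:
    """Mean heading over agents within minimum-image distance r of agent i."""
    d = min_image(state.pos - state.pos[i], L)
    mask = (d * d).sum(axis=1) <= r * r
    s = float(np.sin(state.theta[mask]).sum())
    c = float(np.cos(state.theta[mask]).sum())
    if s == 0.0 and c == 0.0:
        return float(state.theta[i])
    return float(np.mod(np.arctan2(s, c), TWO_PI))


def init_state(params: VicsekParams, seed: int) -> AgentState:
    """Uniform random positions in [0, L)^2 and headings in [0, 2*pi)."""
    return _init_from_rng(params, np.random.default_rng(seed))


def _init_from_rng(params: VicsekParams, rng: np.random.Generator) -> AgentState:
    pos = rng.uniform(0.0, params.L, size=(params.N, 2))
    theta = rng.uniform(0.0, TWO_PI, size=params.N)
    return AgentState(t=0, pos=pos, theta=theta)


def step(state: AgentState, params: VicsekParams,
         rng: np.random.Generator, method: str = "auto") -> AgentState:
    """One synchronous update: positions advance along time-t headings, new
    headings are the time-t neighborhood means plus per-agent uniform noise."""
    new_pos = np.mod(
        state.pos + params.v0 * params.dt * state.heading_vectors(), params.L
    )
    mean_ang = mean_neighbor_angles(state, params, method=method)
    noise = rng.uniform(-params.eta0 / 2.0, params.eta0 / 2.0, size=state.n)
    return AgentState(t=state.t + 1, pos=new_pos, theta=_wrap_angle(mean_ang + noise))


def simulate(params: VicsekParams, T: int, seed: int,
             method: str = "auto") -> Trajectory:
    """Run T update steps from a random initial condition; T+1 states."""
    if T < 0:
        raise ValueError("T must be >= 0")
    rng = np.random.default_rng(seed)
    state = _init_from_rng(params, rng)
    states = [state]
    for _ in range(T):
        state = step(state, params, rng, method=method)
        states.append(state)
    return Trajectory(states=states, params=params, seed=seed)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, params: VicsekParams,
                        seed: int = -1) -> Trajectory:
    """Load an externally supplied trajectory table (t, agent_id, x_units,
    y_units, theta_rad).  Agent order within each time block follows
    agent_id; membership must be constant."""
    df = pd.read_csv(path)
    required = {"t", "agent_id", "x_units", "y_units", "theta_rad"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    states = []
    for t, block in df.sort_values(["t", "agent_id"]).groupby("t", sort=True):
        states.append(
            AgentState(
                t=int(t),
                pos=block[["x_units", "y_units"]].to_numpy(),
                theta=block["theta_rad"].to_numpy(),
            )
        )
    counts = {s.n for s in states}
    if len(counts) > 1:
        raise ValueError("agent membership varies across time blocks")
    return Trajectory(states=states, params=params, seed=seed)
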