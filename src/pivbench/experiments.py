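"""End-to-end computational experiments: simulate -> render -> PIV -> metrics.

Each experiment runs the full pipeline under a seeded ExperimentConfig and
returns a tidy pandas DataFrame.  Trials are replicated with derived seeds
(base seed + trial index, recorded per row).  Metric values that are
undefined under the exclusion rules (no valid vectors, empty circles) are
recorded as NaN — never as zero.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as mt
from .piv import PIVField, PIVParams, piv_field
from .render import Frame, RenderParams, render_frame
from .vicsek import Trajectory, VicsekParams, simulate

__all__ = [
    "ExperimentConfig",
    "run_timeseries",
    "run_grid_radius_landscape",
    "run_noise_radius_landscape",
    "run_sampling_rate",
    "find_transition",
]

log = logging.getLogger("pivbench")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    radii are evaluation radii R in pixels; noise_levels are eta0 values in
    radians; t_eval is the time of the PIV pair (t_eval - tau, t_eval) for
    single-time experiments; stationary_window bounds the time average used
    for v_a and <A^R>.
    """

    vicsek: VicsekParams = field(default_factory=VicsekParams)
    render: RenderParams = field(default_factory=RenderParams)
    piv: PIVParams = field(default_factory=PIVParams)
    radii: tuple[float, ...] = (30.0, 70.0, 120.0, 200.0)
    noise_levels: tuple[float, ...] = (
        np.pi / 6, 3 * np.pi / 6, np.pi, 11 * np.pi / 6,
    )
    trials: int = 1
    t_eval: int = 300
    tau: int = 1
    seed: int = 0
    stationary_window: tuple[int, int] = (200, 300)
    r0_convention: str = "formula"

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.t_eval < self.tau:
            raise ValueError("t_eval must allow at least one PIV pair")
        if self.render.gamma_img != self.vicsek.gamma_img:
            raise ValueError("render.gamma_img must match the simulated image side")
        mt.characteristic_radius(1, 1.0, self.r0_convention)  # validates name
        if self.render.major_px * 2 > self.piv.grid_px:
            warnings.warn(
                "particle size is not small relative to the PIV grid; "
                "correlation peaks may be unreliable", stacklevel=2,
            )
        max_disp = self.tau * self.vicsek.v0_px
        if max_disp > self.piv.margin:
            warnings.warn(
                f"per-interval displacement {max_disp:.1f} px exceeds the "
                f"search margin {self.piv.margin} px; vectors will saturate",
                stacklevel=2,
            )

    def trial_seed(self, trial: int) -> int:
        return int(self.seed) + int(trial)

    @property
    def r0_px(self) -> float:
        return mt.characteristic_radius(
            self.vicsek.N, self.vicsek.gamma_img, self.r0_convention
        )

    @property
    def gamma0_px(self) -> float:
        return mt.gamma0(self.vicsek.N, self.vicsek.gamma_img)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "vicsek": asdict(self.vicsek),
            "render": asdict(self.render),
            "piv": asdict(self.piv),
            "radii": list(self.radii),
            "noise_levels": list(self.noise_levels),
            "trials": self.trials,
            "t_eval": self.t_eval,
            "tau": self.tau,
            "seed": self.seed,
            "stationary_window": list(self.stationary_window),
            "r0_convention": self.r0_convention,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            vicsek=VicsekParams(**d.get("vicsek", {})),
            render=RenderParams(**d.get("render", {})),
            piv=PIVParams(**d.get("piv", {})),
            radii=tuple(d.get("radii", (30.0, 70.0, 120.0, 200.0))),
            noise_levels=tuple(d.get("noise_levels",
                                     (np.pi / 6, np.pi / 2, np.pi, 11 * np.pi / 6))),
            trials=int(d.get("trials", 1)),
            t_eval=int(d.get("t_eval", 300)),
            tau=int(d.get("tau", 1)),
            seed=int(d.get("seed", 0)),
            stationary_window=tuple(d.get("stationary_window", (200, 300))),
            r0_convention=d.get("r0_convention", "formula"),
        )


def _piv_pair(traj: Trajectory, t: int, tau: int, rp: RenderParams,
              pp: PIVParams) -> PIVField:
    """PIV between the recorded frames at t and t + tau."""
    f0 = render_frame(traj[t], traj.params, rp)
    f1 = render_frame(traj[t + tau], traj.params, rp)
    return piv_field(f0, f1, pp)


def _metric_rows(cfg: ExperimentConfig, traj: Trajectory, t: int,
                 fld: PIVField, radii: Sequence[float],
                 extra: dict) -> list[dict]:
    """A^R and D^R rows at one time for each radius, plus v_a and v_a^R."""
    state = traj[t]
    rows = []
    base = dict(extra, t=t, n_vectors=fld.n_valid)
    rows.append(dict(base, metric="v_a", R_px=np.nan, R_over_R0=np.nan,
                     value=mt.order_parameter(state)))
    for R in radii:
        rnorm = R / cfg.r0_px
        for name, fn in (("A^R", mt.alignment_score),
                         ("D^R", lambda f, s, R, p: mt.coherence_difference(s, f, R, p))):
            try:
                val = fn(fld, state, R, cfg.vicsek)
            except mt.MetricUndefinedError:
                val = np.nan   # missing, never zero
            rows.append(dict(base, metric=name, R_px=R, R_over_R0=rnorm, value=val))
        try:
            keep = fld.valid
            _, va_r = mt.local_order(state, fld.anchors[keep], R, cfg.vicsek)
        except mt.MetricUndefinedError:
            va_r = np.nan
        rows.append(dict(base, metric="v_a^R", R_px=R, R_over_R0=rnorm, value=va_r))
    return rows


def run_timeseries(cfg: ExperimentConfig, eta0: float | None = None,
                   t_min: int = 0, t_max: int | None = None,
                   trial: int = 0) -> pd.DataFrame:
    """A^R(t), D^R(t), v_a^R(t) and v_a(t) over a time window, one noise level.

    PIV runs on every recorded pair (t, t + tau) with t_min <= t and
    t + tau <= t_max (default: the configured t_eval horizon).
    """
    eta = cfg.noise_levels[0] if eta0 is None else float(eta0)
    params = replace(cfg.vicsek, eta0=eta)
    if t_max is None:
        t_max = cfg.t_eval
    seed = cfg.trial_seed(trial)
    tic = time.perf_counter()
    traj = simulate(params, t_max, seed)
    log.info("simulate eta0=%.3f T=%d: %.1fs", eta, t_max, time.perf_counter() - tic)
    cfg_run = replace(cfg, vicsek=params)
    rows: list[dict] = []
    tic = time.perf_counter()
    prev: Frame | None = None
    for t in range(t_min, t_max - cfg.tau + 1, cfg.tau):
        f0 = prev if prev is not None and prev.t == t else render_frame(traj[t], params, cfg.render)
        f1 = render_frame(traj[t + cfg.tau], params, cfg.render)
        fld = piv_field(f0, f1, cfg.piv)
        prev = f1
        rows.extend(_metric_rows(cfg_run, traj, t, fld, cfg.radii,
                                 dict(eta0=eta, tau=cfg.tau, trial=trial,
                                      seed=seed, r0_convention=cfg.r0_convention)))
    log.info("piv+metrics over %d pairs: %.1fs",
             (t_max - cfg.tau - t_min) // cfg.tau + 1, time.perf_counter() - tic)
    return pd.DataFrame(rows)


def _single_pair_scores(cfg: ExperimentConfig, eta: float, trial: int,
                        pp: PIVParams, radii: Sequence[float]) -> dict[float, float]:
    """A^R for each radius from the single PIV pair (t_eval - tau, t_eval)."""
    params = replace(cfg.vicsek, eta0=eta)
    traj = simulate(params, cfg.t_eval, cfg.trial_seed(trial))
    rp = cfg.render
    fld = _piv_pair(traj, cfg.t_eval - cfg.tau, cfg.tau, rp, pp)
    state = traj[cfg.t_eval - cfg.tau]
    out = {}
    for R in radii:
        try:
            out[R] = mt.alignment_score(fld, state, R, params)
        except mt.MetricUndefinedError:
            out[R] = np.nan
    return out


def run_noise_radius_landscape(cfg: ExperimentConfig) -> pd.DataFrame:
    """Trial-averaged A^R over (eta0, R/R0) from the final recorded pair."""
    rows = []
    for eta in cfg.noise_levels:
        tic = time.perf_counter()
        per_trial = {R: [] for R in cfg.radii}
        for trial in range(cfg.trials):
            scores = _single_pair_scores(cfg, eta, trial, cfg.piv, cfg.radii)
            for R, v in scores.items():
                per_trial[R].append(v)
        for R in cfg.radii:
            vals = np.asarray(per_trial[R], dtype=float)
            rows.append({
                "eta0": eta, "R_px": R, "R_over_R0": R / cfg.r0_px,
                "A_R": float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan,
                "n_trials": int(np.isfinite(vals).sum()),
                "seed": cfg.seed, "r0_convention": cfg.r0_convention,
            })
        log.info("noise row eta0=%.3f: %.1fs", eta, time.perf_counter() - tic)
    return pd.DataFrame(rows)


def run_grid_radius_landscape(cfg: ExperimentConfig,
                              gamma_norms: Sequence[float] = (1.0, 2.0, 3.0),
                              R_norms: Sequence[float] = (1.0, 2.0, 3.0),
                              eta0: float | None = None) -> pd.DataFrame:
    """Trial-averaged A^R over (gamma/gamma0, R/R0) at one (high) noise level.

    Grid sides are the requested multiples of gamma0 rounded to the nearest
    even integer (the search step is half the grid and the margin half the
    step); border grids are handled by the periodic patch rule.
    """
    eta = float(eta0) if eta0 is not None else 11 * np.pi / 6
    g0 = cfg.gamma0_px
    r0px = cfg.r0_px
    gammas = [max(4, 2 * int(round(k * g0 / 2))) for k in gamma_norms]
    radii = [k * r0px for k in R_norms]
    rows = []
    for gamma_px, gnorm in zip(gammas, gamma_norms):
        pp = replace(cfg.piv, grid_px=gamma_px,
                     step_px=max(2, 2 * int(round(gamma_px / 4))))
        tic = time.perf_counter()
        per_trial = {R: [] for R in radii}
        for trial in range(cfg.trials):
            scores = _single_pair_scores(cfg, eta, trial, pp, radii)
            for R, v in scores.items():
                per_trial[R].append(v)
        for R, knorm in zip(radii, R_norms):
            vals = np.asarray(per_trial[R], dtype=float)
            rows.append({
                "eta0": eta, "gamma_px": gamma_px, "gamma_over_gamma0": gamma_px / g0,
                "gamma_norm_requested": gnorm, "R_px": R, "R_over_R0": R / r0px,
                "R_norm_requested": knorm,
                "A_R": float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan,
                "n_trials": int(np.isfinite(vals).sum()),
                "seed": cfg.seed, "r0_convention": cfg.r0_convention,
            })
        log.info("grid row gamma=%d: %.1fs", gamma_px, time.perf_counter() - tic)
    return pd.DataFrame(rows)


def run_sampling_rate(cfg: ExperimentConfig, taus: Sequence[int] = (1, 2, 4),
                      eta0: float | None = None) -> pd.DataFrame:
    """Time-averaged <A^R> over the stationary window as the recording step
    tau grows (simulation time increment stays 1)."""
    eta = float(eta0) if eta0 is not None else float(np.pi / 2)
    t_lo, t_hi = cfg.stationary_window
    rows = []
    for tau in taus:
        max_disp = tau * cfg.vicsek.v0_px
        if max_disp > cfg.piv.margin:
            warnings.warn(
                f"tau={tau}: displacement {max_disp:.1f} px exceeds the "
                f"search margin {cfg.piv.margin} px", stacklevel=2,
            )
        for trial in range(cfg.trials):
            sub = replace(cfg, tau=int(tau), t_eval=t_hi)
            df = run_timeseries(sub, eta0=eta, t_min=t_lo, t_max=t_hi, trial=trial)
            ar = df[df.metric == "A^R"] if not df.empty else df
            for R in cfg.radii:
                vals = (ar[ar.R_px == R].value.to_numpy()
                        if not ar.empty else np.array([]))
                rows.append({
                    "tau": int(tau), "eta0": eta, "R_px": R,
                    "R_over_R0": R / cfg.r0_px,
                    "mean_A_R": float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan,
                    "trial": trial, "seed": cfg.trial_seed(trial),
                })
    return pd.DataFrame(rows)


def stationary_order(cfg: ExperimentConfig, eta: float, trial: int) -> float:
    """Time-averaged v_a over the stationary window for one trial."""
    params = replace(cfg.vicsek, eta0=float(eta))
    t_lo, t_hi = cfg.stationary_window
    traj = simulate(params, t_hi, cfg.trial_seed(trial))
    return float(np.mean([mt.order_parameter(traj[t]) for t in range(t_lo, t_hi + 1)]))


def find_transition(cfg: ExperimentConfig,
                    sweep: Sequence[float] | None = None) -> tuple[float, pd.DataFrame]:
    """Critical noise where trial-averaged stationary v_a crosses 0.5.

    Linear interpolation between the bracketing sweep points.  Raises with
    the bracketing values when the sweep does not cross 0.5.
    """
    if sweep is None:
        sweep = np.linspace(np.pi / 2, 3 * np.pi / 2, 7)
    sweep = np.asarray(sorted(sweep), dtype=float)
    rows = []
    for eta in sweep:
        vals = [stationary_order(cfg, eta, trial) for trial in range(cfg.trials)]
        rows.append({"eta0": float(eta), "v_a": float(np.mean(vals)),
                     "n_trials": cfg.trials, "seed": cfg.seed})
        log.info("transition sweep eta0=%.3f v_a=%.3f", eta, rows[-1]["v_a"])
    df = pd.DataFrame(rows)
    va = df["v_a"].to_numpy()
    for i in range(len(sweep) - 1):
        if (va[i] - 0.5) * (va[i + 1] - 0.5) <= 0 and va[i] >= 0.5:
            f = (va[i] - 0.5) / (va[i] - va[i + 1])
            return float(sweep[i] + f * (sweep[i + 1] - sweep[i])), df
    raise RuntimeError(
        f"stationary v_a never crosses 0.5 on the sweep: endpoints "
        f"v_a({sweep[0]:.3f})={va[0]:.3f}, v_a({sweep[-1]:.3f})={va[-1]:.3f}"
    )
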