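"""Render agent configurations into synthetic microscopy-like images.

Each agent becomes a black filled oval (default 8 x 6 px) on a white
background, the major axis parallel to its heading — a minimal stand-in for
an elongated migrating cell.  Rasterization is binary: a pixel takes the
foreground intensity iff its center lies inside the rotated ellipse.  Agent
centers keep continuous (sub-pixel) coordinates so rasters change smoothly
as agents move; ellipses wrap periodically across image edges, matching the
periodic simulation box.

Pixel convention (single-sourced here, recorded in frame metadata): pixel
(row, col) samples the continuous point (row, col); agent x maps to column,
y to row; origin at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .vicsek import AgentState, Trajectory, VicsekParams

__all__ = [
    "RenderParams",
    "Frame",
    "render_frame",
    "render_sequence",
    "write_frames",
    "read_frames",
    "COORD_CONVENTION",
]

COORD_CONVENTION = "pixel (row, col) samples point (row, col); x->col, y->row; origin top-left"


@dataclass(frozen=True)
class RenderParams:
    gamma_img: int = 615          # image side in pixels
    major_px: float = 8.0         # oval major axis, pixels
    minor_px: float = 6.0         # oval minor axis, pixels
    fg: int = 0                   # particle intensity
    bg: int = 255                 # background intensity

    def __post_init__(self) -> None:
        if not (0 <= self.fg < self.bg <= 255):
            raise ValueError("intensities must satisfy 0 <= fg < bg <= 255")
        if not (self.major_px >= self.minor_px > 0):
            raise ValueError("axes must satisfy major_px >= minor_px > 0")
        if self.gamma_img <= 0:
            raise ValueError("gamma_img must be positive")


@dataclass
class Frame:
    """One 8-bit grayscale raster plus its provenance metadata."""

    t: int
    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")


def render_frame(state: AgentState, params: VicsekParams,
                 rp: RenderParams | None = None) -> Frame:
    """Rasterize one AgentState into a Frame.

    Overlapping ovals union (still fg); everything else is bg.
    """
    rp = rp or RenderParams(gamma_img=params.gamma_img)
    if rp.gamma_img != params.gamma_img:
        raise ValueError(
            f"RenderParams.gamma_img={rp.gamma_img} does not match "
            f"VicsekParams image side {params.gamma_img}"
        )
    if state.n and (np.any(state.pos < 0) or np.any(state.pos >= params.L)):
        raise ValueError("agent positions must be wrapped into [0, L)")

    G = rp.gamma_img
    img = np.full((G, G), rp.bg, dtype=np.uint8)
    a = rp.major_px / 2.0
    b = rp.minor_px / 2.0
    ppu = params.px_per_unit
    cos_t = np.cos(state.theta)
    sin_t = np.sin(state.theta)
    for i in range(state.n):
        cx = state.pos[i, 0] * ppu   # column
        cy = state.pos[i, 1] * ppu   # row
        rows = np.arange(int(np.floor(cy - a)), int(np.ceil(cy + a)) + 1)
        cols = np.arange(int(np.floor(cx - a)), int(np.ceil(cx + a)) + 1)
        dy = rows[:, None] - cy
        dx = cols[None, :] - cx
        u = dx * cos_t[i] + dy * sin_t[i]      # along major axis
        v = -dx * sin_t[i] + dy * cos_t[i]     # along minor axis
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        rr, cc = np.nonzero(inside)
        img[rows[rr] % G, cols[cc] % G] = rp.fg
    return Frame(
        t=state.t,
        pixels=img,
        meta={
            "px_per_unit": ppu,
            "gamma_img": G,
            "fg": rp.fg,
            "bg": rp.bg,
            "coords": COORD_CONVENTION,
        },
    )


def render_sequence(traj: Trajectory, rp: RenderParams | None = None,
                    tau: int = 1, t_min: int = 0,
                    t_max: int | None = None) -> list[Frame]:
    """Render frames at t = t_min, t_min+tau, ... up to t_max (inclusive).

    tau is the recording step: downstream PIV then reports displacement per
    recorded interval (tau simulation steps).  Frame metadata records tau.
    """
    if tau < 1 or int(tau) != tau:
        raise ValueError("recording step tau must be a positive integer")
    if t_max is None:
        t_max = len(traj) - 1
    frames = []
    for t in range(t_min, t_max + 1, int(tau)):
        f = render_frame(traj[t], traj.params, rp)
        f.meta["tau"] = int(tau)
        frames.append(f)
    return frames


def write_frames(frames: list[Frame], directory: str | Path) -> None:
    """Write frame_%05d.png files plus a JSON sidecar with the metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    times = []
    for k, f in enumerate(frames):
        iio.imwrite(directory / f"frame_{k:05d}.png", f.pixels)
        times.append(int(f.t))
    meta = dict(frames[0].meta) if frames else {}
    meta["times"] = times
    (directory / "frames.json").write_text(json.dumps(meta, indent=2))


def read_frames(directory: str | Path) -> list[Frame]:
    """Load a PNG frame sequence written by write_frames (or externally
    supplied 8-bit grayscale frame_%05d.png files with a frames.json
    sidecar; without a sidecar, times default to 0, tau, 2*tau with tau=1)."""
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    sidecar = directory / "frames.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    times = meta.pop("times", None)
    tau = int(meta.get("tau", 1))
    frames = []
    for k, p in enumerate(paths):
        px = np.asarray(iio.imread(p))
        if px.ndim == 3:  # collapse grayscale stored with channels
            px = px[..., 0]
        t = times[k] if times is not None else k * tau
        frames.append(Frame(t=int(t), pixels=px.astype(np.uint8), meta=dict(meta)))
    return frames
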