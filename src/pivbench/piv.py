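"""Particle image velocimetry by normalized cross-correlation.

The image is tiled into square interrogation grids of side gamma (vector
spacing equals gamma).  For each grid the Z x Z patch at time t is compared
with every Z x Z window inside a (Z + 2m) x (Z + 2m) search zone of the
frame at t+1 (m = step_px / 2 per side); the match score is the normalized
cross-correlation

    C(k, l) = sum[(I_t - mu_t)(I_t1 - mu_t1)] /
              ( ||I_t - mu_t|| * ||I_t1 - mu_t1|| )

over the patch, evaluated at every integer offset |k|, |l| <= m.  The argmax
offset is the grid's displacement vector, optionally refined to sub-pixel
precision by a three-point Gaussian fit per axis.  A grid produces no vector
when its patch at t, or its search region at t+1, contains no foreground
(the empty-grid rule), or when every offset has an undefined (zero-variance)
correlation.  An optional normalized-median test flags outlier vectors.

Patches and search zones access pixels periodically, consistent with the
periodic simulation box; set `periodic=False` on externally supplied,
non-periodic images (border grids whose search zone would leave the image
are then skipped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .render import Frame

__all__ = [
    "PIVParams",
    "PIVField",
    "ncc",
    "piv_field",
    "validate_vectors",
    "write_field_csv",
    "read_field_csv",
]

# Correlation values within this distance of the maximum are treated as tied
# and resolved deterministically (smallest |offset|, then lexicographic).
# Shared by the fast path and the brute-force oracle so that both select the
# same peak despite FFT-vs-longhand rounding differences.
PEAK_TIE_TOL = 1e-9

_VAR_TOL = 1e-3  # sum-of-squared-deviation threshold; a single differing
                 # 8-bit pixel contributes >= 255^2 * (1 - 1/Z^2)


@dataclass(frozen=True)
class PIVParams:
    """Interrogation geometry and post-processing switches.

    Defaults follow the study conditions: 64-px grids, step 32 px (50% of
    the grid) so the search zone is 96 x 96 px and the per-side search
    margin is m = 16 px.
    """

    grid_px: int = 64
    step_px: int = 32
    subpixel: str = "gaussian3"          # {"none", "gaussian3"}
    validate: str = "normalized_median"  # {"none", "normalized_median"}
    validation_threshold: float = 2.0
    bg: int = 255                        # background intensity (empty-grid rule)
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.grid_px <= 0:
            raise ValueError("grid_px must be positive")
        if self.step_px <= 0 or self.step_px % 2:
            raise ValueError("step_px must be a positive even integer")
        if self.subpixel not in ("none", "gaussian3"):
            raise ValueError(f"unknown subpixel mode {self.subpixel!r}")
        if self.validate not in ("none", "normalized_median"):
            raise ValueError(f"unknown validation mode {self.validate!r}")
        if self.validation_threshold <= 0:
            raise ValueError("validation_threshold must be positive")

    @property
    def margin(self) -> int:
        """Per-side search margin m in pixels."""
        return self.step_px // 2

    @property
    def search_px(self) -> int:
        """Search-zone side N_g = grid_px + step_px."""
        return self.grid_px + self.step_px


@dataclass
class PIVField:
    """Displacement vectors on the regular gamma-spaced lattice.

    anchors: (G, 2) grid-center positions (x, y) in pixels;
    vectors:  (G, 2) displacements (u, v) in px per recorded interval,
              u along columns (x), v along rows (y);
    peak_corr: the maximal correlation per grid (nan where invalid);
    valid:   False where the empty-grid rule fired, the correlation was
             everywhere undefined, or validation removed the vector.
    """

    t: int
    anchors: np.ndarray
    vectors: np.ndarray
    peak_corr: np.ndarray
    valid: np.ndarray
    lattice_shape: tuple[int, int]   # (ny, nx)
    grid_px: int
    interval: int = 1                # recorded steps between the two frames

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy(self) -> "PIVField":
        return PIVField(
            self.t, self.anchors.copy(), self.vectors.copy(),
            self.peak_corr.copy(), self.valid.copy(),
            self.lattice_shape, self.grid_px, self.interval,
        )


def _periodic_take(img: np.ndarray, r0: int, c0: int, h: int, w: int) -> np.ndarray:
    rows = np.arange(r0, r0 + h) % img.shape[0]
    cols = np.arange(c0, c0 + w) % img.shape[1]
    return img[np.ix_(rows, cols)]


def ncc(frame_t: Frame | np.ndarray, frame_t1: Frame | np.ndarray,
        grid_origin: tuple[int, int], k: int, l: int, Z: int) -> float:
    """Normalized cross-correlation at a single offset, evaluated longhand.

    grid_origin is the (row, col) of the patch's top-left pixel in frame_t;
    the comparison window in frame_t1 is displaced by k rows and l columns.
    Pixels are accessed periodically.  Returns nan when either patch is
    constant (undefined correlation).
    """
    a = frame_t.pixels if isinstance(frame_t, Frame) else np.asarray(frame_t)
    b = frame_t1.pixels if isinstance(frame_t1, Frame) else np.asarray(frame_t1)
    r0, c0 = grid_origin
    pa = _periodic_take(a, r0, c0, Z, Z).astype(float)
    pb = _periodic_take(b, r0 + k, c0 + l, Z, Z).astype(float)
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    na = math.sqrt(float((pa * pa).sum()))
    nb = math.sqrt(float((pb * pb).sum()))
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float((pa * pb).sum() / (na * nb))


def _window_sums(x: np.ndarray, Z: int) -> np.ndarray:
    """Sliding Z x Z window sums via a padded double cumulative sum."""
    c = np.cumsum(np.cumsum(x, axis=0), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[Z:, Z:] - c[:-Z, Z:] - c[Z:, :-Z] + c[:-Z, :-Z]


def _ncc_map(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """C(k, l) for every window of the search zone; nan where undefined.

    Numerator by FFT correlation of the mean-subtracted template with the
    search zone, denominator by integral-image window norms — numerically
    equivalent to evaluating the longhand formula at each offset.
    """
    Z = template.shape[0]
    t = template.astype(np.float64)
    t -= t.mean()
    tnorm = math.sqrt(float((t * t).sum()))
    n_off = search.shape[0] - Z + 1
    if tnorm == 0.0:
        return np.full((n_off, n_off), np.nan)
    s = search.astype(np.float64)
    s -= s.mean()  # photometric shift; cancels in C, improves conditioning
    num = fftconvolve(s, t[::-1, ::-1], mode="valid")
    s1 = _window_sums(s, Z)
    # residual of the exact numerator: -mu_W * sum(t); sum(t) ~ 0 after
    # mean subtraction but kept for strict agreement with the longhand form
    num -= s1 * (float(t.sum()) / (Z * Z))
    ssd = _window_sums(s * s, Z) - s1 * s1 / (Z * Z)
    defined = ssd > _VAR_TOL
    out = np.full((n_off, n_off), np.nan)
    out[defined] = num[defined] / (tnorm * np.sqrt(ssd[defined]))
    return out


def _ncc_map_brute(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Literal per-offset evaluation; the oracle for the fast map."""
    Z = template.shape[0]
    n_off = search.shape[0] - Z + 1
    t = template.astype(float)
    t = t - t.mean()
    tnorm = math.sqrt(float((t * t).sum()))
    out = np.full((n_off, n_off), np.nan)
    if tnorm == 0.0:
        return out
    for a in range(n_off):
        for b in range(n_off):
            w = search[a:a + Z, b:b + Z].astype(float)
            w = w - w.mean()
            wn = math.sqrt(float((w * w).sum()))
            if wn == 0.0:
                continue
            out[a, b] = float((t * w).sum()) / (tnorm * wn)
    return out


def select_peak(cmap: np.ndarray, margin: int,
                tol: float = PEAK_TIE_TOL) -> tuple[int, int] | None:
    """Deterministic argmax over the correlation map.

    Offsets within tol of the maximum are tied; the tie with the smallest
    |offset| (then lexicographically smallest (k, l)) wins.  Offsets are
    (k, l) = (row, col) displacements in [-margin, margin].  None when the
    whole map is undefined.
    """
    if np.all(np.isnan(cmap)):
        return None
    mx = np.nanmax(cmap)
    with np.errstate(invalid="ignore"):
        rows, cols = np.nonzero(cmap >= mx - tol)
    ks = rows - margin
    ls = cols - margin
    best = np.lexsort((ls, ks, ks * ks + ls * ls))[0]
    return int(ks[best]), int(ls[best])


def _axis_refine(cm: float, c0: float, cp: float) -> float:
    """Sub-pixel offset from three correlation samples along one axis.

    Gaussian three-point fit when all samples are positive (the usual PIV
    peak model); parabolic fallback otherwise; 0 when degenerate.  Clamped
    to [-0.5, 0.5].
    """
    if not (np.isfinite(cm) and np.isfinite(c0) and np.isfinite(cp)):
        return 0.0
    if cm > 0 and c0 > 0 and cp > 0:
        denom = 2.0 * (math.log(cm) + math.log(cp) - 2.0 * math.log(c0))
        if denom >= 0:
            return 0.0
        delta = (math.log(cm) - math.log(cp)) / denom
    else:
        denom = 2.0 * (cm + cp - 2.0 * c0)
        if denom >= 0:
            return 0.0
        delta = (cm - cp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def piv_field(frame_t: Frame, frame_t1: Frame, pp: PIVParams | None = None) -> PIVField:
    """Compute the displacement field between two consecutive frames."""
    pp = pp or PIVParams()
    a = frame_t.pixels
    b = frame_t1.pixels
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    H, W = a.shape
    Z = pp.grid_px
    m = pp.margin
    ny = -(-H // Z)  # ceil: border grids wrap (periodic) or are skipped
    nx = -(-W // Z)

    anchors = np.zeros((ny * nx, 2))
    vectors = np.zeros((ny * nx, 2))
    peaks = np.full(ny * nx, np.nan)
    valid = np.zeros(ny * nx, dtype=bool)

    for gy in range(ny):
        for gx in range(nx):
            j = gy * nx + gx
            r0, c0 = gy * Z, gx * Z
            anchors[j] = ((c0 + Z / 2.0) % W, (r0 + Z / 2.0) % H)
            if pp.periodic:
                tpl = _periodic_take(a, r0, c0, Z, Z)
                search = _periodic_take(b, r0 - m, c0 - m, Z + 2 * m, Z + 2 * m)
            else:
                if r0 - m < 0 or c0 - m < 0 or r0 + Z + m > H or c0 + Z + m > W:
                    continue
                tpl = a[r0:r0 + Z, c0:c0 + Z]
                search = b[r0 - m:r0 + Z + m, c0 - m:c0 + Z + m]
            # empty-grid rule: no foreground at t in the grid, or at t+1 in
            # the search region, means there is nothing to correlate
            if np.all(tpl == pp.bg) or np.all(search == pp.bg):
                continue
            cmap = _ncc_map(tpl, search)
            peak = select_peak(cmap, m)
            if peak is None:
                continue
            k, l = peak
            dk = dl = 0.0
            if pp.subpixel == "gaussian3":
                ki, li = k + m, l + m
                if 0 < ki < 2 * m:
                    dk = _axis_refine(cmap[ki - 1, li], cmap[ki, li], cmap[ki + 1, li])
                if 0 < li < 2 * m:
                    dl = _axis_refine(cmap[ki, li - 1], cmap[ki, li], cmap[ki, li + 1])
            vectors[j] = (l + dl, k + dk)   # (u, v) = (x, y) displacement
            peaks[j] = cmap[k + m, l + m]
            valid[j] = True

    field = PIVField(
        t=int(frame_t.t),
        anchors=anchors,
        vectors=vectors,
        peak_corr=peaks,
        valid=valid,
        lattice_shape=(ny, nx),
        grid_px=Z,
        interval=int(frame_t1.t - frame_t.t) or 1,
    )
    if pp.validate == "normalized_median":
        field = validate_vectors(field, pp.validation_threshold,
                                 periodic=pp.periodic)
    return field


def validate_vectors(field: PIVField, threshold: float = 2.0,
                     eps: float = 0.1, periodic: bool = True) -> PIVField:
    """Normalized-median outlier test (single pass).

    For each valid vector: the component-wise median of its <= 8 valid
    lattice neighbors defines a reference; the vector's residual, normalized
    by the median neighbor residual plus eps (px), must not exceed the
    threshold.  Vectors with fewer than two valid neighbors are kept.
    """
    ny, nx = field.lattice_shape
    out = field.copy()
    if field.n_valid < 2:
        return out
    vec = field.vectors.reshape(ny, nx, 2)
    ok = field.valid.reshape(ny, nx)
    drop = np.zeros((ny, nx), dtype=bool)
    offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dy, dx) != (0, 0)]
    for gy in range(ny):
        for gx in range(nx):
            if not ok[gy, gx]:
                continue
            neigh = []
            for dy, dx in offsets:
                yy, xx = gy + dy, gx + dx
                if periodic:
                    yy %= ny
                    xx %= nx
                elif not (0 <= yy < ny and 0 <= xx < nx):
                    continue
                if (yy, xx) != (gy, gx) and ok[yy, xx]:
                    neigh.append(vec[yy, xx])
            if len(neigh) < 2:
                continue
            neigh = np.asarray(neigh)
            med = np.median(neigh, axis=0)
            res = np.linalg.norm(neigh - med, axis=1)
            r_star = np.linalg.norm(vec[gy, gx] - med) / (np.median(res) + eps)
            if r_star > threshold:
                drop[gy, gx] = True
    out.valid = (ok & ~drop).reshape(-1)
    out.peak_corr = np.where(out.valid, field.peak_corr, np.nan)
    return out


def write_field_csv(field: PIVField, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": field.t,
            "anchor_x_px": field.anchors[:, 0],
            "anchor_y_px": field.anchors[:, 1],
            "u_px": field.vectors[:, 0],
            "v_px": field.vectors[:, 1],
            "peak_corr": field.peak_corr,
            "valid": field.valid,
        }
    ).to_csv(path, index=False)


def read_field_csv(path: str | Path, lattice_shape: tuple[int, int] | None = None,
                   grid_px: int | None = None, interval: int = 1) -> PIVField:
    df = pd.read_csv(path)
    n = len(df)
    if lattice_shape is None:
        side = int(round(math.sqrt(n)))
        if side * side != n:
            raise ValueError("cannot infer lattice shape; pass lattice_shape")
        lattice_shape = (side, side)
    if grid_px is None:
        xs = np.unique(df["anchor_x_px"])
        grid_px = int(round(xs[1] - xs[0])) if len(xs) > 1 else int(2 * xs[0])
    return PIVField(
        t=int(df["t"].iloc[0]),
        anchors=df[["anchor_x_px", "anchor_y_px"]].to_numpy(),
        vectors=df[["u_px", "v_px"]].to_numpy(),
        peak_corr=df["peak_corr"].to_numpy(),
        valid=df["valid"].to_numpy(dtype=bool),
        lattice_shape=lattice_shape,
        grid_px=grid_px,
        interval=interval,
    )
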