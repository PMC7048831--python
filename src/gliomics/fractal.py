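"""Fractal and multi-resolution texture characterizations of tumor regions.

Three pointwise roughness estimators, each producing a characterization map
over the tumor region of interest:

* **PTPSA** — piecewise triangular-prism surface area.  Local intensity is
  treated as a height field; triangulated surface area A(s) is measured over
  cells of increasing size s, and the fractal dimension D = 2 - slope of
  log A(s) vs log s.  Smooth surfaces give D = 2, fully space-filling
  roughness approaches D = 3; for the graph of fractional Brownian motion
  D ≈ 3 - H.

* **mBm Hurst** — multifractional Brownian motion modeling.  Separable 2D
  wavelet detail variances V(j) scale as 2^{j(2H+2)} for fBm texture; the
  local Hurst exponent is H = (slope of log2 V(j) on level j - 2)/2,
  clipped to [0, 1].  Small H means rough texture.

* **Hölder exponent** — pointwise regularity.  The oscillation (max - min)
  of intensity inside Chebyshev balls of growing radius r scales as r^α;
  α is the slope of log(osc + ε) on log r.

Maps are computed slice-wise (axial) inside the region of interest with a
sliding local window; PTPSA/mBm windows at the edge of the tumor bounding
box are filled by reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .io import VolumeImage


class EstimationError(ValueError):
    """A roughness estimate cannot be formed on the given input."""


@dataclass
class FractalMapConfig:
    """Window and scale parameters of the three characterization maps.

    ``window`` is the odd side (voxels) of the local in-slice patch;
    ``ptpsa_steps`` the triangular-prism cell sizes (powers of two);
    ``wavelet_levels``/``wavelet_name`` the mBm analysis depth and filters;
    ``holder_radii`` the oscillation radii; ``epsilon`` stabilizes the log
    of vanishing oscillations; ``alpha_cap`` is the Hölder exponent assigned
    to locally constant patches.
    """

    window: int = 17
    ptpsa_steps: tuple[int, ...] = (1, 2, 4, 8)
    wavelet_levels: int = 3
    wavelet_name: str = "db4"
    holder_radii: tuple[int, ...] = (1, 2, 3, 4)
    epsilon: float = 1e-6
    alpha_cap: float = 2.0
    clip_D: tuple[float, float] = (2.0, 3.0)
    clip_H: tuple[float, float] = (0.0, 1.0)

    def validate(self) -> None:
        if self.window % 2 != 1:
            raise ValueError("window must be odd")
        if self.window < 2 * max(self.ptpsa_steps):
            raise ValueError("window must be >= 2 * max(ptpsa_steps)")
        if len(self.ptpsa_steps) < 3:
            raise ValueError("ptpsa_steps needs at least 3 scales")
        if len(self.holder_radii) < 3:
            raise ValueError("holder_radii needs at least 3 radii")


def _ls_slope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares slope of y on x, vectorized over leading axes of y."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    return (y * xc).sum(axis=-1) / denom


# ---------------------------------------------------------------------------
# PTPSA


def _prism_areas(patches: np.ndarray, step: int) -> tuple[np.ndarray, float]:
    """Total triangulated surface area over s×s cells, batched over patches.

    ``patches`` has shape (..., w, w); corner heights are sampled on the
    grid 0, s, 2s, ..., m·s with m = (w-1)//s, so the covered planar area is
    (m·s)².  Each cell contributes four triangles joining adjacent corners
    to the center point whose height is the mean of the four corner heights.
    Returns (areas, covered planar area).
    """
    s = step
    w = patches.shape[-1]
    m = (w - 1) // s
    corners = patches[..., : m * s + 1 : s, : m * s + 1 : s]
    a = corners[..., :-1, :-1]
    b = corners[..., :-1, 1:]
    c = corners[..., 1:, :-1]
    d = corners[..., 1:, 1:]
    e = 0.25 * (a + b + c + d)

    h = s / 2.0  # planar offset of the center from each corner

    def tri(z1, z2, ze, p1, p2):
        # p1, p2: planar corner coordinates relative to the cell origin.
        (x1, y1), (x2, y2) = p1, p2
        v1 = (x2 - x1, y2 - y1, z2 - z1)
        v2 = (h - x1, h - y1, ze - z1)
        cx = v1[1] * v2[2] - v1[2] * v2[1]
        cy = v1[2] * v2[0] - v1[0] * v2[2]
        cz = v1[0] * v2[1] - v1[1] * v2[0]
        return 0.5 * np.sqrt(cx**2 + cy**2 + cz**2)

    area = (
        tri(a, b, e, (0.0, 0.0), (0.0, float(s)))
        + tri(b, d, e, (0.0, float(s)), (float(s), float(s)))
        + tri(d, c, e, (float(s), float(s)), (float(s), 0.0))
        + tri(c, a, e, (float(s), 0.0), (0.0, 0.0))
    )
    return area.sum(axis=(-2, -1)), float((m * s) ** 2)


def ptpsa_dimension(patch: np.ndarray, steps: tuple[int, ...] = (1, 2, 4, 8)) -> float:
    """Fractal dimension of a 2D patch by the triangular-prism surface-area law."""
    return float(ptpsa_dimension_batch(np.asarray(patch, dtype=float)[None], steps)[0])


def ptpsa_dimension_batch(
    patches: np.ndarray, steps: tuple[int, ...] = (1, 2, 4, 8), clip: tuple[float, float] = (2.0, 3.0)
) -> np.ndarray:
    """Vectorized PTPSA dimension over a stack of equally sized patches."""
    steps = tuple(int(s) for s in steps)
    if len(steps) < 3:
        raise EstimationError("PTPSA needs at least 3 cell sizes")
    w = patches.shape[-1]
    if patches.shape[-2] != w:
        raise EstimationError("PTPSA patches must be square")
    if w - 1 < max(steps):
        raise EstimationError(f"patch side {w} too small for max step {max(steps)}")
    # Normalize to a common planar footprint so that partially covered scales
    # (when w-1 is not a multiple of s) stay comparable; flat patches then
    # give exactly equal areas at all scales.
    areas = []
    for s in steps:
        a, covered = _prism_areas(patches, s)
        areas.append(a * ((w - 1) ** 2 / covered))
    areas = np.stack(areas, axis=-1)
    log_a = np.log(np.maximum(areas, 1e-300))
    slope = _ls_slope(np.log(steps), log_a)
    # Constant / planar patches give exactly equal areas at all scales.
    flat = np.ptp(areas, axis=-1) <= 1e-9 * np.abs(areas).max(axis=-1)
    d = 2.0 - slope
    d = np.where(flat, 2.0, d)
    return np.clip(d, clip[0], clip[1])


# ---------------------------------------------------------------------------
# mBm wavelet Hurst


def _wavelet_level_variances(patches: np.ndarray, wavelet: str, levels: int) -> np.ndarray:
    """Per-level detail-coefficient variances, batched over leading axes.

    Level index runs 1..levels from finest to coarsest.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small patches trigger pywt level warnings
        coeffs = pywt.wavedec2(patches, wavelet, level=levels, mode="periodization", axes=(-2, -1))
    out = []
    for j in range(1, levels + 1):
        details = coeffs[-j]  # (cH, cV, cD) at level j (finest = index -1)
        stacked = [np.asarray(c).reshape(*patches.shape[:-2], -1) for c in details]
        allc = np.concatenate(stacked, axis=-1)
        out.append(allc.var(axis=-1))
    return np.stack(out, axis=-1)


def mbm_hurst(patch: np.ndarray, config: FractalMapConfig | None = None) -> float:
    """Hurst exponent of a 2D patch from the wavelet detail-variance scaling law."""
    config = config or FractalMapConfig()
    return float(
        mbm_hurst_batch(
            np.asarray(patch, dtype=float)[None],
            config.wavelet_name,
            config.wavelet_levels,
            config.clip_H,
        )[0]
    )


def mbm_hurst_batch(
    patches: np.ndarray,
    wavelet: str = "db4",
    levels: int = 3,
    clip: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Vectorized wavelet-variance Hurst estimate over a stack of patches.

    V(j) ∝ 2^{j(2H+2)} for 2D fBm, so H = (slope of log2 V(j) on j - 2)/2.
    Zero-variance detail bands at every level (constant patches) return the
    upper clip bound.
    """
    v = _wavelet_level_variances(np.asarray(patches, dtype=float), wavelet, levels)
    degenerate = (v <= 0).all(axis=-1)
    log_v = np.log2(np.maximum(v, 1e-300))
    beta = _ls_slope(np.arange(1, levels + 1, dtype=float), log_v)
    h = (beta - 2.0) / 2.0
    h = np.where(degenerate, clip[1], h)
    return np.clip(h, clip[0], clip[1])


# ---------------------------------------------------------------------------
# Hölder exponent


def holder_exponent(
    volume: np.ndarray,
    point: tuple[int, int, int],
    radii: tuple[int, ...] = (1, 2, 3, 4),
    epsilon: float = 1e-6,
    alpha_cap: float = 2.0,
) -> float:
    """Pointwise Hölder exponent at one voxel of a 3D volume.

    The oscillation within the Chebyshev ball of radius r (a cube of side
    2r + 1) scales as r^α for Hölder-regular signals; α is estimated by the
    least-squares slope of log(osc + ε) on log r.  Locally constant
    neighborhoods (all oscillations below ε) return ``alpha_cap``.
    """
    volume = np.asarray(volume, dtype=float)
    rmax = max(radii)
    for ax, p in enumerate(point):
        if p < rmax or p > volume.shape[ax] - 1 - rmax:
            raise EstimationError(f"point {point} within {rmax} voxels of the volume boundary")
    oscs = []
    for r in radii:
        sl = tuple(slice(p - r, p + r + 1) for p in point)
        block = volume[sl]
        oscs.append(block.max() - block.min())
    oscs = np.asarray(oscs)
    if np.all(oscs < epsilon):
        return float(alpha_cap)
    return float(_ls_slope(np.log(np.asarray(radii, dtype=float)), np.log(oscs + epsilon)))


def _holder_map(volume: np.ndarray, roi: np.ndarray, config: FractalMapConfig) -> np.ndarray:
    radii = tuple(int(r) for r in config.holder_radii)
    rmax = max(radii)
    padded = np.pad(volume, rmax, mode="reflect")
    oscs = []
    for r in radii:
        size = 2 * r + 1
        mx = ndimage.maximum_filter(padded, size=size)
        mn = ndimage.minimum_filter(padded, size=size)
        osc = (mx - mn)[rmax:-rmax, rmax:-rmax, rmax:-rmax]
        oscs.append(osc)
    osc = np.stack(oscs, axis=-1)
    alpha = _ls_slope(np.log(np.asarray(radii, dtype=float)), np.log(osc + config.epsilon))
    alpha = np.where((osc < config.epsilon).all(axis=-1), config.alpha_cap, alpha)
    out = np.zeros_like(volume)
    out[roi] = alpha[roi]
    return out


# ---------------------------------------------------------------------------
# characterization maps


def characterization_map(
    volume: VolumeImage, roi: np.ndarray, kind: str, config: FractalMapConfig | None = None
) -> VolumeImage:
    """Pointwise roughness map (PTPSA, MBM or HE) over a region of interest.

    For PTPSA/MBM the local estimate at each in-ROI voxel comes from the
    axial in-slice window of side ``config.window`` centered there; the
    volume is cropped to the ROI bounding box (padded by a half window,
    reflected at crop edges), so out-of-ROI intensities influence in-ROI
    values only within the window support.  Voxels outside the ROI are 0.
    """
    config = config or FractalMapConfig()
    config.validate()
    kind = kind.upper()
    if kind not in ("PTPSA", "MBM", "HE"):
        raise ValueError(f"unknown characterization kind {kind!r}")
    roi = np.asarray(roi).astype(bool)
    if roi.shape != volume.data.shape:
        raise EstimationError("roi shape differs from volume shape")
    if not roi.any():
        raise EstimationError("empty region of interest")

    data = volume.data
    half = config.window // 2
    # Crop to the ROI bounding box with a half-window margin (reflect-padded).
    idx = np.nonzero(roi)
    lo = [max(int(i.min()) - half, 0) for i in idx]
    hi = [min(int(i.max()) + half + 1, s) for i, s in zip(idx, data.shape)]
    crop = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = data[crop]
    sub_roi = roi[crop]

    pad = [(half, half), (half, half), (0, 0)]
    if kind == "HE":
        out_sub = _holder_map(sub, sub_roi, config)
    else:
        padded = np.pad(sub, pad, mode="reflect")
        out_sub = np.zeros_like(sub)
        w = config.window
        for z in range(sub.shape[2]):
            centers = np.nonzero(sub_roi[:, :, z])
            if centers[0].size == 0:
                continue
            wins = sliding_window_view(padded[:, :, z], (w, w))
            patches = wins[centers[0], centers[1]]
            if kind == "PTPSA":
                vals = ptpsa_dimension_batch(patches, config.ptpsa_steps, config.clip_D)
            else:
                vals = mbm_hurst_batch(
                    patches, config.wavelet_name, config.wavelet_levels, config.clip_H
                )
            out_sub[centers[0], centers[1], z] = vals

    out = np.zeros_like(data)
    out[crop] = out_sub
    out[~roi] = 0.0
    return VolumeImage(out, volume.spacing, kind)
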