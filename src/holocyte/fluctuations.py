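"""Cell-membrane-fluctuation (CMF) maps from OPD time stacks.

Flicker amplitude per pixel is estimated as the temporal standard
deviation of the OPD signal with the camera/phase noise floor removed in
quadrature:

    CMF(x, y) = sqrt( std_t(OPD)(x, y)^2 - std_bkgd^2 ),

where std_bkgd is the mean per-pixel temporal std over background
(cell-free) pixels. Pixels whose variance falls below the noise floor are
clamped to zero and counted (a data-quality signal). The whole-cell CMF
amplitude is the mean of the map over the projected cell area; the ring
and dimple sub-regions are compared by splitting the mask at a fraction of
the equivalent-disc radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CMFMap",
    "CMFRecord",
    "temporal_std_map",
    "background_std",
    "cmf_map",
    "cmf_amplitude",
    "ring_dimple_split",
    "analyze_stack",
]


@dataclass
class CMFMap:
    """Per-pixel fluctuation amplitude (nm) on the cell mask."""

    data: np.ndarray
    mask: np.ndarray
    bkgd_std_nm: float
    clamped_px: int


@dataclass(frozen=True)
class CMFRecord:
    """Whole-cell and region-wise fluctuation amplitudes."""

    cell_id: int
    cmf_amplitude_nm: float
    cmf_ring_nm: float
    cmf_dimple_nm: float
    bkgd_std_nm: float
    clamped_px: int
    n_frames: int
    temperature_c: float | None = None


def temporal_std_map(stack: np.ndarray, detrend: bool = False) -> np.ndarray:
    """Per-pixel sample standard deviation across frames (divisor T-1).

    ``detrend`` subtracts a per-pixel linear trend in time first (for
    slowly drifting real acquisitions); synthetic stacks need none.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (T, N, M) with T >= 2")
    if detrend:
        t = np.arange(stack.shape[0], dtype=float)
        t = (t - t.mean()) / t.std()
        slope = np.tensordot(t, stack - stack.mean(axis=0), axes=(0, 0)) / len(t)
        stack = stack - t[:, None, None] * slope[None]
    return np.std(stack, axis=0, ddof=1)


def background_std(stack: np.ndarray, bkgd_mask: np.ndarray) -> float:
    """Mean of the per-pixel temporal std over background pixels (nm)."""
    bkgd_mask = np.asarray(bkgd_mask, dtype=bool)
    if not bkgd_mask.any():
        raise ValueError("empty background mask")
    return float(temporal_std_map(stack)[bkgd_mask].mean())


def cmf_map(
    std_map: np.ndarray, bkgd_std_nm: float, mask: np.ndarray
) -> CMFMap:
    """Quadrature subtraction of the noise floor inside the cell mask.

    Negative variance differences are clamped to zero (amplitudes are real
    and non-negative) and counted; the map is zero outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    std_map = np.asarray(std_map, dtype=float)
    var = std_map**2 - bkgd_std_nm**2
    clamped = int(np.count_nonzero(mask & (var < 0)))
    out = np.zeros_like(std_map)
    out[mask] = np.sqrt(np.clip(var[mask], 0.0, None))
    return CMFMap(out, mask, float(bkgd_std_nm), clamped)


def cmf_amplitude(cmf: CMFMap | np.ndarray, mask: np.ndarray | None = None) -> float:
    """Whole-cell CMF amplitude: mean of the map over the projected area."""
    data = cmf.data if isinstance(cmf, CMFMap) else np.asarray(cmf, dtype=float)
    if mask is None:
        if not isinstance(cmf, CMFMap):
            raise ValueError("mask required when passing a bare array")
        mask = cmf.mask
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    return float(data[mask].mean())


def ring_dimple_split(
    mask: np.ndarray,
    centroid: tuple[float, float] | None = None,
    radius_px: float | None = None,
    dimple_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """(ring, dimple) masks: dimple = pixels within ``dimple_fraction * R``
    of the centroid, ring = remainder; their disjoint union is the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    if centroid is None:
        rows, cols = np.nonzero(mask)
        centroid = (float(rows.mean()), float(cols.mean()))
    if radius_px is None:
        radius_px = float(np.sqrt(np.count_nonzero(mask) / np.pi))
    if radius_px < 4:
        raise ValueError("cell radius < 4 px; ring/dimple split unreliable")
    yy = np.arange(mask.shape[0])[:, None] - centroid[0]
    xx = np.arange(mask.shape[1])[None, :] - centroid[1]
    r = np.hypot(yy, xx)
    dimple = mask & (r < dimple_fraction * radius_px)
    ring = mask & ~dimple
    return ring, dimple


def analyze_stack(
    stack: np.ndarray,
    mask: np.ndarray,
    bkgd_mask: np.ndarray,
    cell_id: int = 0,
    temperature_c: float | None = None,
    dimple_fraction: float = 0.5,
    detrend: bool = False,
) -> tuple[CMFRecord, CMFMap]:
    """Full CMF analysis of one cell in an OPD time stack."""
    std_map = temporal_std_map(stack, detrend=detrend)
    bkgd = float(std_map[np.asarray(bkgd_mask, dtype=bool)].mean())
    cmap = cmf_map(std_map, bkgd, mask)
    ring, dimple = ring_dimple_split(mask, dimple_fraction=dimple_fraction)
    record = CMFRecord(
        cell_id=cell_id,
        cmf_amplitude_nm=cmf_amplitude(cmap),
        cmf_ring_nm=float(cmap.data[ring].mean()) if ring.any() else 0.0,
        cmf_dimple_nm=float(cmap.data[dimple].mean()) if dimple.any() else 0.0,
        bkgd_std_nm=bkgd,
        clamped_px=cmap.clamped_px,
        n_frames=int(stack.shape[0]),
        temperature_c=temperature_c,
    )
    return record, cmap
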