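"""Single-cell segmentation from a background-flattened OPD image.

Binarization (Otsu or fixed nm threshold) splits the image into a cell
foreground and a background mask separated by a dilated guard band;
8-connected labeling yields per-cell masks filtered by area and the
image-border rule; a discocyte quality control rejects non-circular or
implausibly shaped cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from . import morphometrics

__all__ = [
    "SegmentationConfig",
    "CellMask",
    "binarize",
    "label_cells",
    "discocyte_qc",
    "segment_cells",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding, guard band and quality-control settings.

    ``threshold_nm = None`` selects Otsu's threshold on the OPD values; a
    fixed threshold gives bit-reproducible masks for synthetic work.
    """

    threshold_nm: float | None = None
    dilation_radius_px: int = 5
    min_area_um2: float = 20.0
    max_area_um2: float = 150.0
    qc_circularity_min: float = 0.8
    qc_sphericity_range: tuple[float, float] = (0.2, 1.2)

    def __post_init__(self) -> None:
        if self.dilation_radius_px < 1:
            raise ValueError("dilation_radius_px must be >= 1")
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")


@dataclass
class CellMask:
    """Binary projected-area mask of one cell plus bookkeeping."""

    mask: np.ndarray  # full-frame boolean
    label: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    centroid: tuple[float, float]  # (row, col), pixels
    pixel_pitch_um: float
    area_px: int

    def cropped(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return self.mask[r0:r1, c0:c1]


def binarize(
    opd_nm: np.ndarray, cfg: SegmentationConfig, pixel_pitch_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Foreground and background masks from a background-compensated OPD map.

    The background mask is the complement of the foreground dilated by the
    guard-band radius, so a one-guard-band annulus around every cell
    belongs to neither mask.
    """
    opd = np.asarray(opd_nm, dtype=float)
    thr = threshold_otsu(opd) if cfg.threshold_nm is None else cfg.threshold_nm
    foreground = opd > thr
    if not foreground.any():
        raise ValueError("empty foreground: no pixels above threshold")
    guard = morphology.dilation(
        foreground, morphology.disk(cfg.dilation_radius_px)
    )
    return foreground, ~guard


def label_cells(
    foreground: np.ndarray, cfg: SegmentationConfig, pixel_pitch_um: float
) -> list[CellMask]:
    """8-connected components filtered by area and the border rule.

    Components touching the image border are removed (their projected area
    is truncated). Output is deterministically ordered by (row, col) of
    the centroid.
    """
    labels = measure.label(np.asarray(foreground, dtype=bool), connectivity=2)
    n0, n1 = labels.shape
    out: list[CellMask] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * pixel_pitch_um**2
        if not cfg.min_area_um2 <= area_um2 <= cfg.max_area_um2:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == n0 or c1 == n1:
            continue
        out.append(
            CellMask(
                mask=labels == region.label,
                label=region.label,
                bbox=(r0, c0, r1, c1),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                pixel_pitch_um=pixel_pitch_um,
                area_px=int(region.area),
            )
        )
    out.sort(key=lambda c: c.centroid)
    for i, cell in enumerate(out):
        cell.label = i + 1
    return out


def _circularity(mask: np.ndarray) -> float:
    region = measure.regionprops(mask.astype(np.uint8))[0]
    perimeter = region.perimeter_crofton
    if perimeter == 0:
        return 0.0
    return float(4.0 * np.pi * region.area / perimeter**2)


def discocyte_qc(
    cell: CellMask, opd_nm: np.ndarray, cfg: SegmentationConfig
) -> tuple[bool, list[str]]:
    """Accept a cell iff it looks like a discocyte.

    Proxies for the visual criterion: mask circularity 4*pi*A/P^2 at least
    ``qc_circularity_min`` (Crofton perimeter) and sphericity coefficient
    within ``qc_sphericity_range``. Returns (accepted, reasons).
    """
    reasons: list[str] = []
    circ = _circularity(cell.cropped())
    if circ < cfg.qc_circularity_min:
        reasons.append(f"circularity {circ:.3f} < {cfg.qc_circularity_min}")
    try:
        k = morphometrics.sphericity(opd_nm, cell.mask)
    except ValueError as exc:
        reasons.append(f"sphericity undefined: {exc}")
    else:
        lo, hi = cfg.qc_sphericity_range
        if not lo <= k <= hi:
            reasons.append(f"sphericity {k:.3f} outside [{lo}, {hi}]")
    return (not reasons, reasons)


def segment_cells(
    opd_nm: np.ndarray,
    cfg: SegmentationConfig,
    pixel_pitch_um: float,
    apply_qc: bool = True,
) -> tuple[list[CellMask], np.ndarray]:
    """Binarize, label and (optionally) QC-filter; returns (cells, bkgd mask)."""
    foreground, background = binarize(opd_nm, cfg, pixel_pitch_um)
    cells = label_cells(foreground, cfg, pixel_pitch_um)
    if apply_qc:
        cells = [c for c in cells if discocyte_qc(c, opd_nm, cfg)[0]]
    return cells, background
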