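"""Complete-block avoidance structure from a predicted dose.

The block is the external body contour minus the predicted 2-Gy isodose
volume, morphologically smoothed (closing then opening with spherical
elements) for geometric continuity, and optionally re-trimmed so the
final structure stays disjoint from the isodose region.  During helical
plan optimization no beamlet may cross a complete block at any point of
its path, so the block confines the deliverable beam directions to the
predicted low-dose corridor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes_io import (
    BinaryMask,
    GridGeometry,
    ImageVolume,
    append_roi_to_rtstruct,
)

__all__ = [
    "BlockParams",
    "extract_isodose",
    "make_complete_block",
    "check_block_dose",
    "export_block",
]


@dataclass(frozen=True)
class BlockParams:
    """Block construction parameters.

    ``threshold_gy`` is the isodose level defining the low-dose surface
    (2 Gy, the conventional boundary of the low-dose bath); the closing
    and opening radii (mm) smooth the raw Boolean subtraction; with
    ``enforce_disjoint`` the isodose volume is subtracted again after
    smoothing so smoothing can never push the block into it.
    """

    threshold_gy: float = 2.0
    closing_radius_mm: float = 5.0
    opening_radius_mm: float = 2.0
    enforce_disjoint: bool = True

    def __post_init__(self) -> None:
        if self.threshold_gy <= 0:
            raise ValueError("threshold must be positive")
        if self.closing_radius_mm < 0 or self.opening_radius_mm < 0:
            raise ValueError("radii must be >= 0")


def extract_isodose(dose: ImageVolume, threshold_gy: float) -> BinaryMask:
    """Voxels receiving at least ``threshold_gy`` (inclusive >=)."""
    return BinaryMask(
        dose.geometry,
        dose.values >= threshold_gy,
        name=f"isodose_{threshold_gy:g}Gy",
    )


def _ball(radius_mm: float, geom: GridGeometry) -> np.ndarray | None:
    """Spherical structuring element in voxels for an anisotropic grid."""
    if radius_mm <= 0:
        return None
    sz, sy, sx = geom.spacing[2], geom.spacing[1], geom.spacing[0]
    rz = int(radius_mm // sz)
    ry = int(radius_mm // sy)
    rx = int(radius_mm // sx)
    if max(rz, ry, rx) == 0:
        return None
    z, y, x = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (z * sz) ** 2 + (y * sy) ** 2 + (x * sx) ** 2 <= radius_mm**2


def make_complete_block(
    body: BinaryMask,
    isodose: BinaryMask,
    params: BlockParams | None = None,
) -> BinaryMask:
    """Boolean-subtract the isodose from the body and smooth the result.

    ``raw = body AND NOT isodose`` is closed with a spherical element of
    ``closing_radius_mm`` then opened with ``opening_radius_mm``; the
    result is clipped to the body, and (if ``enforce_disjoint``) the
    isodose is subtracted again after smoothing.
    """
    params = params or BlockParams()
    if body.geometry != isodose.geometry:
        raise ValueError("body and isodose must share a geometry")
    if not body.values.any():
        raise ValueError("empty body mask")
    block = body.values & ~isodose.values
    close_elem = _ball(params.closing_radius_mm, body.geometry)
    open_elem = _ball(params.opening_radius_mm, body.geometry)
    pads = [
        max(e.shape[a] // 2 for e in (close_elem, open_elem) if e is not None)
        if (close_elem is not None or open_elem is not None)
        else 0
        for a in range(3)
    ]
    if any(pads):
        # edge-replicate padding so structures touching the grid border
        # are treated as continuing beyond it rather than eroded
        padded = np.pad(block, [(p, p) for p in pads], mode="edge")
        if close_elem is not None:
            padded = ndimage.binary_closing(padded, structure=close_elem)
        if open_elem is not None:
            padded = ndimage.binary_opening(padded, structure=open_elem)
        block = padded[
            pads[0] : padded.shape[0] - pads[0],
            pads[1] : padded.shape[1] - pads[1],
            pads[2] : padded.shape[2] - pads[2],
        ]
    block = block & body.values
    if params.enforce_disjoint:
        block &= ~isodose.values
    return BinaryMask(body.geometry, block, name="CompleteBlock")


def check_block_dose(block: BinaryMask, dose: ImageVolume) -> dict:
    """Check the block against its planning constraints.

    The constraints are a maximum dose below 2 Gy and less than half the
    block volume receiving 1 Gy or more (both strict inequalities).
    An empty block yields a not-applicable report.
    """
    if block.geometry != dose.geometry:
        raise ValueError("block and dose must share a geometry")
    n = int(block.values.sum())
    if n == 0:
        return {
            "applicable": False,
            "dmax_gy": None,
            "v1_pct": None,
            "dmax_pass": None,
            "v1_pass": None,
        }
    d = dose.values[block.values]
    dmax = float(d.max())
    v1 = float(100.0 * np.count_nonzero(d >= 1.0) / n)
    return {
        "applicable": True,
        "dmax_gy": dmax,
        "v1_pct": v1,
        "dmax_pass": dmax < 2.0,
        "v1_pass": v1 < 50.0,
    }


def export_block(
    block: BinaryMask,
    case_rtstruct: str | Path,
    out_path: str | Path,
    name: str = "CompleteBlock",
) -> Path:
    """Append the block to a copy of the case's RTSTRUCT file.

    The block is contourized per axial slice; an empty block produces a
    valid ROI with zero contours (with a warning).
    """
    if not block.values.any():
        warnings.warn("exporting an empty block structure")
    return append_roi_to_rtstruct(case_rtstruct, block, out_path, name=name)
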