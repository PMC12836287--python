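"""Dose-volume histogram and plan-quality metrics.

All metrics are exact voxel-counting quantities on a shared grid:

* cumulative DVH (relative volume vs dose, default 0.01 Gy bins);
* ``V_x`` — percent of a structure receiving >= x Gy (inclusive), and
  ``V_x%`` — percent receiving >= x% of the prescription;
* ``D_x%`` — the highest dose received by the hottest x% of the
  structure volume (linear interpolation between voxels);
* mean / max / min dose;
* integral dose (mean dose x structure volume, Gy.L, unit density);
* conformity index (Paddick by default, simple coverage optional);
* homogeneity index ((D2% - D98%) / D50%, ICRU-83 style);
* Dice similarity coefficient between binary masks;
* a clinical dose-volume goal checker for breast planning.

The conformity- and homogeneity-index literature has several competing
definitions; the defaults here (Paddick CI at the 95% isodose, ICRU-83
HI) are stated in every report this module emits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes_io import BinaryMask, ImageVolume, PatientCase

__all__ = [
    "DVHCurve",
    "cumulative_dvh",
    "v_at_dose",
    "d_at_volume",
    "dose_stats",
    "integral_dose",
    "conformity_index",
    "homogeneity_index",
    "dice",
    "compute_plan_metrics",
    "evaluate_clinical_goals",
    "CLINICAL_GOALS",
]


def _masked_doses(dose: ImageVolume, mask: BinaryMask) -> np.ndarray:
    if dose.geometry != mask.geometry:
        raise ValueError("dose and mask must share a geometry")
    d = dose.values[mask.values]
    if d.size == 0:
        raise ValueError(f"mask {mask.name!r} is empty")
    return d


@dataclass
class DVHCurve:
    """Cumulative DVH: percent volume receiving at least each bin dose."""

    structure: str
    bin_edges_gy: np.ndarray
    relative_volume_pct: np.ndarray
    absolute_volume_cc: float

    def v_at(self, dose_gy: float) -> float:
        """Relative volume (%) receiving >= ``dose_gy`` (from the curve)."""
        i = int(np.searchsorted(self.bin_edges_gy, dose_gy, side="left"))
        if i >= self.relative_volume_pct.size:
            return 0.0
        return float(self.relative_volume_pct[i])


def cumulative_dvh(
    dose: ImageVolume, mask: BinaryMask, bin_gy: float = 0.01
) -> DVHCurve:
    """Exact voxel-counting cumulative DVH with ``bin_gy``-wide bins."""
    d = _masked_doses(dose, mask)
    edges = np.arange(0.0, d.max() + 2 * bin_gy, bin_gy)
    # percent of voxels with dose >= edge, for every edge
    counts = np.searchsorted(np.sort(d), edges, side="left")
    rel = 100.0 * (d.size - counts) / d.size
    rel[0] = 100.0  # every voxel receives at least 0 Gy
    return DVHCurve(
        structure=mask.name,
        bin_edges_gy=edges,
        relative_volume_pct=rel,
        absolute_volume_cc=mask.volume_cc,
    )


def v_at_dose(dose: ImageVolume, mask: BinaryMask, x_gy: float) -> float:
    """Percent of the structure receiving >= ``x_gy`` (inclusive)."""
    d = _masked_doses(dose, mask)
    return float(100.0 * np.count_nonzero(d >= x_gy) / d.size)


def d_at_volume(dose: ImageVolume, mask: BinaryMask, x_percent: float) -> float:
    """Dose (Gy) received by the hottest ``x_percent`` of the structure.

    Defined as the largest dose ``d`` such that at least ``x_percent``
    of the volume receives >= ``d``, linearly interpolated between
    voxels of the sorted dose distribution.
    """
    if not 0 <= x_percent <= 100:
        raise ValueError("x_percent must lie in [0, 100]")
    d = np.sort(_masked_doses(dose, mask))[::-1]
    n = d.size
    # position k (1-based) along the descending distribution
    k = x_percent / 100.0 * n
    if k <= 1:
        return float(d[0])
    if k >= n:
        return float(d[-1])
    lo = int(np.floor(k))
    frac = k - lo
    return float(d[lo - 1] + frac * (d[lo] - d[lo - 1]))


def dose_stats(dose: ImageVolume, mask: BinaryMask) -> dict[str, float]:
    """Mean / max / min dose (Gy) over the structure."""
    d = _masked_doses(dose, mask)
    return {
        "mean_gy": float(d.mean()),
        "max_gy": float(d.max()),
        "min_gy": float(d.min()),
    }


def integral_dose(dose: ImageVolume, mask: BinaryMask) -> float:
    """Integral dose in Gy.L: mean dose x structure volume, unit density."""
    if dose.geometry != mask.geometry:
        raise ValueError("dose and mask must share a geometry")
    n = int(mask.values.sum())
    if n == 0:
        warnings.warn(f"integral dose of empty mask {mask.name!r} is 0")
        return 0.0
    mean = float(dose.values[mask.values].mean())
    volume_l = n * mask.geometry.voxel_volume_cc / 1000.0
    return mean * volume_l


def conformity_index(
    dose: ImageVolume,
    target: BinaryMask,
    prescription_gy: float,
    iso_fraction: float = 0.95,
    method: str = "paddick",
) -> float:
    """Target conformity of the prescription isodose.

    ``paddick``: ``CI = TV_PIV^2 / (TV * PIV)`` with ``PIV`` the volume
    receiving at least ``iso_fraction * prescription`` and ``TV_PIV``
    the covered target volume.  ``coverage``: ``CI = TV_PIV / TV``.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    tv_vox = int(target.values.sum())
    if tv_vox == 0:
        raise ValueError("empty target")
    piv = dose.values >= iso_fraction * prescription_gy
    piv_vox = int(piv.sum())
    if piv_vox == 0:
        warnings.warn("prescription isodose volume is empty; CI = 0")
        return 0.0
    tv_piv = int((piv & target.values).sum())
    if method == "paddick":
        return tv_piv**2 / (tv_vox * piv_vox)
    if method == "coverage":
        return tv_piv / tv_vox
    raise ValueError(f"unknown CI method {method!r}")


def homogeneity_index(dose: ImageVolume, target: BinaryMask) -> float:
    """ICRU-83 homogeneity index ``(D2% - D98%) / D50%`` (0 = uniform)."""
    d2 = d_at_volume(dose, target, 2.0)
    d98 = d_at_volume(dose, target, 98.0)
    d50 = d_at_volume(dose, target, 50.0)
    if d50 == 0:
        raise ValueError("median target dose is zero; HI undefined")
    return (d2 - d98) / d50


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient ``2|A.B| / (|A| + |B|)``.

    Two empty masks are defined as perfectly similar (1.0).
    """
    if a.geometry != b.geometry:
        raise ValueError("masks must share a geometry")
    na, nb = int(a.values.sum()), int(b.values.sum())
    if na + nb == 0:
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# per-case metric tables and clinical goals
# ---------------------------------------------------------------------------

# clinical dose-volume goals for breast planning; strict inequalities
CLINICAL_GOALS: list[tuple[str, str, str, float]] = [
    ("PTV_Breast", "V95%", ">", 95.0),
    ("PTV_SCF", "V95%", ">", 95.0),
    ("SpinalCord", "Dmax", "<", 45.0),
    ("Heart", "Dmean", "<", 5.0),
    ("Lung_Ipsi", "V5", "<", 50.0),
    ("Lung_Ipsi", "V10", "<", 40.0),
    ("Lung_Ipsi", "V20", "<", 30.0),
    ("Lung_Ipsi", "V30", "<", 20.0),
    ("Esophagus", "Dmax", "<", 40.0),
]

_TARGETS = ("PTV_Breast", "PTV_SCF")


def compute_plan_metrics(
    case: PatientCase,
    dose: ImageVolume | None = None,
    ci_method: str = "paddick",
) -> pd.DataFrame:
    """Tidy per-structure metric table for one case.

    Rows are structures; columns the standard metrics (Dmean/Dmax/Dmin,
    V2/V5/V10/V20/V25/V30/V40, V95%, D2%/D50%/D98%, integral dose, and
    for targets CI and HI).  ``dose`` defaults to the case's own dose.
    CI uses the Paddick definition at the 95% isodose and HI the ICRU-83
    definition unless configured otherwise; the choice is recorded in the
    table attributes.
    """
    dose = dose or case.dose
    if dose is None:
        raise ValueError("case has no dose and none was provided")
    rx = case.prescription_gy
    rows = []
    for name, mask in case.structures.items():
        if not mask.values.any():
            continue
        stats = dose_stats(dose, mask)
        row = {
            "structure": name,
            "volume_cc": mask.volume_cc,
            "Dmean": stats["mean_gy"],
            "Dmax": stats["max_gy"],
            "Dmin": stats["min_gy"],
            "integral_dose_gyl": integral_dose(dose, mask),
        }
        for x in (1, 2, 5, 10, 20, 25, 30, 40):
            row[f"V{x}"] = v_at_dose(dose, mask, float(x))
        row["V95%"] = v_at_dose(dose, mask, 0.95 * rx)
        for x in (2.0, 50.0, 98.0):
            row[f"D{x:g}%"] = d_at_volume(dose, mask, x)
        if name in _TARGETS:
            row["CI"] = conformity_index(dose, mask, rx, method=ci_method)
            row["HI"] = homogeneity_index(dose, mask)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("structure")
    df.attrs["ci_definition"] = f"{ci_method} @ 95% isodose"
    df.attrs["hi_definition"] = "ICRU-83 (D2%-D98%)/D50%"
    return df


def evaluate_clinical_goals(
    metrics: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Check the clinical dose-volume goals against a metric table.

    ``metrics`` is the frame from :func:`compute_plan_metrics` (or a
    nested mapping ``{structure: {metric: value}}``).  Rows for
    structures absent from the table are marked ``unevaluated``.
    Inequalities are strict, matching the printed goal notation.
    """
    if isinstance(metrics, dict):
        metrics = pd.DataFrame(metrics).T
    alias = {"Dmean": "Dmean", "Dmax": "Dmax", "V95%": "V95%"}
    rows = []
    for structure, parameter, op, limit in CLINICAL_GOALS:
        col = alias.get(parameter, parameter)
        value = np.nan
        status = "unevaluated"
        if structure in metrics.index and col in metrics.columns:
            value = float(metrics.loc[structure, col])
            if np.isfinite(value):
                ok = value < limit if op == "<" else value > limit
                status = "pass" if ok else "fail"
        rows.append(
            {
                "structure": structure,
                "parameter": parameter,
                "goal": f"{op} {limit:g}",
                "value": value,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
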