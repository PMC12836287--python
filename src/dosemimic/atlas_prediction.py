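"""Atlas construction and SSIM-weighted dose prediction.

An atlas is a set of planning cases deformably registered into the frame
of one reference case, with their dose grids warped along.  A new
patient's low-dose distribution is predicted by (1) registering the
patient to the reference, (2) scoring the anatomic similarity between
the warped patient CT and each atlas member's warped CT with a
slice-wise structural similarity index (SSIM), (3) normalizing the
scores into weights, and (4) summing the members' doses — deformed into
the patient's geometry through the inverse field — with those weights.

The prediction is a convex combination, so the predicted dose lies
voxelwise within the range of the warped member doses, and permuting
member order changes nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .registration import (
    RegistrationConfig,
    RegistrationResult,
    apply_field,
    invert_field,
    register,
)
from .volumes_io import (
    BinaryMask,
    DeformationField,
    ImageVolume,
    PatientCase,
)

__all__ = [
    "Atlas",
    "AtlasMember",
    "SimilarityWeights",
    "PredictionResult",
    "build_atlas",
    "slicewise_ssim",
    "compute_weights",
    "predict_dose",
]

logger = logging.getLogger(__name__)

# CT window fixing the SSIM dynamic range L: air to dense tissue/bone
CT_WINDOW_HU = (-1000.0, 1000.0)


@dataclass
class AtlasMember:
    id: str
    warped_ct: ImageVolume
    warped_dose: ImageVolume


@dataclass
class Atlas:
    """Reference case plus members warped into the reference frame.

    The reference participates as a member with an identity warp, so a
    prediction sums over all member doses including the reference's.
    """

    reference: PatientCase
    members: list[AtlasMember]
    config: RegistrationConfig

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("an atlas needs at least one member")
        geom = self.reference.ct.geometry
        for m in self.members:
            if m.warped_ct.geometry != geom or m.warped_dose.geometry != geom:
                raise ValueError(f"member {m.id!r} not on the reference geometry")


@dataclass
class SimilarityWeights:
    """Raw mean slice-wise SSIM per member and normalized weights."""

    member_ids: list[str]
    raw_similarity: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.raw_similarity = np.asarray(self.raw_similarity, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.min() < 0 or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")


@dataclass
class PredictionResult:
    predicted_dose: ImageVolume
    weights: SimilarityWeights
    test_to_reference_field: DeformationField
    reference_to_test_field: DeformationField


def build_atlas(
    cases: list[PatientCase],
    reference_id: str,
    config: RegistrationConfig | None = None,
    reg_cache: dict | None = None,
) -> Atlas:
    """Register every case to the reference and warp its dose along.

    Each non-reference case is registered (as moving image) to the
    reference CT; its CT and dose are pulled back into the reference
    frame.  The reference itself is stored with an identity warp.  A
    member whose registration fails is skipped with a warning; the atlas
    is valid as long as one member remains.

    ``reg_cache`` (optional dict) memoizes registration results under
    ``(fixed_id, moving_id)`` keys; registration is deterministic, so a
    cache hit is bit-identical to recomputation.
    """
    if len(cases) < 2:
        raise ValueError("atlas construction needs at least 2 cases")
    config = config or RegistrationConfig()
    by_id = {c.id: c for c in cases}
    if reference_id not in by_id:
        raise ValueError(f"reference id {reference_id!r} not among cases")
    reference = by_id[reference_id]
    members: list[AtlasMember] = []
    for case in cases:
        if case.id == reference_id:
            members.append(
                AtlasMember(case.id, reference.ct, reference.dose)
            )
            continue
        try:
            result = _cached_register(reference, case, config, reg_cache)
        except Exception as exc:  # registration failure: skip the member
            warnings.warn(f"registration of {case.id!r} failed ({exc}); skipped")
            continue
        warped_dose = apply_field(result.field, case.dose, mode="linear")
        members.append(AtlasMember(case.id, result.warped_moving, warped_dose))
        logger.info("atlas member %s registered to %s", case.id, reference_id)
    return Atlas(reference=reference, members=members, config=config)


def _cached_register(
    fixed_case: PatientCase,
    moving_case: PatientCase,
    config: RegistrationConfig,
    reg_cache: dict | None,
) -> RegistrationResult:
    if reg_cache is None:
        return register(fixed_case.ct, moving_case.ct, config)
    key = (fixed_case.id, moving_case.id)
    if key not in reg_cache:
        reg_cache[key] = register(fixed_case.ct, moving_case.ct, config)
    return reg_cache[key]


def slicewise_ssim(
    a: ImageVolume,
    b: ImageVolume,
    body: BinaryMask | None = None,
    data_range: float | None = None,
) -> float:
    """Mean slice-wise SSIM between two volumes on one geometry.

    Each axial slice is scored with the standard SSIM (Gaussian window,
    stabilizing constants ``c1 = (0.01 L)^2``, ``c2 = (0.03 L)^2``); the
    result is the mean over slices intersecting ``body`` (all slices if
    no body mask is given).  For CT the dynamic range ``L`` is fixed
    from the window −1000..1000 HU so air-only slices cannot inflate the
    similarity; pass ``data_range`` to override.  If the joint dynamic
    range is degenerate (both images constant), the score is 1.0 when
    they are identical and 0.0 otherwise.
    """
    if a.geometry != b.geometry:
        raise ValueError("SSIM requires volumes on the same geometry")
    av, bv = a.values, b.values
    if data_range is None:
        av = np.clip(av, *CT_WINDOW_HU)
        bv = np.clip(bv, *CT_WINDOW_HU)
        data_range = CT_WINDOW_HU[1] - CT_WINDOW_HU[0]
    if data_range == 0:
        return 1.0 if np.array_equal(av, bv) else 0.0
    if body is not None:
        slice_sel = body.values.any(axis=(1, 2))
        if not slice_sel.any():
            slice_sel = np.ones(av.shape[0], dtype=bool)
    else:
        slice_sel = np.ones(av.shape[0], dtype=bool)
    scores = [
        structural_similarity(
            av[k],
            bv[k],
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
        for k in np.flatnonzero(slice_sel)
    ]
    return float(np.mean(scores))


def compute_weights(
    similarities: list[float] | np.ndarray,
    member_ids: list[str] | None = None,
    p: float = 1.0,
    eps: float = 1e-6,
) -> SimilarityWeights:
    """Normalize similarities into convex weights ``s_i^p / sum s_j^p``.

    Values are clamped to at least ``eps`` before the power so negative
    or zero SSIM scores cannot produce negative weights; ``p`` sharpens
    the weighting (``p -> inf`` selects the single most similar member).
    """
    s = np.asarray(similarities, dtype=float)
    if s.size < 1:
        raise ValueError("need at least one similarity")
    ids = member_ids or [str(i) for i in range(s.size)]
    if np.all(s <= 0):
        warnings.warn("all similarities nonpositive; falling back to uniform weights")
        w = np.full(s.size, 1.0 / s.size)
    else:
        clamped = np.maximum(s, eps)
        powered = clamped**p
        w = powered / powered.sum()
    return SimilarityWeights(list(ids), s, w)


def predict_dose(
    atlas: Atlas,
    test: PatientCase,
    p: float = 1.0,
    reg_cache: dict | None = None,
) -> PredictionResult:
    """Predict the test patient's 3D dose from the atlas.

    Pipeline: register the test CT (moving) to the reference (fixed);
    invert the resulting field; score slice-wise SSIM between the warped
    test CT and each member's warped CT in the reference frame; pull
    each member dose into the test geometry through the inverse field;
    return the weighted sum.
    """
    if "Body" not in test.structures:
        raise ValueError("test case needs a Body structure")
    result = _cached_register(atlas.reference, test, atlas.config, reg_cache)
    fwd = result.field
    inv = invert_field(fwd, target=test.ct.geometry)
    ref_body = (
        atlas.reference.structures["Body"]
        if "Body" in atlas.reference.structures
        else None
    )
    sims = [
        slicewise_ssim(result.warped_moving, m.warped_ct, body=ref_body)
        for m in atlas.members
    ]
    weights = compute_weights(sims, [m.id for m in atlas.members], p=p)
    predicted = np.zeros(test.ct.geometry.array_shape)
    for w, member in zip(weights.weights, atlas.members):
        if w == 0.0:
            continue
        dose_in_test = apply_field(inv, member.warped_dose, mode="linear")
        predicted += w * dose_in_test.values
    predicted_vol = ImageVolume(
        test.ct.geometry, np.clip(predicted, 0.0, None), modality="DOSE"
    )
    return PredictionResult(
        predicted_dose=predicted_vol,
        weights=weights,
        test_to_reference_field=fwd,
        reference_to_test_field=inv,
    )
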