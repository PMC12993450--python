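"""PET quantification: meninges masking, smoothing, SUVR, ventricular
radioactivity and A/T biomarker staging.

SUVR (standardized uptake value ratio) is the mean tracer signal in a target
region divided by the mean in a reference region: full cerebellar grey matter
for the amyloid tracer and inferior cerebellar grey matter for the tau
tracer.  In the phantom anatomy a single cerebellar grey-matter label stands
in for both reference regions.

Ventricular radioactivity (VR) is the SUVR inside the lateral ventricles
after excluding the choroid plexus and eroding the mask (~2 mm by default) to
limit boundary partial-volume interactions; it serves as an indirect proxy of
CSF dynamics and clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, ScalarVolume
from .volumetrics import CHOROID_LABELS, VENTRICLE_LABELS

__all__ = [
    "CompositeROI",
    "ATStage",
    "NEOCORTEX_COMPOSITE",
    "TEMPORAL_META_ROI",
    "mask_meninges",
    "smooth_to_fwhm",
    "suvr",
    "composite_suvr",
    "make_vr_mask",
    "vr_suvr",
    "classify_at",
    "A_CUTOFF",
    "T_CUTOFF",
    "MaskError",
    "DegenerateMaskError",
]

#: Amyloid positivity threshold on the neocortical composite SUVR.
A_CUTOFF = 1.55
#: Tau positivity threshold on the temporal meta-ROI SUVR.
T_CUTOFF = 1.18

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class MaskError(ValueError):
    pass


class DegenerateMaskError(ValueError):
    def __init__(self, msg: str, diagnostic_mask: np.ndarray | None = None):
        super().__init__(msg)
        self.diagnostic_mask = diagnostic_mask


@dataclass(frozen=True)
class CompositeROI:
    """A composite target region quantified against a reference region.

    The phantom's sector labels stand in for the anatomical members of the
    published composites (precuneus/prefrontal/orbitofrontal/parietal/
    temporal/cingulate for the neocortex; entorhinal/amygdala/hippocampus/
    parahippocampal/fusiform/lingual/inferior+middle temporal for the
    temporal meta-ROI); the mapping is a modelling convention, not an
    anatomically faithful parcellation.
    """

    name: str
    member_labels: tuple[str, ...]
    reference_label: str

    def __post_init__(self) -> None:
        if not self.member_labels:
            raise ValueError("composite ROI needs at least one member label")
        if self.reference_label in self.member_labels:
            raise ValueError("reference label must be disjoint from members")


NEOCORTEX_COMPOSITE = CompositeROI(
    name="neocortex",
    member_labels=("neocortex_composite",),
    reference_label="cerebellum_gm",
)
TEMPORAL_META_ROI = CompositeROI(
    name="temporal_meta_roi",
    member_labels=("meta_temporal",),
    reference_label="cerebellum_gm",
)


@dataclass(frozen=True)
class ATStage:
    a_positive: bool
    t_positive: bool

    @property
    def stage_label(self) -> str:
        return f"A{'+' if self.a_positive else '-'}T{'+' if self.t_positive else '-'}"


def mask_meninges(volume: ScalarVolume, labels: LabelVolume) -> ScalarVolume:
    """Zero out meningeal voxels (to be applied before smoothing, so that
    meningeal signal cannot spill into adjacent cortex)."""
    if volume.data.shape != labels.data.shape:
        raise ValueError("PET volume and label volume are on different grids")
    out = volume.data.copy()
    out[labels.mask("meninges")] = 0.0
    return ScalarVolume(data=out, voxel_size_mm=volume.voxel_size_mm, tracer=volume.tracer)


def smooth_to_fwhm(volume: ScalarVolume, fwhm_mm: float = 8.0) -> ScalarVolume:
    """Gaussian smoothing to a target full width at half maximum.

    Per-axis sigma is fwhm / (2*sqrt(2*ln 2)) / voxel_size; fwhm 0 is the
    identity.  Reflective boundary handling preserves the global mean.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return ScalarVolume(
            data=volume.data.copy(), voxel_size_mm=volume.voxel_size_mm, tracer=volume.tracer
        )
    sigma = [fwhm_mm * _FWHM_TO_SIGMA / v for v in volume.voxel_size_mm]
    out = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="reflect")
    return ScalarVolume(data=out, voxel_size_mm=volume.voxel_size_mm, tracer=volume.tracer)


def suvr(volume: ScalarVolume, target_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """Mean signal over the target mask divided by mean over the reference mask."""
    target_mask = np.asarray(target_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not target_mask.any():
        raise MaskError("target mask is empty")
    if not reference_mask.any():
        raise MaskError("reference mask is empty")
    ref_mean = float(volume.data[reference_mask].mean())
    if ref_mean <= 0:
        raise MaskError(f"non-positive reference mean ({ref_mean:.4g})")
    return float(volume.data[target_mask].mean()) / ref_mean


def composite_suvr(volume: ScalarVolume, labels: LabelVolume, roi: CompositeROI) -> float:
    """Volume-weighted mean over the union of member labels, divided by the
    reference-region mean."""
    if volume.data.shape != labels.data.shape:
        raise ValueError("PET volume and label volume are on different grids")
    target = labels.union_mask(roi.member_labels)
    reference = labels.mask(roi.reference_label)
    return suvr(volume, target, reference)


def make_vr_mask(labels: LabelVolume, erosion_mm: float = 2.0) -> np.ndarray:
    """Ventricular-radioactivity mask: lateral ventricles minus choroid
    plexus, then binary erosion by a ball of radius ``erosion_mm``.

    The erosion radius in voxels is round(erosion_mm / min voxel size); a
    radius of 0 skips erosion.  Raises if the erosion empties the mask,
    attaching the pre-erosion mask as a diagnostic.
    """
    vent = labels.union_mask(VENTRICLE_LABELS)
    if not vent.any():
        raise MaskError("ventricle labels are empty")
    mask = vent & ~labels.union_mask(CHOROID_LABELS)
    radius_vox = int(round(erosion_mm / min(labels.voxel_size_mm)))
    if radius_vox > 0:
        # Euclidean ball of the given voxel radius
        r = radius_vox
        g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = (g ** 2).sum(axis=0) <= r * r
        eroded = ndimage.binary_erosion(mask, structure=ball)
        if not eroded.any():
            raise DegenerateMaskError(
                f"{erosion_mm} mm erosion emptied the ventricular mask "
                f"({int(mask.sum())} voxels before erosion)",
                diagnostic_mask=mask,
            )
        mask = eroded
    return mask


def vr_suvr(volume: ScalarVolume, labels: LabelVolume, erosion_mm: float = 2.0) -> float:
    """Ventricular-radioactivity SUVR against the tracer-appropriate
    cerebellar reference region."""
    mask = make_vr_mask(labels, erosion_mm=erosion_mm)
    reference = labels.mask("cerebellum_gm")
    return suvr(volume, mask, reference)


def classify_at(
    abeta_suvr: float,
    tau_suvr: float,
    a_cut: float = A_CUTOFF,
    t_cut: float = T_CUTOFF,
) -> ATStage:
    """A/T biomarker stage from composite SUVRs.

    Positivity is strict (> cutoff); values exactly at a cutoff classify
    negative.
    """
    if not (np.isfinite(abeta_suvr) and np.isfinite(tau_suvr)):
        raise ValueError("SUVR inputs must be finite")
    return ATStage(a_positive=bool(abeta_suvr > a_cut), t_positive=bool(tau_suvr > t_cut))
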