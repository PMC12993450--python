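"""Region volumetry, ICV residualization and the Evans' Index.

The Evans' Index (EI) is the ratio of the maximal frontal-horn width of the
lateral ventricles to the internal skull diameter; EI > 0.3 is the
conventional flag for disproportionate ventriculomegaly and is used here as
an exclusion filter, mirroring clinical practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import GREY_MATTER_LABELS, LabelVolume

__all__ = [
    "region_volume",
    "icv",
    "grey_matter_volume",
    "residualize",
    "evans_index",
    "apply_ei_exclusion",
    "EvansResult",
    "DegenerateInputError",
]

VENTRICLE_LABELS = ("lateral_ventricle_L", "lateral_ventricle_R")
CHOROID_LABELS = ("choroid_plexus_L", "choroid_plexus_R")


class DegenerateInputError(ValueError):
    pass


def region_volume(labels: LabelVolume, region) -> float:
    """Volume of a named region (or union of regions) in mm^3.

    A region with no voxels has volume 0.  Unknown names raise KeyError.
    """
    if isinstance(region, str):
        region = [region]
    mask = labels.union_mask(region)
    return float(mask.sum()) * labels.voxel_volume_mm3


def icv(labels: LabelVolume) -> float:
    """Total intracranial volume: all non-background voxels, meninges included."""
    n = int(labels.head_mask().sum())
    if n == 0:
        raise DegenerateInputError("label volume contains no intracranial voxels")
    return n * labels.voxel_volume_mm3


def grey_matter_volume(labels: LabelVolume) -> float:
    """Summed volume of all grey-matter labels (cortical sectors, generic
    grey matter and cerebellar grey matter)."""
    present = [n for n in GREY_MATTER_LABELS if n in labels.label_map]
    return region_volume(labels, present)


def residualize(values, covariate) -> np.ndarray:
    """Residuals of an ordinary least-squares fit of values on (1, covariate).

    Used to correct ventricular and choroid plexus volumes for head size
    before any statistics.  Residuals sum to zero and are orthogonal to the
    covariate.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("values and covariate must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("covariate is constant; design is rank-deficient")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass(frozen=True)
class EvansResult:
    ei: float
    horn_width_mm: float
    skull_diameter_mm: float
    horn_slice_index: int

    def __post_init__(self) -> None:
        if not 0 < self.ei < 1:
            raise ValueError(f"Evans' Index must be in (0, 1), got {self.ei}")
        if self.horn_width_mm > self.skull_diameter_mm:
            raise ValueError("horn width cannot exceed the skull diameter")


def evans_index(labels: LabelVolume, skull_convention: str = "global") -> EvansResult:
    """Evans' Index from a label volume.

    The frontal-horn width is the maximal left-right extent (in mm) of
    lateral-ventricle voxels on any axial slice, restricted to the anterior
    third of the ventricles' own anterior-posterior extent.  The internal
    skull diameter is the maximal left-right extent of the head (all
    non-background voxels).

    Parameters
    ----------
    skull_convention
        "global" (default): skull diameter is the maximum over all axial
        slices.  "same_slice": skull diameter is measured on the axial slice
        where the maximal horn width occurs.
    """
    if skull_convention not in ("global", "same_slice"):
        raise ValueError("skull_convention must be 'global' or 'same_slice'")
    vent = labels.union_mask(VENTRICLE_LABELS)
    if not vent.any():
        raise DegenerateInputError("ventricle mask is empty")
    head = labels.head_mask()
    if not head.any():
        raise DegenerateInputError("head mask is empty")
    vx, vy = labels.voxel_size_mm[0], labels.voxel_size_mm[1]

    ys = np.where(vent.any(axis=(0, 2)))[0]
    y_min, y_max = ys.min(), ys.max()
    # anterior third of the ventricles' own y-extent (anterior = +y)
    y_cut = y_max - (y_max - y_min + 1) / 3.0
    anterior = vent.copy()
    anterior[:, : int(np.floor(y_cut)) + 1, :] = False
    if not anterior.any():  # extent < 3 voxels: keep the anterior-most slice
        anterior = np.zeros_like(vent)
        anterior[:, y_max, :] = vent[:, y_max, :]

    def slice_width(mask2d: np.ndarray) -> float:
        xs = np.where(mask2d.any(axis=1))[0]
        if xs.size == 0:
            return 0.0
        return (xs.max() - xs.min() + 1) * vx

    nz = labels.data.shape[2]
    horn_w = np.array([slice_width(anterior[:, :, z]) for z in range(nz)])
    z_star = int(np.argmax(horn_w))
    horn_width = float(horn_w[z_star])

    skull_w = np.array([slice_width(head[:, :, z]) for z in range(nz)])
    skull_diameter = float(skull_w.max() if skull_convention == "global" else skull_w[z_star])
    if skull_diameter <= 0:
        raise DegenerateInputError("skull diameter is zero")
    return EvansResult(
        ei=horn_width / skull_diameter,
        horn_width_mm=horn_width,
        skull_diameter_mm=skull_diameter,
        horn_slice_index=z_star,
    )


def apply_ei_exclusion(
    cohort: pd.DataFrame,
    phantoms: dict[str, LabelVolume],
    threshold: float = 0.3,
    skull_convention: str = "global",
):
    """Drop participants with disproportionate ventriculomegaly (EI > threshold).

    Parameters
    ----------
    cohort
        Participant table with an ``id`` column.
    phantoms
        Mapping id -> LabelVolume (or PhantomBundle-like with a ``labels``
        attribute) for every participant in the table.
    threshold
        Retain participants with EI <= threshold (strict exclusion above).

    Returns
    -------
    (retained_table, report)
        ``report`` is a DataFrame of excluded participants with their EI.
    """
    records = []
    for pid in cohort["id"]:
        vol = phantoms[pid]
        labels = getattr(vol, "labels", vol)
        records.append((pid, evans_index(labels, skull_convention=skull_convention).ei))
    ei = pd.DataFrame(records, columns=["id", "ei"])
    merged = cohort.merge(ei, on="id", how="left", suffixes=("", "_measured"))
    excluded = merged[merged["ei"] > threshold]
    retained = merged[merged["ei"] <= threshold].reset_index(drop=True)
    report = excluded[["id", "ei"]].reset_index(drop=True)
    if len(report):
        warnings.warn(
            f"excluded {len(report)} participant(s) with Evans' Index > {threshold}",
            stacklevel=2,
        )
    return retained, report
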