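"""NIfTI-1 input/output for label and scalar volumes.

Volumes are written RAS-oriented with a diagonal affine built from the voxel
sizes; on read, images are reoriented to closest-canonical (RAS) and voxel
sizes are taken from the header.
"""

from __future__ import annotations

import warnings

import nibabel as nib
import numpy as np

from .volumes import DEFAULT_LABEL_MAP, LabelVolume, ScalarVolume

__all__ = ["read_volume", "write_volume", "VolumeFormatError"]

#: warn when voxel anisotropy (max/min edge ratio) exceeds this
ANISOTROPY_TOLERANCE = 3.0


class VolumeFormatError(IOError):
    pass


def write_volume(volume, path) -> None:
    """Write a LabelVolume or ScalarVolume as NIfTI-1 (.nii or .nii.gz)."""
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    if isinstance(volume, LabelVolume):
        img = nib.Nifti1Image(volume.data.astype(np.int16), affine)
    else:
        img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def read_volume(path, kind: str = "auto", label_map: dict | None = None, tracer: str = "none"):
    """Read a NIfTI-1 volume as a LabelVolume or ScalarVolume.

    Parameters
    ----------
    kind
        "label", "scalar", or "auto" (labels when the on-disk dtype is
        integral).
    label_map
        Name->code map for label volumes; defaults to the package's canonical
        anatomy labels.
    """
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path!r} as NIfTI-1: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if max(zooms) / min(zooms) > ANISOTROPY_TOLERANCE:
        warnings.warn(f"voxel anisotropy {zooms} exceeds tolerance", stacklevel=2)
    is_int = np.issubdtype(data.dtype, np.integer)
    if kind == "auto":
        kind = "label" if is_int else "scalar"
    if kind == "label":
        return LabelVolume(
            data=data.astype(np.int16),
            voxel_size_mm=zooms,
            label_map=dict(label_map or DEFAULT_LABEL_MAP),
        )
    if kind == "scalar":
        return ScalarVolume(data=data.astype(np.float64), voxel_size_mm=zooms, tracer=tracer)
    raise ValueError("kind must be 'label', 'scalar' or 'auto'")
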