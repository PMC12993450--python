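"""In-memory 3D volume containers.

All volumes live on a regular grid with anisotropy allowed but discouraged.
Axis convention is RAS-like: axis 0 = x (left->right), axis 1 = y
(posterior->anterior), axis 2 = z (inferior->superior).  Voxel sizes are in
millimetres; volumes derived from them are in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "LabelVolume",
    "ScalarVolume",
    "DEFAULT_LABEL_MAP",
    "GREY_MATTER_LABELS",
]

#: Canonical anatomy labels used by the phantom generator and the extraction
#: pipeline.  background must be 0; all other codes are arbitrary but unique.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "background": 0,
    "white_matter": 1,
    "grey_matter": 2,
    "lateral_ventricle_L": 3,
    "lateral_ventricle_R": 4,
    "choroid_plexus_L": 5,
    "choroid_plexus_R": 6,
    "cerebellum_gm": 7,
    "meta_temporal": 8,
    "neocortex_composite": 9,
    "meninges": 10,
    "head_interior": 11,
}

#: Labels counted as grey matter when computing the grey-matter-volume
#: covariate.
GREY_MATTER_LABELS = (
    "grey_matter",
    "neocortex_composite",
    "meta_temporal",
    "cerebellum_gm",
)


@dataclass(frozen=True)
class GridSpec:
    """Shape and voxel size of the sampling grid.

    Parameters
    ----------
    shape
        Voxels per axis (x, y, z).  Each entry must be >= 16.
    voxel_size_mm
        Physical voxel edge lengths in mm, all > 0.  Default isotropic 2 mm.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size_mm) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(int(s) < 16 for s in self.shape):
            raise ValueError(f"all grid shape entries must be >= 16, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size_mm))


@dataclass
class LabelVolume:
    """Integer-coded segmentation on a regular grid.

    The intracranial region (ICV) is defined as the union of all
    non-background labels, meninges included.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label data must be integer-typed")
        codes = list(self.label_map.values())
        if len(set(codes)) != len(codes):
            raise ValueError("label_map codes must be unique")
        if any(c < 0 for c in codes):
            raise ValueError("label codes must be non-negative")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def code(self, name: str) -> int:
        try:
            return self.label_map[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; known: {sorted(self.label_map)}"
            ) from None

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a single named region."""
        return self.data == self.code(name)

    def union_mask(self, names) -> np.ndarray:
        out = np.zeros(self.data.shape, dtype=bool)
        for n in names:
            out |= self.mask(n)
        return out

    def head_mask(self) -> np.ndarray:
        """All non-background voxels (the intracranial region, meninges included)."""
        return self.data != self.label_map.get("background", 0)


@dataclass
class ScalarVolume:
    """Floating-point 3D image (PET SUVR map, t-map, ...) on a regular grid."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tracer: str = "none"  # one of {"amyloid", "tau", "none"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("scalar data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scalar volume contains non-finite values")
        if self.tracer not in ("amyloid", "tau", "none"):
            raise ValueError(f"unknown tracer {self.tracer!r}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )
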