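"""Per-participant 3D brain phantoms.

Each phantom realizes one participant's latent biomarkers as a label volume
plus co-registered amyloid- and tau-PET SUVR volumes on a shared grid:

* an intracranial ellipsoid sized to the participant's ICV, with a 1-voxel
  meningeal rim just inside the skull boundary and a 1-voxel subarachnoid
  CSF layer beneath it;
* a cortical ribbon partitioned into a neocortical-composite sector, a
  temporal meta-ROI sector and a generic grey-matter layer, plus an inferior
  cerebellar grey-matter blob (the PET reference region);
* two lateral ventricles, each a posterior body fused with an anterior
  frontal horn, scaled by bisection until the summed cavity volume matches
  the requested ventricular + choroid-plexus volume; choroid-plexus blobs
  are carved out of the ventricular cavities the same way.

PET volumes are piecewise-constant tissue means plus Gaussian noise, with
means chosen so that composite SUVRs recover the latent amyloid/tau values
and the eroded ventricular mask recovers the latent ventricular-radioactivity
SUVRs (before any smoothing).

Phantoms are generated pre-aligned on the grid; no registration is modelled,
and cortical folding, partial-volume physics and scanner noise models are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import DEFAULT_LABEL_MAP, GridSpec, LabelVolume, ScalarVolume

__all__ = ["ParticipantRecord", "PhantomBundle", "simulate_phantom", "InfeasibleGeometryError"]


class InfeasibleGeometryError(ValueError):
    """Requested anatomy does not fit inside the head at this grid size."""


@dataclass(frozen=True)
class ParticipantRecord:
    """Ground-truth biomarkers of one synthetic participant."""

    id: str
    stage: str
    age: float
    sex: int
    apoe4: int
    icv: float  # mm^3
    latent_vv: float  # mm^3, lateral-ventricle (CSF) volume, choroid plexus excluded
    latent_cpv: float  # mm^3
    latent_vr_amyloid: float  # SUVR
    latent_vr_tau: float  # SUVR
    latent_abeta: float  # neocortical composite SUVR
    latent_tau: float  # temporal meta-ROI SUVR

    def __post_init__(self) -> None:
        if min(self.icv, self.latent_vv, self.latent_cpv) <= 0:
            raise ValueError("all volumes must be positive")
        if not self.latent_vv < self.icv:
            raise ValueError("ventricular volume must be smaller than ICV")
        if not self.latent_cpv < self.latent_vv:
            raise ValueError("choroid plexus volume must be smaller than ventricular volume")

    @classmethod
    def from_row(cls, row) -> "ParticipantRecord":
        return cls(
            id=str(row["id"]),
            stage=str(row["stage"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            apoe4=int(row["apoe4"]),
            icv=float(row["icv"]),
            latent_vv=float(row["latent_vv"]),
            latent_cpv=float(row["latent_cpv"]),
            latent_vr_amyloid=float(row["latent_vr_amyloid"]),
            latent_vr_tau=float(row["latent_vr_tau"]),
            latent_abeta=float(row["latent_abeta"]),
            latent_tau=float(row["latent_tau"]),
        )


@dataclass
class PhantomBundle:
    labels: LabelVolume
    amyloid: ScalarVolume | None
    tau: ScalarVolume | None
    truth: ParticipantRecord


def _ellipsoid_into(out: np.ndarray, grid: GridSpec, center_mm, semi_mm) -> None:
    """OR an axis-aligned ellipsoid into a boolean array, touching only its
    bounding box (voxel centres at (i + 0.5 - N/2) * voxel)."""
    shape = grid.shape
    vox = grid.voxel_size_mm
    sl = []
    for ax in range(3):
        lo = int(np.floor((center_mm[ax] - semi_mm[ax]) / vox[ax] + shape[ax] / 2 - 0.5))
        hi = int(np.ceil((center_mm[ax] + semi_mm[ax]) / vox[ax] + shape[ax] / 2 + 0.5))
        sl.append(slice(max(lo, 0), min(hi, shape[ax])))
    if any(s.start >= s.stop for s in sl):
        return
    coords = []
    for ax, s in enumerate(sl):
        c = (np.arange(s.start, s.stop) + 0.5 - shape[ax] / 2) * vox[ax]
        shp = [1, 1, 1]
        shp[ax] = -1
        coords.append(((c - center_mm[ax]) / semi_mm[ax]).reshape(shp))
    out[tuple(sl)] |= coords[0] ** 2 + coords[1] ** 2 + coords[2] ** 2 <= 1.0


_CROSS = ndimage.generate_binary_structure(3, 1)


def _ventricle_masks(grid: GridSpec, scale: float, allowed: np.ndarray):
    """Left and right ventricular cavity masks at a given shape scale."""
    u = scale
    sides = []
    for sgn in (-1.0, 1.0):
        m = np.zeros(grid.shape, dtype=bool)
        # posterior body, close to the midline
        _ellipsoid_into(m, grid, (sgn * (6.0 + 3.0 * u), -8.0, 8.0), (6.0 * u, 24.0 * u, 9.5 * u))
        # anterior frontal horn; its lateral reach sets the Evans' Index
        _ellipsoid_into(
            m, grid, (sgn * (6.0 + 4.0 * u), 18.0 + 3.0 * u, 4.0), (5.0 * u, 14.0 * u, 8.0 * u)
        )
        sides.append(m & allowed)
    sides[1] &= ~sides[0]  # keep sides disjoint for extreme scales
    return sides


def _search_scale(count_at, target_vox: int, lo: float, hi: float, tol: float = 0.015):
    """Bisection on a monotone voxel-count function; returns best scale found."""
    n_hi = count_at(hi)
    if n_hi < target_vox:
        return hi, n_hi, False
    best = (hi, n_hi)
    a, b = lo, hi
    for _ in range(40):
        mid = 0.5 * (a + b)
        n = count_at(mid)
        if abs(n - target_vox) < abs(best[1] - target_vox):
            best = (mid, n)
        if n >= target_vox:
            b = mid
        else:
            a = mid
        if target_vox > 0 and abs(n - target_vox) / target_vox <= tol:
            return mid, n, True
    return best[0], best[1], True


# Piecewise-constant tissue means.  Entries may be callables of the record.
_AMYLOID_MEANS = {
    "meninges": lambda r: 1.9,
    # subarachnoid CSF held at a population-mean level; only the ventricular
    # CSF signal carries the participant-specific clearance value
    "head_interior": lambda r: 0.62,
    "white_matter": lambda r: 1.35,
    "grey_matter": lambda r: 0.9 * r.latent_abeta,
    "neocortex_composite": lambda r: r.latent_abeta,
    "meta_temporal": lambda r: 0.95 * r.latent_abeta,
    "cerebellum_gm": lambda r: 1.0,
    "lateral_ventricle_L": lambda r: r.latent_vr_amyloid,
    "lateral_ventricle_R": lambda r: r.latent_vr_amyloid,
    "choroid_plexus_L": lambda r: 1.8,
    "choroid_plexus_R": lambda r: 1.8,
}
_TAU_MEANS = {
    "meninges": lambda r: 1.5,
    "head_interior": lambda r: 0.58,
    "white_matter": lambda r: 0.55,
    "grey_matter": lambda r: 0.5 + 0.35 * r.latent_tau,
    "neocortex_composite": lambda r: 0.55 + 0.4 * r.latent_tau,
    "meta_temporal": lambda r: r.latent_tau,
    "cerebellum_gm": lambda r: 1.0,
    "lateral_ventricle_L": lambda r: r.latent_vr_tau,
    "lateral_ventricle_R": lambda r: r.latent_vr_tau,
    "choroid_plexus_L": lambda r: 1.9,
    "choroid_plexus_R": lambda r: 1.9,
}


def simulate_phantom(
    record: ParticipantRecord,
    grid: GridSpec | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
    pet: bool = True,
) -> PhantomBundle:
    """Render a participant record into a label volume and PET volumes.

    Parameters
    ----------
    record
        Ground-truth biomarkers; the rendered ventricular / choroid-plexus /
        intracranial volumes track the record's values to within voxel
        quantization (ventricles ~2%, choroid plexus ~10% for small blobs).
    grid
        Sampling grid; default 96^3 voxels at isotropic 2 mm.
    seed
        Seed for the PET noise; identical record + seed gives identical
        volumes.
    noise_sd
        Standard deviation of the additive Gaussian PET noise (SUVR units).
    pet
        When False, only the label volume is generated (faster for purely
        volumetric experiments).
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    voxvol = grid.voxel_volume_mm3
    lm = DEFAULT_LABEL_MAP

    # --- head ellipsoid sized to ICV ------------------------------------
    ratios = (0.80, 1.0, 0.82)
    k = (3.0 * record.icv / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = tuple(r * k for r in ratios)
    for ax in range(3):
        if 2 * semi[ax] > grid.extent_mm[ax] - 2 * grid.voxel_size_mm[ax]:
            raise InfeasibleGeometryError(
                f"head of ICV {record.icv:.0f} mm^3 does not fit on grid {grid.shape} "
                f"at {grid.voxel_size_mm} mm voxels"
            )
    head = np.zeros(grid.shape, dtype=bool)
    _ellipsoid_into(head, grid, (0.0, 0.0, 0.0), semi)

    interior = ndimage.binary_erosion(head, _CROSS)
    meninges = head & ~interior
    parench = ndimage.binary_erosion(interior, _CROSS)
    subarachnoid = interior & ~parench
    r1 = ndimage.binary_erosion(parench, _CROSS)
    r2 = ndimage.binary_erosion(r1, _CROSS)
    r3 = ndimage.binary_erosion(r2, _CROSS)
    cortex = parench & ~r2  # two-layer composite ribbon
    gm_layer = r2 & ~r3  # generic grey matter beneath the composite ribbon

    cere = np.zeros(grid.shape, dtype=bool)
    _ellipsoid_into(
        cere, grid, (0.0, -0.45 * semi[1], -0.62 * semi[2]), (0.42 * semi[0], 0.30 * semi[1], 0.26 * semi[2])
    )
    cere &= parench

    X = ((np.arange(grid.shape[0]) + 0.5 - grid.shape[0] / 2) * grid.voxel_size_mm[0])[:, None, None]
    Z = ((np.arange(grid.shape[2]) + 0.5 - grid.shape[2] / 2) * grid.voxel_size_mm[2])[None, None, :]
    temporal_zone = (np.abs(X) > 0.30 * semi[0]) & (Z < -0.10 * semi[2])
    meta = cortex & temporal_zone & ~cere
    neo = cortex & ~meta & ~cere

    # --- ventricular cavities (CSF volume + choroid plexus) -------------
    wm_zone = r3 & ~cere
    cavity_target = int(round((record.latent_vv + record.latent_cpv) / voxvol))
    if cavity_target < 2:
        raise InfeasibleGeometryError("requested ventricular volume below grid resolution")

    def cavity_count(u: float) -> int:
        left, right = _ventricle_masks(grid, u, wm_zone)
        return int(left.sum() + right.sum())

    u, got, ok = _search_scale(cavity_count, cavity_target, 0.25, 2.4)
    if not ok or abs(got - cavity_target) / cavity_target > 0.04:
        raise InfeasibleGeometryError(
            f"could not fit ventricular cavity of {cavity_target} voxels "
            f"(best {got} at scale {u:.2f}); requested volume too large for the head"
        )
    vent_L, vent_R = _ventricle_masks(grid, u, wm_zone)

    # --- choroid plexus blobs inside each cavity ------------------------
    cp_target_side = record.latent_cpv / 2.0 / voxvol
    cp_masks = []
    for sgn, cav in ((-1.0, vent_L), (1.0, vent_R)):
        center = (sgn * (6.0 + 3.0 * u), -9.0, 7.0)

        def cp_count(w: float) -> int:
            m = np.zeros(grid.shape, dtype=bool)
            _ellipsoid_into(m, grid, center, (3.2 * w, 9.0 * w, 3.2 * w))
            return int((m & cav).sum())

        if cp_target_side < 1.0:
            # degenerate: minimum blob of one voxel at the cavity centroid
            m = np.zeros(grid.shape, dtype=bool)
            idx = np.argwhere(cav)
            m[tuple(idx[len(idx) // 2])] = True
            cp_masks.append(m)
            continue
        w, _, _ = _search_scale(cp_count, int(round(cp_target_side)), 0.05, 3.0, tol=0.02)
        m = np.zeros(grid.shape, dtype=bool)
        _ellipsoid_into(m, grid, center, (3.2 * w, 9.0 * w, 3.2 * w))
        m &= cav
        if not m.any():
            idx = np.argwhere(cav)
            m[tuple(idx[len(idx) // 2])] = True
        cp_masks.append(m)
    cp_L, cp_R = cp_masks
    vent_L = vent_L & ~cp_L
    vent_R = vent_R & ~cp_R

    # --- assemble label volume ------------------------------------------
    data = np.zeros(grid.shape, dtype=np.int16)
    data[meninges] = lm["meninges"]
    data[subarachnoid] = lm["head_interior"]
    data[neo] = lm["neocortex_composite"]
    data[meta] = lm["meta_temporal"]
    data[gm_layer] = lm["grey_matter"]
    data[r3] = lm["white_matter"]
    data[cere] = lm["cerebellum_gm"]
    data[vent_L] = lm["lateral_ventricle_L"]
    data[vent_R] = lm["lateral_ventricle_R"]
    data[cp_L] = lm["choroid_plexus_L"]
    data[cp_R] = lm["choroid_plexus_R"]

    for name, code in lm.items():
        if name == "background":
            continue
        if not (data == code).any():
            raise InfeasibleGeometryError(f"anatomy label {name!r} has no voxels")

    labels = LabelVolume(data=data, voxel_size_mm=grid.voxel_size_mm, label_map=dict(lm))
    if not pet:
        return PhantomBundle(labels=labels, amyloid=None, tau=None, truth=record)

    # --- PET volumes ------------------------------------------------------
    head_any = data != 0

    def render(means: dict, tracer: str) -> ScalarVolume:
        img = np.zeros(grid.shape, dtype=np.float64)
        for name, fn in means.items():
            img[data == lm[name]] = fn(record)
        noise = rng.normal(0.0, noise_sd, grid.shape)
        img[head_any] += noise[head_any]
        return ScalarVolume(data=img, voxel_size_mm=grid.voxel_size_mm, tracer=tracer)

    amyloid = render(_AMYLOID_MEANS, "amyloid")
    tau = render(_TAU_MEANS, "tau")
    return PhantomBundle(labels=labels, amyloid=amyloid, tau=tau, truth=record)
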