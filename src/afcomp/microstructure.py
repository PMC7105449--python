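"""Specimen geometry: lamella stacks, fiber-bundle layouts, voxel models.

The annulus fibrosus is built from lamellae (0.2 mm thick layers) whose
collagen fiber bundles alternate between +30 deg and -30 deg to the
transverse (circumferential) plane.  Two specimen descriptions are
produced:

* a *ply stack* for the angle-ply laminate solver (each lamella is one ply),
* a *voxel model* for the finite element solver, where the separate-volume
  (SEP) description assigns fiber-bundle material to the voxels occupied by
  the explicit bundle cylinders and matrix elsewhere, while the homogenized
  (HOM) description carries the blended material with both fiber families in
  every voxel.

Mesh axes: x = loading direction (specimen length), y = width, z = radial
(thickness).  For a circumferential specimen x is the circumferential axis;
for an axial specimen x is the axial axis and the in-plane fiber angle is the
complement (90 - theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .materials import MaterialParams, preset

__all__ = [
    "LamellaSpec",
    "SpecimenSpec",
    "Ply",
    "PlyStack",
    "VoxelModel",
    "fiber_volume_fraction",
    "build_specimen",
    "build_ply_stack",
    "build_voxel_model",
    "write_vtk",
]


@dataclass(frozen=True)
class LamellaSpec:
    """One lamella: thickness, fiber layout, and constituent materials.

    ``spacing`` is the in-plane center-to-center distance between bundle
    axes by default; set ``spacing_convention="edge"`` to interpret it as the
    edge-to-edge gap instead.
    """

    thickness: float = 0.2
    fiber_angle: float = 30.0
    bundle_radius: float = 0.06
    spacing: float = 0.22
    spacing_convention: str = "center"
    matrix: MaterialParams = field(default_factory=lambda: preset("SEP-matrix"))
    bundle: MaterialParams = field(default_factory=lambda: preset("SEP-fiber-bundle"))

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if not abs(self.fiber_angle) < 90:
            raise ValueError("|fiber_angle| must be < 90 deg")
        if self.spacing_convention not in ("center", "edge"):
            raise ValueError("spacing_convention must be 'center' or 'edge'")
        if self.bundle_radius < 0 or self.spacing <= 0:
            raise ValueError("bundle_radius >= 0 and spacing > 0 required")
        if 2.0 * self.bundle_radius > min(self.center_spacing, self.thickness):
            raise ValueError("bundles overlap: 2r must not exceed spacing or thickness")

    @property
    def center_spacing(self) -> float:
        if self.spacing_convention == "edge":
            return self.spacing + 2.0 * self.bundle_radius
        return self.spacing


@dataclass(frozen=True)
class SpecimenSpec:
    """Multi-lamellar specimen: planform, layer count, orientation, family."""

    length: float = 10.0
    width: float = 2.5
    n_lamellae: int = 3
    orientation: str = "circumferential"
    model_family: str = "SEP"

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")
        if self.n_lamellae < 1:
            raise ValueError("n_lamellae must be >= 1")
        if self.orientation not in ("circumferential", "axial"):
            raise ValueError("orientation must be 'circumferential' or 'axial'")
        if self.model_family not in ("SEP", "HOM"):
            raise ValueError("model_family must be 'SEP' or 'HOM'")

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.width


def fiber_volume_fraction(lamella: LamellaSpec) -> float:
    """Areal density of bundle cross-sections in a lamella cross-cut.

    One row of full-length cylinders of radius r per lamella mid-plane with
    in-plane pitch s gives pi r^2 / (s * t).
    """
    s, t = lamella.center_spacing, lamella.thickness
    if s * t == 0:
        raise ValueError("spacing and thickness must be nonzero")
    return np.pi * lamella.bundle_radius**2 / (s * t)


def _lamella_angles(spec: SpecimenSpec, lamella: LamellaSpec) -> list[float]:
    """Signed fiber angle (to the transverse plane) per lamella, alternating."""
    return [lamella.fiber_angle * (1 if i % 2 == 0 else -1)
            for i in range(spec.n_lamellae)]


def inplane_fiber_dir(angle_to_transverse: float, orientation: str) -> np.ndarray:
    """Unit fiber direction in mesh coordinates (x = loading, y = width).

    The fiber lies in the lamella plane at ``angle_to_transverse`` degrees to
    the circumferential axis.
    """
    a = np.deg2rad(angle_to_transverse)
    circ, ax = np.cos(a), np.sin(a)
    if orientation == "circumferential":
        v = np.array([circ, ax, 0.0])
    else:
        v = np.array([ax, circ, 0.0])
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# ply stack (laminate path)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ply:
    thickness: float
    fiber_dirs: tuple          # unit vectors in mesh coordinates
    angle_to_transverse: float


@dataclass(frozen=True)
class PlyStack:
    plies: tuple
    spec: SpecimenSpec
    lamella: LamellaSpec

    @property
    def total_thickness(self) -> float:
        return sum(p.thickness for p in self.plies)

    def to_dict(self) -> dict:
        return {
            "model_family": self.spec.model_family,
            "orientation": self.spec.orientation,
            "plies": [
                {"thickness": p.thickness,
                 "angle_to_transverse": p.angle_to_transverse,
                 "fiber_dirs": [list(map(float, d)) for d in p.fiber_dirs]}
                for p in self.plies
            ],
        }


def build_ply_stack(spec: SpecimenSpec, lamella: LamellaSpec) -> PlyStack:
    plies = []
    for ang in _lamella_angles(spec, lamella):
        if spec.model_family == "HOM":
            dirs = (inplane_fiber_dir(abs(ang), spec.orientation),
                    inplane_fiber_dir(-abs(ang), spec.orientation))
        else:
            dirs = (inplane_fiber_dir(ang, spec.orientation),)
        plies.append(Ply(thickness=lamella.thickness, fiber_dirs=dirs,
                         angle_to_transverse=ang))
    return PlyStack(plies=tuple(plies), spec=spec, lamella=lamella)


# ---------------------------------------------------------------------------
# voxel model (FE path)
# ---------------------------------------------------------------------------


@dataclass
class VoxelModel:
    """Regular hexahedral voxel grid with per-voxel constituent data.

    ``bundle_weight`` is the exact volume fraction of each voxel occupied by
    fiber-bundle cylinders (zero everywhere for HOM); ``bundle_label`` marks
    voxels that are majority-bundle (the discretized separate-volume map).
    ``fiber_dirs`` has shape (n_lamellae, n_families, 3) in mesh coordinates
    and ``lamella_of_layer`` maps each z layer of voxels to its lamella.
    """

    h: tuple                   # (hx, hy, hz) voxel edge lengths, mm
    shape: tuple               # (nx, ny, nz) voxel counts
    dims: tuple                # realized (Lx, Ly, Lz) in mm
    bundle_weight: np.ndarray  # (nx, ny, nz)
    bundle_label: np.ndarray   # (nx, ny, nz) bool
    fiber_dirs: np.ndarray     # (n_lamellae, n_fam, 3)
    lamella_of_layer: np.ndarray
    spec: SpecimenSpec
    lamella: LamellaSpec

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def labeled_fiber_fraction(self) -> float:
        return float(np.mean(self.bundle_label))

    def weighted_fiber_fraction(self) -> float:
        return float(np.mean(self.bundle_weight))


def build_voxel_model(spec: SpecimenSpec, lamella: LamellaSpec,
                      resolution, subsamples: int | None = None) -> VoxelModel:
    """Voxelize a specimen on a regular grid (mm).

    ``resolution`` is a voxel edge length, or an ``(hx, hy, hz)`` triple for
    anisotropic voxels (e.g. finer through-thickness sampling).  The
    planform is snapped to whole voxels and the lamella thickness must be an
    integer number of voxels (``hz <= thickness``).  Bundle occupancy is
    sampled on a sub-grid per voxel, giving a partial-volume weight; a voxel
    is labeled bundle when majority-occupied.
    """
    if np.isscalar(resolution):
        hx = hy = hz = float(resolution)
    else:
        hx, hy, hz = (float(v) for v in resolution)
    t = lamella.thickness
    if hz > t + 1e-12:
        raise ValueError("voxel thickness must not exceed the lamella thickness")
    nz_per = int(round(t / hz))
    if abs(nz_per * hz - t) > 1e-9:
        raise ValueError("lamella thickness must be an integer number of voxels")
    nx = max(1, int(round(spec.length / hx)))
    ny = max(1, int(round(spec.width / hy)))
    nz = nz_per * spec.n_lamellae
    dims = (nx * hx, ny * hy, nz * hz)

    angles = _lamella_angles(spec, lamella)
    if spec.model_family == "HOM":
        fdirs = np.array([[inplane_fiber_dir(abs(a), spec.orientation),
                           inplane_fiber_dir(-abs(a), spec.orientation)]
                          for a in angles])
    else:
        fdirs = np.array([[inplane_fiber_dir(a, spec.orientation)] for a in angles])
    lam_of_layer = np.repeat(np.arange(spec.n_lamellae), nz_per)

    weight = np.zeros((nx, ny, nz))
    if spec.model_family == "SEP" and lamella.bundle_radius > 0:
        if subsamples is None:
            # sub-cell edge must resolve the bundle radius
            subsamples = max(3, int(np.ceil(3.0 * max(hx, hy, hz)
                                            / lamella.bundle_radius)))
        m = subsamples
        off = (np.arange(m) + 0.5) / m  # sub-cell centers in [0,1)
        xs = (np.arange(nx)[:, None] + off[None, :]).ravel() * hx
        ys = (np.arange(ny)[:, None] + off[None, :]).ravel() * hy
        pitch = lamella.center_spacing
        r2 = lamella.bundle_radius**2
        X = xs[:, None]
        Y = ys[None, :]
        for li, ang in enumerate(angles):
            d = inplane_fiber_dir(ang, spec.orientation)
            # in-plane perpendicular distance to the nearest bundle axis
            u = X * (-d[1]) + Y * d[0]
            du = u - np.round(u / pitch) * pitch          # (nx*m, ny*m)
            zc = (li + 0.5) * t
            for kz in range(li * nz_per, (li + 1) * nz_per):
                zs = (kz + off) * hz
                dz = zs - zc                               # (m,)
                inside = du[:, :, None] ** 2 + dz[None, None, :] ** 2 <= r2
                w = inside.reshape(nx, m, ny, m, -1).mean(axis=(1, 3, 4))
                weight[:, :, kz] = w
    label = weight >= 0.5
    return VoxelModel(h=(hx, hy, hz), shape=(nx, ny, nz), dims=dims, bundle_weight=weight,
                      bundle_label=label, fiber_dirs=fdirs,
                      lamella_of_layer=lam_of_layer, spec=spec, lamella=lamella)


def build_specimen(spec: SpecimenSpec, lamella: LamellaSpec,
                   resolution: float | None = None):
    """Build a model description: ply stack (``resolution=None``) or voxel map."""
    if resolution is None:
        return build_ply_stack(spec, lamella)
    return build_voxel_model(spec, lamella, resolution)


def write_vtk(model: VoxelModel, path: str) -> None:
    """Write the voxel constituent map as a legacy-ASCII VTK structured-points file."""
    nx, ny, nz = model.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("afcomp voxel model\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {model.h[0]} {model.h[1]} {model.h[2]}\n")
        f.write(f"CELL_DATA {model.n_voxels}\n")
        f.write("SCALARS bundle_weight float 1\nLOOKUP_TABLE default\n")
        w = model.bundle_weight.transpose(2, 1, 0).ravel()
        np.savetxt(f, w, fmt="%.4f")
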