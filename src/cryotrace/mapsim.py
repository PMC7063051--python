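"""Gaussian-sum density simulation, voxel label maps, and MRC2014 I/O.

Internal arrays are indexed ``grid[ix, iy, iz]`` with x fastest-varying in the
file sense: the world coordinate of voxel (i, j, k) is
``origin + (i, j, k) * voxel_size``. All modules share this convention; MRC
files with permuted MAPC/MAPR/MAPS are transposed to it on read.

The simulator mirrors the pdb2mrc-style convention: every atom contributes an
isotropic Gaussian of the same width regardless of B-factor, and the map is
the plain sum of those Gaussians on the grid. The width follows the EMAN2
criterion sigma = resolution / (pi * sqrt(2)) (Fourier amplitude falls to 1/e
at spatial frequency 1/resolution); the convention is recorded in the map
metadata and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomicModel, BACKBONE_ATOMS, SSE_HELIX, SSE_LOOP, SSE_SHEET

log = logging.getLogger(__name__)

#: default binarization radii for label maps (Angstrom)
R_CALPHA = 1.0
R_BACKBONE = 1.2

#: default padding around the model bounding box (Angstrom)
DEFAULT_PADDING = 5.0


def sigma_from_resolution(resolution: float) -> float:
    """Gaussian width for a nominal map resolution (EMAN2-style 1/e criterion)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return resolution / (np.pi * np.sqrt(2.0))


@dataclass
class DensityMap:
    """A 3D scalar field on a regular grid.

    grid[i, j, k] lives at world position origin + (i, j, k) * voxel_size.
    """

    grid: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a world position."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + np.arange(self.shape[d]) * self.voxel_size[d]
            for d in range(3)
        )

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.grid.copy(), self.voxel_size.copy(), self.origin.copy(),
            dict(self.metadata),
        )

    def like(self, grid: np.ndarray) -> "DensityMap":
        """A new map sharing this map's frame with different values."""
        return DensityMap(grid, self.voxel_size.copy(), self.origin.copy())


@dataclass
class LabelMaps:
    """Binary voxel labels congruent to a reference map.

    helix/sheet/loop are mutually exclusive; every calpha-positive voxel is
    backbone-positive (enforced at construction).
    """

    helix: np.ndarray
    sheet: np.ndarray
    loop: np.ndarray
    backbone: np.ndarray
    calpha: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in self.arrays()}
        if len(shapes) != 1:
            raise ValueError("label maps must be congruent")
        if np.any(self.helix & self.sheet) or np.any(self.helix & self.loop) or np.any(
            self.sheet & self.loop
        ):
            raise ValueError("SSE labels must be mutually exclusive per voxel")
        if np.any(self.calpha & ~self.backbone):
            raise ValueError("every calpha voxel must be backbone")

    def arrays(self) -> tuple[np.ndarray, ...]:
        return (self.helix, self.sheet, self.loop, self.backbone, self.calpha)

    def stack(self) -> np.ndarray:
        return np.stack(self.arrays())


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_density(
    model: AtomicModel,
    resolution: float,
    voxel_size: float = 1.0,
    padding: float = DEFAULT_PADDING,
    sigma: Optional[float] = None,
    cutoff_sigmas: float = 4.5,
) -> DensityMap:
    """Sum an isotropic Gaussian splat per atom on a regular grid.

    value(v) = sum_atoms exp(-|x_v - x_atom|^2 / (2 sigma^2)), one sigma for
    every atom. The grid covers the model bounding box plus ``padding``.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    sig = sigma_from_resolution(resolution) if sigma is None else float(sigma)

    coords = model.coords()
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = tuple(int(np.floor((hi[d] - lo[d]) / voxel_size)) + 1 for d in range(3))
    dm = DensityMap(
        np.zeros(shape, dtype=np.float64),
        voxel_size=np.full(3, float(voxel_size)),
        origin=lo,
        metadata={"resolution": resolution, "sigma": sig,
                  "sigma_convention": "resolution/(pi*sqrt(2))"},
    )
    _splat_gaussians(dm.grid, dm, coords, sig, cutoff_sigmas)
    return dm


def _splat_gaussians(out, dm: DensityMap, coords, sig, cutoff_sigmas, combine="sum"):
    """Accumulate per-atom Gaussians into ``out`` within a cutoff box."""
    reach = cutoff_sigmas * sig
    inv = 1.0 / (2.0 * sig * sig)
    xs, ys, zs = dm.axis_coords()
    for c in coords:
        i0 = np.searchsorted(xs, c[0] - reach)
        i1 = np.searchsorted(xs, c[0] + reach, side="right")
        j0 = np.searchsorted(ys, c[1] - reach)
        j1 = np.searchsorted(ys, c[1] + reach, side="right")
        k0 = np.searchsorted(zs, c[2] - reach)
        k1 = np.searchsorted(zs, c[2] + reach, side="right")
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx2 = (xs[i0:i1] - c[0]) ** 2
        dy2 = (ys[j0:j1] - c[1]) ** 2
        dz2 = (zs[k0:k1] - c[2]) ** 2
        g = np.exp(-(dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) * inv)
        if combine == "sum":
            out[i0:i1, j0:j1, k0:k1] += g
        else:
            np.maximum(out[i0:i1, j0:j1, k0:k1], g, out=out[i0:i1, j0:j1, k0:k1])


def _mask_within(dm: DensityMap, coords: np.ndarray, radius: float) -> np.ndarray:
    """Boolean grid: voxel centers within ``radius`` of any coordinate."""
    mask = np.zeros(dm.shape, dtype=bool)
    xs, ys, zs = dm.axis_coords()
    r2 = radius * radius
    for c in coords:
        i0 = np.searchsorted(xs, c[0] - radius)
        i1 = np.searchsorted(xs, c[0] + radius, side="right")
        j0 = np.searchsorted(ys, c[1] - radius)
        j1 = np.searchsorted(ys, c[1] + radius, side="right")
        k0 = np.searchsorted(zs, c[2] - radius)
        k1 = np.searchsorted(zs, c[2] + radius, side="right")
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        d2 = (
            (xs[i0:i1, None, None] - c[0]) ** 2
            + (ys[None, j0:j1, None] - c[1]) ** 2
            + (zs[None, None, k0:k1] - c[2]) ** 2
        )
        mask[i0:i1, j0:j1, k0:k1] |= d2 <= r2
    return mask


def generate_label_maps(
    model: AtomicModel,
    reference: DensityMap,
    r_ca: float = R_CALPHA,
    r_bb: float = R_BACKBONE,
) -> LabelMaps:
    """Distance-thresholded binary label maps on the reference grid.

    A voxel is calpha-positive iff its center lies within ``r_ca`` of a CA
    atom, backbone-positive iff within ``r_bb`` of any N/CA/C atom; SSE labels
    are assigned to backbone-positive voxels by the nearest residue's label.
    """
    bb_atoms = [a for a in model.atoms if a.atom_name in BACKBONE_ATOMS]
    if not bb_atoms:
        raise ValueError("model has no backbone atoms")
    bb_coords = np.stack([a.coord for a in bb_atoms])
    _check_in_bounds(model, reference)

    ca_coords = model.ca_coords()
    r_bb = max(r_bb, r_ca)  # guarantee calpha subset backbone
    calpha = _mask_within(reference, ca_coords, r_ca)
    backbone = _mask_within(reference, bb_coords, r_bb)
    backbone |= calpha

    helix = np.zeros_like(backbone)
    sheet = np.zeros_like(backbone)
    loop = np.zeros_like(backbone)
    idx = np.argwhere(backbone)
    if len(idx):
        centers = reference.voxel_to_world(idx)
        tree = cKDTree(bb_coords)
        _, nearest = tree.query(centers)
        labels = np.array(
            [model.residue_sse(bb_atoms[i].residue_index) for i in nearest]
        )
        for name, arr in ((SSE_HELIX, helix), (SSE_SHEET, sheet), (SSE_LOOP, loop)):
            sel = idx[labels == name]
            arr[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return LabelMaps(helix=helix, sheet=sheet, loop=loop, backbone=backbone, calpha=calpha)


def _check_in_bounds(model: AtomicModel, reference: DensityMap) -> None:
    lo = reference.origin
    hi = reference.voxel_to_world(np.array(reference.shape) - 1)
    bad = [
        f"{a.atom_name}/{a.residue_index}"
        for a in model.atoms
        if np.any(a.coord < lo - reference.voxel_size)
        or np.any(a.coord > hi + reference.voxel_size)
    ]
    if bad:
        raise ValueError(f"atoms outside reference grid: {', '.join(bad[:10])}")


# ---------------------------------------------------------------------------
# MRC2014 I/O (gemmi)
# ---------------------------------------------------------------------------

def read_mrc(path) -> DensityMap:
    """Read an MRC2014/CCP4 map, normalizing axis order to x, y, z.

    The origin is taken from the MRC ORIGIN header words when set, otherwise
    from NXSTART/NYSTART/NZSTART times the voxel size.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed MRC file {path}: {exc}") from exc
    grid = np.array(m.grid, copy=True).astype(np.float64)
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise ValueError("only orthogonal cells are supported")
    voxel = np.array(m.grid.spacing, dtype=float)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.allclose(origin, 0.0):
        nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    if np.any(~np.isfinite(grid)):
        grid = np.nan_to_num(grid)
    return DensityMap(grid, voxel_size=voxel, origin=origin,
                      metadata={"source": str(path)})


def write_mrc(dmap: DensityMap, path) -> Path:
    """Write a DensityMap as an MRC2014 mode-2 (float32) file."""
    path = Path(path)
    nx, ny, nz = dmap.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(g, copy=False)
    arr[:] = dmap.grid.astype(np.float32)
    g.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel_size[0], ny * dmap.voxel_size[1], nz * dmap.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))
    return path
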