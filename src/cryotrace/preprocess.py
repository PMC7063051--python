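"""Map normalization, 1-Angstrom resampling, 64^3 cube split/stitch, HDF5 datasets.

Normalization stages, in order: (1) zero every voxel below the threshold,
(2) divide by the median of the remaining positive voxels, (3) cap at the 98th
percentile of the positive voxels (percentile taken before capping). The
median and the percentile are computed over positive voxels only: after
thresholding the global median is typically zero and would make the division
meaningless. Resampling to a 1 A voxel is the extra stage experimental maps
need (simulated maps are generated at 1 A already); it uses trilinear
interpolation, which is exact on linear fields.

Cubing: the network consumes 64^3 cubes whose 50^3 cores tile the volume
disjointly with a 7-voxel margin on every face; stitching keeps only the
cores, so split -> stitch is an exact identity. Borders are zero padded,
matching the zeroed-background statistics of preprocessed maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

from .mapsim import DensityMap, generate_label_maps, simulate_density
from .structure import AtomicModel

CUBE_EDGE = 64
CORE_EDGE = 50
PERCENTILE_CAP = 98.0

LABEL_NAMES = ("helix", "sheet", "loop", "backbone", "calpha")


class EmptyMapError(ValueError):
    """Raised when thresholding removes every voxel."""


def preprocess_map(dmap: DensityMap, threshold: float) -> DensityMap:
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = dmap.grid.astype(np.float64).copy()
    g[g < threshold] = 0.0
    pos = g[g > 0]
    if pos.size == 0:
        raise EmptyMapError("no voxels above threshold")
    g /= np.median(pos)
    cap = np.percentile(g[g > 0], PERCENTILE_CAP)
    np.minimum(g, cap, out=g)
    out = dmap.like(g)
    out.metadata = dict(dmap.metadata)
    out.metadata.update(threshold=threshold, cap=float(cap))
    return out


def resample_to_unit_voxel(dmap: DensityMap) -> DensityMap:
    """Trilinear resample to exactly 1 A voxels on every axis, keeping the origin."""
    vs = dmap.voxel_size
    if np.allclose(vs, 1.0):
        return dmap.copy()
    if any(n < 2 for n in dmap.shape):
        raise ValueError("cannot resample a degenerate (single-plane) map")
    new_shape = tuple(int(np.floor((n - 1) * vs[d])) + 1 for d, n in enumerate(dmap.shape))
    axes = [np.arange(n) / vs[d] for d, n in enumerate(new_shape)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    vals = map_coordinates(
        dmap.grid.astype(np.float64), np.stack([ii, jj, kk]), order=1, mode="nearest"
    )
    out = DensityMap(vals, voxel_size=np.ones(3), origin=dmap.origin.copy())
    out.metadata = dict(dmap.metadata)
    out.metadata["resampled_from"] = tuple(float(v) for v in vs)
    return out


@dataclass
class CubeGrid:
    """Bookkeeping for the overlapping-cube decomposition of one volume."""

    cube_edge: int
    core_edge: int
    margin: int
    offsets: list[tuple[int, int, int]]  # cube corners, original-volume coords
    original_shape: tuple[int, int, int]

    def __post_init__(self):
        if self.cube_edge != self.core_edge + 2 * self.margin:
            raise ValueError("cube_edge must equal core_edge + 2*margin")


def split_into_cubes(
    dmap: DensityMap, cube_edge: int = CUBE_EDGE, core_edge: int = CORE_EDGE
) -> tuple[list[np.ndarray], CubeGrid]:
    """Split a map into overlapping cubes whose cores tile the volume.

    Cube corners advance with stride ``core_edge``; the volume is zero padded
    by the margin on the low side and by whatever the last core needs on the
    high side, so any shape is valid.
    """
    if (cube_edge - core_edge) % 2:
        raise ValueError("cube_edge - core_edge must be even")
    margin = (cube_edge - core_edge) // 2
    shape = dmap.shape
    n_cores = [int(np.ceil(n / core_edge)) for n in shape]
    padded_shape = [margin + c * core_edge + margin for c in n_cores]
    padded = np.zeros(padded_shape, dtype=dmap.grid.dtype)
    padded[
        margin : margin + shape[0],
        margin : margin + shape[1],
        margin : margin + shape[2],
    ] = dmap.grid

    cubes: list[np.ndarray] = []
    offsets: list[tuple[int, int, int]] = []
    for ci in range(n_cores[0]):
        for cj in range(n_cores[1]):
            for ck in range(n_cores[2]):
                o = (ci * core_edge, cj * core_edge, ck * core_edge)
                cubes.append(
                    padded[
                        o[0] : o[0] + cube_edge,
                        o[1] : o[1] + cube_edge,
                        o[2] : o[2] + cube_edge,
                    ].copy()
                )
                offsets.append((o[0] - margin, o[1] - margin, o[2] - margin))
    return cubes, CubeGrid(cube_edge, core_edge, margin, offsets, tuple(shape))


def stitch_cubes(cubes: Sequence[np.ndarray], grid: CubeGrid) -> np.ndarray:
    """Reassemble a volume from cube cores; inverse of :func:`split_into_cubes`."""
    if len(cubes) != len(grid.offsets):
        raise ValueError(
            f"expected {len(grid.offsets)} cubes, got {len(cubes)}"
        )
    m, core = grid.margin, grid.core_edge
    out = np.zeros(grid.original_shape, dtype=np.asarray(cubes[0]).dtype)
    for cube, off in zip(cubes, grid.offsets):
        cube = np.asarray(cube)
        if cube.shape != (grid.cube_edge,) * 3:
            raise ValueError("cube shape mismatch")
        # core position in original coords
        start = [off[d] + m for d in range(3)]
        stop = [min(start[d] + core, grid.original_shape[d]) for d in range(3)]
        if any(start[d] >= grid.original_shape[d] for d in range(3)):
            continue
        out[start[0] : stop[0], start[1] : stop[1], start[2] : stop[2]] = cube[
            m : m + stop[0] - start[0],
            m : m + stop[1] - start[1],
            m : m + stop[2] - start[2],
        ]
    return out


# ---------------------------------------------------------------------------
# training-set builder
# ---------------------------------------------------------------------------

def _rot90_z(arr: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Axis-aligned rotation about z (the last grid axis)."""
    return np.rot90(arr, k=quarter_turns, axes=(0, 1))


def build_training_set(
    models: Sequence[AtomicModel],
    resolution_range: tuple[float, float],
    out,
    augment: bool = True,
    seed: int = 0,
    threshold: float = 0.0,
    voxel_size: float = 1.0,
    padding: float = 5.0,
) -> Path:
    """Simulate, preprocess and label each model; write samples to HDF5.

    Each model yields one sample (or 4 with ``augment``: joint 0/90/180/270
    degree z-rotations of density and labels). Layout: one group per sample
    with datasets ``density, helix, sheet, loop, backbone, calpha`` and
    attributes ``resolution, voxel_size, source, rotation_deg``. Deterministic
    for a fixed seed.
    """
    if not models:
        raise ValueError("no models given")
    rng = np.random.default_rng(seed)
    out = Path(out)
    with h5py.File(out, "w") as fh:
        fh.attrs["voxel_size"] = voxel_size
        fh.attrs["augment"] = bool(augment)
        idx = 0
        for m_i, model in enumerate(models):
            resolution = float(rng.uniform(*resolution_range))
            dmap = simulate_density(model, resolution, voxel_size, padding)
            dmap = preprocess_map(dmap, threshold)
            labels = generate_label_maps(model, dmap)
            rotations = (0, 1, 2, 3) if augment else (0,)
            for q in rotations:
                grp = fh.create_group(f"sample_{idx:05d}")
                grp.create_dataset(
                    "density", data=_rot90_z(dmap.grid, q).astype(np.float32)
                )
                for name, arr in zip(LABEL_NAMES, labels.arrays()):
                    grp.create_dataset(name, data=_rot90_z(arr, q).astype(np.uint8))
                grp.attrs["resolution"] = resolution
                grp.attrs["voxel_size"] = voxel_size
                grp.attrs["source"] = m_i
                grp.attrs["rotation_deg"] = 90 * q
                idx += 1
    return out


def make_toy_cubes(
    n_samples: int,
    edge: int = 32,
    seed: int = 0,
    segments: Sequence[tuple[str, int]] = (("helix", 8), ("loop", 3), ("sheet", 5)),
    resolution_range: tuple[float, float] = (2.5, 4.5),
) -> list[dict[str, np.ndarray]]:
    """Small fixed-size training cubes from synthetic proteins, in memory.

    Each sample is a dict with the same keys as one HDF5 group of
    :func:`build_training_set` (density float32 + five boolean label cubes),
    cropped/zero-padded to ``edge``^3. Used for toy-scale training runs and
    tests; deterministic per seed.
    """
    from .structure import generate_synthetic_protein

    rng = np.random.default_rng(seed)
    out: list[dict[str, np.ndarray]] = []
    for _ in range(n_samples):
        model = generate_synthetic_protein(
            list(segments), seed=int(rng.integers(2**31)))
        dmap = simulate_density(model, float(rng.uniform(*resolution_range)),
                                padding=4.0)
        dmap = preprocess_map(dmap, 0.0)
        labels = generate_label_maps(model, dmap)

        def fit(a: np.ndarray) -> np.ndarray:
            b = np.zeros((edge,) * 3, dtype=a.dtype)
            s = [min(edge, a.shape[d]) for d in range(3)]
            b[: s[0], : s[1], : s[2]] = a[: s[0], : s[1], : s[2]]
            return b

        sample = {"density": fit(dmap.grid).astype(np.float32)}
        for name, arr in zip(LABEL_NAMES, labels.arrays()):
            sample[name] = fit(arr).astype(bool)
        out.append(sample)
    return out


def load_training_samples(path) -> list[dict[str, np.ndarray]]:
    """Read back all samples of a :func:`build_training_set` file, in order."""
    samples = []
    with h5py.File(path, "r") as fh:
        for key in sorted(k for k in fh.keys() if k.startswith("sample_")):
            grp = fh[key]
            s = {"density": grp["density"][()].astype(np.float64)}
            for name in LABEL_NAMES:
                s[name] = grp[name][()].astype(bool)
            s["attrs"] = dict(grp.attrs)
            samples.append(s)
    return samples
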