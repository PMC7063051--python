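"""Atomic models, Calpha traces, PDB I/O and a synthetic ground-truth protein generator.

Coordinates are Angstroms in the PDB frame throughout the package; no recentering is
performed here, so map-origin handling lives entirely in :mod:`cryotrace.mapsim`.
Only ATOM/TER/HELIX/SHEET records are honored; HETATM, altloc and insertion codes
are ignored with a logged warning.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure.io.pdb as pdbio

log = logging.getLogger(__name__)

SSE_HELIX = "helix"
SSE_SHEET = "sheet"
SSE_LOOP = "loop"
SSE_LABELS = (SSE_HELIX, SSE_SHEET, SSE_LOOP)

#: backbone atom names in the N-CA-C repeating chain
BACKBONE_ATOMS = ("N", "CA", "C")


class EmptyModelError(ValueError):
    """Raised when a PDB file contains no ATOM records."""


@dataclass
class Atom:
    atom_name: str
    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    coord: np.ndarray  # (3,) Angstrom

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"bad coordinate for atom {self.atom_name}: {self.coord}")


@dataclass
class AtomicModel:
    """A protein model: a list of atoms plus per-residue secondary-structure labels.

    ``sse_labels`` maps ``(chain_id, residue_index)`` is flattened to residue_index
    for single-chain models; keys are ``residue_index`` and labels are one of
    ``helix``/``sheet``/``loop``. Residues without an entry default to loop.
    """

    atoms: list[Atom] = field(default_factory=list)
    sse_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        per_chain: dict[str, int] = {}
        ca_seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if not np.all(np.isfinite(a.coord)):
                raise ValueError("non-finite coordinate")
            if a.atom_name == "CA":
                key = (a.chain_id, a.residue_index)
                if key in ca_seen:
                    raise ValueError(f"residue {key} has more than one CA atom")
                ca_seen.add(key)
            prev = per_chain.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise ValueError(
                    f"residue indices not non-decreasing in chain {a.chain_id}"
                )
            per_chain[a.chain_id] = a.residue_index
        for lab in self.sse_labels.values():
            if lab not in SSE_LABELS:
                raise ValueError(f"unknown SSE label {lab!r}")

    # -- convenience accessors -------------------------------------------------
    def coords(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        sel = self.atoms if names is None else [a for a in self.atoms if a.atom_name in names]
        if not sel:
            return np.zeros((0, 3))
        return np.stack([a.coord for a in sel])

    def ca_coords(self) -> np.ndarray:
        return self.coords(["CA"])

    def backbone_coords(self) -> np.ndarray:
        return self.coords(BACKBONE_ATOMS)

    def ca_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.atom_name == "CA"]

    def residue_sse(self, residue_index: int) -> str:
        return self.sse_labels.get(residue_index, SSE_LOOP)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class CaTrace:
    """An ordered chain of Calpha positions with optional per-point SSE labels."""

    points: np.ndarray  # (N, 3)
    sse: Optional[list[str]] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("empty trace")
        if len(self.points) > 1:
            d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(d <= 0):
                raise ValueError("repeated consecutive points in trace")
        if self.sse is not None and len(self.sse) != len(self.points):
            raise ValueError("sse labels do not match point count")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> AtomicModel:
    """Read ATOM records (via biotite) and HELIX/SHEET records from a PDB file.

    Residues covered by a HELIX record are labeled helix, by a SHEET record
    sheet, all others loop.
    """
    path = Path(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises on files without coordinates
        raise EmptyModelError(f"no ATOM records in {path}") from exc
    mask = ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise EmptyModelError(f"no ATOM records in {path}")
    n_het = int(np.count_nonzero(~mask))
    if n_het:
        log.warning("%s: ignored %d HETATM records", path.name, n_het)

    atoms = [
        Atom(
            atom_name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            chain_id=str(arr.chain_id[i]),
            residue_index=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            coord=np.array(arr.coord[i], dtype=float),
        )
        for i in range(arr.array_length())
    ]

    sse_labels: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "HELIX ":
                lo, hi = int(line[21:25]), int(line[33:37])
                for r in range(lo, hi + 1):
                    sse_labels[r] = SSE_HELIX
            elif rec == "SHEET ":
                lo, hi = int(line[22:26]), int(line[33:37])
                for r in range(lo, hi + 1):
                    sse_labels.setdefault(r, SSE_SHEET)
    return AtomicModel(atoms=atoms, sse_labels=sse_labels)


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def write_trace_pdb(traces: Sequence[CaTrace], path) -> Path:
    """Write a set of Calpha traces as a PDB file.

    Each trace becomes one chain of CA-only ATOM records terminated by TER;
    helix/sheet runs in the per-point SSE labels are emitted as HELIX/SHEET
    records. Coordinates are written at PDB precision (3 decimals).
    """
    if len(traces) == 0:
        raise ValueError("empty trace set")
    path = Path(path)
    header: list[str] = []
    body: list[str] = []
    serial = 1
    n_helix = n_sheet = 0
    for t_idx, trace in enumerate(traces):
        chain = _CHAIN_IDS[t_idx % len(_CHAIN_IDS)]
        if trace.sse is not None:
            for lo, hi, lab in _sse_runs(trace.sse):
                if lab == SSE_HELIX:
                    n_helix += 1
                    header.append(
                        f"HELIX  {n_helix:3d} {n_helix:3d} ALA {chain} {lo + 1:4d} "
                        f"ALA {chain} {hi + 1:4d}  1{'':30s}{hi - lo + 1:5d}          "
                    )
                elif lab == SSE_SHEET:
                    n_sheet += 1
                    header.append(
                        f"SHEET  {n_sheet:3d} S{n_sheet:2d} 1 ALA {chain}{lo + 1:4d}  "
                        f"ALA {chain}{hi + 1:4d}  0{'':40s}"
                    )
        for i, p in enumerate(trace.points):
            x, y, z = p
            body.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{'C':>2s}  "
            )
            serial += 1
        body.append(f"TER   {serial:5d}      ALA {chain}{len(trace.points):4d}{'':53s}")
        serial += 1
    body.append("END" + " " * 77)
    path.write_text("\n".join(header + body) + "\n")
    return path


def _sse_runs(labels: Sequence[str]):
    """Yield (start, end, label) runs of identical labels, 0-based inclusive."""
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            yield start, i - 1, labels[start]
            start = i


# ---------------------------------------------------------------------------
# Synthetic ground-truth generator
# ---------------------------------------------------------------------------

#: ideal alpha-helix Calpha geometry used by the generator
HELIX_RISE = 1.5          # Angstrom axial advance per residue
HELIX_TURN = np.deg2rad(100.0)  # rotation per residue (right-handed)
HELIX_CA_RADIUS = 2.3     # Calpha distance from the screw axis
STRAND_RISE = 3.5         # axial advance per residue along a strand
LOOP_STEP = 3.8           # Calpha-Calpha virtual bond length
MIN_SEPARATION = 3.0      # self-avoidance: min non-consecutive Calpha distance


def _perp_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, w)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, ref)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def _helix_points(n: int, base: np.ndarray, axis: np.ndarray, phase: float) -> np.ndarray:
    """Right-handed ideal alpha-helix: radius 2.3, rise 1.5, 100 deg/residue."""
    u, v = _perp_basis(axis)
    k = np.arange(n)
    ang = phase + k * HELIX_TURN
    pts = (
        base[None, :]
        + HELIX_CA_RADIUS * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
        + (k * HELIX_RISE)[:, None] * axis
    )
    return pts


def _strand_points(n: int, start: np.ndarray, axis: np.ndarray, rng) -> np.ndarray:
    """Near-straight strand with a small alternating pleat, ~3.5 A rise."""
    u, _ = _perp_basis(axis)
    k = np.arange(n)
    pleat = 0.5 * ((k % 2) * 2 - 1)
    return start[None, :] + (k * STRAND_RISE)[:, None] * axis + pleat[:, None] * u


def _min_nonconsecutive_dist(points: np.ndarray) -> float:
    if len(points) < 3:
        return np.inf
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    n = len(points)
    iu = np.triu_indices(n, k=2)
    return float(d[iu].min()) if len(iu[0]) else np.inf


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _bend(direction: np.ndarray, rng, sigma: float) -> np.ndarray:
    d = direction + rng.normal(scale=sigma, size=3)
    return d / np.linalg.norm(d)


def generate_synthetic_protein(
    spec: Sequence[tuple[str, int]],
    seed: int,
    backbone_atoms: bool = True,
    max_retries: int = 1000,
) -> AtomicModel:
    """Generate a self-avoiding Calpha chain from a list of (sse, length) segments.

    Helix segments follow ideal alpha-helix geometry (rise 1.5 A/residue,
    100 deg turn/residue, radius 2.3 A); ``strand`` segments are near-straight
    with ~3.5 A rise; loops are smooth random walks with 3.8 A steps, rejection
    sampled against self-collision (non-consecutive Calpha closer than 3.0 A).
    Deterministic for a fixed seed. When ``backbone_atoms`` is set, pseudo C
    and N atoms are interpolated at 1/3 and 2/3 of each Calpha-Calpha segment
    so that backbone label/confidence maps form a connected tube.
    """
    spec = [(("sheet" if s in ("strand", "sheet") else s), int(n)) for s, n in spec]
    for s, n in spec:
        if s not in SSE_LABELS:
            raise ValueError(f"unknown segment type {s!r}")
        if n < 1:
            raise ValueError("segment length must be >= 1")
    total = sum(n for _, n in spec)
    if total < 2:
        raise ValueError("need at least 2 residues in total")

    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        pts = _attempt_chain(spec, rng)
        if pts is not None and _min_nonconsecutive_dist(pts) >= MIN_SEPARATION:
            break
    else:
        raise RuntimeError("failed to generate a self-avoiding chain")

    labels: list[str] = []
    for s, n in spec:
        labels.extend([s] * n)

    atoms: list[Atom] = []
    for i, p in enumerate(pts):
        if backbone_atoms and i > 0:
            n_pos = pts[i - 1] + (p - pts[i - 1]) * (2.0 / 3.0)
            atoms.append(Atom("N", "N", "A", i + 1, "ALA", n_pos))
        atoms.append(Atom("CA", "C", "A", i + 1, "ALA", p))
        if backbone_atoms and i + 1 < len(pts):
            c_pos = p + (pts[i + 1] - p) / 3.0
            atoms.append(Atom("C", "C", "A", i + 1, "ALA", c_pos))
    sse_labels = {i + 1: lab for i, lab in enumerate(labels)}
    return AtomicModel(atoms=atoms, sse_labels=sse_labels)


def _attempt_chain(spec, rng) -> Optional[np.ndarray]:
    """One rejection-sampling attempt at the full chain; None on collision."""
    pts_list: list[np.ndarray] = []
    direction = _random_direction(rng)
    pos = np.zeros(3)
    for s, n in spec:
        if s == SSE_HELIX:
            axis = _bend(direction, rng, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            seg = _helix_points(n, np.zeros(3), axis, phase)
            start = pos + LOOP_STEP * axis if pts_list else pos
            seg = seg + (start - seg[0])
            direction = axis
        elif s == SSE_SHEET:
            axis = _bend(direction, rng, 0.3)
            start = pos + LOOP_STEP * axis if pts_list else pos
            seg = _strand_points(n, start, axis, rng)
            direction = axis
        else:  # loop: smooth random walk
            seg = np.empty((n, 3))
            p = pos
            for i in range(n):
                direction = _bend(direction, rng, 0.45)
                p = p + LOOP_STEP * direction if (pts_list or i > 0) else p
                seg[i] = p
        pts_list.append(seg)
        pos = seg[-1]
        if len(seg) > 1:
            direction = seg[-1] - seg[-2]
            direction = direction / np.linalg.norm(direction)
        all_pts = np.concatenate(pts_list)
        if _min_nonconsecutive_dist(all_pts) < MIN_SEPARATION:
            return None
    return np.concatenate(pts_list)
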