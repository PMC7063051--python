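"""Tabu-search path walking: tracing Calpha chains through confidence maps.

The walker repeatedly seeds at the highest-confidence untraced Calpha voxel
and grows a trace in both directions, one Calpha-sized step (2.8-4.2 A) at a
time. Candidate positions are non-maximum-suppressed local peaks of the
Calpha confidence map, refined to sub-voxel accuracy by a confidence-weighted
centroid; each accepted position permanently marks its surroundings visited
(the tabu region), which is what terminates a walk when it runs into
already-traced territory. A step is scored by a linear combination of the
candidate's Calpha confidence, the mean backbone confidence along the step
segment, the deviation of the step length from the ideal 3.8 A, and a
pseudo-bond-angle penalty against near-backtracking; steps below the
Calpha/backbone confidence floors are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .ccnn import ConfidenceMaps
from .structure import CaTrace, SSE_HELIX, SSE_LOOP, SSE_SHEET


@dataclass
class WalkParams:
    """Tunable knobs of the tracer; defaults follow the display thresholds
    (Calpha > 50%, backbone > 40% confidence) and ideal chain geometry."""

    ca_conf_min: float = 0.50
    bb_conf_min: float = 0.40
    step_min: float = 2.8
    step_max: float = 4.2
    ideal_step: float = 3.8
    w_conf: float = 1.0
    w_bb: float = 0.5
    w_dist: float = 1.0
    w_angle: float = 0.5
    w_helix: float = 0.0          # helix-radius bonus, disabled pending calibration
    helix_radius: float = 2.3
    exclusion_radius: float = 2.0
    nms_radius: float = 1.5
    angle_cos_cut: float = float(np.cos(np.deg2rad(150.0)))

    def __post_init__(self):
        if not (self.step_min < self.ideal_step < self.step_max):
            raise ValueError("need step_min < ideal_step < step_max")
        for w in (self.w_conf, self.w_bb, self.w_dist, self.w_angle):
            if w < 0:
                raise ValueError("weights must be >= 0")


@dataclass
class Peak:
    """A candidate Calpha location: an NMS peak with sub-voxel refinement."""

    voxel: tuple[int, int, int]
    position: np.ndarray  # refined world position
    confidence: float
    consumed: bool = False


@dataclass
class WalkState:
    """Visited (tabu) bookkeeping shared by all walks over one map."""

    maps: ConfidenceMaps
    params: WalkParams
    visited: np.ndarray = None
    peaks: list[Peak] = field(default_factory=list)
    _tree: Optional[cKDTree] = None

    def __post_init__(self):
        if self.visited is None:
            self.visited = np.zeros(self.maps.shape, dtype=bool)
        if not self.peaks:
            self.peaks = find_peaks(self.maps, self.params)
        if self.peaks and self._tree is None:
            self._tree = cKDTree(np.stack([p.position for p in self.peaks]))

    def is_visited_at(self, position: np.ndarray) -> bool:
        ijk = np.rint(self.maps.world_to_voxel(position)).astype(int)
        ijk = np.clip(ijk, 0, np.array(self.maps.shape) - 1)
        return bool(self.visited[tuple(ijk)])

    def mark_visited(self, position: np.ndarray, radius: Optional[float] = None) -> None:
        radius = self.params.exclusion_radius if radius is None else radius
        _mark_sphere(self.visited, self.maps, position, radius)

    def candidates_near(self, position: np.ndarray, r_lo: float, r_hi: float) -> list[Peak]:
        if self._tree is None:
            return []
        idx = sorted(self._tree.query_ball_point(position, r_hi))
        out = []
        for i in idx:
            p = self.peaks[i]
            if p.consumed:
                continue
            d = float(np.linalg.norm(p.position - position))
            if r_lo <= d <= r_hi:
                out.append(p)
        return out


def _mark_sphere(mask: np.ndarray, maps, position: np.ndarray, radius: float) -> None:
    vs = maps.voxel_size
    lo = np.floor((position - radius - maps.origin) / vs).astype(int)
    hi = np.ceil((position + radius - maps.origin) / vs).astype(int)
    lo = np.clip(lo, 0, np.array(mask.shape) - 1)
    hi = np.clip(hi, 0, np.array(mask.shape) - 1)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)],
                             indexing="ij")
    centers = maps.voxel_to_world(np.stack([ii, jj, kk], axis=-1))
    within = ((centers - position) ** 2).sum(axis=-1) <= radius * radius
    mask[ii[within], jj[within], kk[within]] = True


def find_peaks(maps: ConfidenceMaps, params: WalkParams,
               floor: float = 0.15) -> list[Peak]:
    """Non-maximum-suppressed local maxima of the Calpha confidence map.

    Peaks are local maxima within ``nms_radius`` (in world units), kept when
    above a permissive floor (final acceptance applies ``ca_conf_min``), and
    refined to the confidence-weighted centroid of the surrounding voxels.
    Ties are broken lexicographically by voxel index so the result is
    deterministic.
    """
    conf = maps.calpha
    r_vox = np.maximum(np.rint(params.nms_radius / maps.voxel_size).astype(int), 1)
    size = tuple(2 * r_vox + 1)
    local_max = ndimage.maximum_filter(conf, size=size, mode="constant") == conf
    cand = np.argwhere(local_max & (conf >= floor))
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    peaks: list[Peak] = []
    taken = np.zeros(conf.shape, dtype=bool)
    for ijk in cand[order]:
        t = tuple(ijk)
        if taken[t]:
            continue
        center = maps.voxel_to_world(ijk)
        pos = _weighted_centroid(maps, center, params.nms_radius)
        peaks.append(Peak(voxel=t, position=pos, confidence=float(conf[t])))
        _mark_sphere(taken, maps, center, params.nms_radius)
    peaks.sort(key=lambda p: (-p.confidence, p.voxel))
    return peaks


def _weighted_centroid(maps: ConfidenceMaps, center: np.ndarray,
                       radius: float) -> np.ndarray:
    """Confidence-weighted centroid of calpha voxels within ``radius``."""
    vs = maps.voxel_size
    lo = np.floor((center - radius - maps.origin) / vs).astype(int)
    hi = np.ceil((center + radius - maps.origin) / vs).astype(int)
    lo = np.clip(lo, 0, np.array(maps.shape) - 1)
    hi = np.clip(hi, 0, np.array(maps.shape) - 1)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)],
                             indexing="ij")
    centers = maps.voxel_to_world(np.stack([ii, jj, kk], axis=-1))
    d2 = ((centers - center) ** 2).sum(axis=-1)
    within = d2 <= radius * radius
    w = maps.calpha[ii[within], jj[within], kk[within]]
    if w.sum() <= 0:
        return np.asarray(center, dtype=float)
    return (centers[within] * w[:, None]).sum(axis=0) / w.sum()


def interpolate(volume: np.ndarray, maps, positions: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a congruent volume at world positions."""
    pos = np.atleast_2d(positions)
    vox = (pos - maps.origin) / maps.voxel_size
    return ndimage.map_coordinates(volume, vox.T, order=1, mode="nearest")


def segment_mean_backbone(maps: ConfidenceMaps, a: np.ndarray, b: np.ndarray,
                          n_samples: int = 8) -> float:
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    return float(interpolate(maps.backbone, maps, pts).mean())


def select_seed(calpha: np.ndarray, visited: np.ndarray,
                params: WalkParams) -> Optional[tuple[int, int, int]]:
    """Unvisited voxel of maximal Calpha confidence, or None below the floor."""
    masked = np.where(visited, -np.inf, calpha)
    flat = int(np.argmax(masked))
    ijk = np.unravel_index(flat, calpha.shape)
    if masked[ijk] < params.ca_conf_min:
        return None
    return tuple(int(v) for v in ijk)


REJECT = None


def score_step(
    current: np.ndarray,
    prev: Optional[np.ndarray],
    candidate: np.ndarray,
    maps: ConfidenceMaps,
    params: WalkParams,
    candidate_conf: Optional[float] = None,
) -> Optional[float]:
    """Score a move current -> candidate; None means the move is rejected.

    score = w_conf * calpha(candidate)
          + w_bb * mean backbone confidence along the segment
          - w_dist * |d - ideal| / ideal
          - w_angle * max(0, cos(theta) - cos 150deg)
    where theta is the pseudo-bond angle at ``current`` (prev-current-candidate).
    """
    current = np.asarray(current, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    d = float(np.linalg.norm(candidate - current))
    if not (params.step_min <= d <= params.step_max):
        return REJECT
    ca_conf = (float(interpolate(maps.calpha, maps, candidate)[0])
               if candidate_conf is None else float(candidate_conf))
    if ca_conf < params.ca_conf_min:
        return REJECT
    bb_mean = segment_mean_backbone(maps, current, candidate)
    if bb_mean < params.bb_conf_min:
        return REJECT
    score = (params.w_conf * ca_conf
             + params.w_bb * bb_mean
             - params.w_dist * abs(d - params.ideal_step) / params.ideal_step)
    if prev is not None:
        a = np.asarray(prev, dtype=float) - current
        b = candidate - current
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na > 0 and nb > 0:
            cos_t = float(np.dot(a, b) / (na * nb))
            score -= params.w_angle * max(0.0, cos_t - params.angle_cos_cut)
    if params.w_helix > 0:
        h_conf = float(interpolate(maps.helix, maps, candidate)[0])
        score += params.w_helix * h_conf
    return score


def _walk_direction(start: np.ndarray, prev: Optional[np.ndarray],
                    maps: ConfidenceMaps, state: WalkState) -> list[Peak]:
    params = state.params
    out: list[Peak] = []
    current, previous = start, prev
    while True:
        best: tuple[float, Peak] | None = None
        for peak in state.candidates_near(current, params.step_min, params.step_max):
            if state.is_visited_at(peak.position):
                continue
            s = score_step(current, previous, peak.position, maps, params,
                           candidate_conf=peak.confidence)
            if s is None:
                continue
            if best is None or s > best[0] or (s == best[0] and peak.voxel < best[1].voxel):
                best = (s, peak)
        if best is None:
            return out
        peak = best[1]
        peak.consumed = True
        state.mark_visited(peak.position)
        out.append(peak)
        previous, current = current, peak.position


def walk_trace(seed_voxel: tuple[int, int, int], maps: ConfidenceMaps,
               state: WalkState) -> CaTrace:
    """Grow a trace bidirectionally from a seed voxel.

    The seed is refined to its confidence-weighted centroid; the walk extends
    in one direction until no acceptable candidate remains or it enters
    visited territory, then continues in the opposite direction from the
    seed, and the two halves are concatenated.
    """
    if state.visited[tuple(seed_voxel)]:
        raise ValueError(f"seed voxel {seed_voxel} already visited")
    seed_world = maps.voxel_to_world(np.asarray(seed_voxel))
    # snap to the pre-computed peak containing the seed, if any
    seed_pos = _weighted_centroid(maps, seed_world, state.params.nms_radius)
    for p in state.peaks:
        if not p.consumed and np.linalg.norm(p.position - seed_pos) <= state.params.nms_radius:
            p.consumed = True
            seed_pos = p.position
            break
    state.mark_visited(seed_pos)
    fwd = _walk_direction(seed_pos, None, maps, state)
    prev_for_back = fwd[0].position if fwd else None
    back = _walk_direction(seed_pos, prev_for_back, maps, state)
    pts = [p.position for p in reversed(back)] + [seed_pos] + [p.position for p in fwd]
    points = np.stack(pts)
    sse = _sse_labels_at(maps, points)
    return CaTrace(points=points, sse=sse)


def _sse_labels_at(maps: ConfidenceMaps, points: np.ndarray) -> list[str]:
    vals = np.stack([interpolate(maps.helix, maps, points),
                     interpolate(maps.sheet, maps, points),
                     interpolate(maps.loop, maps, points)])
    names = (SSE_HELIX, SSE_SHEET, SSE_LOOP)
    return [names[i] for i in vals.argmax(axis=0)]


def trace_all(maps: ConfidenceMaps, params: Optional[WalkParams] = None) -> list[CaTrace]:
    """Walk traces until no unvisited high-confidence Calpha voxel remains."""
    params = params or WalkParams()
    state = WalkState(maps=maps, params=params)
    traces: list[CaTrace] = []
    while True:
        seed = select_seed(maps.calpha, state.visited, params)
        if seed is None:
            break
        trace = walk_trace(seed, maps, state)
        traces.append(trace)
    return traces
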