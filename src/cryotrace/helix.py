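"""Alpha-helix detection and idealized refitting about an estimated screw axis.

An alpha-helix is modeled as a point rotating about its screw axis (the
center line the helix winds around) with fixed geometry: Calpha radius
2.11 A, angular pitch omega = 1.149 rad per Angstrom of axis, and an axial
rise of 1.5 A per residue. The screw axis of a predicted helix is estimated
by connecting centroids of sliding windows of consecutive Calpha positions
(window 4, about one turn), smoothing, and end-extrapolation; refitting then
places ideal Calpha atoms every 1.5 A of axis arclength and optimizes the
axial shift s and phase rotation r to minimize the mean distance to the
original prediction (coarse grid search, then a derivative-free polish).

The local frame at axis position t follows the construction: new z = unit
tangent; new y = normalize(global x cross z); new x = normalize(z cross y);
when the tangent is nearly parallel to global x, global y takes its place.
This frame with the (sin, cos) offset yields a right-handed helix, the
physical chirality of protein alpha-helices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .ccnn import ConfidenceMaps
from .graph_refine import TraceGraph
from .pathwalk import interpolate
from .structure import CaTrace, SSE_HELIX

HELIX_RADIUS = 2.11   # A, Calpha distance from the screw axis
HELIX_OMEGA = 1.149   # rad of rotation per A travelled along the axis
HELIX_RISE = 1.5      # A of axis advance per residue
DEFAULT_WINDOW = 4    # residues per centroid window (~one turn)

_GLOBAL_X = np.array([1.0, 0.0, 0.0])
_GLOBAL_Y = np.array([0.0, 1.0, 0.0])


class ScrewAxis:
    """Arclength-parameterized polyline: t in [0, length] -> point, tangent."""

    def __init__(self, polyline: np.ndarray):
        polyline = np.asarray(polyline, dtype=float).reshape(-1, 3)
        if len(polyline) < 2:
            raise ValueError("axis polyline needs at least 2 points")
        seg = np.diff(polyline, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        keep = seglen > 1e-9
        if not np.all(keep):
            polyline = np.concatenate([polyline[:1], polyline[1:][keep]])
            seg = np.diff(polyline, axis=0)
            seglen = np.linalg.norm(seg, axis=1)
        if len(polyline) < 2:
            raise ValueError("degenerate axis polyline")
        self.polyline = polyline
        self._cum = np.concatenate([[0.0], np.cumsum(seglen)])
        self._tangents = seg / seglen[:, None]

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def _segment(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > self.length + 1e-9):
            raise ValueError(f"t={t} outside axis range [0, {self.length}]")
        i = np.searchsorted(self._cum, t, side="right") - 1
        return np.clip(i, 0, len(self._tangents) - 1)

    def point_at(self, t):
        i = self._segment(t)
        res = self.polyline[i] + (np.asarray(t, dtype=float) - self._cum[i])[..., None] \
            * self._tangents[i]
        return res if np.ndim(t) else res.reshape(3)

    def tangent_at(self, t):
        res = self._tangents[self._segment(t)]
        return res if np.ndim(t) else res.reshape(3)


@dataclass
class HelixParams:
    """Shift/rotation phase of an ideal helix about a screw axis."""

    axis: ScrewAxis
    s: float = 0.0                 # axial shift, [0, rise)
    r: float = 0.0                 # phase rotation, [0, 2*pi)
    radius: float = HELIX_RADIUS
    omega: float = HELIX_OMEGA
    rise: float = HELIX_RISE


def local_frame(tangent: np.ndarray) -> np.ndarray:
    """Rows are the local x, y, z axes at a point with the given tangent."""
    z = tangent / np.linalg.norm(tangent)
    ref = _GLOBAL_X
    if np.linalg.norm(np.cross(ref, z)) < 1e-6:
        ref = _GLOBAL_Y
    y = np.cross(ref, z)
    y /= np.linalg.norm(y)
    x = np.cross(z, y)
    x /= np.linalg.norm(x)
    return np.stack([x, y, z])


def ideal_helix_point(t: float, params: HelixParams) -> np.ndarray:
    """Point of the ideal helix at axis arclength t.

    theta = omega * (t - s) + r; the offset radius*(sin theta, cos theta, 0)
    is expressed in the local frame, so the result is at distance exactly
    ``radius`` from axis(t).
    """
    axis_pt = params.axis.point_at(t)
    frame = local_frame(params.axis.tangent_at(t))
    theta = params.omega * (t - params.s) + params.r
    offset = params.radius * (np.sin(theta) * frame[0] + np.cos(theta) * frame[1])
    return axis_pt + offset


def estimate_screw_axis(points: np.ndarray, window: int = DEFAULT_WINDOW) -> ScrewAxis:
    """Axis from sliding-window centroids of consecutive Calpha positions.

    Centroids (window length ``window``, hop 1) are smoothed with a 3-point
    moving average — raw centroids of a 100 deg/residue helix carry a small
    systematic radial offset that the smoothing largely cancels — and the
    polyline is extrapolated by half a window span at both ends so the axis
    covers the helix termini.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < window + 1:
        raise ValueError(f"need at least {window + 1} points, got {len(points)}")
    n_c = len(points) - window + 1
    w = _phase_cancelling_weights(window)
    centroids = np.stack([w @ points[i : i + window] for i in range(n_c)])
    if len(centroids) >= 3:
        sm = centroids.copy()
        sm[1:-1] = (centroids[:-2] + centroids[1:-1] + centroids[2:]) / 3.0
        centroids = sm
    # end extrapolation by half a window span along the end tangents
    ext = 0.5 * window * HELIX_RISE
    if len(centroids) >= 2:
        t0 = centroids[0] - centroids[1]
        t1 = centroids[-1] - centroids[-2]
        n0, n1 = np.linalg.norm(t0), np.linalg.norm(t1)
        pre = centroids[0] + (t0 / n0) * ext if n0 > 1e-9 else None
        post = centroids[-1] + (t1 / n1) * ext if n1 > 1e-9 else None
        parts = ([pre] if pre is not None else []) + [centroids] + (
            [post] if post is not None else [])
        centroids = np.vstack([np.atleast_2d(p) for p in parts])
    return ScrewAxis(centroids)


def _phase_cancelling_weights(window: int,
                              alpha: float = HELIX_OMEGA * HELIX_RISE) -> np.ndarray:
    """Window-centroid weights that put an ideal helix's centroid on its axis.

    The plain mean of ``window`` consecutive Calpha of an alpha-helix
    (~100 deg of twist per residue; 98.75 deg for the omega/rise constants
    used here) carries a systematic radial offset unless the window closes a
    full turn (3.6 residues); these weights are the closest weights to
    uniform (least squares) whose helical phase sum
    ``sum_j w_j exp(i j alpha)`` vanishes,
    so the weighted centroid of an ideal straight helix lies exactly on the
    screw axis. Solved via the KKT system of the equality-constrained LSQ.
    """
    j = np.arange(window)
    # constraints: sum w = 1, sum w cos(j a) = 0, sum w sin(j a) = 0
    A = np.stack([np.ones(window), np.cos(j * alpha), np.sin(j * alpha)])
    b = np.array([1.0, 0.0, 0.0])
    uniform = np.full(window, 1.0 / window)
    try:
        lam = np.linalg.solve(A @ A.T, b - A @ uniform)
    except np.linalg.LinAlgError:
        return uniform
    return uniform + A.T @ lam


def detect_helix_segments(
    graph: TraceGraph,
    maps: ConfidenceMaps,
    min_len: int = 6,
    sample_radius: float = 2.0,
) -> list[list[int]]:
    """Maximal runs of >= min_len consecutive helix-labeled nodes.

    A node counts as helix when the mean helix confidence within
    ``sample_radius`` of it exceeds both the sheet and loop means. Runs are
    collected along maximal simple (degree <= 2) chains of the graph.
    """
    is_helix: dict[int, bool] = {}
    for n in graph.nodes:
        c = graph.nodes[n]["coord"]
        means = [_mean_conf_near(m, maps, c, sample_radius)
                 for m in (maps.helix, maps.sheet, maps.loop)]
        is_helix[n] = means[0] > means[1] and means[0] > means[2]

    segments: list[list[int]] = []
    for chain in _simple_chains(graph):
        run: list[int] = []
        for n in chain:
            if is_helix[n]:
                run.append(n)
            else:
                if len(run) >= min_len:
                    segments.append(run)
                run = []
        if len(run) >= min_len:
            segments.append(run)
    return segments


def _mean_conf_near(volume: np.ndarray, maps: ConfidenceMaps,
                    center: np.ndarray, radius: float) -> float:
    vs = maps.voxel_size
    lo = np.clip(np.floor((center - radius - maps.origin) / vs).astype(int),
                 0, np.array(maps.shape) - 1)
    hi = np.clip(np.ceil((center + radius - maps.origin) / vs).astype(int),
                 0, np.array(maps.shape) - 1)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)],
                             indexing="ij")
    centers = maps.voxel_to_world(np.stack([ii, jj, kk], axis=-1))
    within = ((centers - center) ** 2).sum(axis=-1) <= radius * radius
    if not np.any(within):
        return float(interpolate(volume, maps, center)[0])
    return float(volume[ii[within], jj[within], kk[within]].mean())


def _simple_chains(graph: TraceGraph) -> list[list[int]]:
    chains = []
    seen_edges: set[frozenset] = set()
    starts = [n for n in sorted(graph.nodes) if graph.degree[n] != 2]
    for start in starts:
        for nb in sorted(graph.neighbors(start)):
            if frozenset((start, nb)) in seen_edges:
                continue
            chain = [start, nb]
            seen_edges.add(frozenset((start, nb)))
            prev, cur = start, nb
            while graph.degree[cur] == 2:
                nxt = next(n for n in graph.neighbors(cur) if n != prev)
                seen_edges.add(frozenset((cur, nxt)))
                chain.append(nxt)
                prev, cur = cur, nxt
            chains.append(chain)
    return chains


def refit_helix(
    segment_points: np.ndarray,
    maps: Optional[ConfidenceMaps] = None,
    window: int = DEFAULT_WINDOW,
    grid_s_step: float = 0.05,
    grid_r_step: float = 0.05,
) -> CaTrace:
    """Replace a helix segment by ideal Calpha atoms on a fitted screw axis.

    Atoms are placed at axis arclengths t = s, s + 1.5, s + 3.0, ... and
    (s, r) minimize the mean distance from the placed atoms to the original
    points: a coarse grid (s in [0, 1.5) step 0.05 A; r in [0, 2 pi) step
    0.05 rad) followed by Nelder-Mead. Deterministic. A segment whose axis is
    shorter than one rise is returned unchanged.
    """
    pts = np.asarray(segment_points, dtype=float).reshape(-1, 3)
    axis = estimate_screw_axis(pts, window=window)
    if axis.length < HELIX_RISE:
        import logging
        logging.getLogger(__name__).warning(
            "degenerate screw axis (length %.2f A); segment unchanged", axis.length)
        return CaTrace(points=pts, sse=[SSE_HELIX] * len(pts))

    def place(s: float, r: float) -> np.ndarray:
        ts = np.arange(s % HELIX_RISE, axis.length + 1e-9, HELIX_RISE)
        a, x, y = _axis_frames(axis, ts)
        theta = HELIX_OMEGA * (ts - s) + r
        return a + HELIX_RADIUS * (np.sin(theta)[:, None] * x
                                   + np.cos(theta)[:, None] * y)

    def objective(sr) -> float:
        placed = place(float(sr[0]), float(sr[1]))
        if len(placed) == 0:
            return np.inf
        d = np.linalg.norm(placed[:, None, :] - pts[None, :, :], axis=-1)
        return float(d.min(axis=1).mean())

    rs = np.arange(0.0, 2 * np.pi, grid_r_step)
    best = None
    for s in np.arange(0.0, HELIX_RISE, grid_s_step):
        ts = np.arange(s, axis.length + 1e-9, HELIX_RISE)
        a, x, y = _axis_frames(axis, ts)
        theta = HELIX_OMEGA * (ts[:, None] - s) + rs[None, :]  # (T, R)
        placed = (a[:, None, :] + HELIX_RADIUS
                  * (np.sin(theta)[..., None] * x[:, None, :]
                     + np.cos(theta)[..., None] * y[:, None, :]))  # (T, R, 3)
        d = np.linalg.norm(placed[:, :, None, :] - pts[None, None, :, :], axis=-1)
        vals = d.min(axis=2).mean(axis=0)  # (R,)
        k = int(np.argmin(vals))
        if best is None or vals[k] < best[0]:
            best = (float(vals[k]), float(s), float(rs[k]))
    res = minimize(objective, x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
    s_opt, r_opt = (res.x if res.fun <= best[0] else (best[1], best[2]))
    placed = place(float(s_opt), float(r_opt))
    return CaTrace(points=placed, sse=[SSE_HELIX] * len(placed))


def _axis_frames(axis: ScrewAxis, ts: np.ndarray):
    """Axis points and local x/y frame vectors for an array of arclengths."""
    a = axis.point_at(ts)
    z = axis.tangent_at(ts)
    ref = np.broadcast_to(_GLOBAL_X, z.shape).copy()
    degenerate = np.linalg.norm(np.cross(ref, z), axis=-1) < 1e-6
    ref[degenerate] = _GLOBAL_Y
    y = np.cross(ref, z)
    y /= np.linalg.norm(y, axis=-1, keepdims=True)
    x = np.cross(z, y)
    x /= np.linalg.norm(x, axis=-1, keepdims=True)
    return a, x, y


def refine_helices(
    graph: TraceGraph,
    maps: ConfidenceMaps,
    min_len: int = 6,
    window: int = DEFAULT_WINDOW,
) -> TraceGraph:
    """Detect helix segments in the graph and replace them by refit traces.

    Refit nodes are re-stitched to the flanking nodes of the original segment
    by nearest-endpoint edges (when within a plausible bond length).
    """
    g = graph.copy()
    segments = detect_helix_segments(g, maps, min_len=min_len)
    next_id = (max(g.nodes) + 1) if len(g.nodes) else 0
    for seg in segments:
        if not all(n in g for n in seg):
            continue
        pts = np.stack([g.nodes[n]["coord"] for n in seg])
        refit = refit_helix(pts, maps, window=window)
        flanks = []
        for end in (seg[0], seg[-1]):
            flanks.extend(nb for nb in g.neighbors(end) if nb not in seg)
        # orient refit trace along the segment direction
        if np.linalg.norm(refit.points[0] - pts[0]) > np.linalg.norm(
                refit.points[-1] - pts[0]):
            refit = CaTrace(points=refit.points[::-1].copy(), sse=refit.sse)
        g.remove_nodes_from(seg)
        new_ids = []
        for p in refit.points:
            g.add_node(next_id, coord=p, sse=SSE_HELIX)
            if new_ids:
                g.add_edge(next_id - 1, next_id)
            new_ids.append(next_id)
            next_id += 1
        for fl in flanks:
            if fl not in g:
                continue
            dists = [float(np.linalg.norm(g.nodes[fl]["coord"] - g.nodes[e]["coord"]))
                     for e in (new_ids[0], new_ids[-1])]
            end = new_ids[0] if dists[0] <= dists[1] else new_ids[-1]
            if min(dists) <= 4.5:
                g.add_edge(fl, end)
    return g


def helix_rise_estimate(points: np.ndarray, window: int = DEFAULT_WINDOW) -> float:
    """Per-residue rise of a helix: axis arclength per residue hop."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n_c = len(pts) - window + 1
    w = _phase_cancelling_weights(window)
    centroids = np.stack([w @ pts[i : i + window] for i in range(n_c)])
    if len(centroids) < 2:
        raise ValueError("too few points to estimate rise")
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    return float(seg.sum() / (n_c - 1))
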