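"""The cascaded three-network semantic-segmentation model (C-CNN).

Three four-layer dilated CNNs run in sequence on a density cube: the SSE
network (3-class: helix/sheet/loop) sees the density; the backbone network
(2-class) sees density + the three SSE confidence maps; the Calpha network
(2-class) sees density + SSE + backbone confidences. Layers 2-3 of each
network are dilated (rate 2) and followed by leaky ReLU (alpha 0.1); filter
counts are 32/64/64/n_classes; kernels are 5^3 for the SSE and backbone
networks and 4^3 for the Calpha network; every layer is stride 1 with "same"
padding, so each output volume is congruent to the input cube.

Training minimizes the sum of the three per-voxel cross-entropies with
inverse-frequency class weights (Calpha-positive voxels are very rare).
Confidences of earlier stages are forwarded with gradients flowing end-to-end
so all three networks train simultaneously; a stop-gradient variant is
available. Voxels outside the backbone have no SSE label of their own and are
assigned to the loop class, the catch-all for "not helix, not sheet".

:func:`oracle_confidence` builds idealized confidence maps straight from a
ground-truth model so the tracing and refinement stages can be exercised and
tested without any training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .mapsim import DensityMap
from .preprocess import LABEL_NAMES, load_training_samples, split_into_cubes, stitch_cubes
from .structure import AtomicModel, BACKBONE_ATOMS

log = logging.getLogger(__name__)

#: per-network layer description: (kernel, dilation, filters)
NETWORK_SPEC = {
    "sse": {"in_channels": 1, "n_classes": 3, "kernel": 5},
    "backbone": {"in_channels": 4, "n_classes": 2, "kernel": 5},
    "calpha": {"in_channels": 6, "n_classes": 2, "kernel": 4},
}
FILTERS = (32, 64, 64)
LEAKY_ALPHA = 0.1
DEFAULT_EPOCHS = 15
DEFAULT_LR = 1e-3

ORACLE_SIGMA = 0.8  # narrow enough that Calpha >= 2.8 A apart stay separate maxima


@dataclass
class ConfidenceMaps:
    """Five per-voxel probability volumes aligned to the input grid.

    helix + sheet + loop = 1 per voxel; backbone and calpha hold the
    positive-class probability of their 2-class softmax.
    """

    helix: np.ndarray
    sheet: np.ndarray
    loop: np.ndarray
    backbone: np.ndarray
    calpha: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        shapes = {a.shape for a in self.arrays()}
        if len(shapes) != 1:
            raise ValueError("confidence maps must be congruent")
        s = self.helix + self.sheet + self.loop
        if not np.allclose(s, 1.0, atol=1e-4):
            raise ValueError("SSE confidences must sum to 1 per voxel")

    def arrays(self):
        return (self.helix, self.sheet, self.loop, self.backbone, self.calpha)

    @property
    def shape(self):
        return self.helix.shape

    def world_to_voxel(self, xyz):
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def voxel_to_world(self, ijk):
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size


def _make_net(in_channels: int, n_classes: int, kernel: int,
              rng: np.random.Generator) -> nn.Sequential:
    c1, c2, c3 = FILTERS
    return nn.Sequential([
        nn.Conv3d(in_channels, c1, kernel, dilation=1, rng=rng),
        nn.Conv3d(c1, c2, kernel, dilation=2, rng=rng),
        nn.LeakyReLU(LEAKY_ALPHA),
        nn.Conv3d(c2, c3, kernel, dilation=2, rng=rng),
        nn.LeakyReLU(LEAKY_ALPHA),
        nn.Conv3d(c3, n_classes, kernel, dilation=1, rng=rng),
    ])


class CascadedCNN:
    """Model handle for the three-stage cascade."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.nets = {
            name: _make_net(cfg["in_channels"], cfg["n_classes"], cfg["kernel"], rng)
            for name, cfg in NETWORK_SPEC.items()
        }
        self.class_weights = {
            "sse": np.ones(3), "backbone": np.ones(2), "calpha": np.ones(2)
        }
        self.trained = False
        self.seed = seed

    # -- introspection used by tests and the JSON sidecar ------------------
    def layer_filters(self, net: str) -> tuple[int, ...]:
        return tuple(l.cout for l in self.nets[net].layers if isinstance(l, nn.Conv3d))

    def input_channels(self, net: str) -> int:
        return NETWORK_SPEC[net]["in_channels"]

    def spec_dict(self) -> dict:
        out = {}
        for name, net in self.nets.items():
            layers = []
            for l in net.layers:
                if isinstance(l, nn.Conv3d):
                    layers.append({"kind": "dilated-conv" if l.dilation > 1 else "standard-conv",
                                   "kernel": l.k, "dilation": l.dilation, "filters": l.cout})
            out[name] = {"in_channels": NETWORK_SPEC[name]["in_channels"], "layers": layers,
                         "leaky_relu_alpha": LEAKY_ALPHA}
        return out

    def params(self):
        return [p for net in self.nets.values() for p in net.params()]

    # -- forward / backward ------------------------------------------------
    def forward(self, density: np.ndarray) -> dict[str, np.ndarray]:
        """Run the cascade on one (D, H, W) density cube.

        Returns softmax probabilities: 'sse' (3, ...), 'backbone' (2, ...),
        'calpha' (2, ...) with the positive class first in the 2-class heads.
        """
        x = np.asarray(density, dtype=nn.DTYPE)[None]
        ls = self.nets["sse"].forward(x)
        ps = nn.softmax(ls)
        lb = self.nets["backbone"].forward(np.concatenate([x, ps]))
        pb = nn.softmax(lb)
        lc = self.nets["calpha"].forward(np.concatenate([x, ps, pb]))
        pc = nn.softmax(lc)
        self._cache = (ps, pb, pc)
        return {"sse": ps, "backbone": pb, "calpha": pc}

    def train_step(self, density, targets, stop_gradient: bool = False) -> float:
        """One forward/backward pass; returns the joint loss. Gradients are
        accumulated into the layers (caller zeroes and steps the optimizer)."""
        probs = self.forward(density)
        ps, pb, pc = probs["sse"], probs["backbone"], probs["calpha"]
        loss_s, gls = nn.weighted_cross_entropy(ps, targets["sse"], self.class_weights["sse"])
        loss_b, glb = nn.weighted_cross_entropy(pb, targets["backbone"], self.class_weights["backbone"])
        loss_c, glc = nn.weighted_cross_entropy(pc, targets["calpha"], self.class_weights["calpha"])

        gin_c = self.nets["calpha"].backward(glc)
        g_pb = gin_c[4:6]
        g_ps = gin_c[1:4].copy()
        if stop_gradient:
            glb_total = glb
        else:
            glb_total = glb + nn.softmax_backward(pb, g_pb)
        gin_b = self.nets["backbone"].backward(glb_total)
        g_ps += gin_b[1:4]
        if stop_gradient:
            gls_total = gls
        else:
            gls_total = gls + nn.softmax_backward(ps, g_ps)
        self.nets["sse"].backward(gls_total)
        return loss_s + loss_b + loss_c

    # -- persistence -------------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        arrays = {}
        for name, net in self.nets.items():
            conv_i = 0
            for l in net.layers:
                if isinstance(l, nn.Conv3d):
                    arrays[f"{name}_w{conv_i}"] = l.w
                    arrays[f"{name}_b{conv_i}"] = l.b
                    conv_i += 1
        for name, w in self.class_weights.items():
            arrays[f"cw_{name}"] = np.asarray(w)
        arrays["trained"] = np.array(int(self.trained))
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.spec_dict(), indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "CascadedCNN":
        path = Path(path)
        try:
            data = np.load(path.with_suffix(".npz"))
        except (OSError, ValueError) as exc:
            raise ValueError(f"invalid checkpoint {path}: {exc}") from exc
        model = cls()
        for name, net in model.nets.items():
            conv_i = 0
            for l in net.layers:
                if isinstance(l, nn.Conv3d):
                    l.w = data[f"{name}_w{conv_i}"].astype(nn.DTYPE)
                    l.b = data[f"{name}_b{conv_i}"].astype(nn.DTYPE)
                    l.gw = np.zeros_like(l.w)
                    l.gb = np.zeros_like(l.b)
                    conv_i += 1
        for name in model.class_weights:
            if f"cw_{name}" in data:
                model.class_weights[name] = data[f"cw_{name}"]
        model.trained = bool(data["trained"])
        return model


def build_ccnn(seed: int = 0) -> CascadedCNN:
    """Build the untrained three-stage cascade with the standard layer spec."""
    return CascadedCNN(seed=seed)


def _sample_targets(sample: dict) -> dict[str, np.ndarray]:
    helix, sheet, loop = sample["helix"], sample["sheet"], sample["loop"]
    bb, ca = sample["backbone"], sample["calpha"]
    background = ~(helix | sheet | loop)
    t_sse = np.stack([helix, sheet, loop | background]).astype(nn.DTYPE)
    t_bb = np.stack([bb, ~bb]).astype(nn.DTYPE)
    t_ca = np.stack([ca, ~ca]).astype(nn.DTYPE)
    return {"sse": t_sse, "backbone": t_bb, "calpha": t_ca}


def train_ccnn(
    model: CascadedCNN,
    dataset,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    lr: float = DEFAULT_LR,
    max_steps: Optional[int] = None,
    stop_gradient: bool = False,
) -> tuple[CascadedCNN, list[float]]:
    """Train the cascade on an HDF5 dataset; returns (model, loss history).

    Joint loss = sum of the three per-voxel cross-entropies with
    inverse-frequency class weights computed from the dataset. One optimizer
    step per cube (batch size 1); deterministic for a fixed seed.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    samples = load_training_samples(dataset) if not isinstance(dataset, list) else dataset
    if not samples:
        raise ValueError("empty dataset")
    targets = [_sample_targets(s) for s in samples]
    for head, n_cls in (("sse", 3), ("backbone", 2), ("calpha", 2)):
        agg = np.stack([t[head].reshape(n_cls, -1).sum(axis=1) for t in targets]).sum(axis=0)
        model.class_weights[head] = nn.inverse_frequency_weights(
            agg.reshape(n_cls, 1), n_cls)

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.params(), lr=lr)
    history: list[float] = []
    done = False
    for _ in range(epochs):
        order = rng.permutation(len(samples))
        for idx in order:
            opt.zero_grad()
            loss = model.train_step(samples[idx]["density"], targets[idx],
                                    stop_gradient=stop_gradient)
            opt.step()
            history.append(loss)
            if max_steps is not None and len(history) >= max_steps:
                done = True
                break
        if done:
            break
    model.trained = True
    return model, history


def predict_confidence(
    model: CascadedCNN,
    dmap: DensityMap,
    cube_edge: int = 64,
    core_edge: int = 50,
) -> ConfidenceMaps:
    """Cube the map, run the cascade on each cube, stitch the 50^3 cores."""
    if not isinstance(model, CascadedCNN):
        raise ValueError("invalid model handle")
    if not np.allclose(dmap.voxel_size, 1.0, atol=1e-3):
        log.warning("predict_confidence expects a 1 A voxel map; got %s",
                    dmap.voxel_size)
    cubes, grid = split_into_cubes(dmap, cube_edge, core_edge)
    outs = {name: [] for name in LABEL_NAMES}
    for cube in cubes:
        probs = model.forward(cube)
        outs["helix"].append(probs["sse"][0])
        outs["sheet"].append(probs["sse"][1])
        outs["loop"].append(probs["sse"][2])
        outs["backbone"].append(probs["backbone"][0])
        outs["calpha"].append(probs["calpha"][0])
    stitched = {
        name: stitch_cubes(chunks, grid).astype(np.float64)
        for name, chunks in outs.items()
    }
    # zero-padded border voxels of partial cubes keep their softmax value;
    # renormalize the SSE triple so the stitched maps satisfy the invariant
    s = stitched["helix"] + stitched["sheet"] + stitched["loop"]
    s[s == 0] = 1.0
    for name in ("helix", "sheet", "loop"):
        stitched[name] = stitched[name] / s
    return ConfidenceMaps(
        helix=stitched["helix"], sheet=stitched["sheet"], loop=stitched["loop"],
        backbone=stitched["backbone"], calpha=stitched["calpha"],
        voxel_size=dmap.voxel_size, origin=dmap.origin,
    )


# ---------------------------------------------------------------------------
# oracle confidence maps
# ---------------------------------------------------------------------------

def _normalized_splats(reference: DensityMap, coords: np.ndarray,
                       sigma: float) -> np.ndarray:
    """Max-combined per-atom Gaussians, each scaled so its nearest voxel is 1."""
    out = np.zeros(reference.shape, dtype=np.float64)
    if len(coords) == 0:
        return out
    xs, ys, zs = reference.axis_coords()
    reach = 4.5 * sigma
    inv = 1.0 / (2.0 * sigma * sigma)
    for c in coords:
        i0 = np.searchsorted(xs, c[0] - reach); i1 = np.searchsorted(xs, c[0] + reach, side="right")
        j0 = np.searchsorted(ys, c[1] - reach); j1 = np.searchsorted(ys, c[1] + reach, side="right")
        k0 = np.searchsorted(zs, c[2] - reach); k1 = np.searchsorted(zs, c[2] + reach, side="right")
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        d2 = ((xs[i0:i1, None, None] - c[0]) ** 2
              + (ys[None, j0:j1, None] - c[1]) ** 2
              + (zs[None, None, k0:k1] - c[2]) ** 2)
        g = np.exp(-(d2 - d2.min()) * inv)
        np.maximum(out[i0:i1, j0:j1, k0:k1], g, out=out[i0:i1, j0:j1, k0:k1])
    return out


def oracle_confidence(
    model: AtomicModel,
    reference: DensityMap,
    sigma: float = ORACLE_SIGMA,
) -> ConfidenceMaps:
    """Idealized confidence maps computed from ground-truth coordinates.

    calpha: Gaussian splats (width ``sigma``) at the CA positions, each
    normalized so the voxel nearest the atom reads 1.0; backbone: the same
    over N/CA/C atoms; SSE: one-hot by nearest-residue label on
    backbone-positive voxels (backbone >= 0.5), uniform 1/3 elsewhere.
    """
    shape = reference.shape
    if len(model) == 0 or len(model.ca_coords()) == 0:
        log.warning("oracle_confidence: empty model, returning background maps")
        third = np.full(shape, 1.0 / 3.0)
        return ConfidenceMaps(
            helix=third.copy(), sheet=third.copy(), loop=third.copy(),
            backbone=np.zeros(shape), calpha=np.zeros(shape),
            voxel_size=reference.voxel_size, origin=reference.origin,
        )
    ca = model.ca_coords()
    bb_atoms = [a for a in model.atoms if a.atom_name in BACKBONE_ATOMS]
    bb = np.stack([a.coord for a in bb_atoms])
    calpha = _normalized_splats(reference, ca, sigma)
    backbone = _normalized_splats(reference, bb, sigma)
    backbone = np.maximum(backbone, calpha)

    helix = np.full(shape, 1.0 / 3.0)
    sheet = np.full(shape, 1.0 / 3.0)
    loop = np.full(shape, 1.0 / 3.0)
    idx = np.argwhere(backbone >= 0.5)
    if len(idx):
        centers = reference.voxel_to_world(idx)
        tree = cKDTree(bb)
        _, nearest = tree.query(centers)
        labels = np.array([model.residue_sse(bb_atoms[i].residue_index) for i in nearest])
        onehot = {"helix": helix, "sheet": sheet, "loop": loop}
        for name, arr in onehot.items():
            vals = (labels == name).astype(np.float64)
            arr[idx[:, 0], idx[:, 1], idx[:, 2]] = vals
    return ConfidenceMaps(
        helix=helix, sheet=sheet, loop=loop, backbone=backbone, calpha=calpha,
        voxel_size=reference.voxel_size, origin=reference.origin,
    )
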