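"""End-to-end backbone prediction pipeline.

Stages, in order: read map -> preprocess (threshold + normalize, resample to
1 A) -> confidence maps (trained cascade, or the oracle generator from a
ground-truth model) -> path walking -> graph refinement -> helix refinement
-> PDB output; one-to-one Calpha metrics are computed whenever a ground-truth
model is supplied. Every stage writes an inspectable intermediate under the
output directory, and a manifest records all resolved parameters so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import graph_refine, helix, mapsim, metrics, pathwalk, preprocess, structure
from .ccnn import CascadedCNN, oracle_confidence, predict_confidence

log = logging.getLogger(__name__)

MODE_NETWORK = "network"
MODE_ORACLE = "oracle"


@dataclass
class PipelineConfig:
    map_path: Optional[str] = None
    threshold: float = 0.0
    mode: str = MODE_ORACLE
    checkpoint: Optional[str] = None       # network mode
    ground_truth_pdb: Optional[str] = None  # oracle mode and/or evaluation
    out_dir: str = "cryotrace_out"
    seed: int = 0
    simulate_resolution: float = 3.0       # used when no map is given
    walk_params: dict = field(default_factory=dict)
    helix_refinement: bool = True
    helix_min_len: int = 6
    merge_radius: float = 3.0
    cube_edge: int = 64
    core_edge: int = 50

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.mode not in (MODE_NETWORK, MODE_ORACLE):
            raise ValueError(f"mode must be network or oracle, got {self.mode!r}")
        if self.mode == MODE_ORACLE and self.ground_truth_pdb is None:
            raise ValueError("oracle mode requires a ground-truth PDB")
        if self.mode == MODE_NETWORK and self.checkpoint is None:
            raise ValueError("network mode requires a checkpoint")


def run_pipeline(config: PipelineConfig) -> tuple[Path, Optional[metrics.MetricsReport]]:
    """Run all stages; returns (output PDB path, metrics or None)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = None
    if config.ground_truth_pdb is not None:
        gt_path = Path(config.ground_truth_pdb)
        if not gt_path.exists():
            raise FileNotFoundError(f"ground-truth PDB not found: {gt_path}")
        model = structure.read_pdb(gt_path)

    if config.map_path is not None:
        map_path = Path(config.map_path)
        if not map_path.exists():
            raise FileNotFoundError(f"input map not found: {map_path}")
        dmap = mapsim.read_mrc(map_path)
    elif model is not None:
        log.info("no input map; simulating at %.1f A from the ground truth",
                 config.simulate_resolution)
        dmap = mapsim.simulate_density(model, config.simulate_resolution)
    else:
        raise ValueError("need an input map or a ground-truth PDB")

    # --- preprocessing ----------------------------------------------------
    dmap = preprocess.resample_to_unit_voxel(dmap)
    dmap = preprocess.preprocess_map(dmap, config.threshold)
    mapsim.write_mrc(dmap, out_dir / "preprocessed.mrc")

    # --- confidence maps --------------------------------------------------
    if config.mode == MODE_ORACLE:
        maps = oracle_confidence(model, dmap)
    else:
        net = CascadedCNN.load(Path(config.checkpoint))
        maps = predict_confidence(net, dmap, config.cube_edge, config.core_edge)
    np.savez_compressed(
        out_dir / "confidence.npz",
        helix=maps.helix.astype(np.float32), sheet=maps.sheet.astype(np.float32),
        loop=maps.loop.astype(np.float32), backbone=maps.backbone.astype(np.float32),
        calpha=maps.calpha.astype(np.float32),
        voxel_size=maps.voxel_size, origin=maps.origin,
    )

    # --- tracing ----------------------------------------------------------
    params = pathwalk.WalkParams(**config.walk_params)
    traces = pathwalk.trace_all(maps, params)
    if traces:
        structure.write_trace_pdb(traces, out_dir / "traces_raw.pdb")

    # --- graph refinement -------------------------------------------------
    graph = graph_refine.traces_to_graph(traces)
    graph = graph_refine.refine_graph(graph, dmap, merge_radius=config.merge_radius)

    # --- helix refinement ---------------------------------------------------
    if config.helix_refinement:
        graph = helix.refine_helices(graph, maps, min_len=config.helix_min_len)

    final_traces = graph_refine.graph_to_traces(graph)
    out_pdb = out_dir / "prediction.pdb"
    if final_traces:
        structure.write_trace_pdb(final_traces, out_pdb)
    else:
        log.warning("no traces found; writing empty prediction")
        out_pdb.write_text("END" + " " * 77 + "\n")

    # --- metrics ----------------------------------------------------------
    report = None
    if model is not None and final_traces:
        pred = np.concatenate([t.points for t in final_traces])
        report = metrics.compute_metrics(pred, model.ca_coords())
        report.to_json(out_dir / "metrics.json")
        report.to_csv(out_dir / "metrics.csv")

    manifest = dataclasses.asdict(config)
    manifest["resolved_walk_params"] = dataclasses.asdict(params)
    manifest["n_traces"] = len(final_traces)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_pdb, report
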