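"""Pipeline configuration, seed fan-out, and the end-to-end runner.

A :class:`PipelineConfig` selects stages and carries per-stage parameter
blocks; one global seed fans out deterministically to per-stage seeds via
:class:`numpy.random.SeedSequence`, so any stage can be rerun in
isolation with its own seed.  ``run_pipeline`` executes the requested
stages in dependency order and writes a manifest recording parameters,
seeds, and SHA-256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import assembly, clusters, ephys, io, sparklets, synthetic

logger = logging.getLogger("chanclust")

#: Fixed stage order; also the order of seed fan-out.
STAGES = ("fixtures", "assembly", "clusters", "sparklets", "ephys")

_KNOWN_KEYS = {
    "stages",
    "seed",
    "output_dir",
    "cluster_spec",
    "render_spec",
    "sparklet_spec",
    "assembly_params",
    "segmentation",
    "quantal",
    "membrane_area_um2",
    "fraction_functional",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: tuple[str, ...] = STAGES
    seed: int = 0
    output_dir: str = "chanclust_out"
    cluster_spec: dict = field(default_factory=dict)
    render_spec: dict = field(default_factory=dict)
    sparklet_spec: dict = field(default_factory=dict)
    assembly_params: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    quantal: dict = field(default_factory=dict)
    membrane_area_um2: float = 1000.0
    fraction_functional: float = 0.01

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; known stages are {STAGES}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = sorted(set(raw) - _KNOWN_KEYS)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        raw = dict(raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Derive one sub-seed per stage from the global seed.

    ``SeedSequence(global_seed)`` is spawned once per stage in the fixed
    :data:`STAGES` order; each child's first generated state word (mod
    2³¹) is that stage's seed.
    """
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages and return the output manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {s: seeds[s] for s in config.stages},
        "stages": {},
    }
    outputs: list[Path] = []

    def record(stage: str, started: float, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "elapsed_s": round(time.monotonic() - started, 3),
            "parameters": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }
        outputs.extend(files)

    if "fixtures" in config.stages:
        t0 = time.monotonic()
        cspec = synthetic.SyntheticClusterSpec(
            **{"n_clusters": 500, "mean_volume": 0.12, "seed": seeds["fixtures"],
               **config.cluster_spec}
        )
        pop = synthetic.gen_cluster_population(cspec)
        io.write_clusters(out / "clusters_synthetic.csv", pop)
        rspec = synthetic.ImageRenderSpec(
            **{"seed": seeds["fixtures"], **config.render_spec}
        )
        stack = synthetic.render_image_stack(pop, rspec)
        io.write_stack(out / "stack_synthetic.tif", stack)
        sspec = synthetic.SparkletSimSpec(
            **{"seed": seeds["fixtures"], **config.sparklet_spec}
        )
        trace, record_gt = synthetic.gen_sparklet_trace(sspec)
        io.write_trace(out / "sparklet_trace.csv", trace)
        io.write_idealized(out / "sparklet_truth.csv", record_gt)
        record("fixtures", t0, {"cluster_spec": asdict(cspec), "render_spec": asdict(rspec),
                                "sparklet_spec": asdict(sspec)},
               [out / "clusters_synthetic.csv", out / "stack_synthetic.tif",
                out / "sparklet_trace.csv", out / "sparklet_truth.csv"])

    if "assembly" in config.stages:
        t0 = time.monotonic()
        params = assembly.AssemblyParams(
            **{"p_nucleation": 1e-4, "p_growth": 0.01, "p_removal": 0.05,
               "grid_shape": (256, 256), "max_steps": 4000,
               "seed": seeds["assembly"], **config.assembly_params}
        )
        res = assembly.run_to_steady_state(params)
        io.write_distribution(out / "assembly_distribution.csv", res.distribution)
        p = asdict(params)
        p["converged"] = res.converged
        p["n_steps"] = res.n_steps
        record("assembly", t0, p, [out / "assembly_distribution.csv"])

    if "clusters" in config.stages:
        t0 = time.monotonic()
        stack = io.read_stack(out / "stack_synthetic.tif")
        seg = clusters.SegmentationConfig(
            **{"intensity_threshold": 50.0, **config.segmentation}
        )
        pop = clusters.segment_stack(stack, seg)
        io.write_clusters(out / "clusters_segmented.csv", pop)
        metrics = clusters.cell_metrics(pop, config.membrane_area_um2)
        thr = clusters.macro_threshold(0.12, 0.03)
        macro, micro, frac = clusters.classify_macro_micro(pop, thr.threshold)
        summary = {
            "clusters_per_cell": metrics.clusters_per_cell,
            "total_cluster_volume_um3": metrics.total_cluster_volume,
            "mean_cluster_volume_um3": metrics.mean_cluster_volume,
            "membrane_occupancy_pct": metrics.membrane_occupancy_pct,
            "macro_threshold_um3": thr.threshold,
            "macro_count": macro,
            "micro_count": micro,
            "macro_fraction": frac,
        }
        (out / "cluster_metrics.json").write_text(json.dumps(summary, indent=1))
        record("clusters", t0, asdict(seg),
               [out / "clusters_segmented.csv", out / "cluster_metrics.json"])

    if "sparklets" in config.stages:
        t0 = time.monotonic()
        trace = io.read_trace(out / "sparklet_trace.csv")
        qcfg = sparklets.QuantalConfig(**{"quantal_amplitude": 1.0, **config.quantal})
        rec = sparklets.detect_and_idealize(trace, qcfg)
        activity = sparklets.compute_nPs(rec)
        n_ch = max(rec.n_levels_reached, 2)
        est = sparklets.estimate_kappa(rec, n_ch) if rec.duration_frames >= 100 else None
        summary = {
            "nPs": activity.nPs,
            "activity_class": activity.activity_class,
            "n_levels_reached": rec.n_levels_reached,
            "kappa": None if est is None else est.kappa,
            "open_prob": None if est is None else est.open_prob,
        }
        io.write_idealized(out / "sparklet_idealized.csv", rec)
        (out / "sparklet_summary.json").write_text(json.dumps(summary, indent=1))
        record("sparklets", t0, asdict(qcfg),
               [out / "sparklet_idealized.csv", out / "sparklet_summary.json"])

    if "ephys" in config.stages:
        t0 = time.monotonic()
        f = config.fraction_functional
        preds = {}
        for ref in (ephys.MALE_REFERENCE_IV, ephys.FEMALE_REFERENCE_IV):
            p = ephys.scale_current(ref, f)
            preds[ref.sex_label] = {
                "voltages_mV": list(p.voltages_mV),
                "reported_pA_pF": list(p.reported),
            }
        (out / "current_predictions.json").write_text(
            json.dumps({"fraction_functional": f, "predictions": preds}, indent=1)
        )
        record("ephys", t0, {"fraction_functional": f}, [out / "current_predictions.json"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline finished: %d stage(s), %d output file(s)",
                len(manifest["stages"]), len(outputs))
    return manifest
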