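"""End-to-end orchestration: fit -> reconstruct/simulate -> evaluate.

One call wires the stages together, writes every artifact beside a JSON
run manifest (config, seeds, per-stage wall time, version, metric summary),
and leaves a failure marker naming the stage when something breaks, so the
completed artifacts are still usable.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .hcd import (
    ClusteringConfig,
    HCDModel,
    add_variance_matching_noise,
    hcr_fit,
    reconstruct,
    variance_explained,
)
from .hcs import hcs_simulate
from .io import serialize_model
from .matrix import (
    ExpressionMatrix,
    matrix_from_values,
    read_expression_matrix,
    write_expression_matrix,
)
from .netstats import compare_structures
from .synthdata import BlockSpec, generate_hierarchical_blocks

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str
    input_path: str | None = None
    synth_spec: str | None = None  # BlockSpec JSON; used when input_path is None
    orientation: str = "variables_in_rows"
    f_E: float = 0.5
    k: int = 5
    g_max: int = 2
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    variant: str = "normal"
    simulate: bool = True
    n_sim_samples: int | None = None
    add_noise: bool = True
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        clust = ClusteringConfig(**doc.pop("clustering", {}))
        return cls(clustering=clust, **doc)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow, returning {status, model_path, metrics, ...}.

    A stage failure is recorded in the manifest (stage name + error type)
    rather than propagated, so artifacts written by earlier stages survive.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_dict(config),
        "stages": [],
        "status": "running",
    }
    result: dict = {"manifest_path": str(out / "manifest.json")}

    def stage(name: str):
        t0 = time.monotonic()

        def done(**extra):
            manifest["stages"].append(
                {"stage": name, "wall_seconds": round(time.monotonic() - t0, 4), **extra}
            )

        return done

    try:
        done = stage("load")
        X = _load_input(config)
        done(n_samples=X.n_samples, n_variables=X.n_variables)

        done = stage("fit")
        model = hcr_fit(
            X, f_E=config.f_E, k=config.k, g_max=config.g_max,
            clustering=config.clustering, seed=config.seed,
        )
        v_e = variance_explained(model)
        model_path = out / "model.hcd"
        serialize_model(model, model_path)
        done(v_explained=v_e,
             v_explained_per_level=[lv.v_explained_after for lv in model.levels])
        result["model_path"] = str(model_path)

        done = stage("reconstruct")
        XR = reconstruct(model)
        if config.add_noise:
            XR = add_variance_matching_noise(XR, model, seed=config.seed)
        write_expression_matrix(
            matrix_from_values(XR, model.variable_ids), out / "reconstruction.tsv"
        )
        done()

        query = XR
        if config.simulate:
            done = stage("simulate")
            sim = hcs_simulate(
                model, variant=config.variant,
                n=config.n_sim_samples or model.n_samples,
                seed=config.seed, add_noise=config.add_noise,
            )
            write_expression_matrix(
                matrix_from_values(sim.values, model.variable_ids),
                out / "simulation.tsv",
            )
            sidecar = {"variant": sim.variant, "seed": sim.seed,
                       "noise_added": sim.noise_added,
                       "model_fingerprint": sim.model_fingerprint}
            (out / "simulation.json").write_text(json.dumps(sidecar, indent=1))
            done(**sidecar)
            query = sim.values

        done = stage("evaluate")
        metrics = compare_structures(X, query, v_explained=v_e).as_dict()
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        done(**metrics)
        result["metrics"] = metrics
        manifest["status"] = "ok"
    except Exception as exc:  # failure marker, artifacts from earlier stages remain
        manifest["status"] = "failed"
        manifest["failure"] = {
            "stage": _current_stage(manifest),
            "error_type": type(exc).__name__,
            "error": str(exc),
        }
        result["error"] = str(exc)
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    result["status"] = manifest["status"]
    result["manifest"] = manifest
    return result


def _current_stage(manifest: dict) -> str:
    order = ["load", "fit", "reconstruct", "simulate", "evaluate"]
    completed = {s["stage"] for s in manifest["stages"]}
    for name in order:
        if name not in completed:
            return name
    return "evaluate"


def _load_input(config: RunConfig) -> ExpressionMatrix:
    if config.input_path:
        return read_expression_matrix(config.input_path, orientation=config.orientation)
    if config.synth_spec:
        spec = BlockSpec.from_json(config.synth_spec)
    else:
        from .synthdata import default_block_spec

        spec = default_block_spec()
    X, _ = generate_hierarchical_blocks(spec, seed=config.seed)
    return X


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
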