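"""Configuration, seeding, serialization and run management.

One master seed expands deterministically into named sub-streams
(structural connectivity, dynamical inputs, per-trial seeds), so the same
anatomy can be re-stimulated and whole experiments are reproducible from
(config hash, master seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .network import NetworkInstance, aggregate_singles, build_network


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    scheme: str = "default"
    n_lateral_glomeruli: int = 2
    seed: int = 0
    n_instances: int = 1
    n_trials: int = 8
    dt: float = 0.1  # ms
    conc: float = 1.0  # % saturated vapor
    pg_per_glom: int = 1000
    aggregate_ratio: int = 100
    orn_scale: Optional[float] = None  # None -> calibrated default
    air_gain: Optional[float] = None
    protocol: str = "freely-breathing"
    scale_instances: float = 1.0  # multipliers for scaled-down runs
    scale_trials: float = 1.0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    valid = {f.name for f in dataclasses.fields(ExperimentConfig)}
    errors = [f"unknown key: {k}" for k in data if k not in valid]
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return ExperimentConfig(**data)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def split_seed(master: int, stream: str, index: int = 0) -> int:
    """Deterministic sub-seed below 2^31 for a named stream."""
    h = hashlib.sha256(f"{master}:{stream}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def seed_rng(master: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(split_seed(master, stream, index))


# ---------------------------------------------------------------------------
# run persistence
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "1.0"


def save_network(net: NetworkInstance, out_dir) -> None:
    """Serialize a network instance: cell + synapse tables (CSV) + JSON
    metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm = net.gm
    pd.DataFrame({
        "mitral": gm.mitral, "comp": gm.comp, "granule": gm.granule,
        "path_um": gm.path, "dend": gm.dend, "diam_ratio": gm.diam_ratio,
        "x": gm.x, "y": gm.y, "w_inh_nS": gm.w_inh, "w_ampa_nS": gm.w_ampa,
        "w_nmda_nS": gm.w_nmda,
    }).to_csv(out / "granule_synapses.csv", index=False)
    pd.DataFrame({
        "x": net.mitral_soma[:, 0], "y": net.mitral_soma[:, 1],
        "glomerulus": net.mitral_glom, "rotation": net.mitral_rotation,
    }).to_csv(out / "mitral_cells.csv", index=False)
    pd.DataFrame({"x": net.granule_pos[:, 0], "y": net.granule_pos[:, 1],
                  "leak_offset": net.granule_leak_offset}).to_csv(
        out / "granule_cells.csv", index=False)
    pd.DataFrame(net.m2pg).to_csv(out / "mitral_to_pg.csv", index=False)
    pd.DataFrame(net.pg2m).to_csv(out / "pg_to_mitral.csv", index=False)
    meta = {
        "schema": SCHEMA_VERSION, "scheme": net.scheme, "seed": net.seed,
        "n_lateral": net.n_lateral, "n_mitral": net.n_mitral,
        "n_granule": net.n_granule,
        "shared_granules": net.shared_granule_count(),
        "super_edges": [list(map(int, e)) for e in net.super_edges],
        "glomeruli": net.glom_pos.tolist(),
    }
    (out / "network.json").write_text(json.dumps(meta, indent=1))


def save_run(result: dict, cfg: ExperimentConfig, out_dir) -> None:
    """Persist protocol output: binned responses (npz) + config + hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    meta = {"schema": SCHEMA_VERSION, "config_hash": cfg.hash()}
    arrays = {}
    summary = {}
    for k, v in result.items():
        if isinstance(v, np.ndarray):
            arrays[k] = v
        elif isinstance(v, dict) and all(isinstance(x, np.ndarray)
                                         for x in v.values()):
            for kk, vv in v.items():
                arrays[f"{k}.{kk}"] = vv
        elif isinstance(v, (int, float, str, list)):
            summary[k] = v
    np.savez(out / "responses.npz", **arrays)
    meta["summary"] = summary
    (out / "run.json").write_text(json.dumps(meta, indent=1, default=str))


def load_run(run_dir) -> dict:
    """Load a persisted run; raises on hash/schema mismatch."""
    run_dir = Path(run_dir)
    if not run_dir.exists():
        raise FileNotFoundError(f"run directory {run_dir} does not exist")
    meta = json.loads((run_dir / "run.json").read_text())
    major = meta.get("schema", "0").split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(f"incompatible run schema {meta.get('schema')}")
    cfg = load_config(run_dir / "config.yaml")
    if cfg.hash() != meta["config_hash"]:
        raise ValueError("config hash mismatch (corrupted run directory)")
    data = dict(np.load(run_dir / "responses.npz", allow_pickle=False))
    return {"config": cfg, "meta": meta, "arrays": data,
            "summary": meta.get("summary", {})}


def build_and_aggregate(cfg: ExperimentConfig, instance: int = 0
                        ) -> NetworkInstance:
    """Build + aggregate the network of one instance of an experiment."""
    seed = split_seed(cfg.seed, "structure", instance)
    net = build_network(cfg.scheme, cfg.n_lateral_glomeruli, seed=seed,
                        pg_per_glom=cfg.pg_per_glom)
    return aggregate_singles(net, ratio=cfg.aggregate_ratio)
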