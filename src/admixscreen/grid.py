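"""Run-grid orchestration: config expansion, manifests, resumability.

A screening campaign is a grid over landscape types, protocols, sampling
densities, replicates and experiments.  Each cell gets a YAML manifest
carrying the full configuration, its hash and the seed, so any output table
is reconstructible from its manifest alone; completed cells are skipped on
rerun via the manifest hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Configuration of a screening campaign."""

    landscape_types: tuple[str, ...] = (
        "1e-5_1e-4",
        "1e-4_1e-3",
        "1e-3_1e-2",
        "1e-5_1e-2",
    )
    protocols: tuple[str, ...] = (
        "distal-nonrotating",
        "proximal-nonrotating",
        "distal-rotating",
        "proximal-rotating",
    )
    densities: tuple[int, ...] = (13, 18)
    n_replicates: int = 10
    n_experiments: int = 40
    genome_mb: float = 500.0
    seed: int = 1
    out_dir: str = "runs"

    def cells(self):
        """One cell per (type, replicate, protocol, density, experiment)."""
        for lt in self.landscape_types:
            for rep in range(self.n_replicates):
                for proto in self.protocols:
                    for dens in self.densities:
                        for exp in range(self.n_experiments):
                            yield {
                                "landscape_type": lt,
                                "replicate": rep,
                                "protocol": proto,
                                "density": dens,
                                "experiment": exp,
                            }

    def n_cells(self) -> int:
        return (
            len(self.landscape_types)
            * self.n_replicates
            * len(self.protocols)
            * len(self.densities)
            * self.n_experiments
        )


def cell_seed(config: RunConfig, cell: dict) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    payload = json.dumps({"seed": config.seed, **cell}, sort_keys=True)
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def cell_hash(config: RunConfig, cell: dict) -> str:
    payload = json.dumps({**asdict(config), **cell}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, cell: dict, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = (
        f"{cell['landscape_type']}_r{cell['replicate']}_{cell['protocol']}"
        f"_d{cell['density']}_e{cell['experiment']}.yaml"
    )
    path = out_dir / name
    manifest = {
        "cell": cell,
        "config": asdict(config),
        "seed": cell_seed(config, cell),
        "hash": cell_hash(config, cell),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def run_grid(config: RunConfig, runner=None, resume: bool = True):
    """Expand the grid, write manifests, and execute ``runner`` per cell.

    ``runner(cell, seed) -> result`` (optional; manifest-only runs are used
    for planning).  A cell whose manifest exists with a matching hash is
    skipped when resuming; manifests with stale hashes are rewritten and
    rerun, never silently reused.
    """
    out_dir = Path(config.out_dir)
    results = {}
    for cell in config.cells():
        name_key = tuple(cell.values())
        path = out_dir / (
            f"{cell['landscape_type']}_r{cell['replicate']}_{cell['protocol']}"
            f"_d{cell['density']}_e{cell['experiment']}.yaml"
        )
        if resume and path.exists():
            with open(path) as fh:
                manifest = yaml.safe_load(fh)
            if manifest.get("hash") == cell_hash(config, cell):
                done = path.with_suffix(".done")
                if done.exists() or runner is None:
                    continue
        write_manifest(config, cell, out_dir)
        if runner is not None:
            results[name_key] = runner(cell, cell_seed(config, cell))
            path.with_suffix(".done").touch()
    return results
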