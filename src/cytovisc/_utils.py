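"""Run manifests and seed derivation for the pipeline CLI."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from one root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    subcommand: str,
    config: dict,
    inputs: list[str | Path],
    outputs: list[str | Path],
    seeds: dict | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Write a machine-readable record of one run."""
    from . import __version__

    def entry(p):
        p = Path(p)
        return {"path": str(p), "sha256": file_sha256(p) if p.is_file() else None}

    manifest = {
        "subcommand": subcommand,
        "software": {"name": "cytovisc", "version": __version__},
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds or {},
        "inputs": [entry(p) for p in inputs],
        "outputs": [entry(p) for p in outputs],
    }
    if stages is not None:
        manifest["stages"] = stages
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
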