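"""Run manifests: enough provenance to re-execute a stage bit-identically."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def hash_inputs(paths) -> dict:
    """Content hashes of input files; directories hash their sorted files."""
    out = {}
    for p in paths:
        p = Path(p)
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256_file(f)
        elif p.is_file():
            out[str(p)] = _sha256_file(p)
    return out


def config_hash(config_obj) -> str:
    payload = json.dumps(config_obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


class RunManifest:
    """Collects command, config, seed, inputs, timings and warnings."""

    def __init__(self, command: str, seed=None, config=None):
        self.data = {
            "command": command,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
            "config": config,
            "inputs": {},
            "outputs": [],
            "warnings": [],
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._t0 = time.monotonic()
        from . import __version__
        self.data["version"] = __version__

    def add_inputs(self, *paths):
        self.data["inputs"].update(hash_inputs(paths))

    def add_outputs(self, *paths):
        self.data["outputs"].extend(str(p) for p in paths)

    def warn(self, message: str):
        self.data["warnings"].append(message)

    def write(self, out_dir) -> Path:
        self.data["elapsed_s"] = round(time.monotonic() - self._t0, 3)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path
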