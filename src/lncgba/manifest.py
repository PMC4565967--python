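"""Run manifests: a reproducibility record written beside every output set."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

from . import __version__


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config: Mapping,
    inputs: Iterable,
    seed: int | None = None,
) -> Path:
    """Write ``manifest.json``: command, resolved config, input hashes,
    tool version, seed. Deliberately timestamp-free so identical runs
    yield byte-identical manifests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_snapshot": {k: config[k] for k in sorted(config)},
        "input_hashes": {str(p): _sha256(Path(p)) for p in sorted(map(str, inputs))},
        "tool_version": __version__,
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
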