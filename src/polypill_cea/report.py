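"""Run manifests and validation reports.

Every CLI run writes a manifest (config hash, seed, software version,
capped parameters, timestamp) so outputs can be traced back to their
exact inputs, plus a plain-text validation report listing every point
where the executable model had to diverge from the printed inputs
(capped SDs, defaulted effects, distribution-family substitutions).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .parameters import ParameterSet

__all__ = ["write_manifest", "write_validation_report"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    output_dir,
    config_path,
    params: ParameterSet,
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_path": str(config_path),
        "config_sha256": _sha256(config_path) if Path(config_path).exists() else None,
        "seed": seed,
        "version": __version__,
        "capped_parameters": params.capped_parameters(),
        "defaulted_effects": params.defaulted_effects(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def write_validation_report(output_dir, params: ParameterSet) -> Path:
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    path = output_dir / "validation_report.txt"
    path.write_text(params.validation_report())
    return path
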