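"""Run configuration, result serialization and manifests.

Configs are YAML or JSON, schema-validated with defaults filled and unknown
keys rejected.  Results are written atomically: files are staged in a
temporary sibling directory and moved into place only after every table has
been serialized, so a failure never leaves a half-written result set.  A
manifest records the package version, the config hash, per-file SHA-256
digests and convergence diagnostics — enough to re-run bit-identically.

Machine files carry fractions at full precision; percent-scaled report
columns are suffixed ``_pct`` so nothing gets double-scaled.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import os
import shutil
import tempfile
from pathlib import Path

import pandas as pd
import pydantic
import yaml


class RunConfig(pydantic.BaseModel):
    """Validated solver/scenario settings with documented defaults."""

    model_config = pydantic.ConfigDict(extra="forbid")

    seed: int = 0
    tolerance: float = 1e-6
    damping: float = 0.5
    max_iter: int = 500
    coverage: float = 0.95
    fallback_pct: float = 0.5
    eta: float = 0.2
    land_elasticity: float = 0.1
    shock_level: str = "mean"
    dependence_source: str = "synthetic"
    out_dir: str = "results"
    verbose: bool = False

    @pydantic.field_validator("tolerance", "damping")
    @classmethod
    def _positive(cls, v, info):
        if not 0 < v <= 1:
            raise ValueError(f"{info.field_name} must lie in (0, 1]")
        return v

    @pydantic.field_validator("coverage")
    @classmethod
    def _coverage(cls, v):
        if not 0 < v < 1:
            raise ValueError("coverage must lie in (0, 1)")
        return v

    @pydantic.field_validator("shock_level")
    @classmethod
    def _level(cls, v):
        if v not in ("low", "mean", "high"):
            raise ValueError("shock_level must be low, mean or high")
        return v


def parse_and_validate_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file; unknown keys raise with their name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig(**raw)
    except pydantic.ValidationError as err:
        keys = ", ".join(str(e["loc"][0]) for e in err.errors() if e["loc"])
        raise ValueError(f"invalid config {path} (offending keys: {keys}): {err}") from err


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    created: str
    file_digests: dict[str, str]
    diagnostics: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(
    outputs: dict[str, "pd.DataFrame | dict"],
    out_dir: str | Path,
    config: RunConfig | None = None,
    diagnostics: dict | None = None,
) -> RunManifest:
    """Serialize tables (CSV, RFC-4180, UTF-8) and dicts (JSON) atomically.

    ``outputs`` maps file stems to DataFrames or JSON-serializable dicts.
    Returns the manifest, also written as ``manifest.json`` alongside.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    stage = Path(tempfile.mkdtemp(prefix=".stage-", dir=out_dir.parent))
    try:
        digests = {}
        for stem, obj in outputs.items():
            if isinstance(obj, pd.DataFrame):
                path = stage / f"{stem}.csv"
                obj.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")
            else:
                path = stage / f"{stem}.json"
                path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
            digests[path.name] = _digest(path)
        manifest = RunManifest(
            version=__version__,
            config_hash=config_hash(config),
            seed=config.seed,
            created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            file_digests=digests,
            diagnostics=diagnostics or {},
        )
        (stage / "manifest.json").write_text(manifest.to_json())
        out_dir.mkdir(exist_ok=True)
        for item in stage.iterdir():
            os.replace(item, out_dir / item.name)
    finally:
        shutil.rmtree(stage, ignore_errors=True)
    return manifest
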