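"""Configuration loading, output writing and run provenance.

Configs are YAML mappings with optional ``network``, ``stimulus``,
``alpha``, ``protocol`` and ``experiment`` sections whose keys mirror
the corresponding dataclass fields; omitted keys fall back to the model
defaults (Theta=0.13, tau1=0.07, tau2=0.006, d1=0.55, d2=0.36,
lambda0=15).  Unknown keys and out-of-range values are rejected with the
violated invariant named.

Every run directory receives a JSON manifest listing the resolved
configuration, the master seed, the software version and a checksum
inventory of the written files; re-running a manifest's configuration
with its seed reproduces the CSV outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import yaml

from . import __version__
from .engine import AlphaModulation, StimulusDrive, TrialProtocol
from .experiments import ExperimentSpec
from .network import NetworkConfig

__all__ = ["load_config", "dump_config", "write_outputs", "RunManifest"]

_SECTIONS = {
    "network": NetworkConfig,
    "stimulus": StimulusDrive,
    "alpha": AlphaModulation,
    "protocol": TrialProtocol,
    "experiment": ExperimentSpec,
}


def _build(cls, mapping: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    return cls(**mapping)


def load_config(path) -> dict:
    """Parse and validate a YAML config; returns a dict of spec objects.

    Sections absent from the file are returned as None except
    ``network`` and ``protocol``, which fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown section(s) {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            out[name] = _build(cls, raw[name] or {}, name)
        elif name in ("network", "protocol"):
            out[name] = cls()
        else:
            out[name] = None
    return out


def dump_config(objects: dict, path) -> None:
    """Serialize spec objects back to YAML (inverse of load_config)."""
    raw = {}
    for name, obj in objects.items():
        if obj is None:
            continue
        raw[name] = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    config: dict
    master_seed: int | None
    version: str
    created: str
    files: dict  # name -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def write_outputs(
    results: dict,
    out_dir,
    config: dict | None = None,
    master_seed: int | None = None,
) -> RunManifest:
    """Write result tables/objects and a checksum manifest to ``out_dir``.

    ``results`` maps file names to pandas DataFrames (written as CSV),
    strings (written verbatim) or dicts (written as JSON).  A marker
    file ``INCOMPLETE`` guards against partial writes: it is created
    first and removed only after the manifest is on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    files = {}
    for name, obj in results.items():
        path = out / name
        if hasattr(obj, "to_csv"):
            obj.to_csv(path, index=False)
        elif isinstance(obj, dict):
            path.write_text(json.dumps(obj, indent=2, default=str))
        else:
            path.write_text(str(obj))
        files[name] = _sha256(path)
    cfg_repr = {}
    for k, v in (config or {}).items():
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            cfg_repr[k] = dataclasses.asdict(v)
        elif v is not None:
            cfg_repr[k] = v
    manifest = RunManifest(
        config=cfg_repr,
        master_seed=master_seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files=files,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    marker.unlink()
    return manifest
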