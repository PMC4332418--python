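"""JSON report serialization with config echo, input checksums, validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from importlib import resources
from pathlib import Path

import numpy as np

from serpinscope import __version__
from serpinscope.config import RunConfig

__all__ = ["build_report", "write_report", "validate_report", "sha256_file"]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def build_report(
    command: str,
    config: RunConfig,
    inputs: dict[str, str | Path],
    results: dict,
) -> dict:
    """Assemble a validated report dictionary."""
    report = {
        "tool": "serpinscope",
        "version": __version__,
        "command": command,
        "config": _jsonable(config.as_dict()),
        "inputs": {str(p): sha256_file(p) for p in inputs.values()},
        "results": _jsonable(results),
    }
    validate_report(report)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_schema() -> dict:
    text = resources.files("serpinscope.data").joinpath("report.schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Check a report against the published schema (minimal validator)."""
    schema = load_schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["tool"] != "serpinscope":
        raise ValueError("report tool must be 'serpinscope'")
    for key in ("tool", "version", "command"):
        if not isinstance(report[key], str):
            raise ValueError(f"report key {key!r} must be a string")
    for key in ("config", "inputs", "results"):
        if not isinstance(report[key], dict):
            raise ValueError(f"report key {key!r} must be an object")
    digest = re.compile(r"^[0-9a-f]{64}$")
    for path, checksum in report["inputs"].items():
        if not isinstance(checksum, str) or not digest.match(checksum):
            raise ValueError(f"input {path!r} has an invalid sha256 digest")
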