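"""CSV/TSV/JSON output with a fixed dialect and a reproducibility manifest.

All tables are written comma-delimited (tab for edge lists), UTF-8, header
row, no index column, floats at 6 significant digits.  The manifest records
the config snapshot, master seed and substream labels needed to regenerate
every file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = ["RunManifest", "write_table", "write_edges", "write_manifest"]

FLOAT_FORMAT = "%.6g"


def _ensure_parent(path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)


def write_table(frame: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a CSV table; returns the path."""
    path = Path(path)
    _ensure_parent(path)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_edges(edges: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a tick-stamped edge list as TSV (header-only when empty)."""
    path = Path(path)
    _ensure_parent(path)
    edges.to_csv(path, index=False, sep="\t", float_format=FLOAT_FORMAT)
    return path


def _jsonable(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple, set)):
        return [_jsonable(v) for v in value]
    if hasattr(value, "item"):  # numpy scalars
        return value.item()
    if isinstance(value, Path):
        return str(value)
    return value


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's output files."""

    command: str
    master_seed: int
    config: object
    substreams: list = field(default_factory=list)
    version: str = ""
    files: dict = field(default_factory=dict)

    def record_file(self, path: Union[str, Path], rows: int) -> None:
        self.files[str(path)] = {"rows": int(rows)}

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "master_seed": self.master_seed,
            "config": _jsonable(self.config),
            "substreams": list(self.substreams),
            "version": self.version,
            "files": self.files,
        }


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> Path:
    path = Path(path)
    _ensure_parent(path)
    path.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    return path
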