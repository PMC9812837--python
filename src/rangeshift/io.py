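"""CSV and JSON serialization with reproducibility headers.

Every CSV written by the pipeline starts with ``#`` comment lines recording
the package version, a hash of the run configuration, and the seed, so any
output file identifies the run that produced it. Readers skip those lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(
    df: pd.DataFrame, path, *, seed=None, config: dict | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [
        f"# rangeshift {__version__}",
        f"# config_hash: {config_hash(config or {})}",
        f"# seed: {seed}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)
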