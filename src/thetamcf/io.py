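"""Tabular output: CSV tables with JSON sidecars describing how they were made."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy

__all__ = ["write_table", "sidecar_path"]


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def _jsonify(obj: Any):
    if isinstance(obj, Mapping):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonify(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, Any]) -> Path:
    """Write an RFC-4180 CSV plus a JSON sidecar with the full configuration.

    The sidecar records every parameter, truncation and seed used, plus
    library versions, so the table can be regenerated bit-for-bit.
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {
        "config": _jsonify(dict(meta)),
        "versions": {
            "thetamcf": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return path
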