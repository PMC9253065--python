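"""Shared readers/writers: delimited-text matrices, CSV tables, manifests."""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_history",
    "write_manifest",
    "read_manifest",
]


def write_matrix(M: np.ndarray, path: str | Path) -> Path:
    """Write a matrix as header-free comma-delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(M, dtype=float), delimiter=",", fmt="%.12g")
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_history(history, path: str | Path) -> Path:
    """Training or reward history as CSV via pandas."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(history, "loss"):
        df = pd.DataFrame({
            "epoch": np.arange(1, len(history.loss) + 1),
            "loss": history.loss,
            "acc_train": history.acc_train,
            "acc_val": history.acc_val,
        })
    else:
        df = pd.DataFrame({
            "episode": np.arange(1, len(history.rewards) + 1),
            "reward": history.rewards,
            "length": history.lengths,
        })
    df.to_csv(path, index=False)
    return path


def write_manifest(manifest: dict[str, Any], path: str | Path) -> Path:
    """JSON run manifest with version stamps for reproducibility."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = dict(manifest)
    manifest.setdefault("versions", {
        "cogmap": __version__,
        "numpy": np.__version__,
        "python": platform.python_version(),
    })
    path.write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return path


def read_manifest(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
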