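"""Gridded CSV exports and the run manifest."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["export_gridded_csv", "sha256_file", "write_manifest"]


def export_gridded_csv(path, x: np.ndarray, y: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    """Write node-wise gridded data with x_um, y_um plus named columns.

    All arrays in ``columns`` must have shape (len(y), len(x)).  Floats are
    written with repr-stable formatting so identical runs produce identical
    bytes.
    """
    gx, gy = np.meshgrid(x, y, indexing="xy")
    data = {"x_um": gx.ravel() * 1e6, "y_um": gy.ravel() * 1e6}
    for name, arr in columns.items():
        data[name] = np.asarray(arr).ravel()
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, payload: dict) -> Path:
    """Write manifest.json atomically, adding a checksummed file inventory."""
    out_dir = Path(out_dir)
    inventory = {}
    for p in sorted(out_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            inventory[p.name] = sha256_file(p)
    payload = dict(payload)
    payload["outputs"] = inventory
    target = out_dir / "manifest.json"
    fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".manifest.tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, target)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return target
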