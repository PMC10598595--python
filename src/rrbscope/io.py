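"""Format adapters shared by the pipeline stages.

Connectivity matrices travel as labeled tab-separated text (header row and
column of channel names, 17 significant digits so doubles round-trip
exactly) with a manifest CSV naming subject, condition, file and trial
count.  Epoch containers are .npz (see :mod:`rrbscope.epochs`); montages are
JSON; everything else is CSV/TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import ConnectivityMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_connectivity_dir",
    "read_connectivity_dir",
    "checksum_file",
]

FLOAT_FMT = "%.17g"


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.channels, columns=matrix.channels)
    frame.to_csv(Path(path), sep="\t", float_format=FLOAT_FMT)


def read_matrix(path, subject_id: str = "", condition: str = "",
                n_trials: int = 0) -> ConnectivityMatrix:
    frame = pd.read_csv(Path(path), sep="\t", index_col=0)
    channels = tuple(frame.columns)
    if tuple(frame.index) != channels:
        raise ValueError(f"{path}: row and column channel labels disagree")
    return ConnectivityMatrix(
        subject_id=subject_id, condition=condition,
        values=frame.to_numpy(float), channels=channels, n_trials=n_trials,
    )


def write_connectivity_dir(matrices: list[ConnectivityMatrix], out_dir) -> Path:
    """Write one labeled matrix per subject x condition plus manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in matrices:
        fname = f"wpli_{m.subject_id}_{m.condition}.tsv"
        write_matrix(m, out_dir / fname)
        rows.append((m.subject_id, m.condition, fname, m.n_trials))
    manifest = pd.DataFrame(rows, columns=["subject_id", "condition", "file", "n_trials"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def read_connectivity_dir(in_dir) -> list[ConnectivityMatrix]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    out = []
    for row in manifest.itertuples(index=False):
        out.append(read_matrix(in_dir / row.file, subject_id=str(row.subject_id),
                               condition=str(row.condition), n_trials=int(row.n_trials)))
    return out


def checksum_file(path) -> str:
    """SHA-256 of a file's content.

    .npz containers are hashed logically (array names and bytes) because the
    zip wrapper embeds timestamps; all text artifacts are hashed as raw bytes.
    """
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for key in sorted(z.files):
                h.update(key.encode())
                h.update(np.ascontiguousarray(z[key]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def checksum_tree(root, patterns=("*.csv", "*.tsv", "*.json", "*.npz")) -> dict[str, str]:
    root = Path(root)
    out = {}
    for pattern in patterns:
        for path in sorted(root.rglob(pattern)):
            if path.name == "manifest.json":
                continue
            out[str(path.relative_to(root))] = checksum_file(path)
    return out


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
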