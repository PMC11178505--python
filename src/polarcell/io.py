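"""TIFF / manifest reading and writing.

Each cell or doublet is one multi-page TIFF holding a channel-major
(C, Z, Y, X) array. A manifest CSV maps files to cohort labels:
columns ``file, cell_id, condition, replicate, role, channels`` with
``role`` in {single, pair} and ``channels`` a semicolon-joined list of
channel names in page order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import ImageStack

MANIFEST_COLUMNS = [
    "file", "cell_id", "condition", "replicate", "role", "channels",
]


def write_stack(path: Path, stack: ImageStack) -> None:
    """Write one cell as a (C, Z, Y, X) multi-page TIFF."""
    tifffile.imwrite(
        path, stack.pixels.astype(np.float32), photometric="minisblack"
    )


def read_stack(path: Path, channel_names: tuple[str, ...]) -> ImageStack:
    """Read a cell TIFF back into an ImageStack.

    Accepts (C, Z, Y, X), (C, Y, X) (single z) or (Y, X) (single channel
    and z) page layouts.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"{path}: unsupported TIFF shape {arr.shape}")
    return ImageStack(pixels=np.asarray(arr, dtype=float),
                      channel_names=channel_names)


def read_manifest(path: Path) -> pd.DataFrame:
    """Load and validate a manifest CSV."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"manifest {path} is missing column(s): {', '.join(missing)}"
        )
    if len(df) == 0:
        raise ValueError(f"manifest {path} lists no images")
    return df


def parse_channels(entry: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in str(entry).split(";") if s.strip())


def write_params_record(path: Path, record: dict) -> None:
    """Reproducibility record: effective parameters, seed, version."""
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def write_csv(path: Path, df: pd.DataFrame) -> None:
    """Deterministic CSV output (fixed float format, no index)."""
    df.to_csv(path, index=False, float_format="%.6g")
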