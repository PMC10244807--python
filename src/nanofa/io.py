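"""Reading and writing of localization tables, trajectories and images.

The in-memory currency of the package is a :class:`pandas.DataFrame`:

* localization table — columns ``frame`` (int), ``x_nm``, ``y_nm`` (float,
  nanometres), ``photons``, ``uncertainty_nm`` and, when the ground truth is
  known (synthetic data), ``molecule_id``;
* trajectory — columns ``frame``, ``x_nm``, ``y_nm`` for a single molecule.

Coordinates are continuous nanometres with the origin at the top-left corner
of the field; pixel (i, j) of a rendered image covers the half-open square
[j*a, (j+1)*a) x [i*a, (i+1)*a) for pixel size a.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "uncertainty_nm"]
TRAJ_COLUMNS = ["frame", "x_nm", "y_nm"]


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization table CSV; validates the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"localization table {path} lacks columns {missing}")
    df["frame"] = df["frame"].astype(int)
    return df


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in LOC_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols + extra)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory {path} lacks columns {missing}")
    return df


def write_trajectory(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a rendered image as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
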