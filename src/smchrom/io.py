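"""File formats: TIFF movie stacks with JSON sidecars, schema-checked CSV
tables (localizations, events, sites, chromatograms) and results JSON.

All tables are plain CSV with a header row; positions are in nm and times
in s.  Movies are multi-page 16-bit unsigned TIFF; the pixel size and frame
interval travel in a ``<movie>.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, SchemaError
from .kinetics import EVENT_COLUMNS, SITE_COLUMNS
from .localize import LOCALIZATION_COLUMNS
from .synthetic import EVENT_COLUMNS as TRUTH_EVENT_COLUMNS, ImagingSpec

__all__ = [
    "save_movie",
    "load_movie",
    "write_table",
    "read_table",
    "write_localizations",
    "read_localizations",
    "write_events",
    "read_events",
    "write_sites",
    "read_sites",
    "write_truth_events",
    "read_truth_events",
    "read_chromatogram",
    "write_profile",
    "write_json",
    "read_json",
]

CHROMATOGRAM_COLUMNS = ["time_s", "signal"]
PROFILE_COLUMNS = ["time_s", "density"]


def save_movie(path, movie: np.ndarray, imaging: ImagingSpec) -> Path:
    """Write a uint16 movie stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    movie = np.asarray(movie)
    if movie.dtype != np.uint16:
        raise DataError(f"movie must be uint16, got {movie.dtype}")
    tifffile.imwrite(path, movie, photometric="minisblack")
    sidecar = {
        "pixel_size_nm": imaging.pixel_size_nm,
        "frame_interval_s": imaging.frame_interval_s,
        "n_frames": int(movie.shape[0]),
        "shape": list(movie.shape[1:]),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_movie(path) -> tuple[np.ndarray, dict]:
    """Read a movie stack and its sidecar metadata (empty dict if absent)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"movie not found: {path}")
    movie = tifffile.imread(path)
    if movie.ndim == 2:
        movie = movie[None]
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return movie, meta


def write_table(df: pd.DataFrame, path, columns: list[str]) -> Path:
    """Write a CSV with the schema columns first; extra columns follow."""
    path = Path(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(path, missing)
    extras = [c for c in df.columns if c not in columns]
    df[columns + extras].to_csv(path, index=False)
    return path


def read_table(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(path, missing)
    return df


def write_localizations(df, path):
    return write_table(df, path, LOCALIZATION_COLUMNS)


def read_localizations(path):
    return read_table(path, LOCALIZATION_COLUMNS)


def write_events(df, path):
    return write_table(df, path, EVENT_COLUMNS)


def read_events(path):
    return read_table(path, EVENT_COLUMNS)


def write_sites(df, path):
    return write_table(df, path, SITE_COLUMNS)


def read_sites(path):
    return read_table(path, SITE_COLUMNS)


def write_truth_events(df, path):
    return write_table(df, path, TRUTH_EVENT_COLUMNS)


def read_truth_events(path):
    return read_table(path, TRUTH_EVENT_COLUMNS)


def read_chromatogram(path):
    """time_s,signal CSV as exported from an HPLC detector trace."""
    return read_table(path, CHROMATOGRAM_COLUMNS)


def write_profile(profile, path) -> Path:
    df = pd.DataFrame({"time_s": profile.time_s, "density": profile.density})
    return write_table(df, path, PROFILE_COLUMNS)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(data, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return path


def read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    return json.loads(path.read_text())
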