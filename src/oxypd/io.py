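"""Shared I/O: NIfTI volumes, CSV tables, transforms and phantom sidecars.

Volumes travel as NIfTI-1 with the affine preserved through round-trips;
tables are CSV with declared column schemas that are checked on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .registration import AffineTransform

#: Required columns of the long-format flux table.
FLUX_COLUMNS = ("animal_id", "session", "time_min", "photon_flux_per_s")

#: Required columns of the caliper table.
CALIPER_COLUMNS = ("animal_id", "day", "length_mm", "width_mm")


class SchemaError(ValueError):
    """A table is missing required columns."""


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine)), path)
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(path)
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_transform(path: str | Path, transform: AffineTransform) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(transform.to_dict(), indent=2))
    return path


def read_transform(path: str | Path) -> AffineTransform:
    return AffineTransform.from_dict(json.loads(Path(path).read_text()))


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def flux_table(timecourses: dict[str, dict]) -> pd.DataFrame:
    """Long-format flux table from phantom/measured timecourses."""
    rows = []
    for animal, sessions in timecourses.items():
        for session, tc in sessions.items():
            for t, f in zip(tc.times_min, tc.flux):
                rows.append({"animal_id": animal, "session": session,
                             "time_min": t, "photon_flux_per_s": f})
    return pd.DataFrame(rows, columns=list(FLUX_COLUMNS))


def timecourses_from_table(df: pd.DataFrame) -> dict[str, dict]:
    """Group a long-format flux table back into FluxTimecourse objects."""
    from .bli import FluxTimecourse

    missing = [c for c in FLUX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"flux table missing required column(s) {missing}")
    out: dict[str, dict] = {}
    for (animal, session), g in df.groupby(["animal_id", "session"], sort=True):
        g = g.sort_values("time_min")
        out.setdefault(str(animal), {})[str(session)] = FluxTimecourse(
            str(animal), str(session),
            g["time_min"].to_numpy(float), g["photon_flux_per_s"].to_numpy(float))
    return out
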