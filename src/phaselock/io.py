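"""HDF5 / TSV / JSON serialization of the pipeline's artefacts."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocessing import BandSpec, EpochSet
from .source_space import SourceGrid

__all__ = [
    "save_grid",
    "load_grid",
    "save_continuous",
    "load_continuous",
    "save_epochs",
    "load_epochs",
    "save_plv",
    "load_plv",
    "read_manifest",
    "write_json",
]


def save_grid(path, grid: SourceGrid) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("positions", data=grid.positions.astype(np.float64))
        d.attrs["spacing_mm"] = float(grid.spacing)


def load_grid(path) -> SourceGrid:
    with h5py.File(path, "r") as f:
        pos = f["positions"][...]
        spacing = float(f["positions"].attrs["spacing_mm"])
    return SourceGrid(positions=pos, spacing=spacing)


def save_continuous(path, data: np.ndarray, fs: float, subject_id: str) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=np.asarray(data, dtype=np.float64))
        d.attrs["fs_hz"] = float(fs)
        d.attrs["subject_id"] = subject_id


def load_continuous(path) -> tuple[np.ndarray, float, str]:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return d[...], float(d.attrs["fs_hz"]), str(d.attrs["subject_id"])


def save_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=epochs.data)
        d.attrs["fs_hz"] = float(epochs.fs)
        d.attrs["epoch_len_s"] = float(epochs.epoch_len)
        d.attrs["subject_id"] = epochs.subject_id
        if epochs.band is not None:
            d.attrs["band_name"] = epochs.band.name
            d.attrs["band_lo_hz"] = float(epochs.band.lo)
            d.attrs["band_hi_hz"] = float(epochs.band.hi)
        else:
            d.attrs["band_name"] = "broadband"


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        d = f["data"]
        band = None
        if d.attrs["band_name"] != "broadband":
            band = BandSpec(
                str(d.attrs["band_name"]),
                float(d.attrs["band_lo_hz"]),
                float(d.attrs["band_hi_hz"]),
            )
        return EpochSet(
            subject_id=str(d.attrs["subject_id"]),
            band=band,
            data=d[...],
            fs=float(d.attrs["fs_hz"]),
            epoch_len=float(d.attrs["epoch_len_s"]),
        )


def save_plv(path, values: np.ndarray, subject_id: str, band: str) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("plv", data=np.asarray(values, dtype=np.float32))
        d.attrs["subject_id"] = subject_id
        d.attrs["band"] = band


def load_plv(path) -> tuple[np.ndarray, str, str]:
    with h5py.File(path, "r") as f:
        d = f["plv"]
        return d[...].astype(np.float64), str(d.attrs["subject_id"]), str(d.attrs["band"])


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, cls=_NumpyEncoder, sort_keys=True)
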