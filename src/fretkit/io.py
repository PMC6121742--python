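"""Readers and writers for the package's plain-text and HDF5 formats.

Formats (documented in docs/formats.md):

* photon streams -- CSV/TSV with columns ``timestamp_s, channel, slot``
  (channel in {Dem, Aem}, slot in {Dex, Aex}), or HDF5 with datasets
  ``/photons/timestamps`` (float64 s), ``/photons/channel`` and
  ``/photons/slot`` (uint8; 0 = Dem/Dex, 1 = Aem/Aex);
* trace sets -- long-format TSV with columns ``trace_id, frame, I_DemDex,
  I_AemDex, I_AemAex, x, y``;
* spectra -- two-column CSV ``wavelength_nm, value``;
* AV clouds -- XYZ-style text ``x y z weight``;
* obstacle sets -- CSV ``x, y, z, radius``;
* run configuration -- YAML; reports -- JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .av import AccessibleVolume, ObstacleSet
from .burst import CH_AEM, CH_DEM, SLOT_AEX, SLOT_DEX, PhotonStream
from .traces import Trace

PathLike = Union[str, Path]

_CH_TO_NAME = {CH_DEM: "Dem", CH_AEM: "Aem"}
_SLOT_TO_NAME = {SLOT_DEX: "Dex", SLOT_AEX: "Aex"}
_NAME_TO_CH = {v: k for k, v in _CH_TO_NAME.items()}
_NAME_TO_SLOT = {v: k for k, v in _SLOT_TO_NAME.items()}


def _sep_for(path: PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


# ---------------------------------------------------------------- photons

def write_photons_csv(stream: PhotonStream, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "timestamp_s": stream.times,
            "channel": [_CH_TO_NAME[c] for c in stream.channel],
            "slot": [_SLOT_TO_NAME[s] for s in stream.slot],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_photons_csv(path: PathLike) -> PhotonStream:
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = {"timestamp_s", "channel", "slot"} - set(df.columns)
    if missing:
        raise ValueError(f"photon table missing columns: {sorted(missing)}")
    return PhotonStream(
        df["timestamp_s"].to_numpy(float),
        df["channel"].map(_NAME_TO_CH).to_numpy(np.uint8),
        df["slot"].map(_NAME_TO_SLOT).to_numpy(np.uint8),
    )


def write_photons_hdf5(stream: PhotonStream, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("photons")
        grp.create_dataset("timestamps", data=stream.times)
        grp.create_dataset("channel", data=stream.channel)
        grp.create_dataset("slot", data=stream.slot)
        grp.attrs["channel_codes"] = "0=Dem, 1=Aem"
        grp.attrs["slot_codes"] = "0=Dex, 1=Aex"
        grp.attrs["time_unit"] = "s"


def read_photons_hdf5(path: PathLike) -> PhotonStream:
    with h5py.File(path, "r") as f:
        grp = f["photons"]
        return PhotonStream(
            grp["timestamps"][:], grp["channel"][:], grp["slot"][:]
        )


def read_photons(path: PathLike) -> PhotonStream:
    """Dispatch on extension: .h5/.hdf5 vs. CSV/TSV."""
    if str(path).endswith((".h5", ".hdf5")):
        return read_photons_hdf5(path)
    return read_photons_csv(path)


# ----------------------------------------------------------------- traces

def write_traces_tsv(traces: Sequence[Trace], path: PathLike) -> None:
    frames = []
    for i, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": i,
                    "frame": np.arange(len(tr)),
                    "I_DemDex": tr.I_DemDex,
                    "I_AemDex": tr.I_AemDex,
                    "I_AemAex": tr.I_AemAex,
                    "x": tr.position[0],
                    "y": tr.position[1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep_for(path), index=False)


def read_traces_tsv(path: PathLike, frame_period: float = 0.4) -> list[Trace]:
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"trace_id", "frame", "I_DemDex", "I_AemDex", "I_AemAex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame")
        pos = (
            (float(grp["x"].iloc[0]), float(grp["y"].iloc[0]))
            if "x" in grp and "y" in grp
            else (0.0, 0.0)
        )
        traces.append(
            Trace(
                grp["I_DemDex"].to_numpy(float),
                grp["I_AemDex"].to_numpy(float),
                grp["I_AemAex"].to_numpy(float),
                position=pos,
                frame_period=frame_period,
            )
        )
    return traces


# ------------------------------------------------------- spectra, AV, misc

def read_spectrum_csv(path: PathLike) -> np.ndarray:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return df.iloc[:, :2].to_numpy(float)


def write_av_xyz(av: AccessibleVolume, path: PathLike) -> None:
    data = np.column_stack([av.points, av.weights])
    np.savetxt(path, data, header="x y z weight", comments="# ")


def read_av_xyz(path: PathLike) -> AccessibleVolume:
    data = np.atleast_2d(np.loadtxt(path))
    if data.shape[1] == 3:
        return AccessibleVolume(data)
    return AccessibleVolume(data[:, :3], data[:, 3])


def read_obstacles_csv(path: PathLike) -> ObstacleSet:
    df = pd.read_csv(path, sep=_sep_for(path))
    return ObstacleSet(df[["x", "y", "z"]].to_numpy(float), df["radius"].to_numpy(float))


def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(obj: dict, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
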