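"""Readers and writers for photon streams, configs and result tables.

Photon streams are stored either in a photon-HDF5-style HDF5 layout
(datasets ``timestamps`` [float64 s], ``channel`` [uint8], ``excitation``
[uint8]; root attributes ``duration`` and ``sync_rate_hz``) or as flat CSV
with columns ``timestamp_s, channel, excitation``.  Simulation and binding
configs round-trip through YAML or JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from gqfret.simulate import BindingModelParams, SimulationConfig
from gqfret.stream import DEFAULT_SYNC_RATE_HZ, PhotonStream

_CSV_COLUMNS = ["timestamp_s", "channel", "excitation"]


class FormatError(ValueError):
    """Raised for files that do not conform to the expected layout."""


def write_photon_stream(stream: PhotonStream, path, fmt: str | None = None) -> None:
    """Write a photon stream to HDF5 (``.h5``) or CSV; format from extension
    unless ``fmt`` is given."""
    path = Path(path)
    fmt = fmt or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("timestamps", data=stream.timestamps, dtype=np.float64)
            f.create_dataset("channel", data=stream.channel, dtype=np.uint8)
            f.create_dataset("excitation", data=stream.excitation, dtype=np.uint8)
            f.attrs["duration"] = float(stream.duration)
            f.attrs["sync_rate_hz"] = float(stream.sync_rate_hz)
    elif fmt == "csv":
        df = pd.DataFrame(
            {
                "timestamp_s": stream.timestamps,
                "channel": stream.channel,
                "excitation": stream.excitation,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# duration={stream.duration!r} sync_rate_hz={stream.sync_rate_hz!r}\n")
            df.to_csv(fh, index=False, float_format="%.9e")
    else:
        raise ValueError("fmt must be 'h5' or 'csv'")


def read_photon_stream(path, fmt: str | None = None) -> PhotonStream:
    """Read a photon stream written by :func:`write_photon_stream`.

    CSV round-trips bit-exactly at the written precision; HDF5 round-trips
    value-exactly.  A missing column or dataset raises :class:`FormatError`
    naming it; an empty file yields an empty stream with a warning.
    """
    path = Path(path)
    fmt = fmt or ("h5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "h5":
        with h5py.File(path, "r") as f:
            for name in ("timestamps", "channel", "excitation"):
                if name not in f:
                    raise FormatError(f"HDF5 file {path} lacks dataset '{name}'")
            return PhotonStream(
                timestamps=f["timestamps"][:],
                channel=f["channel"][:],
                excitation=f["excitation"][:],
                duration=float(f.attrs.get("duration", f["timestamps"][-1] if len(f["timestamps"]) else 0.0)),
                sync_rate_hz=float(f.attrs.get("sync_rate_hz", DEFAULT_SYNC_RATE_HZ)),
            )
    if fmt != "csv":
        raise ValueError("fmt must be 'h5' or 'csv'")

    if path.stat().st_size == 0:
        warnings.warn(f"empty photon file {path}; returning empty stream", stacklevel=2)
        return PhotonStream(np.empty(0), np.empty(0, np.uint8), np.empty(0, np.uint8), duration=0.0)
    duration, sync = 0.0, DEFAULT_SYNC_RATE_HZ
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
        duration = float(meta.get("duration", 0.0))
        sync = float(meta.get("sync_rate_hz", DEFAULT_SYNC_RATE_HZ))
    df = pd.read_csv(path, comment="#")
    if df.empty and df.columns.size == 0:
        warnings.warn(f"photon CSV {path} has no data; returning empty stream", stacklevel=2)
        return PhotonStream(np.empty(0), np.empty(0, np.uint8), np.empty(0, np.uint8), duration=duration)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"photon CSV {path} lacks column(s): {sorted(missing)}")
    ts = df["timestamp_s"].to_numpy(dtype=np.float64)
    if not duration:
        duration = float(ts[-1]) if ts.size else 0.0
    return PhotonStream(
        timestamps=ts,
        channel=df["channel"].to_numpy(dtype=np.uint8),
        excitation=df["excitation"].to_numpy(dtype=np.uint8),
        duration=duration,
        sync_rate_hz=sync,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = dict(config.__dict__)
    d["states"] = [[float(e), float(w)] for e, w in config.states]
    return d


def save_config(config: SimulationConfig | BindingModelParams, path) -> None:
    """Serialize a config dataclass to YAML (``.yml``/``.yaml``) or JSON."""
    path = Path(path)
    d = config_to_dict(config) if isinstance(config, SimulationConfig) else dict(config.__dict__)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))


def _load_dict(path) -> dict:
    path = Path(path)
    text = path.read_text()
    return yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)


def load_simulation_config(path) -> SimulationConfig:
    d = _load_dict(path)
    if "states" in d:
        d["states"] = [tuple(s) for s in d["states"]]
    return SimulationConfig(**d)


def load_binding_params(path) -> BindingModelParams:
    return BindingModelParams(**_load_dict(path))
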