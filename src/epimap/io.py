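"""Readers and writers for the package's on-disk formats.

Recordings travel as HDF5 (/traces, /fs, /channel_ids, /condition),
event tables and cell maps as CSV, and histology images as
multi-channel TIFF whose ImageDescription tag carries a JSON payload
with the micrometre-per-pixel scale and channel names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ephys import Recording
from .errors import InputError


@dataclass
class HistoImage:
    """Multi-channel 2-D histology image with physical pixel scale."""

    channels: np.ndarray  # (n_channels, height, width)
    channel_names: list[str]
    um_per_px: float

    def __post_init__(self) -> None:
        self.channels = np.atleast_3d(np.asarray(self.channels))
        if self.um_per_px <= 0:
            raise InputError("um_per_px must be positive")
        if len(self.channel_names) != self.channels.shape[0]:
            raise InputError("channel_names length != number of channels")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[self.channel_names.index(name)]
        except ValueError:
            raise InputError(f"no channel named {name!r}") from None


def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f["fs"] = float(rec.fs_hz)
        f["channel_ids"] = np.asarray(rec.channel_ids, dtype=np.int64)
        f["condition"] = rec.condition


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        cond = f["condition"][()]
        if isinstance(cond, bytes):
            cond = cond.decode()
        return Recording(
            traces=f["traces"][...],
            fs_hz=float(f["fs"][()]),
            channel_ids=[int(c) for c in f["channel_ids"][...]],
            condition=str(cond),
        )


def write_image(path, img: HistoImage) -> None:
    desc = json.dumps({"um_per_px": img.um_per_px,
                       "channels": img.channel_names})
    tifffile.imwrite(path, img.channels.astype(np.float32), description=desc,
                     photometric="minisblack")


def read_image(path) -> HistoImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        raise InputError("TIFF lacks the JSON scale/channel metadata") from None
    return HistoImage(np.atleast_3d(data), list(meta["channels"]),
                      float(meta["um_per_px"]))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
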