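"""Photon containers and file I/O for sFLIM measurements.

The central object is the :class:`SFLIMCube`: a per-pixel photon count
histogram over (excitation epoch x spectral channel x TCSPC bin). Photon
streams (in-memory stand-ins for time-tagged time-resolved records) are
binned into cubes; cubes round-trip losslessly through a documented HDF5
layout and can be reduced to conventional bandpass-filter channel images.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np

from .instrument import InstrumentConfig, IRFSet

__all__ = [
    "SFLIMCube",
    "PhotonStream",
    "FormatError",
    "bin_photons",
    "write_cube",
    "read_cube",
    "bandpass_channel_images",
    "write_tiff_stack",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match the documented layout."""


@dataclass
class PhotonStream:
    """Unordered TTTR-style photon records.

    All fields are equal-length 1-D arrays: integer pixel coordinates, the
    micro time in ns within the sync period, and the spectral channel index.
    """

    pixel_row: np.ndarray
    pixel_col: np.ndarray
    micro_time: np.ndarray
    spectral_channel: np.ndarray

    def __post_init__(self):
        self.pixel_row = np.asarray(self.pixel_row, dtype=np.int64)
        self.pixel_col = np.asarray(self.pixel_col, dtype=np.int64)
        self.micro_time = np.asarray(self.micro_time, dtype=float)
        self.spectral_channel = np.asarray(self.spectral_channel, dtype=np.int64)
        n = len(self.pixel_row)
        if not all(len(a) == n for a in (self.pixel_col, self.micro_time, self.spectral_channel)):
            raise ValueError("all PhotonStream fields must have equal length")

    def __len__(self) -> int:
        return len(self.pixel_row)


@dataclass
class SFLIMCube:
    """Per-pixel photon histogram over (epoch, spectral channel, TCSPC bin).

    ``counts`` has shape ``(rows, cols, n_epochs, n_spectral,
    n_tcspc_per_epoch)``; TCSPC bin 0 of each epoch starts at that epoch's
    offset (half-open bins). Pixels are 0-based and row-major.
    """

    counts: np.ndarray
    config: InstrumentConfig
    pixel_size: float = 78.125  # nm; 40 um / 512 px of the reference scan
    metadata: dict = field(default_factory=dict)
    irf: Optional[IRFSet] = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.round(c)):
                raise ValueError("counts must be integers")
            c = c.astype(np.uint32)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        expected = (self.config.n_epochs, self.config.n_spectral,
                    self.config.n_tcspc_per_epoch)
        if c.ndim != 5 or c.shape[2:] != expected:
            raise ValueError(
                f"counts shape {c.shape} incompatible with config "
                f"(expected (*, *, {expected[0]}, {expected[1]}, {expected[2]}))")
        self.counts = c

    @property
    def shape(self):
        return self.counts.shape[:2]

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def pixel_histograms(self) -> np.ndarray:
        """Flattened view ``(n_pixels, n_epochs*n_spectral*n_tcspc_per_epoch)``."""
        rows, cols = self.shape
        return self.counts.reshape(rows * cols, -1)


def bin_photons(stream: PhotonStream, config: InstrumentConfig,
                image_shape: Sequence[int], pixel_size: float = 78.125) -> SFLIMCube:
    """Histogram a photon stream into an :class:`SFLIMCube`.

    Each photon joins the epoch whose offset interval contains its micro
    time, at TCSPC bin ``floor((t - offset) / bin_width)``. Records whose
    pixel coordinates fall outside ``image_shape`` or whose spectral channel
    is out of range are dropped; the number of dropped records is stored in
    ``metadata["n_dropped"]``. Photons are otherwise conserved.
    """
    rows, cols = int(image_shape[0]), int(image_shape[1])
    period = config.sync_period_ns
    t = np.mod(stream.micro_time, period)

    ok = ((stream.pixel_row >= 0) & (stream.pixel_row < rows)
          & (stream.pixel_col >= 0) & (stream.pixel_col < cols)
          & (stream.spectral_channel >= 0)
          & (stream.spectral_channel < config.n_spectral))
    n_dropped = int(len(stream) - ok.sum())

    offsets = np.asarray(config.epoch_offsets)
    # epoch = index of last offset <= t; times before the first offset wrap
    # around to the final epoch of the previous period
    epoch = np.searchsorted(offsets, t[ok], side="right") - 1
    t_in = t[ok] - offsets[np.maximum(epoch, 0)]
    wrap = epoch < 0
    if np.any(wrap):
        epoch[wrap] = config.n_epochs - 1
        t_in[wrap] = t[ok][wrap] + period - offsets[-1]
    tbin = np.minimum((t_in / config.tcspc_bin_ns).astype(np.int64),
                      config.n_tcspc_per_epoch - 1)

    shape = (rows, cols, config.n_epochs, config.n_spectral,
             config.n_tcspc_per_epoch)
    flat = np.ravel_multi_index(
        (stream.pixel_row[ok], stream.pixel_col[ok], epoch,
         stream.spectral_channel[ok], tbin), shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).astype(np.uint32)
    return SFLIMCube(counts=counts.reshape(shape), config=config,
                     pixel_size=pixel_size,
                     metadata={"n_dropped": n_dropped, "n_records": len(stream)})


# ---- HDF5 I/O --------------------------------------------------------------
#
# Layout:
#   /counts       uint32, (rows, cols, n_epochs, n_spectral, n_tcspc_per_epoch)
#   /counts attrs pixel_size (nm), metadata (JSON string)
#   root attrs    config (JSON string of InstrumentConfig)
#   /irf          optional float64 (n_epochs, n_tcspc_per_epoch)

def write_cube(cube: SFLIMCube, path) -> None:
    """Write a cube to the documented HDF5 layout (lossless)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=cube.counts, compression="gzip",
                             compression_opts=1)
        d.attrs["pixel_size"] = cube.pixel_size
        d.attrs["metadata"] = json.dumps(cube.metadata)
        f.attrs["config"] = cube.config.to_json()
        f.attrs["format"] = "sflim-cube-v1"
        if cube.irf is not None:
            f.create_dataset("irf", data=cube.irf.response)


def read_cube(path) -> SFLIMCube:
    """Read a cube written by :func:`write_cube`.

    Raises :class:`FormatError` naming the missing dataset/attribute when
    the file does not follow the layout.
    """
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError(f"{path}: missing dataset /counts")
        if "config" not in f.attrs:
            raise FormatError(f"{path}: missing root attribute 'config'")
        config = InstrumentConfig.from_json(f.attrs["config"])
        d = f["counts"]
        counts = d[()]
        pixel_size = float(d.attrs.get("pixel_size", 78.125))
        metadata = json.loads(d.attrs.get("metadata", "{}"))
        irf = None
        if "irf" in f:
            irf = IRFSet(response=f["irf"][()], config=config)
    return SFLIMCube(counts=counts, config=config, pixel_size=pixel_size,
                     metadata=metadata, irf=irf)


# ---- bandpass channel-mode emulation ---------------------------------------

def bandpass_channel_images(cube: SFLIMCube,
                            filters: Sequence[tuple],
                            excitations: Sequence[int]) -> np.ndarray:
    """Emulate conventional filter-based channel-mode imaging.

    Each filter is ``(center_nm, full_width_nm)`` paired with the index of
    the excitation epoch it observes. Spectral channels are weighted by the
    fractional overlap of the channel interval with the filter passband,
    then summed over all TCSPC bins of the assigned epoch.

    Returns an array ``(n_filters, rows, cols)`` of weighted intensities.
    A filter with zero overlap yields an all-zero image and a warning.
    """
    if len(filters) != len(excitations):
        raise ValueError("one excitation epoch per filter required")
    edges = cube.config.spectral_channel_edges
    width = cube.config.spectral_channel_width
    # counts summed over TCSPC time: (rows, cols, epoch, channel)
    by_channel = cube.counts.sum(axis=4)
    images = np.zeros((len(filters),) + cube.shape, dtype=float)
    for i, ((center, fw), epoch) in enumerate(zip(filters, excitations)):
        if not (0 <= epoch < cube.config.n_epochs):
            raise ValueError(f"filter {i}: epoch {epoch} out of range")
        lo, hi = center - fw / 2.0, center + fw / 2.0
        overlap = np.clip(np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1]),
                          0.0, None) / width
        if overlap.sum() <= 0:
            warnings.warn(
                f"filter {center}/{fw} nm has no overlap with the detection range",
                stacklevel=2)
            continue
        images[i] = np.tensordot(by_channel[:, :, epoch, :], overlap, axes=([2], [0]))
    return images


def write_tiff_stack(images: np.ndarray, path, description: str = "") -> None:
    """Write a stack of images as a multi-page 32-bit float TIFF."""
    import tifffile

    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(path, arr, photometric="minisblack", description=description)
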