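"""Instrument model: PIE timing, spectral channel grid, TCSPC binning and the IRF.

The data model mirrors a two-laser pulsed-interleaved-excitation (PIE)
confocal setup with spectrally dispersed detection: within one laser sync
period each laser fires once, photons are tagged with a micro time (TCSPC)
and a spectral detection channel, and the sync period is partitioned into
per-laser *epochs* so every photon is attributable to its excitation source.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = [
    "InstrumentConfig",
    "IRFSet",
    "default_config",
    "spectral_channel_of",
    "gaussian_irf",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Static description of the acquisition system.

    Parameters
    ----------
    rep_rate : float
        Laser pulse repetition frequency in Hz. Both PIE lasers share one
        sync period of ``1 / rep_rate``.
    excitation_wavelengths : tuple of float
        Laser wavelengths in nm, ordered by their pulse time in the period.
    epoch_offsets : tuple of float
        Start time (ns) of each laser's detection epoch within the sync
        period. Offsets must be strictly increasing, lie in ``[0, period)``
        and be equally spaced so that every epoch spans the same number of
        TCSPC bins.
    spectral_min, spectral_max : float
        Bounds of the spectral detection range in nm.
    n_spectral : int
        Number of equal-width spectral channels over the detection range.
    n_tcspc : int
        TCSPC bins per sync period (must be divisible by the number of
        lasers; each epoch owns ``n_tcspc / n_lasers`` bins).
    irf_fwhm : float
        Instrument response FWHM in picoseconds.
    notch : (float, float) or None
        Optional laser-blocking notch filter, given as
        ``(center_nm, transmission)`` with transmission in [0, 1] applied to
        the single spectral channel containing the center.
    """

    rep_rate: float = 40e6
    excitation_wavelengths: tuple = (485.0, 561.0)
    epoch_offsets: tuple = (0.0, 12.5)
    spectral_min: float = 490.0
    spectral_max: float = 640.0
    n_spectral: int = 8
    n_tcspc: int = 1024
    irf_fwhm: float = 120.0
    notch: Optional[tuple] = (561.0, 0.2)

    def __post_init__(self):
        object.__setattr__(self, "excitation_wavelengths",
                           tuple(float(w) for w in self.excitation_wavelengths))
        object.__setattr__(self, "epoch_offsets",
                           tuple(float(o) for o in self.epoch_offsets))
        if self.notch is not None:
            object.__setattr__(self, "notch", tuple(self.notch))
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")
        period = self.sync_period_ns
        offs = self.epoch_offsets
        if len(offs) != len(self.excitation_wavelengths):
            raise ValueError("one epoch offset per excitation wavelength required")
        if any(not (0.0 <= o < period) for o in offs):
            raise ValueError(f"epoch offsets must lie in [0, {period}) ns")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("epoch offsets must be strictly increasing")
        if len(offs) > 1:
            spacing = period / len(offs)
            expect = tuple(offs[0] + k * spacing for k in range(len(offs)))
            if any(abs(o - e) > 1e-9 * period for o, e in zip(offs, expect)):
                raise ValueError("epoch offsets must be equally spaced over the period")
        if self.spectral_max <= self.spectral_min:
            raise ValueError("spectral_max must exceed spectral_min")
        if self.n_spectral < 1:
            raise ValueError("n_spectral must be >= 1")
        if self.n_tcspc < 2 or self.n_tcspc % self.n_epochs != 0:
            raise ValueError("n_tcspc must be a positive multiple of the number of lasers")
        if self.irf_fwhm <= 0:
            raise ValueError("irf_fwhm must be positive")
        if self.notch is not None:
            center, transmission = self.notch
            if not (0.0 <= transmission <= 1.0):
                raise ValueError("notch transmission must lie in [0, 1]")

    # ---- derived geometry -------------------------------------------------
    @property
    def sync_period_ns(self) -> float:
        return 1e9 / self.rep_rate

    @property
    def n_epochs(self) -> int:
        return len(self.excitation_wavelengths)

    @property
    def epoch_duration_ns(self) -> float:
        return self.sync_period_ns / self.n_epochs

    @property
    def n_tcspc_per_epoch(self) -> int:
        return self.n_tcspc // self.n_epochs

    @property
    def tcspc_bin_ns(self) -> float:
        return self.sync_period_ns / self.n_tcspc

    @property
    def spectral_channel_width(self) -> float:
        return (self.spectral_max - self.spectral_min) / self.n_spectral

    @property
    def spectral_channel_edges(self) -> np.ndarray:
        """Channel edges: ``spectral_min + k * width`` for k = 0 .. n_spectral."""
        return self.spectral_min + np.arange(self.n_spectral + 1) * self.spectral_channel_width

    def epoch_time_axis(self, epoch: int) -> np.ndarray:
        """Bin start times (ns, relative to the epoch offset) of one epoch."""
        return np.arange(self.n_tcspc_per_epoch) * self.tcspc_bin_ns

    # ---- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["excitation_wavelengths"] = list(self.excitation_wavelengths)
        d["epoch_offsets"] = list(self.epoch_offsets)
        d["notch"] = list(self.notch) if self.notch is not None else None
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        d = dict(d)
        if d.get("notch") is not None:
            d["notch"] = tuple(d["notch"])
        d["excitation_wavelengths"] = tuple(d["excitation_wavelengths"])
        d["epoch_offsets"] = tuple(d["epoch_offsets"])
        return cls(**d)

    @classmethod
    def from_json(cls, text_or_path) -> "InstrumentConfig":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Short stable hash used to pair patterns with compatible cubes."""
        import hashlib
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def default_config() -> InstrumentConfig:
    """The reference configuration: 40 MHz PIE with 485/561 nm lasers, eight
    18.75 nm spectral channels over 490-640 nm, 1024 TCSPC bins per period
    (~24.4 ps) and a 120 ps FWHM instrument response."""
    return InstrumentConfig()


def spectral_channel_of(wavelength: float, config: InstrumentConfig) -> Optional[int]:
    """Index of the half-open spectral channel containing ``wavelength`` (nm).

    Returns ``None`` when the wavelength lies outside
    ``[spectral_min, spectral_max)``.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if not (config.spectral_min <= wavelength < config.spectral_max):
        return None
    idx = int((wavelength - config.spectral_min) // config.spectral_channel_width)
    return min(idx, config.n_spectral - 1)


@dataclass(frozen=True)
class IRFSet:
    """Per-epoch normalized instrument response histograms.

    ``response`` has shape ``(n_epochs, n_tcspc_per_epoch)``; each row sums
    to one and is defined on its epoch's time grid (bin 0 at the epoch
    offset).
    """

    response: np.ndarray
    config: InstrumentConfig

    def __post_init__(self):
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", r)
        expected = (self.config.n_epochs, self.config.n_tcspc_per_epoch)
        if r.shape != expected:
            raise ValueError(f"IRF shape {r.shape} != expected {expected}")
        if np.any(r < 0):
            raise ValueError("IRF histograms must be nonnegative")
        sums = r.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each IRF histogram must sum to 1")

    def full_period(self) -> np.ndarray:
        """IRF laid out on the full sync-period grid (length ``n_tcspc``),
        concatenating the per-epoch blocks in epoch order."""
        return self.response.reshape(-1)


def gaussian_irf(config: InstrumentConfig, fwhm_ps: Optional[float] = None,
                 center_ns: float = 0.25) -> IRFSet:
    """Gaussian instrument response of the given FWHM, one copy per epoch.

    The response is bin-integrated (not point-sampled) and centered
    ``center_ns`` after each epoch offset so that essentially all of its
    mass lies inside the epoch.
    """
    from scipy.special import erf

    fwhm_ps = config.irf_fwhm if fwhm_ps is None else fwhm_ps
    sigma = fwhm_ps * 1e-3 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    edges = np.arange(config.n_tcspc_per_epoch + 1) * config.tcspc_bin_ns
    z = (edges - center_ns) / (sigma * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    hist = np.diff(cdf)
    total = hist.sum()
    if total <= 0:
        raise ValueError("IRF has no mass inside the epoch window")
    hist = hist / total
    response = np.tile(hist, (config.n_epochs, 1))
    return IRFSet(response=response, config=config)
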