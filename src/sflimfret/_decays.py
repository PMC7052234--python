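"""Shared low-level kernels for periodic exponential decays.

With a pulsed laser every decay is periodically re-excited, so an
exponential observed over one period T carries the wrapped tails of all
previous pulses; the periodic sum has the closed form
``exp(-t/tau) / (1 - exp(-T/tau))`` on ``t in [0, T)``. All decay shapes
here are bin-integrated (not point-sampled) and convolution with the IRF is
circular over the period.
"""

from __future__ import annotations

import numpy as np

__all__ = ["periodic_exp_bins", "circular_convolve"]


def periodic_exp_bins(tau: float, n_bins: int, period: float) -> np.ndarray:
    """Bin-integrated periodic exponential, normalized to sum exactly 1.

    ``tau`` and ``period`` share units; the mass of bin ``[t0, t1)`` is
    ``(exp(-t0/tau) - exp(-t1/tau)) / (1 - exp(-T/tau))``.
    """
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    edges = np.linspace(0.0, period, n_bins + 1)
    e = np.exp(-edges / tau)
    denom = 1.0 - np.exp(-period / tau)
    if denom <= 0:  # tau >> period: numerically uniform
        return np.full(n_bins, 1.0 / n_bins)
    mass = (e[:-1] - e[1:]) / denom
    return mass / mass.sum()


def circular_convolve(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution over the period via FFT; tiny negative ripple
    from the FFT round trip is clipped to zero."""
    if signal.shape != kernel.shape:
        raise ValueError("signal and kernel must share the bin grid")
    out = np.fft.irfft(np.fft.rfft(signal) * np.fft.rfft(kernel), n=len(signal))
    return np.clip(out, 0.0, None)
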