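"""Fluorescence correlation spectroscopy: multi-tau autocorrelation,
single-species 3D diffusion fitting, confocal-volume calibration and
concentration estimation.

The amplitude convention follows the standard effective-volume definition
``V_eff = pi^{3/2} w0^2 z0`` for a 3D Gaussian detection profile, under
which ``G(0) = 1/N`` with ``N`` the mean number of molecules in ``V_eff``,
so that a fitted ``N`` converts directly to a molar concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from .cube import FormatError
from .exceptions import FitError

__all__ = [
    "FCSCurve",
    "FCSFit",
    "Calibration",
    "autocorrelate",
    "diffusion_3d_model",
    "fit_fcs",
    "calibrate",
    "concentration",
    "write_fcs_trace",
    "read_fcs_trace",
]

AVOGADRO = 6.02214076e23


@dataclass
class FCSCurve:
    """Autocorrelation curve on a quasi-logarithmic (multi-tau) lag grid."""

    lags: np.ndarray            # s, strictly increasing, > 0
    G: np.ndarray               # dimensionless fluctuation autocorrelation
    n_samples: np.ndarray = None  # products averaged per lag
    dt: float = float("nan")

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G values must be finite")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"lag_s": self.lags, "G": self.G})


@dataclass
class FCSFit:
    """Single-species free 3D diffusion fit:
    ``G(tau) = (1/N) (1 + tau/tau_D)^-1 (1 + tau/(kappa^2 tau_D))^-1/2``."""

    N: float
    tau_D: float                # s
    kappa: float
    stderr: dict = field(default_factory=dict)
    kappa_fixed: bool = False

    def __post_init__(self):
        if self.N <= 0 or self.tau_D <= 0:
            raise ValueError("N and tau_D must be positive")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")


@dataclass
class Calibration:
    """Confocal volume calibration from a reference dye of known diffusion
    coefficient: ``w0 = sqrt(4 D tau_D)``, ``z0 = kappa w0``,
    ``V_eff = pi^{3/2} w0^2 z0`` (in fl = um^3)."""

    w0: float                   # um
    z0: float                   # um
    kappa: float
    V_eff: float                # fl
    D_ref: float                # um^2/s

    @classmethod
    def from_fit(cls, fit: FCSFit, D_ref: float) -> "Calibration":
        return calibrate(fit, D_ref)

    @classmethod
    def from_volume(cls, V_eff_fl: float, kappa: float, D_ref: float) -> "Calibration":
        """Reconstruct the geometry from a known effective volume, e.g. to
        configure a simulation matching a published calibration."""
        w0 = (V_eff_fl / (math.pi ** 1.5 * kappa)) ** (1.0 / 3.0)
        return cls(w0=w0, z0=kappa * w0, kappa=kappa,
                   V_eff=V_eff_fl, D_ref=D_ref)

    @property
    def tau_D(self) -> float:
        """Diffusion time (s) implied by ``w0`` and ``D_ref``."""
        return self.w0 ** 2 / (4.0 * self.D_ref)

    def to_dict(self) -> dict:
        return {"w0_um": self.w0, "z0_um": self.z0, "kappa": self.kappa,
                "V_eff_fl": self.V_eff, "D_ref_um2_s": self.D_ref}


# ---------------------------------------------------------------------------
# correlator
# ---------------------------------------------------------------------------

def autocorrelate(trace: np.ndarray, dt: float, n_per_level: int = 8,
                  max_levels: Optional[int] = None) -> FCSCurve:
    """Multi-tau autocorrelation of a binned intensity trace.

    Eight lags per level; after each level the trace is re-binned by a
    factor of two. The estimator uses symmetric normalization,
    ``G(tau) = <F(t) F(t+tau)> / (<F(t)> <F(t+tau)>) - 1``
    with the two means taken over the actually overlapping samples, which
    removes the bias from slow drifts at long lags.
    """
    f = np.asarray(trace, dtype=float).ravel()
    if f.mean() == 0:
        raise ValueError("trace has zero mean; cannot normalize G")
    if len(f) < 2 * n_per_level:
        raise ValueError("trace shorter than twice the smallest lag block")

    lags, G, counts = [], [], []
    level = 0
    width = 1  # current bin width in units of dt
    while True:
        ks = range(1, n_per_level + 1) if level == 0 \
            else range(n_per_level // 2 + 1, n_per_level + 1)
        if len(f) < 2 * n_per_level:
            break
        for k in ks:
            left, right = f[:-k], f[k:]
            m = left.mean() * right.mean()
            num = np.mean(left * right)
            lags.append(k * width * dt)
            G.append(num / m - 1.0 if m > 0 else 0.0)
            counts.append(len(left))
        # coarsen for the next level
        if len(f) % 2:
            f = f[:-1]
        f = f[0::2] + f[1::2]
        width *= 2
        level += 1
        if max_levels is not None and level >= max_levels:
            break
    return FCSCurve(lags=np.array(lags), G=np.array(G),
                    n_samples=np.array(counts), dt=dt)


# ---------------------------------------------------------------------------
# model and fit
# ---------------------------------------------------------------------------

def diffusion_3d_model(tau, N, tau_D, kappa):
    """Single-species free 3D diffusion autocorrelation."""
    tau = np.asarray(tau, dtype=float)
    return (1.0 / N) / ((1.0 + tau / tau_D) * np.sqrt(1.0 + tau / (kappa ** 2 * tau_D)))


def fit_fcs(curve: FCSCurve, fix_kappa: Optional[float] = None,
            weights: Optional[np.ndarray] = None) -> FCSFit:
    """Weighted least-squares fit of the 3D diffusion model to a curve.

    ``fix_kappa`` pins the axial/lateral ratio to a calibration value (the
    amplitude and the diffusion time are then the only free parameters).
    Raises :class:`FitError` with diagnostics on non-convergence.
    """
    if len(curve.lags) < 10:
        raise ValueError("need at least 10 lags spanning the diffusion time")
    import lmfit

    g0 = float(np.mean(curve.G[:2]))
    if g0 <= 0:
        g0 = max(float(curve.G.max()), 1e-3)
    # first lag where G halves: diffusion-time scale
    below = np.nonzero(curve.G < g0 / 2.0)[0]
    tau_d0 = float(curve.lags[below[0]]) if len(below) else float(np.median(curve.lags))

    model = lmfit.Model(diffusion_3d_model, independent_vars=["tau"])
    params = model.make_params(
        N=dict(value=max(1.0 / g0, 1e-3), min=1e-6),
        tau_D=dict(value=tau_d0, min=float(curve.lags[0]) / 10.0,
                   max=float(curve.lags[-1]) * 10.0),
        kappa=dict(value=fix_kappa if fix_kappa else 5.0, min=1.0, max=50.0,
                   vary=fix_kappa is None))
    result = model.fit(curve.G, params, tau=curve.lags, weights=weights)
    if not result.success:
        raise FitError(f"FCS fit did not converge: {result.message}",
                       best=result.best_values)
    se = {name: (result.params[name].stderr if result.params[name].stderr else np.nan)
          for name in result.params}
    return FCSFit(N=float(result.params["N"].value),
                  tau_D=float(result.params["tau_D"].value),
                  kappa=float(result.params["kappa"].value),
                  stderr=se, kappa_fixed=fix_kappa is not None)


def calibrate(fit: FCSFit, D_ref: float) -> Calibration:
    """Confocal-volume calibration from a fit of a reference dye with known
    diffusion coefficient ``D_ref`` (um^2/s)."""
    if D_ref <= 0:
        raise ValueError("D_ref must be positive")
    w0 = math.sqrt(4.0 * D_ref * fit.tau_D)
    z0 = fit.kappa * w0
    return Calibration(w0=w0, z0=z0, kappa=fit.kappa,
                       V_eff=math.pi ** 1.5 * w0 ** 2 * z0, D_ref=D_ref)


def concentration(N: float, V_eff_fl: float) -> float:
    """Molar concentration from the mean molecule number in the effective
    volume: ``C = N / (N_A V_eff)`` with ``V_eff`` in fl (1 fl = 1e-15 L)."""
    if N <= 0 or V_eff_fl <= 0:
        raise ValueError("N and V_eff must be positive")
    return N / (AVOGADRO * V_eff_fl * 1e-15)


# ---------------------------------------------------------------------------
# trace I/O  (layout: /trace int64 counts, /dt scalar seconds)
# ---------------------------------------------------------------------------

def write_fcs_trace(trace: np.ndarray, dt: float, path, metadata: Optional[dict] = None) -> None:
    import json
    with h5py.File(path, "w") as f:
        f.create_dataset("trace", data=np.asarray(trace, dtype=np.int64),
                         compression="gzip", compression_opts=1)
        f.create_dataset("dt", data=float(dt))
        f.attrs["format"] = "sflim-fcs-trace-v1"
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata)


def read_fcs_trace(path) -> tuple:
    with h5py.File(path, "r") as f:
        if "trace" not in f:
            raise FormatError(f"{path}: missing dataset /trace")
        if "dt" not in f:
            raise FormatError(f"{path}: missing dataset /dt")
        return f["trace"][()], float(f["dt"][()])
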