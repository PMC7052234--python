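"""Pydantic schemas for CLI reports and manifests."""

from __future__ import annotations

from typing import Dict, List, Optional

from pydantic import BaseModel, Field


class Manifest(BaseModel):
    """Provenance stamp written next to every CLI output; a command rerun
    with the same config and seed reproduces its outputs bit-for-bit."""

    command: str
    seed: Optional[int] = None
    config_hash: str
    package_version: str
    inputs: Dict[str, str] = Field(default_factory=dict)
    outputs: List[str] = Field(default_factory=list)
    parameters: Dict[str, float | int | str | bool | None] = Field(default_factory=dict)


class PatternSummary(BaseModel):
    label: str
    total_contribution: float


class UnmixReport(BaseModel):
    """Per-run summary of a pattern-matching unmixing."""

    patterns: List[PatternSummary]
    n_iterations: int
    converged: bool
    rebin: int
    total_counts: float
    mean_deviance: float
    config_hash: str


class DecayFitReport(BaseModel):
    components: List[List[float]]   # (amplitude, lifetime ns) pairs
    background_per_bin: float
    shift_ns: float
    chi2_red: float
    tau_int_ns: float
    tau_amp_ns: float
    total_counts: float


class FretReport(BaseModel):
    tau_d_ns: float
    tau_da_ns: float
    delta_tau_int_ns: float
    efficiency: float


class FcsFitReport(BaseModel):
    n_molecules: float
    tau_d_s: float
    kappa: float
    kappa_fixed: bool
    v_eff_fl: Optional[float] = None
    concentration_nm: Optional[float] = None
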