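# sflimfret

Spectrally resolved FLIM-FRET analysis for multiplexed immunofluorescence
with cross-labelling secondary antibodies — simulation, pattern-matching
unmixing, reconvolution lifetime fitting and FCS calibration.

## The problem

Indirect immunofluorescence with secondary antibodies breaks down when two
primary antibodies from the same host species are used: secondary
antibodies cross-label, structures show up in the wrong colour channel,
and conventional bandpass ("channel-mode") imaging cannot tell a genuine
signal from a false positive. But cross-labelling has a physical
fingerprint: it places donor- and acceptor-conjugated antibodies within
Förster distance, so the donor lifetime drops (FRET). An sFLIM detector —
recording, for every photon, its excitation laser (pulsed interleaved
excitation), spectral channel and TCSPC arrival time — can turn that
fingerprint into a separate analysis channel.

This package implements that analysis chain end to end on synthetic data:

- **Instrument/data model** — two-laser PIE at 40 MHz (485/561 nm), 8
  spectral channels over 490–640 nm, per-pixel TCSPC histograms
  (`SFLIMCube`, HDF5-backed), bandpass channel-mode emulation.
- **Forward simulator** — organelle-like scenes labelled with
  fluorophores or FRET pairs (quenched donor + sensitized acceptor),
  Poisson photon statistics; plus Brownian-dynamics FCS photon traces.
- **Lifetime/FRET** — Poisson maximum-likelihood reconvolution fitting of
  periodic multi-exponential decays; intensity-/amplitude-weighted mean
  lifetimes; Δτ_int and FRET efficiency; Student's t-test for group shifts.
- **Pattern-matching unmixing** — reference patterns over
  (excitation × spectral × time) bins; per-pixel nonnegative Poisson-ML
  contributions (EM warm start + projected Newton); residual-crosstalk
  (bleed-through) matrices.
- **FCS** — multi-tau autocorrelation, single-species 3D diffusion fit
  `G(τ) = (1/N)(1+τ/τ_D)⁻¹(1+τ/(κ²τ_D))⁻¹ᐟ²`, confocal-volume calibration
  (`V_eff = π³ᐟ² w₀² z₀`) and molar concentration `C = N/(N_A V_eff)`.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Quantify the donor lifetime quench that cross-labelling produces, from two
synthetic million-photon decays:

```python
from sflimfret.experiments import delta_tau_experiment

result = delta_tau_experiment(seed=20201)
print(f"tau_D  = {result['tau_int_donor']:.3f} ns")
print(f"tau_DA = {result['tau_int_quenched']:.3f} ns")
print(f"delta  = {result['delta_tau_int']:.3f} ns, "
      f"E = {result['efficiency']:.3f}")
```

prints

```
tau_D  = 3.824 ns
tau_DA = 3.181 ns
delta  = 0.643 ns, E = 0.168
```

i.e. the fitted intensity-weighted donor lifetime falls from ≈3.84 ns to
≈3.18 ns on the cross-labelled sample — a ≈0.66 ns shift, an apparent FRET
efficiency of ≈17% — which is the signature the unmixing uses to separate
a cross-labelled structure from the same two fluorophores seen singly.

The full triple-antigen demonstration (three antigens, two fluorophores)
runs from the command line:

```bash
sflim simulate --demo triple --seed 4 --out run/
sflim channel-mode --cube run/cube.h5 --out run/bands.tif   # the failure mode
sflim unmix --cube run/cube.h5 --pattern p1.h5 --pattern p2.h5 \
            --pattern p3.h5 --out run/unmixed/               # the fix
```

`run/unmixed/contributions.tif` holds one page per antigen channel;
`report.json` records convergence and per-channel totals. Patterns come
from `sflim extract-pattern` on pure-structure masks. `sflim fcs-sim` /
`sflim fcs-fit` cover the concentration calibration workflow.

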