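# msmr — mean single-molecule rate analysis of fluorescence fluctuations

`msmr` analyses photon-count traces from confocal fluorescence
fluctuation spectroscopy (FFS) experiments — single-photon excitation,
one detector — and answers two questions about the molecules diffusing
through the detection volume: **how bright is one molecule** and **how
fast does it diffuse**.  It is aimed at people running FCS-style
measurements (labelled nucleic acids, proteins, dyes) who want a
brightness-centred alternative to autocorrelation analysis that can be
corrected cleanly for detector artefacts.

## The statistic

For counts k collected in bins of width T, Mandel's Q parameter

    Q(T) = (⟨k²⟩ − ⟨k⟩² − ⟨k⟩) / ⟨k⟩

measures the deviation from Poisson statistics (Q = 0 for pure shot
noise).  Dividing by the sampling time gives the *mean single-molecule
rate* (mSMR),

    μ(T) = Q(T)/T = γ₂ · μ0 · Γ_diff(T) · Γ_iso(T),

whose short-T plateau is γ₂μ0 — γ₂ = 1/(2√2) for a 3D Gaussian
detection volume, μ0 the count rate of a single molecule at the volume
maximum — and whose sigmoidal decay with T encodes the diffusion time
τD (D = r0²/4τD).  Γ_diff and Γ_iso are closed-form binning functions
of the 3D-Gaussian diffusion kernel and of an optional on/off
dark-state (blinking) kernel with dark fraction F and relaxation time
τF.  The curve is read like an FCS correlogram, but the amplitude is a
per-molecule brightness instead of 1/N — which makes it directly
correctable for dead time, afterpulsing and background
(`msmr.corrections`).

The package provides:

* `msmr.models` — closed-form model functions plus independent
  quadrature oracles;
* `msmr.traces` — trace containers, divisor-grid rebinning, exact
  moment computation, the empirical mSMR curve;
* `msmr.corrections` — first-order dead-time/afterpulsing moment
  correction, background correction, and synthetic artefact injection
  for testing;
* `msmr.simulate` — a lattice-walk Monte Carlo simulator of diffusing
  (optionally blinking) emitters, the package's ground-truth generator;
* `msmr.fitting` — least-squares model fitting as a scikit-learn
  estimator (`MSMRRegressor`) plus replicate aggregation;
* `msmr.cli` / `msmr.workflow` — the `msmr` command
  (`simulate`, `msmr`, `fit`, `pipeline`) binding everything into the
  simulate → process → correct → fit workflow.

## Worked example

Simulate 20 molecules at 100 kCps diffusing at D = 50 µm²/s through a
0.4 µm detection volume for 2 s, build the mSMR curve, and fit it:

```python
import numpy as np
from msmr import (PSFGeometry, SimulationConfig, Species,
                  simulate_trace, msmr_curve, MSMRRegressor,
                  diffusion_coefficient)

cfg = SimulationConfig(
    species=(Species(D=50.0, count=20, mu0=100e3),),
    geometry=PSFGeometry(r0=0.4, z0=0.4),
    duration=2.0, seed=7)
trace = simulate_trace(cfg)
curve = msmr_curve(trace)

est = MSMRRegressor(r=1.0).fit(curve.T, curve.mu)
print(f"mu0  = {est.mu0_/1e3:.1f} kCps")
print(f"tauD = {est.tau_d_*1e3:.3f} ms")
print(f"D    = {diffusion_coefficient(est.tau_d_, 0.4):.1f} um^2/s")
```

prints

```
mu0  = 97.9 kCps
tauD = 0.845 ms
D    = 47.4 um^2/s
```

The fitted brightness (97.9 kCps) and diffusion coefficient
(47.4 µm²/s) recover the simulation inputs (100 kCps, 50 µm²/s) to
within the sampling noise of a single 2 s trace; averaging five 10 s
replicates, as the validation protocol does, tightens both to a few
percent.  The same chain runs from the shell:

```sh
msmr simulate --config sim.yaml --out trace.txt
msmr msmr --trace trace.txt --out curve.csv
msmr fit --curve curve.csv --r 1.0 --r0-um 0.4
```

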