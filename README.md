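# fnirsim

Simulation and analysis of periodic hemodynamic oscillations in
time-domain (TD) and continuous-wave (CW) functional near-infrared
spectroscopy (fNIRS).

Resting-state brain activity modulates oxy- and deoxy-hemoglobin (O2Hb,
HHb) concentrations with periodic components — cardiac pulsation, Mayer
waves, vasomotion. Whether an fNIRS instrument can *detect* such an
oscillation, and *localize* it in depth, depends on the photon budget per
histogram (N̄tot), the measurement length (Tmeas), the sampling rate (fs)
and the source–detector distance (SDD). `fnirsim` answers these questions
with fully synthetic experiments, for researchers designing fNIRS
protocols or analysis pipelines:

* **Forward models** — analytic time-domain diffusion solutions for a
  homogeneous slab (extrapolated-boundary image sources) and a two-layer
  finite cylinder (1 cm superficial "UP" layer over a 4 cm deep "DW"
  layer; radial J₀ eigenfunction expansion, FFT time inversion).
* **Tissue dynamics** — sinusoidal perturbations
  c(t) = c₀(1 + A sin(2πft + φ)) of the layer hemoglobin concentrations,
  mapped to μa(λ, t) by Beer's law; μs′(λ) = a(λ₀/λ)^b.
* **Acquisition** — distributions of photon times of flight (DTOFs) with
  per-bin Poisson counting noise, time gates (ten 500 ps windows over
  0–5 ns), and full-integral CW intensities.
* **Spectral analysis** — third-order polynomial detrending, un-windowed
  periodogram PSD, and the peak contrast statistic
  C(f) = PSD(f)/ε, C_dB = 10·log₁₀ C, where ε is the mean PSD in a
  noise-only band; peaks with C_dB ≥ 15 dB count as significant.
* **Inversion** — Levenberg–Marquardt baseline fitting of (μa, μs′), the
  time-dependent mean partial pathlength (TMPP) method
  (R(t) = R₀(t)·exp(−Σⱼ Δμa,ⱼ Lⱼ(t)), inverted per frame over time gates)
  for layer-resolved absorption, the CW modified Beer–Lambert law, and
  chromophore unmixing back to ΔO2Hb/ΔHHb.
* **Experiments** — named scenario grids (`H_Ntot`, `H_Tmeas`, `H_fs`,
  `H_SDD` for the homogeneous medium; `B_UP` … `B_AmpFreq` for the
  bilayer), a scenario runner, scaling reports and gate-contrast profiles,
  plus a thin `fnirsim` command-line interface.

The headline results these tools reproduce: the 1 Hz intensity-PSD peak
grows as N̄tot² and Tmeas and is invariant to fs; the noise floor grows as
N̄tot, falls as fs⁻¹, and is invariant to Tmeas and SDD; the first 500 ps
gate senses only the superficial layer at any SDD; TMPP localizes a 1%
oscillation to the correct layer with no cross-talk at SDD = 4 cm but is
blind to the deep layer at 1 cm — while the CW intensity at 1 cm still
detects deep oscillations, which challenges short-separation regression
assumptions for oscillatory signals.

## Worked example

Sweep the photon budget over 10⁴–10⁶ photons per DTOF (case `H_Ntot`:
15 min at 20 Hz, SDD 1 and 4 cm, a 1% 1 Hz oscillation of both hemoglobin
species) and fit the power laws of the 1 Hz peak, the noise floor ε and
the peak contrast:

```python
from fnirsim import experiments as xp

config = xp.get_case("H_Ntot", master_seed=0)
table = xp.run_case(config)            # one record per grid point
report = xp.scaling_report(table)
cols = ["sdd", "wavelength", "metric", "exponent", "r_squared"]
print(report[report.wavelength == 690.0][cols].to_string(index=False))
```

```
 sdd  wavelength   metric  exponent  r_squared
 1.0       690.0 peak_amp  1.992748   0.999994
 1.0       690.0      eps  1.004884   0.999819
 1.0       690.0 contrast  0.987863   0.999926
 4.0       690.0 peak_amp  2.000372   1.000000
 4.0       690.0      eps  0.997321   0.999999
 4.0       690.0 contrast  1.003051   0.999995
```

The 1 Hz peak amplitude scales as N̄tot² (exponent ≈ 2), the Poisson noise
floor as N̄tot (exponent ≈ 1), hence the detection contrast grows linearly
with the photon budget — with fit qualities r² > 0.999. The same machinery
exposes the depth-selectivity results, e.g.

```bash
fnirsim gates --case B_DW --n-tot 1e6 --sdd 1 --seed 0
```

prints the per-gate 1 Hz contrast of the deep-layer perturbation case at
SDD = 1 cm: gate 1 (0–500 ps) stays below the 15 dB significance line —
early photons never reach the deep layer — while the CW channel remains
significant.

See `docs/methods.md` for the models, conventions and numerical choices.

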