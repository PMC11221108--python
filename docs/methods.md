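# Methods

`fnirsim` simulates time-domain (TD) and continuous-wave (CW) functional
near-infrared spectroscopy measurements of a tissue-like medium whose
hemoglobin concentrations oscillate periodically, and analyzes how
detectable those oscillations are. This note documents the models, the
conventions, and the choices made where the design was genuinely open.

## Tissue model and dynamics

The medium contains two chromophores, oxy- and deoxy-hemoglobin, with
baseline concentrations 30 and 20 μM. Beer's law maps concentrations to
the absorption coefficient at the two operating wavelengths (690 and
830 nm) through specific absorption factors stored as package data
(`data/extinction.yaml`, derived from the standard Gratzer/Prahl molar
extinction compilation via μa = ln(10)·ε·c·10⁻⁶; the file documents the
source values). The implied baselines are μa(690) ≈ 0.1136 cm⁻¹ and
μa(830) ≈ 0.0992 cm⁻¹. Reduced scattering follows the Mie-approximation
power law μs′(λ) = a(λ₀/λ)^b with a = 10 cm⁻¹, b = 1, λ₀ = 690 nm, held
constant in time; the refractive index is 1.4.

Perturbations are constant-amplitude, constant-frequency sinusoids of the
concentrations, c(t) = c₀(1 + Σ A sin(2πft + φ)), the standard idealization
of cardiac-band physiological oscillations (default A = 1% of baseline,
f = 1 Hz). Each (layer, species, frequency) term receives an independent
random phase from U[0, 2π) unless an explicit phase or an
in-phase/out-of-phase layer relationship is requested — there is no
consensus on the physiological phase relationships, so none is imposed.
Phases are drawn **once per scenario** and shared across every acquisition
setting of that scenario: the medium is physically the same whether it is
observed at 1 or 4 cm, with 10⁴ or 10⁶ photons. (Without this, the
parameter-sweep power laws would be contaminated by amplitude re-draws.)

## Forward models

Both geometries are solved with the time-dependent diffusion equation
under the extrapolated-boundary condition (EBC), D = 1/(3μs′) with μa not
included in D, and the detected signal is the Fick outward flux D ∂φ/∂z at
the surface. The internal-reflection parameter uses the standard
reflection-moment polynomial, A(1.4) ≈ 3.25. Boundary-condition variant and
D convention are not uniquely fixed by the literature; all headline
quantities here are contrasts, ratios and scaling exponents, which are
insensitive to these conventions.

**Homogeneous slab** (5 cm thick, laterally infinite): image-source
expansion, truncated when an added image pair contributes < 10⁻¹² of the
series (≤ ~7 pairs in practice). Because D excludes μa, absorption enters
only through exp(−μa v t); this exact factorization is the fast path for
frame synthesis (one model evaluation per scenario instead of one per
frame) and is verified to machine precision in the tests. The slab curve is
additionally pinned against an independently coded oracle (sine-series
eigenfunction expansion in depth × lateral Gaussian kernel) frozen in the
test suite.

**Two-layer finite cylinder** (radius 10 cm, 1 cm superficial "UP" layer
over 4 cm deep "DW" layer): expansion in the radial eigenfunctions
J₀(s_n ρ) of the extrapolated cylinder (s_n from the zeros of J₀), with a
closed-form two-layer one-dimensional Green's-function flux per
(eigenvalue, temporal frequency), assembled in the frequency domain and
inverted to time with an inverse FFT. Numerical safeguards:

* the mode count is chosen adaptively from the zero-frequency mode
  spectrum: the expansion is truncated where the conservative remainder
  bound Σ|w_n G_n| falls below 10⁻¹² of the total (typically ~1000 modes);
* the time inversion runs on an 8× finer internal sampling (the DTOF rise
  at short separations has spectral content far beyond the nominal
  Nyquist frequency) over a 4× longer window, then fine samples are summed
  into the requested bins; truncation ringing and wrap-around are below
  10⁻⁸ of the curve maximum, verified by the identical-layer degeneracy
  test against the slab solution (< 10⁻⁵ relative on all bins holding
  ≥ 10⁻⁶ of the maximum, against a 1% acceptance bound).

Curves are stored per time bin (flux × bin width) on 0–5 ns grids: 8 ps
resolution for the homogeneous medium, 20 ps for the bilayer medium (where
the eigenfunction solver dominates cost). A `point_sampled` mode returns
exact band-limited bin-center samples instead of bin integrals; the
distinction matters only on the steep early rise (see TMPP below).

**Per-frame bilayer synthesis** uses a precomputed 5×5 grid of curves over
(μa_UP, μa_DW) spanning ±1.5% of baseline, interpolated bilinearly in
log R per time bin; since log R is nearly linear in μa, the interpolation
error is < 0.05% (certified in the tests), far below Poisson noise. The
TMPP operator never uses this grid — its curves are direct evaluations —
so inversion and synthesis cannot share a bias.

## Acquisition model

A measurement is round(Tmeas·fs) DTOF frames. One scale factor per series,
fixed so that the **baseline** curve integrates to the photon budget N̄tot,
converts curves to count expectations; each bin of each frame is an
independent Poisson draw. Per-bin Poisson noise is the physical
photon-counting model and makes gated counts automatically Poisson; the
fixed scale lets absorption oscillations modulate the detected totals,
which is exactly the CW signal. N̄tot is therefore the *expected* baseline
total, not the realized one. One RNG stream per (scenario point,
wavelength), spawned deterministically from the master seed. The
instrument response is an ideal delta; a unit-area synthetic IRF can be
convolved in (`convolve_irf`), which leaves all spectral conclusions
unchanged. Dead time, afterpulsing and background counts are not modeled.

Time gates are half-open intervals assigned by bin center (default: ten
500 ps gates covering 0–5 ns), which makes gate sums conserve frame totals
exactly. CW intensity is the full-window frame total.

## Spectral analysis

Signals are detrended with a third-order least-squares polynomial and fed
to the **un-windowed one-sided periodogram density**
(`scipy.signal.periodogram`, boxcar, scaling="density"): maximum frequency
resolution, no variance reduction. Under this normalization an on-grid
sinusoid of amplitude A gives a single-bin peak A²·Tmeas/2 and a
unit-variance white sequence a flat density 2/fs — which is what makes the
peak amplitude invariant to fs, proportional to Tmeas, and the Poisson
noise floor proportional to N̄tot/fs, as the scaling experiments measure.
A "per-bin" normalization would scale peak and floor by fs·Tmeas jointly;
contrasts and fit qualities are unaffected, but the individual exponents
quoted here assume the density convention.

The noise floor ε is the mean PSD over a noise-only band: (5, fs/2] Hz
when the Nyquist frequency exceeds 5 Hz; (2, 2.5] Hz at fs = 5 Hz (the
band that avoids the 2 Hz second harmonic); (2.5, fs/2] for intermediate
rates, 5 < fs ≤ 10 — same harmonic-avoidance logic while keeping as many
bins as possible, since a half-Hz band at 15 min has only ~450 bins and
would make ε needlessly noisy (σ ≈ 4.7%). The contrast is C(f) = PSD(f)/ε,
reported in dB; a peak is significant when C_dB ≥ 15 dB (the maximum
contrast observed in noise-only bands at these record lengths). Peak
amplitude is the PSD at the single grid bin nearest the target frequency
(the simulation grids place the target exactly on-bin; ties break to the
lower frequency); the zero-frequency bin is excluded everywhere.
Third-order detrending distorts a 1 Hz tone by ~1/Tmeas — 0.35% of its
amplitude at the 15 min records used here.

Power-law fits are OLS in log–log space; r² is reported in that space,
matching straight-line fits on log–log axes.

## Inversion

**Baseline fit**: Levenberg–Marquardt (`scipy.optimize.least_squares`,
method="lm") of (log amplitude, log μa, log μs′) of the homogeneous slab
model to the time-averaged DTOF, Poisson-weighted, on bins above 10⁻³ of
the curve maximum. Noiseless recovery is < 0.5% error; at N̄tot = 10⁵ and
15 min the fitted parameters are within ~0.1% of truth.

**TMPP** (time-dependent mean partial pathlength): the per-layer
pathlengths L_j(t) = −∂ln R(t)/∂μa_j are central finite differences of the
bilayer model at the fitted baseline (step δ = 10⁻³ cm⁻¹; ln R is nearly
linear in μa so the step's curvature error is negligible, while a 10×
smaller step lets the solver's deterministic truncation error at the DTOF
rise survive the ±δ cancellation and corrupt L_j there — the δ/2δ
consistency check in `tmpp_pathlengths(validate=True)` guards this).
Gate aggregates are baseline-weighted means
⟨L_j⟩_g = Σ R₀L_j/ΣR₀. On bin-integrated curves L_j is the *bin-averaged*
log-derivative — exactly the operator gated counts need; the pointwise
identity Σ_j L_j(t) = v·t (identical layers) holds for the `point_sampled`
operator, to < 0.1%.

Per frame, Δμa = (Δμa_UP, Δμa_DW) solves ln(N_g,0/N_g) = Σ_j Δμa_j⟨L_j⟩_g
by least squares over the usable gates (baseline mean ≥ 10 counts; at
SDD = 1 cm the last four gates are empty and drop out). Zero counts enter
the log as 0.5, and ln N is debiased by +1/(2N) (E[ln N] ≈ ln μ − 1/(2μ)
for Poisson counts); the retrieval is then unbiased over gates with ≥ 100
baseline counts, while gates near the 10-count threshold leave a constant
offset of order 10⁻⁴ cm⁻¹ (the O(1/N²) terms) — a DC term invisible to
every spectral quantity, since detrending removes offsets.
Gate weighting defaults to **uniform** (OLS). Inverse-variance Poisson
weights (`weighting="poisson"`) are implemented and are statistically more
efficient — efficient enough that at SDD = 1 cm, N̄tot = 10⁵ they recover
the deep-layer 1 Hz peak (~19–21 dB) that the reference depth-selectivity
behavior this package reproduces reports as absent; with OLS the short-SDD
deep peak stays below threshold (5–13 dB) while every long-SDD and
superficial result is unchanged. Uniform weighting is therefore the
faithful default, and the weighted variant a documented option.

Retrieved Δμa at the two wavelengths are unmixed per layer by solving the
2×2 Beer's-law system (condition number checked); contrast analysis then
runs on the per-layer, per-species concentration series.

**CW retrieval**: Δμa(t) = −ln(I(t)/I₀)/⟨L⟩ with I₀ the whole-measurement
mean intensity and ⟨L⟩ = v·⟨t⟩ the count-weighted mean time of flight of
the baseline model curve — the model's own differential pathlength, so no
literature DPF value is imported. One whole-medium estimate; CW at a
single separation has no depth resolution.

## What the generator does and does not emulate

The generator reproduces the study conditions: delta IRF, pure Poisson
noise, constant-amplitude constant-frequency sinusoids, homogeneous or
two-homogeneous-layer media with known geometry. Real measurements add a
broadened IRF (available as plumbing; it does not change the spectral
conclusions), background/dark counts, detector dead time, amplitude and
frequency drift of the physiological oscillations (which broadens or
splits spectral peaks), and many-layered anatomy with unknown thicknesses.
Passing tests therefore demonstrate the detectability limits and
depth-selectivity of the *methods* under ideal conditions; in-vivo
sensitivity will be lower, and TMPP accuracy degrades when the assumed
layer geometry is wrong.

## Problem sizes and reproducibility

The named scenarios run at full scale: 15 min at 20 Hz (18 000 frames),
N̄tot up to 10⁶, 625 (homogeneous) or 250 (bilayer) time bins. The test
suite and the acceptance script run these sizes directly — the homogeneous
sweeps take seconds via the absorption factorization; each bilayer
(μa-grid + syntheses) case takes a few minutes, dominated by the ~25
eigenfunction solver calls of the interpolation grid, which are memoized
and shared across scenarios with a common baseline. `ScenarioConfig
(scale_down=True)` caps Tmeas at 2 min and N̄tot at 10⁵ for quick
exploration; contrasts then scale down by the fitted laws. Every random
choice (phases, Poisson streams) derives deterministically from one master
seed; re-running a case reproduces its outputs bit for bit.

## Known limitations

* Layers share one refractive index; mismatched-index interfaces are not
  modeled.
* No scattering dynamics: μs′ is constant in time, and the inversions
  retrieve absorption only.
* The TMPP implementation assumes the true layer geometry; thickness
  misspecification is untested here.
* Media with more than two layers, Monte Carlo transport, and
  short-separation regression as a correction algorithm are out of scope.
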