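# Methods

## Scope and model

The package analyses calibrated pulse-echo data from a single-element
high-frequency transducer scanning layered gastrointestinal tissue, plus
two satellite analyses (acoustic output of a miniature 4 MHz focused
therapy transducer; TER barrier-function response to insonation). All
imaging inputs are synthetic: a ray-based simulator generates RF A-lines
of plane-layered phantoms, and the simulator's ground truth is the
reference against which the estimators are validated. The simulator is
first-class, tested code, not a fixture.

### Pulse-echo simulation

Each A-line is an impulse train convolved with a Gaussian-enveloped
sinusoidal pulse. The impulse train holds:

* **specular echoes** at every impedance interface, delayed by the
  round-trip time `2·Σ(thickness_i / c_i)` and scaled by the pressure
  reflection coefficient, the two-way transmission products `1 − R²` of
  shallower interfaces, and the cumulative amplitude attenuation
  `10^(−2·α_i·d_i/20)`;
* **diffuse speckle** from Poisson-count point scatterers (per layer, per
  line) with zero-mean Gaussian amplitudes of variance
  `backscatter_strength`, subject to the same transmission/attenuation
  law. The expected backscattered *energy* is therefore proportional to
  `backscatter_strength`, which is the property the backscatter-coefficient
  tests exploit;
* optional additive white Gaussian RF noise.

The model carries no diffraction, focusing, multiple scattering or
nonlinearity; the incident amplitude is a single scale shared by all
depths. Echo placement rounds to the nearest sample, so arrival-time
error is at most half a sample period.

Defaults (chosen once; the source data report none of them): imaging pulse
48 MHz with 50% −6 dB fractional bandwidth, sampled at 400 MHz; coupling
medium dPBS (Z_w = 1.48 MRayl, c = 1480 m/s); tissue sound speed
1540 m/s; fused-quartz reference Z_q = 13.1 MRayl; transducer half-angle
θ_T = arcsin(2.5/15) from the focused-bowl geometry (5 mm aperture, 15 mm
radius of curvature). The stock phantom is a 2 mm mucosa/submucosa band
(Z = 1.60 MRayl, α = 1.86 dB/mm — the ex vivo average the estimators must
recover) over a quieter muscularis on agar. Scatterer density defaults to
200/mm²: about six scatterers per axial resolution cell per line, enough
for fully developed speckle (a Rayleigh envelope), which the speckle model
exists to provide. Scan geometry defaults to 61 lines at 0.5 mm pitch
(a 30 mm lateral span).

Interface transmission losses are included by default but can be switched
off (`include_transmission=False`), because the substitution attenuation
relation ignores them; the exact-recovery tests use the off mode, and in
the on mode the recovered α carries a small positive offset of
`−20·log10(1−R²)/(2d)` from the slab's surface transmission.

### Segmentation

Envelope = per-line analytic-signal magnitude (Hilbert transform),
log-compressed relative to the brightest pixel of the whole scan. The mask
keeps pixels at or **above** −26 dB (inclusive boundary), is closed with an
elliptical structuring element of radius 2 lines × 3 samples, and the
largest 8-connected component becomes the ROI. The input is padded before
closing so the operation remains extensive at image borders. Depth
conversion uses the assumed sound speed in the scan metadata,
`depth = sample_index · c / (2 f_s)`, 0-based from the image top.
Variable-thickness sub-segmentation retains, per line, the ROI from its
top surface down to the requested thickness (the top sample always
survives, giving a well-defined thickness → 0 limit).

Open choices, resolved and fixed: the envelope (not rectified RF) is
thresholded; the reference level is the whole-scan brightest pixel (not
per line); all defaults are configurable but pinned in the tests.

### Estimators

* **Impedance.** Per line, `V_r` is the signed envelope peak within the
  first 0.2 mm of that line's ROI; the sign comes from the RF polarity at
  the envelope maximum so soft reflectors (Z_t < Z_w) resolve correctly.
  `V_i` is calibrated from the bare quartz echo by inverting the
  impedance relation with Z_t = Z_q. Lines without ROI are skipped, not
  failed. Aggregation uses the population standard deviation (ddof = 0;
  configurable).
* **Attenuation.** The substitution estimate uses envelope peaks of the
  reference-reflector echo with and without the slab, windowed about the
  known echo times. The neper value is always derived from the dB value
  (never stored separately), so `a′ = α/8.686` holds to machine precision.
* **Backscatter coefficient.** The printed formula is grouped as
  geometry factor × energy ratio × gate compensation. The compensation
  `4a′/(e^(−4a′d1) − e^(−4a′d2))` is evaluated via `expm1`, is continuous
  at a′ = 0, and equals `1/(d2−d1)` there. Gates are each line's ROI
  extent; `d1`/`d2` are the whole-mask depth extremes; the reference
  energy integrates the full quartz record. Integrals are discrete sums
  × sample period. `R_q` enters squared.

### Transducer output arithmetic

`W_input = V_pp²/(8Z)` — the mean power of a sinusoid into a resistive
load. The transducer's electrical impedance magnitude at 4 MHz was never
measured directly; `V_pp²/(8·W_input)` across the ten bench drive levels
is constant to ~0.5%, and its least-squares value, 49.2 Ω, is shipped as a
documented constant with a refit function as the test oracle. Intensity is
the spatial average over the −6 dB beam disc. MI uses the underated
regulatory form; the bench dataset's printed MI values appear truncated
rather than rounded, so comparisons allow one unit in the last printed
digit. The table builder flags (does not reject) rows where P_ac exceeds
W_input, and marks efficiency/intensity absent where the force balance
could not resolve the acoustic power (1–2 V_pp). The
radiation-force-balance conversion defaults to the physics factor `g·c`
(water, 20 °C) when no temperature-specific calibration factor is given.

### TER analysis

`TER = (Res − Res_control)·Area`; default membrane area 1.13 cm² (12-well
insert; the plate format is named in the source, the area is the vendor's
standard value). Barrier readiness is the inclusive 500–1000 Ω·cm² window.
The baseline is the mean of all pre-insonation samples (a window average,
reducing to the single initial reading when the window holds one sample);
the drop is baseline → post-window minimum; recovery is the first time
after the minimum at which TER re-attains baseline within a 1% tolerance.
Per-well drops are computed first and averaged per condition (rather than
dropping the averaged curve).

The TER generator models an abrupt fractional dip at insonation with an
exponential return whose time constant is chosen so baseline is re-attained
within 1% exactly at the configured recovery time (5.5 min by default,
inside the observed 5–6 min window). Condition means default to 0%,
2.94% and 5.52% for MB-only, US-only and US+MB. Stochasticity has two
levels: per-well response magnitude (Gaussian around the condition mean,
relative SD 20%, truncated to [0, 0.99]) and iid Gaussian measurement
noise on the readout. The Monte-Carlo calibration test (50 wells per
condition) isolates the biological level and sets measurement noise to
zero, deliberately: the drop statistic is a post-baseline *minimum*, an
extreme-value statistic that is positively biased under any iid
measurement noise, so a noisy-meter configuration cannot recover a 0%
truth no matter the sample size. That bias is a known limitation of the
minimum-based drop definition, visible in the MB-only arm whenever
`noise_sd > 0`.

## What the synthetic data does and does not show

The generator reproduces the features the estimators rely on — interface
timing and amplitudes, Beer–Lambert amplitude attenuation, energy-linear
fully developed speckle, reference-echo geometry — with exact ground
truth. It does not emulate diffraction/focusing, frequency-dependent
attenuation, coherent layer microstructure, electronic ringdown, or
biological variability between samples. Passing tests therefore
demonstrate correctness of the analysis chain under its own stated model,
not field performance on real tissue; in particular the real-data error
bars (e.g. ±0.72 dB/mm across slab samples) have no synthetic
counterpart.

## Test fixtures and problem sizes

Fixtures are generated at test time. The segmentation-overlap check runs
on the stock bright-band phantom (61 lines) and requires IoU ≥ 0.95
against the geometric band extent. Impedance recovery uses a homogeneous
weak-scattering slab (speckle ~20 dB below the surface echo): the
surface-echo amplitude picker is unbiased only when the surface echo
dominates local speckle, and with strong speckle the envelope-peak picker
can even flip the echo polarity. Backscatter ratio tests use
coupling-matched phantoms (no specular echoes) so the gated energy is pure
backscatter — with a surface echo inside the gate, the energy ratio of two
phantoms is no longer the ratio of their backscatter strengths. Scan
simulations complete in well under a second each, and the whole suite in a
few seconds.

## Numerical conventions

Population (n) standard deviations for error bars; inclusive thresholds
and readiness bounds; 8-connectivity for components, ties broken to the
first label in scan order; nearest-sample echo placement; `expm1` for the
BSC compensation; one `numpy` Generator per simulation seeded from the
caller's integer, with identical (config, seed) giving bit-identical
arrays and (through timestamp-free HDF5 and sorted-key JSON writers)
byte-identical files.
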