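# Methods

This note documents the physical model behind `mrtdose`, the approximations
it makes, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate.

## Source spectrum

The bending-magnet source is the vertically integrated Schwinger spectrum:
photon flux per unit horizontal angle and 0.1% bandwidth
∝ E_e I G₁(y), with y = E/ε_c, ε_c = 0.665 E_e²[GeV] B[T] keV and
G₁(y) = y ∫_y^∞ K₅⁄₃(x) dx.  For the default ring (2.4 GeV, 1.45 T,
160 mA) ε_c ≈ 5.55 keV.  Conversions: per-keV flux divides the
per-bandwidth value by 10⁻³E, so the *photon* spectrum diverges softly
(∝E^(−2/3)) toward low energy while E·Φ(E) has the familiar single broad
maximum — all quoted "flux" is per keV.  The spectrum is integrated over
the stated vertical acceptance; its vertical angular dependence is ignored,
which is benign because hard filtration dominates the shape.  The default
grid is 5–150 keV in 0.5 keV steps; outside it the filtered flux is
negligible (below 5 keV the 3.5 mm Al filter transmits < 10⁻²⁰).

**Mean energy is flux-weighted** (photon-number weighting), matching the
use of the spectrum as a Monte Carlo source term.  A power-weighted mean
(each photon weighted by its energy) would be ~2 keV higher; the
convention is a documented choice, not a physical claim.  The filtered
(2 mm Be + 3.5 mm Al) mean energy evaluates to 28.2 keV, consistent with
the nominal "approximately 30 keV".

## Attenuation data

Packaged tables (5–150 keV, ≥48 log-spaced nodes, log–log interpolation)
cover beryllium, aluminium, tungsten, water and air with total,
photoelectric, incoherent and coherent mass attenuation coefficients.
Provenance (see `scripts/build_material_tables.py`): totals are anchored on
transcribed standard-reference tabulations; incoherent partials come from
the exact Klein–Nishina cross section with a binding correction built from
Molière/Thomas–Fermi form factors (hydrogen exact); coherent partials from
the same independent-atom form factors; photoelectric is the residual at
low energy joined to a log–log power law at high energy, with the sum
identity exact at every node.  Totals are accurate to ~1–2% (pinned by
tests at 10/30/60/100 keV for all five materials), partials are
model-grade (~5%).  Tungsten's L and K edges are represented by
duplicate-energy nodes; tungsten precision is uncritical since 8 mm of
lamella is opaque (transmission < 10⁻¹⁵⁰ at 30 keV).

## Collimator geometry

The MSC is an ideal periodic comb: 74 slits of 50 µm at 400 µm pitch in
8 mm-deep tungsten, centred on the beam axis 15.5 m from the source (the
even slit count places the 20-beam experimental array symmetrically about
the axis; a horizontal aperture of 8 mm selects it).  Tungsten path
lengths are computed analytically from the linear ray sweep across the
comb — validated against a 1 µm step-march oracle to <0.5 µm — and rays
through off-axis slits walk laterally by depth × x/15.5 m, narrowing the
effective opening: ≈42 µm at the ±15 mm acceptance edge vs 50.0 µm on
axis.  Effective widths are quoted at the collimator plane ("nominal");
the geometric magnification to the sample plane (≈1.019) is applied when
`frame="projected"`.  Lamella manufacturing error, yaw and slit-edge
scattering are not modelled.

## Monte Carlo transport

Photon histories are sampled from a Gaussian source (horizontal angular
FWHM 7 mrad; vertical width set so the beam at the sample has the observed
1.5 mm FWHM; source size σ_x = 0.1 mm, σ_y = 0.02 mm).  Transport:

* **Collimator and air** — deterministic attenuation (implicit capture):
  the photon weight is multiplied by exp(−μ_W path) and the 30 cm air
  transmission.  Collimator scatter and fluorescence are not modelled.
* **Air scatter** — a single-scatter cohort: the flux removed from the
  primaries by scattering attenuation in the 30 cm air path is re-injected
  as Compton/Rayleigh-scattered photons sampled along the path and tracked
  into the phantom.  Air scatter is ~0.8% of the beam vs ~2% in-water
  interaction probability, i.e. not negligible for the valley.
* **Phantom** — a water slab: 1.2 mm water-equivalent entrance layer (the
  polystyrene bottom of a typical 24-well plate, through which the beam
  reaches the plated cells) followed by the 1 mm scored layer.  Energy is
  scored depth-integrated over the scored layer only, in 5 µm (horizontal,
  the microbeam-modulated axis) × 100 µm (vertical) voxels.  The vessel
  layer matters: its scatter is a structural contributor to the valley
  dose — without it the simulated PVDR rises from ~130 to ~320.
* **Interactions** — analogue branching by tabulated partials:
  photoelectric deposits locally; Compton samples Klein–Nishina (Kahn
  rejection) with an incoherent-scattering-function rejection for water,
  deposits the recoil locally and tracks the scattered photon until
  escape from the phantom box or the 5 keV cutoff (then deposited
  locally); Rayleigh redirects using the packaged water form factors.
  Doppler broadening and electron transport are not modelled.
* **Kerma approximation** — secondary electrons deposit at the interaction
  site; an optional lateral Gaussian blur (default σ = 5 µm, about one
  CSDA range at these energies) approximates electron spread.  This is
  the main simplification relative to a full condensed-history code and
  the stated reason the PVDR acceptance band is wide (±15).

**Variance reduction.**  Two unbiased devices: (i) *slit-angle importance
sampling* — horizontal angles are drawn only from the slit-subtending
windows (plus a 2 µm margin), with the exact per-photon window probability
(≈0.0098) as statistical weight, so one sampled history represents ~100
analogue histories; (ii) *forced first interaction* — primaries always
interact in the phantom, weighted by the interaction probability, with the
depth from the truncated exponential (pointwise unbiased even where the
slab is laterally truncated).  `n_histories` always counts
analogue-equivalent ("effective") histories; with importance sampling on,
the sampled count is n_eff × window probability.  10⁹ effective histories
run in ~30 s on one CPU.

**Uncertainties.**  Per-voxel standard errors come from ≥2 independent
batches (default 10) with child RNG streams of one master seed.  Regional
quantities (peak, valley, PVDR) are *not* assembled from per-voxel errors
— voxels within a batch are spatially correlated through the scan
superposition, the electron blur and multi-deposit scatter tracks, which
makes voxel-pooled errors underdispersed by an order of magnitude.
Instead, region means are computed per batch and their spread across
batches gives the error; the PVDR error includes the peak–valley batch
covariance.

## Scanned field and absolute dose

The sample moves vertically at constant speed through the 1.5 mm (FWHM)
Gaussian-profiled beam.  Because the model is vertically
translation-invariant, the scanned field is the superposition of the
static field at 100 µm source offsets — and the offsets must span the
*full* vertical extent of the static grid, not just the Gaussian envelope:
the valley's scatter halo extends several mm beyond the envelope, and
clipping the scan range at envelope ±3σ would bias the valley low by
~20%.  The default static grid is therefore ±6 mm tall.  The scanned
field is vertically uniform over the 1 mm sample to <0.1%.

Absolute dose is anchored to measurement, not to simulated fluence: the
dose-on-sample formula D = (beam height / speed) × dose rate gives
1.5/1.638 × 70 = 64.1 Gy ("approximately 65 Gy"), and the scanned grid is
rescaled so the central ±20 µm peak region reads this value.  The PVDR is
invariant under this rescaling.

## Profile analysis

Peak dose: mean over ±20 µm about each beam centre (centres from local
maxima with 3-point parabolic refinement, spacing checked against the
400 µm pitch).  Valley dose: mean over the central 100 µm between
adjacent centres — symmetric, penumbra-free at this pitch, and exposed in
config since the valley-region width is a convention.  The headline PVDR
is reported for the beam nearest the field centre, where the valley is
highest (most conservative); the array-averaged PVDR is ~8% higher
because edge valleys receive less lateral scatter.  At 3 × 10⁹ effective
histories the model gives a central-beam PVDR of ≈134 ± 2 with a valley
of ≈0.48 Gy at the 64.1 Gy peak — inside the reference band (123 ± 15)
once the kerma simplification is allowed for, with the residual excess
plausibly from unmodelled collimator scatter, downstream backscatter and
electron transport.

## Film dosimetry

Net optical density netOD = log₁₀(I_ref/I), clipped at zero; saturated
pixels are flagged.  Calibration uses the monotone rational model
D = a·netOD + b·netODⁿ (n fixed, default 2.5; a, b ≥ 0 fitted by least
squares), which is invertible by construction; the inverse is evaluated by
monotone interpolation.  The study's five-point synchrotron calibration
values are unpublished, so canonical synthetic curves per film type
(EBT3: 0.1–20 Gy; HD-V2: 10–1000 Gy) stand in — they are labelled
synthetic and only used as generator ground truth and defaults.  Dose maps
flag out-of-range pixels (NaN) rather than extrapolate.  Peak-region
analysis pools ≥2 regions of 40 µm × 100 µm per beam.  Analysis is
single-channel, emulating a grayscale microscope readout; an orthovoltage
"fine-tuning" curve can be represented as a second calibration but is not
blended by default.

## Synthetic data

The film generator renders the truth dose comb (beam width, pitch, count,
peak/valley levels, flat or Gaussian vertical envelope, optional 10 µm
edge feature), blurs it with the film PSF (σ = resolution FWHM/2.355:
≈10.6 µm for EBT3, ≈2.1 µm for HD-V2), maps dose → netOD → intensity
through the calibration, adds multiplicative (CV 1%) and additive
(σ = 100 counts) intensity noise and quantizes to 16 bits.  It reproduces
the resolution asymmetry of the two films: a 10 µm edge feature survives
HD-V2 but is washed out by the EBT3 PSF.  What these tests show is that
the *analysis* recovers known truth through a realistic response chain;
they do not validate film energy dependence, lateral scanner response or
darkening kinetics, which are not modelled.

Cell counts are lognormal around the condition mean (control, and
control × survival), with a common CV (default 0.1) and n = 3 replicates —
emulating the study conditions (survival ≈20.5% at 24 h, ≈23.5% at 72 h).
The real replicate dispersion is only published as SEM error bars, so the
CV is a free, documented parameter.

## Survival statistics

The survival fraction is mean(treated)/mean(control) with first-order SEM
propagation.  Because the noise model is multiplicative with a common CV,
log counts are normal with equal variances, and the **pooled (Student)
two-sided t-test on log counts** is the exact location test; it is the
default.  On raw counts the control variance dominates and the
Welch–Satterthwaite df collapses to ~2, capping attainable p-values near
5 × 10⁻³ at n = 3 — incompatible with p ~ 10⁻⁴ outcomes.  Welch and
Student on raw counts and a permutation test (whose two-sided p at
n = 3 + 3 cannot go below 0.1) remain available as sensitivity checks.
Simulated power of the default test at α = 0.001 under the study
conditions is >99%; type-I error at α = 0.05 is verified nominal over
2000 null simulations.

## Problem sizes and determinism

Defaults were chosen so every stage is a desk-scale computation: the test
suite runs ~10⁹ effective histories in total (~25 s); the acceptance
script uses 3 × 10⁹ for the PVDR (~2 min) and measures the uncertainty
scaling at 10⁶–10⁸ before extrapolating to the production-scale 3 × 10¹⁰.
All randomness flows from one master seed through `numpy` SeedSequence
spawning; identical configurations produce byte-identical JSON summaries.

## Known limitations

No electron transport (kerma + blur), no collimator scatter or tungsten
fluorescence, no Doppler broadening, no downstream backscatter geometry,
air treated as attenuator + single-scatter source, vessel reduced to a
water-equivalent flat layer of assumed 1.2 mm thickness, independent-atom
coherent form factors, and attenuation partials of model grade.  The PVDR
is the quantity most sensitive to these simplifications; peak-side results
(mean energy, scan dose, peak flatness, geometry) are insensitive to them.
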