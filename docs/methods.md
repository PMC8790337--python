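# Methods

## Poroelastic injection-transport model

An intravitreal injection of volume *V* creates a spherical bolus of
radius *a* = (3*V*/4π)^(1/3) inside a vitreous of radius *R*₀. The vitreous
is modelled as a poroelastic medium in the Biot-consolidation sense: the
injection locally raises pore pressure by *P*₀, and the overpressure drives
Darcy flow that relaxes pressure back to baseline while advecting injected
material. The implemented scaling quantities are

- advection relaxation time τ = *f* (*R*₀ − *a*)³ / (*a* κ *P*₀) [s]
- Darcy velocity scale *V*₀ = κ *P*₀ / *R*₀ [cm/s]
- transport length *L*₀ = τ · *V*₀ [cm]

with *f* the fluid volume fraction (≈1 for the highly porous vitreous), κ
the hydraulic permeability (8.4×10⁻⁸ cm⁴ dyn⁻¹ s⁻¹, measured for bovine
vitreous) and *P*₀ estimated from ocular rigidity: IOP rises by ≈1 mmHg per
µl of added volume, so a 50 µl bolus gives a *lower bound* of 50 mmHg =
6.7×10⁴ dyn cm⁻². Everything internal is CGS; clinical inputs (µl, mmHg)
pass through explicit converters with 1 mmHg = 101325/760 Pa =
1333.22 dyn cm⁻².

**Formula form.** The τ expression is implemented without a factor 3 in
the denominator. With the reference inputs the implemented form yields
705 s while the 3*a*-denominator variant yields 235 s; the reference
parameter set is only arithmetically consistent with the no-3 form, which
is therefore the one fixed here (`FORMULA_VERSION` records the choice).
Note that *P*₀ cancels in *L*₀ = τ·*V*₀, so the transport length is
independent of the injection overpressure; the degenerate limits *P*₀ = 0
(τ = ∞) and *a* = *R*₀ (τ = 0) return sentinels rather than raising,
because parameter sweeps legitimately touch them.

**Numerical oracle.** `simulate_relaxation` provides an independent check
of the closed form. It solves the spherically symmetric quasi-static Darcy
drainage problem on *r* ∈ [*a*, *R*₀] — a step change to *P*₀ held at the
bolus surface, zero overpressure at the outer boundary, diffusivity
κ*P*₀/*f* (the injection overpressure is the only stiffness scale the
parameter set supplies) — by explicit finite differences, and then
measures the *advective transit time* of a fluid element carried from the
bolus edge to the outer boundary through the relaxed velocity field,
∫ *f* d*r* / (κ |∂*p*/∂*r*|). This is the operational meaning of τ (the
characteristic time for injection-driven advection), and the measured
transit agrees with the closed form within a geometric factor of ≈2 across
parameter sweeps (exactly, the ratio is 3*R*₀(*R*₀−*a*)²/(*R*₀³−*a*³),
independent of *f*, κ and *P*₀). We deliberately do **not** use the decay
time of mean bolus pressure as the oracle statistic: for a freely decaying
initial bolus the pressure e-folds on the local diffusion scale
*a*²·(*f*/κ*P*₀), two orders of magnitude faster than τ, and a fit to it
validates nothing about the advection scaling. The oracle is an
order-of-magnitude validator only; its contract is agreement within a
factor of 5, not precision.

Out of scope by design: the finite-domain elastic-shell extension of the
consolidation theory, hindered macromolecular transport, and anatomically
realistic 3-D flow.

## Outflow facility and inclusion

Enucleated eyes perfused at constant flow *F* = 2.4 µl min⁻¹ (the
physiological aqueous production rate) reach a steady IOP set by the
outflow resistance; facility is *C* = *F*/IOP with **no episcleral venous
pressure term** — EVP does not exist ex vivo, so the Goldmann correction
is intentionally absent. Transiently non-positive pressures (the anterior
chamber depressurizes briefly during aqueous sampling) are masked to NaN,
not treated as errors.

Inclusion gating admits an eye when facility over the final 30 min
stability window stays inside the species band (pig 0.18–0.35, human
0.18–0.40 µl min⁻¹ mmHg⁻¹, stored canonically as (min, max)) and shows no
trend: |mean of last third − mean of first third| / window mean ≤ 10%.
The trend form is used instead of the window's peak-to-peak range because
transducer noise with ~3% CV spans 4–5σ peak-to-peak over a 30-sample
window and would flag perfectly stable eyes; the 10% bound itself is a
package convention (no quantitative stability rule accompanies the
published bands). Drug response (e.g. cytochalasin D) is quantified as
(treated post/pre facility ratio) / (contralateral post/pre ratio) around
an intervention timestamp with a 30 min baseline.

## Bead quantification

Stock bead counts follow beads ml⁻¹ = 6*S*·10¹²/(ρπφ³) (*S* solids g/ml,
ρ polymer density g/ml, φ diameter µm). The reference 20 nm and 2000 nm
stocks carry vendor-stated counts (4.143×10¹³ and 1.326×10⁸ beads ml⁻¹)
as data; the formula evaluated at nominal 2% solids and ρ = 1.055 does not
reproduce them (the vendor values reflect per-lot solids loadings), so the
two routes are kept independent rather than reconciled.

Standard curves are ordinary least squares with a **free intercept**
(plate readers have background fluorescence; forcing the origin would
bias low-end inversion). Readings at or below the fitted intercept clamp
to zero concentration with a below-background flag — negative bead counts
are not physical. Dispersion rates are OLS slopes of concentration vs
sampling time; by default only measured timepoints enter the fit (the
experimental design samples at 2 h and 4 h), with an optional
`anchor_origin` flag adding an implicit (0, 0) point. Percent-of-injected
normalization requires the anterior-chamber volume explicitly (≈250–300 µl
for pig/human is a literature convention, not measured here; no silent
default). Known unmodelled effect: the 2 h draw (30–40 µl) and reservoir
refill slightly dilute the 4 h sample; no correction is applied.

## Synthetic-data generators

All generators are bit-reproducible given (parameters, seed); one
run-level seed fans out to independent per-stage substreams (CRC32 of the
stage name mixed into the seed sequence).

- **Pressure traces**: *P*(*t*) = *F*/*C* + drift·*t* + AR(1) noise
  (autoregression 0.9, stationary sd 0.3 mmHg by default) — AR(1) for
  physiological smoothness.
- **Bead kinetics**: two-compartment mass balance. The vitreous depot
  loses beads at first-order rate *k*; the chamber (volume 250 µl)
  accumulates them, optionally losing beads to aqueous turnover
  (`washout_rate`); each timed draw removes its sample volume at the
  current concentration. The linear ODEs are integrated in closed form
  between events, so the noiseless ledger conserves beads to machine
  precision. Measured concentrations carry unit-mean multiplicative
  lognormal noise (CV 5% default — plate-chemistry convention). The
  default configuration sets bead washout to zero: observed anterior
  accumulation is near-linear over the 4 h horizon, which implies beads
  reaching the chamber are not appreciably cleared by fluid turnover on
  that time scale (turnover at 2.4 µl min⁻¹ would visibly saturate the
  curve). Default transfer rates (pig 4×10⁻³ h⁻¹ / 1.9×10⁻⁴ h⁻¹ for
  20 nm / 2000 nm; human 1.5×10⁻³ / 2.7×10⁻⁴) place the fitted rates at
  the reported orders of magnitude (10¹⁰ vs 10³ beads ml⁻¹ h⁻¹) with a
  ~10⁶–10⁷-fold size separation. Note that with the reported doses, the
  2000 nm channel reaches ~0.07% of injected dose at 4 h — "near
  baseline" relative to the percent-level 20 nm channel, but not
  literally zero.
- **Plate readings**: linear response times unit-mean lognormal noise
  (CV 2% default).
- **Particle fields**: non-overlapping disks (rejection sampling, packing
  error if the field is too crowded), lognormal diameters (median 15 µm /
  log-sd 0.25 for the milled 10–20 µm population; median 7.5 µm for the
  5–10 µm population), additive Gaussian background at the stated SNR,
  clipped at zero. Ground truth is returned alongside every image.

What the generators do **not** emulate: spatial transport in the vitreous
(only the transport module's oracle covers the radial physics), bead
adhesion/settling, spectral crosstalk between fluorophores, autofocus and
illumination artefacts, and touching/overlapping particles. Passing tests
therefore demonstrate that the estimators are correct and unbiased under
the stated noise models — not that real micrographs or real plates are
free of those additional effects.

## Particle detection choices

Global threshold (fixed, or Otsu when unspecified), 8-connectivity,
minimum region area 4 px to suppress shot noise. Touching particles are
not split (no watershed); for sparse spotted fields this under-counts
rarely and is the documented limitation of the simple counting approach.
Equivalent diameter is pixel_size·√(4·area/π). Summaries over replicate
images average per-image counts (≥3 images per sample by default; fewer
is allowed only explicitly and warns) and pool diameters.

## Problem sizes and numerical settings

The relaxation oracle defaults to a 64-point radial grid with explicit
time steps at 0.2× the diffusion-stability limit and an
8·(*R*₀−*a*)²/(π²·D) horizon (~0.1 s per solve); parameter-recovery
checks use 50–200 seeds; planted-field detection uses 384–512 px images
with 20–50 disks. These sizes give sub-percent Monte-Carlo error on every
asserted mean while keeping the full suite fast.

## Acceptance reporting

`scripts/acceptance.py` rebuilds the reference parameter set from clinical
inputs (50 µl, 1 mmHg µl⁻¹, κ = 8.4×10⁻⁸, *R*₀ = 1.2 cm), evaluates τ and
*V*₀, and writes them at the reported precisions (3 and 2 significant
figures). The computation is deterministic; the `--seed` argument exists
for interface uniformity.
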