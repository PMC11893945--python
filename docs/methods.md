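# Methods

## Scope and model overview

`microdsb` estimates DNA double-strand-break (DSB) induction and cellular
S-values for lymphocytes suspended in a radioactive blood vial, using a
two-stage Monte Carlo pipeline: a macroscopic transport stage that carries
decay emissions through the vial and scores a phase-space at each cell
surface, and a microscopic damage stage that converts nucleus-crossing
particles into clustered strand breaks. The physics is a deliberately
simplified, fully documented stand-in for condensed-history and
track-structure codes; the damage bookkeeping (sensitive-volume thinning,
damage-probability ramp, DBSCAN clustering, dose-normalized metrics) is
implemented exactly.

## Geometry

* Vial: water-equivalent sphere of 8 cm³ (radius 1.2407 cm) by default; an
  8 cm³ sphere is also the reference geometry against which published S-value
  benchmarks for this volume are quoted. An equilateral cylinder of the same
  volume is available for sensitivity checks (`vial_shape="cylinder"`).
* Cells: 1000 spheres of radius 3.75 µm with concentric nuclei of radius
  3.1 µm, placed i.i.d. uniformly with non-overlap enforced by rejection
  (physical cells cannot interpenetrate; at a packing fraction of ~3×10⁻⁵
  rejection is essentially free). Placement is reseeded per seed so the
  five-seed spread includes geometric variability.
* Cold source: decay positions are uniform over the blood, i.e. the vial
  minus the cell spheres — cells carry no activity, so there is no
  self-irradiation.
* Blood mass 8 g, nucleus mass 1.248×10⁻¹³ kg (volume 124.8 µm³ at
  1 g/cm³).
* DNA sensitive volume: one cylinder of radius 1.1 nm and length
  0.34 nm/bp × 6.4×10⁹ bp ≈ 2.2 m, volume ≈ 8.3 µm³; divided by the nucleus
  volume this gives a sensitive fraction of 0.066, used in the damage model
  at the conventional rounded value **f = 0.07**.

## Decay chains

One simulated particle history corresponds to one *nuclear transformation*
of the parent. All retained daughters are assumed to decay promptly with the
parent, so a transformation emits the whole retained chain's inventory with
effective intensities = line intensity × occurrence factor (product of
branching fractions along the path). Chains are truncated at daughters with
half-life above 15 days and at the conventional explicit cut points
(Rn-222→Pb-210, Ra-226→Po-210, Th-232→Ra-228, Np-237→Pa-233, Pu-238→U-234,
Pu-239→U-235, Am-241→Np-237, Cm-244→Pu-240, Cf-252→Cm-248, Ra-228→Th-228,
Ac-225/Bi-213→Bi-209, At-211 excludes Bi-207); where the two rules could
disagree for a user-supplied nuclide, the explicit list wins. Transient- or
secular-equilibrium kinetics are not simulated: all reported quantities are
per parent transformation with the full retained chain. The Cf-252
spontaneous-fission branch (3.09%: neutrons, fission fragments) is omitted;
only charged-particle and photon emissions are modeled, and anti-neutrinos
are never generated.

Emission data are shipped as two TSV fixtures: a *paper-anchored* table
whose numeric values are exactly the published ones used by the acceptance
checks, and an *extended* convenience table compiled by hand in the style of
standard decay-data compilations (approximate mean/line energies; see its
provenance header).

## Macroscopic transport

* **Alphas** travel straight CSDA tracks: range R(E) = ∫dE′/S(E′) from a
  1 keV cutoff, residual energy E(R−s) after a path s. Lateral straggling is
  neglected — alpha tracks in water are nearly straight over their 25–90 µm
  ranges, which preserves chord statistics.
* **Electrons** use the same straight-track CSDA contract with a
  configurable *detour factor* δ ≤ 1 multiplying the geometric path length
  (default δ = 1.0, i.e. no multiple-scattering shortening — the dominant
  desk-scale simplification; reducing δ shortens penetration and reduces
  wall escape). Beta energies are drawn from the analytic spectrum
  E^α(E_max−E)², a scaled Beta(α+1, 3) law with α chosen so the spectrum
  mean equals the tabulated mean energy.
* **Photons** propagate with exponential attenuation; at the first
  interaction point the full photon energy is handed to a secondary electron
  (kerma approximation, forward direction) and the photon history ends;
  photons leaving the vial deposit nothing.
* **Scoring**: each particle is scored at most once per cell, at its first
  intersection with the cell sphere, carrying its residual energy there. All
  per-cell phase-spaces are pooled into one store, which is the micro-stage
  source.
* **Stopping-power and attenuation tables** are shipped TSV fixtures —
  smooth hand-built tabulations consistent with published range–energy
  anchors for water (alpha CSDA ranges ≈ 26 µm at 4.081 MeV, ≈ 47 µm at
  6 MeV, ≈ 89 µm at 8.954 MeV; Bragg-peak stopping ≈ 250 keV/µm near
  0.7 MeV; electron ranges ≈ 3.9 mm at 0.93 MeV and ≈ 1.1 cm at 2.28 MeV).
  They are inputs with provenance headers, not claims of NIST fidelity;
  interpolation is log-log and the range integral uses a dense trapezoidal
  grid (4000 points), cross-checked in the tests against an independent
  trapezoid oracle on the raw nodes.
* **Energy bookkeeping** is exact per decay: deposited + escaped = emitted.

### Source sampling and variance reduction

Analog mode samples decay points uniformly over the blood. For alpha chains
the default is an unbiased stratification ("importance sampling"): decay
points for record generation are drawn only from the spherical shells
r_cell < |x−c_i| < R_max + r_cell around the cells — the only region from
which an alpha can reach any cell — and each sampled decay carries the
weight N·V_shell/(V_blood·m(x)), where m(x) is the number of active shells
containing x (overlaps are rare and handled exactly; points inside another
cell or outside the vial get weight 0). This is provably unbiased because
points outside the active region cannot produce records; the tests verify
analog/importance agreement on a miniature vial. Because the active region
is not representative of the whole blood volume, the blood-dose tally under
importance sampling is computed from a separate analog position sample
(capped at 2×10⁵ positions; the only positional effect on blood dose is wall
escape). The cold-cell excluded volume (≈3×10⁻⁵ of the vial) is neglected in
the dose tally.

## Microscopic damage model

The track-structure stage is replaced by a one-parameter Poisson event
model. For each phase-space particle whose ray reaches the nucleus:

1. The in-nucleus path is min(geometric chord, residual CSDA range at
   entry); tracks may end inside the nucleus (Bragg end).
2. Energy-deposition events form an inhomogeneous 1D Poisson process along
   the path with local density LET(E(s))/⟨ε⟩ (CSDA-updated LET; 0.05 µm
   steps). Event energies are i.i.d. exponential truncated at 500 eV with
   the scale solved so the truncated mean equals ⟨ε⟩ — the expected summed
   event energy then equals the CSDA energy loss along the segment exactly
   (Wald identity, verified by test).
3. Each event is in the DNA sensitive volume with probability f = 0.07,
   receives a fair-coin strand label, and becomes a single-strand break with
   probability 0 below 5 eV, rising linearly to 1 at 37.5 eV.
4. SSBs are clustered with DBSCAN (ε = 3.4 nm ≡ 10 bp × 0.34 nm, minimum 2
   points; scikit-learn implementation, verified against a brute-force
   pairwise-connectivity oracle). A cluster is a DSB only if both strand
   labels occur (`require_both_strands=True` by default; the published DSB
   definition says only "two SSBs", but density-based SSB clustering as
   implemented in track-structure toolkits distinguishes strands, so the
   strict rule is the default with a config switch). Base-pair separation is
   identified with Euclidean distance via 0.34 nm/bp.
5. The experimental selection threshold marks tracks with path > 0.75 µm
   and ≥ 7 DSBs ("at least seven" — the inclusive reading is adopted where
   wording varies).

Per-track RNG streams are spawned from the run seed by track index, so
per-track results are reproducible regardless of processing order.

### Calibration of ⟨ε⟩

⟨ε⟩ — the mean energy per deposition event — is the model's only free
parameter. It is fixed **once** by requiring that a Ra-223 alpha source (the
parent's mean alpha line, 5.667 MeV at 100% intensity) reproduce the
experimentally validated DSB linear density of 9.6 DSB/µm with the default
geometry and damage parameters; the solved value ⟨ε⟩ = 86.7 eV ships as the
package default and is never re-tuned per nuclide. The anchor uses the
nuclide's own alpha line, parallel to how the Th-232 and Cf-252 density
predictions use their single printed lines: DSB linear density is a
per-track, LET-driven quantity, and the full Ra-223 chain's range-weighted
alpha energy (≳6.6 MeV) would exceed Cf-252's 6.219 MeV line, making the
physically expected LET ordering (Cf-252 < Ra-223 < Th-232) unrepresentable
under any LET-monotone damage model anchored on the chain.
`microdsb.calibration.calibrate_default_event_mean` reruns the calibration
(deterministic objective via fixed seeds, Brent root finding).

### S_Lymph accounting

Nucleus energy deposition uses the CSDA energy loss over the in-nucleus
segment (identical expectation to summing the sampled event energies, lower
variance). For alpha chains only alpha depositions are counted in
S_Lymph←Blood; for beta/gamma chains, electron depositions (including
photon-induced secondaries) are counted. S_Blood←Blood uses the simulated
blood tally, so escape affects numerator and denominator consistently.

## Metrics, uncertainties and problem sizes

All damage metrics are ratios of weighted totals: DSBs·cell⁻¹·mGy⁻¹ =
ΣwᵢDSBᵢ/(N_cells × dose), DSBs/µm = ΣwᵢDSBᵢ/Σwᵢℓᵢ (robust to very short
tracks; with this accounting the identity dsb/cell/mGy = tracks/cell/mGy ×
dsb/µm × mean path is exact). Runs use five independent seeds; results are
reported as mean ± k·SD with k = 2, and the relative uncertainty of the
nucleus deposition is checked against a 5% target — an unmet target is
flagged in the manifest and logs, never silently dropped.

Default problem sizes are chosen for single-CPU, minutes-scale runs:
10⁶ weighted transformations per seed for track-rate/S_Lymph quantities and
2–4×10⁵ per seed for DSB-density runs, giving per-seed relative SDs of 1–3%
on the alpha metrics. Analog beta/gamma runs at these budgets give a solid
blood tally but sparse cell-crossing statistics (the electron crossing rate
is ≈2×10⁻⁵ per decay by the fluence identity), so beta S_Lymph values are
reported with the uncertainty flag raised; published-scale runs used 10⁹-
scale budgets for exactly this reason.

## What the synthetic data emulate — and what they do not

The synthetic module generates every input the pipeline needs offline:
nuclide fixture tables, isotropic-flux phase-spaces with known chord
statistics (cosine-law entries reproducing the 4r/3 mean chord), and planted
SSB patterns with known cluster counts for clustering oracles. Passing tests
on these inputs validates the geometry, bookkeeping and clustering logic —
not the fidelity of the underlying physics: real track structure has lateral
spread, delta rays, and a non-exponential event-energy spectrum, all of
which are absorbed (imperfectly) into the single calibrated parameter.

## Numerical choices

* Log-log interpolation of stopping powers; 1 keV transport cutoff with
  local deposition below it.
* Poisson event sampling in 0.05 µm steps (≥4 steps per chord).
* DBSCAN cluster output sorted by first-member coordinates for deterministic
  ordering; ties in strand labels impossible (binary labels).
* Seeds: all user-facing seeds are 31-bit; per-stage and per-track streams
  are spawned via `numpy.random.SeedSequence`.
* Degenerate inputs: zero-length chords yield no events; zero alpha tracks
  yield absent (None) alpha metrics rather than zeros; fewer than two seeds
  cannot be aggregated.

## Known limitations

* The one-parameter event model compresses the steepness of the LET→DSB
  relationship relative to full track-structure transport: with the Ra-223
  anchor fixed, the Th-232 density prediction lands near 13 DSB/µm versus
  the published 16.8 (within the model's stated ±30% transfer band), and
  consequently the composite Th-232 DSB yield per cell per mGy computes to
  ≈0.057 against the published 0.0914. Under ratio-of-totals accounting this
  composite is bounded by (fluence-capped track rate) × density × (mean
  chord ≤ 4a/3), so the gap cannot be closed without re-tuning the anchored
  calibration; the package reports the computed value.
* Electron transport ignores multiple scattering unless a detour factor is
  supplied; gamma transport is single-interaction kerma. Bremsstrahlung,
  Auger cascades, neutrons/protons, positrons, DNA repair and chromatin
  geometry are out of scope.
* Nuclide data in the extended table are approximate compilation-style
  values intended for demonstration, not metrology.
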