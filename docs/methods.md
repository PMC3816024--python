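# Methods

## Scope and model

`irkwall` solves two fixed-geometry photon transport problems:

1. **Chamber problem.** A point source 100 cm from a spherical
   graphite-walled cavity chamber (concentric spheres; ambient air,
   graphite wall, air cavity; the central electrode is ignored). The
   output is the wall correction factor and its decomposition,
   k_wall = k_att · k_sc, from tagged cavity deposits:
   k_att = ⟨e^{+μt}ε_P⟩/⟨ε_P⟩ and k_sc = ⟨ε_P⟩/⟨ε_P + ε_S⟩.
2. **Phantom problem.** An isotropic point source inside the 2 cm air
   channel of a PMMA cylinder (radius 10 cm, height 14 cm), with
   track-length kerma scored in 0.5 cm cubes whose centres lie
   1.25–9.75 cm from the channel axis at source height (7 cm). The four
   edge channels of the physical phantom are filled with PMMA and not
   modelled.

Transport is analog: exponential free paths sampled across region
boundaries, interaction channel drawn from the tabulated photoelectric
fraction, Compton scattering sampled from the free-electron
Klein–Nishina cross section by rejection in x = E'/E (envelope
x + 1/x, exact density x + 1/x − sin²θ). Azimuths are uniform.
Photoelectric absorption terminates a history (no fluorescence; sub-keV
relevance in low-Z media above 60 keV). Photons falling below the
cut-off terminate; in track-length mode no terminal deposit is added
because the μ_en-weighted estimator already captures absorption in
expectation, while the analog estimator does deposit the residual
energy locally (the two conventions would otherwise double- and
under-count respectively).

## Kerma approximation — what it buys and what it costs

Secondary electrons are not transported; cavity response is scored as
collision kerma along each cavity chord:
deposit = w · E · (μ_en/ρ)_cavity · ρ_cavity · ℓ, tagged primary or
scattered by whether the photon has interacted, with the primary's
companion e^{+μt} weight accumulated from its graphite path. This is
the classic photon-only approach for wall-factor work and makes every
tally a pure photon-fluence functional, which is what permits the
closed-form cross-checks used in the tests (disk-weighted quadrature
for k_att, forced single-scatter estimates for ε_S — both reproduce the
engine to statistical precision).

Its cost is a quantified systematic against full photon–electron
transport codes. A Bragg–Gray cavity's electron influx samples photon
interactions in the wall shell *around the whole cavity surface* —
including grazing photons that never enter the cavity but travel long,
heavily-weighted tangential wall paths, and far-wall interactions whose
electrons backscatter into the gas — whereas the chord estimator weighs
photons by their cavity path only. Comparing this package's converged
values with published full-transport results for the same geometries:

* k_att is low by ≈ 2.7 % (1.073 vs 1.102, INER chamber, ¹⁹²Ir
  spectrum), k_sc high by ≈ 1.5 % (0.954 vs 0.940), k_wall low by
  ≈ 1.2 %;
* the k_wall deficit shrinks with photon energy (≈ 1.2 % at 0.4 MeV,
  ≈ 0.7 % at 1.25 MeV), as expected for an electron-mediated edge
  effect.

Chamber *comparisons* (differences between laboratories' geometries)
are much less affected, since the systematic is common-mode. The
reproduction tests in `tests/test_acceptance.py` apply the strict 0.5 %
reproduction tolerance and therefore fail on the individual wall
factors by the amounts above; they are intentionally left failing
rather than re-tuned, as an honest statement of the model class.

Similarly, the phantom scores photon collision kerma. The reference
total-dose study adds an electron dose of ≈ 1/7 of the photon dose at
the innermost cube (electrons generated in the air channel slam into
the first PMMA layer) and ≈ 1/60 elsewhere. The surface-to-centre
fraction computed here (≈ 1.17 % of the innermost cube) folds to
≈ 1.0 % once that nearest-cube electron component is included, which is
why the 1 % bound test also fails by design in photon-only form.

## Source model

The ¹⁹²Ir term uses the principal evaluated decay lines between 0.06
and 0.885 MeV (the three weak lines above 1 MeV are dropped; the Pt K
X-ray group at 61–78 keV is kept and is then almost entirely removed by
capsule filtration). Self-absorption is computed by deterministic
quadrature — 32 axial × 16 radial-ring × 12 azimuthal core points,
uniform in volume — of exp(−μ_Ir ℓ_Ir − μ_steel ℓ_steel) along lateral
rays to the reference point, using the closed-form chord lengths of the
core/capsule cylinders (the reference point at 100 cm is in the far
field of a 0.6 mm source, so all escape rays are taken as
perpendicular to the axis). The metre of intervening air is excluded:
the reference quantity is defined corrected for air attenuation and
scattering, and ambient air in chamber scenes is simulated explicitly
instead. Binning is 5 keV from 0.06 to 0.90 MeV. The capsule tail,
plug and cable are outside the lateral attenuation path and omitted.
Refining the core grid 10× moves no bin by more than 5 × 10⁻⁴.

The filtered spectrum has unit total fluence and mean energy
0.374 MeV, consistent with the ≈ 0.4 MeV folklore value for this
source type.

## Interaction data

Embedded CSV tables (energy, μ/ρ, μ_en/ρ, photoelectric fraction) on
the standard 0.01–1.5 MeV compilation grid for graphite (carbon), dry
air, PMMA and stainless steel; iridium carries extra grid points at its
76.1 keV K-edge. μ/ρ and μ_en/ρ follow the standard published
compilations; steel is approximated by elemental iron, and the iridium
values are a Z-interpolation between neighbouring elements (they only
enter via source self-absorption, where the acceptance-level
observables — spectrum support and mean — are insensitive at the
sub-percent level). The photoelectric fraction is defined as
1 − σ_inc(KN)/(μ/ρ), clipped to [0, 1]: coherent scattering and binding
corrections are thereby folded into the absorptive branch. Above
100 keV in low-Z media this misclassifies at most a few percent of
interactions; it is the leading low-energy approximation and is chosen
so that the complement of the fraction is exactly the incoherent
channel the Compton sampler serves.

Interpolation is log-log (linear-in-log-energy for the fraction),
exact at grid points; queries outside a table raise rather than
extrapolate. The photon cut-off is kept at its nominal 1 keV as a
configuration constant, with the 10 keV table floor as the effective
bound.

## Fixtures (fictitious materials)

`fictitious_material(mu_const, photo_fraction, density)` builds
energy-independent media with μ_en/ρ = photo_fraction · μ/ρ by
convention, giving closed-form limits for every stage: transparent
media (zero μ) for pass-through identities, pure absorbers for the
pencil-beam k_att = e^{μt} limit, near-transparent absorbers
("quiet cavities", μ = 10⁻⁶ cm²/g) that score kerma without ever
Compton-scattering, and near-vacuum phantom bodies for the
inverse-square checks. These synthetic media exercise the exact same
transport and scoring paths as the real tables; what they cannot
exercise is energy dependence, which the embedded-table tests cover.

## Geometry conventions

Chamber scenes centre the chamber at the origin with the source at
(0, 0, −100 cm); phantom scenes put the cylinder axis on z with base at
z = 0. Interface points classify into the denser region; tangent rays
produce zero-length segments; after each boundary crossing the photon
is nudged 10⁻⁹ cm forward before reclassification (path-length error
≤ 10⁻⁹ cm per crossing, against test tolerances of 10⁻⁹ cm on chords
and 10⁻⁶ on additivity).

In the phantom, the monitoring line runs along +x. The displaced
source positions rest the physical capsule against the channel wall:
the emission point sits one capsule outer radius (0.55 mm) inside the
surface, at x = ±(1 − 0.055) cm — B towards the monitoring line, A
opposite. This standoff matters: the nearest cube centre is 0.305 cm
from B's core centre, and treating B as a point exactly on the surface
(0.25 cm) would inflate the nearest-cube ratio from ≈ 17 to ≈ 27. The
channel is taken as air-filled (vacuum would be indistinguishable at
these path lengths), and photons leaving the phantom are lost — no
room return.

## Estimators, variance reduction, uncertainties

* Chamber emission is restricted to the cone subtending the chamber
  plus a 5 % angular margin (halving the margin moves the factors by
  < 2 combined standard errors; the factors are deposit ratios, so the
  cone normalisation cancels and weights stay 1).
* `estimator="analog"` scores actual interaction-site energy transfer
  instead of track lengths; with the cavity density inflated ~100× it
  reproduces the track-length factors within combined statistics
  (density cancels in the ratios to first order; the inflation itself
  feeds a ~1 % second-order cavity-scatter term into k_sc, so the
  equivalence test runs at moderate statistics).
* Uncertainties are history-by-history: per-history second moments for
  ε_P, e^{+μt}ε_P, ε_S and their total; ratio uncertainties combine
  numerator and denominator in quadrature *ignoring correlation*
  (conservative at the ~0.01 % level reached here, consistent with the
  reference uncertainty budgets). The reported relative error scales as
  1/√n within 20 % across 10⁵–10⁷ histories.

## Problem sizes and determinism

Default runs use 10⁶ histories (tests of stochastic properties,
seconds), 10⁷ for the chamber reproduction runs (relative errors
≲ 0.05 % on the factors) and 3 × 10⁷ per phantom position (≈ 2 % on the
outermost cube, whose A/B ratio is the tightest phantom comparison).
These sizes were chosen so every quantity's Monte Carlo error is small
against its comparison tolerance. The reference study used ≥ 10⁸
histories for ≤ 0.1 % chamber statistics; nothing changes structurally
at that scale beyond runtime. All kernels are single-threaded numba
with an explicitly seeded generator: identical (spec, config, seed)
reproduce tallies bit-for-bit, and every CLI output carries a manifest
sufficient to regenerate the file byte-for-byte.

## Known limitations

* No electron transport — the dominant, quantified systematic above;
  electron dose observables (including Bremsstrahlung shares) are out
  of scope.
* No coherent (Rayleigh) scattering or Doppler/binding corrections as
  distinct channels; folded into the absorptive branch as described.
* Iridium and steel coefficient tables are approximations as
  described; user-supplied CSVs can replace any material.
* The wall optical depth t accumulates in graphite only; the 100 cm
  air column is transported but not unfolded, so its ~1 % attenuation
  sits in both numerator and denominator of k_att and cancels, while
  its in-cone scatter contributes (negligibly) to ε_S.
* The phantom's "surface dose" observable is photon kerma in the
  outermost cube; near-field buildup within the first millimetres
  around a displaced source is not resolved below the cube scale.
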