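# irkwall

Monte Carlo evaluation of the **wall correction factor** for spherical
graphite cavity chambers used as air-kerma primary standards for HDR
¹⁹²Ir brachytherapy sources, plus a companion study of how far the
delivered dose departs from plan when the source drifts inside a body
cavity (esophagus/bronchus-like) modelled as an air channel in a PMMA
phantom.

It is written for medical physicists and metrologists who want a small,
fully-testable, pure-Python (numba-accelerated) photon transport code
for these two desk-scale problems, rather than a general-purpose MC
system.

## The physics

A graphite-walled cavity chamber measuring the reference air-kerma rate
(RAKR) of an ¹⁹²Ir source reads low because the wall attenuates the
primary photons, and reads high because the wall scatters photons into
the cavity. The wall correction factor separates the two effects:

    k_att  = ⟨e^{+μt} ε_P⟩ / ⟨ε_P⟩        (attenuation)
    k_sc   = ⟨ε_P⟩ / ⟨ε_P + ε_S⟩          (scatter)
    k_wall = k_att · k_sc

where ε_P and ε_S are the cavity energy deposits from primary
(uncollided) and scattered photons, μ the wall attenuation coefficient
at the photon energy and t the wall path the primary traversed before
entering the cavity. The simulator emits photons from a point source at
100 cm into the cone subtending the chamber, transports them through
ambient air, graphite wall and air cavity with analog free-path
sampling, Klein–Nishina Compton scattering and photoelectric
absorption, and scores cavity collision kerma with a track-length
estimator (the kerma approximation — secondary electrons deposit
locally; see `docs/methods.md` for what that does and does not buy).

The source term is the encapsulated microSelectron-type ¹⁹²Ir source:
principal decay lines filtered by deterministic quadrature of
self-absorption in the 3.5 mm × 0.6 mm iridium core and the 250 µm
stainless-steel capsule (mean energy ≈ 0.374 MeV).

The displacement study places an isotropic point source with this
spectrum in a 2 cm air channel on the axis of a PMMA cylinder
(r = 10 cm, h = 14 cm) — centred, or resting against either side of the
channel wall — and scores kerma in 0.5 cm cubes along a radius at
source height.

## Worked example

```bash
$ irkwall kwall --chamber iner --source ir192 --histories 1000000 --seed 42 --out kwall.csv
k_sc=0.9541 k_att=1.0727 k_wall=1.0234 -> kwall.csv
```

Reading: for the 102 cm³ INER-type chamber (graphite wall 2.899→3.200 cm,
ρ = 1.78 g/cm³) under the encapsulated ¹⁹²Ir spectrum, wall scatter
inflates the cavity signal by ~4.8 % (k_sc = 0.9541 divides it back
out), wall attenuation suppresses the primaries by ~6.8 % (k_att = 1.0727
restores them), and the net correction multiplies the measured charge by
k_wall ≈ 1.023. The CSV adds the history-by-history relative standard
errors (~0.1 % at 10⁶ histories). Full photon–electron transport codes
report a slightly larger correction (k_wall ≈ 1.036) for this chamber;
the ~1 % difference is the documented electron-transport systematic of
the kerma approximation, quantified in `docs/methods.md`.

The same library surface in Python:

```python
import irkwall as ik

spectrum = ik.attenuated_spectrum(ik.hdr_ir192_classic_source())
chamber  = ik.standard_chamber("iner")          # also: nist_50cc1, npl
tally    = ik.simulate_chamber(chamber, spectrum,
                               ik.RunConfig(n_histories=1_000_000, seed=42))
print(ik.wall_factors(tally))
```

Other entry points: `irkwall spectrum` (the filtered source spectrum as
CSV), `irkwall scan` (wall factors vs photon energy), `irkwall phantom`
/ `irkwall ratios` (displacement dose profiles and their ratio table),
`irkwall validate` (fast physics invariants). Every output file gets a
JSON manifest whose parameters reproduce it byte-for-byte.

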