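# NIST 50cc-1 spherical graphite primary-standard chamber (51.3 cm^3)
kind: chamber
inner_radius_cm: 2.305
outer_radius_cm: 2.670
source_distance_cm: 100.0
wall_material: graphite
wall_density_g_cm3: 1.73
cavity_material: air
cavity_density_g_cm3: 1.20479e-3
ambient_material: air
ambient_density_g_cm3: 1.20479e-3
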