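# NPL spherical graphite primary-standard chamber (103 cm^3)
kind: chamber
inner_radius_cm: 2.910
outer_radius_cm: 3.290
source_distance_cm: 100.0
wall_material: graphite
wall_density_g_cm3: 1.75
cavity_material: air
cavity_density_g_cm3: 1.20479e-3
ambient_material: air
ambient_density_g_cm3: 1.20479e-3
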