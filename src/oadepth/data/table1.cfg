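# Reference layer stack: the PVDF probe glued between two PMMA sheets,
# coupled to the ink-on-glass test sample.  Order runs from the
# detector-side outermost layer (5 mm PMMA backing) toward the sample.
#
# Adhesive sound velocity and thickness and the ink parameters are
# estimates (the adhesive datasheet lists no sound velocity; the ink layer
# is only known to be distinctly thinner than 100 um); the PVDF velocity is
# the manufacturer's datasheet value.  All densities are modelled at
# 1 kg/dm^3.  The ink is a strong optical absorber (~100 mm^-1, the scale
# of black plastic); the probe layers and the glass are transparent.
layers:
  - material: PMMA        # backing
    sound_velocity_m_s: 2777.0
    thickness_mm: 5.00
    density_kg_m3: 1000.0
    mu_a_per_mm: 0.0
  - material: Adhesive
    sound_velocity_m_s: 2000.0
    thickness_mm: 0.02
    density_kg_m3: 1000.0
    mu_a_per_mm: 0.0
  - material: PVDF        # piezoelectric sensor film
    sound_velocity_m_s: 2250.0
    thickness_mm: 0.01
    density_kg_m3: 1000.0
    mu_a_per_mm: 0.0
  - material: Adhesive
    sound_velocity_m_s: 2000.0
    thickness_mm: 0.02
    density_kg_m3: 1000.0
    mu_a_per_mm: 0.0
  - material: PMMA        # fronting
    sound_velocity_m_s: 2777.0
    thickness_mm: 0.5
    density_kg_m3: 1000.0
    mu_a_per_mm: 0.0
  - material: Ink         # board-marker ink on the glass plate
    sound_velocity_m_s: 1500.0
    thickness_mm: 0.04
    density_kg_m3: 1000.0
    mu_a_per_mm: 100.0
  - material: Glass       # borosilicate plate
    sound_velocity_m_s: 5640.0
    thickness_mm: 4.00
    density_kg_m3: 1000.0
    mu_a_per_mm: 0.0
detector: PVDF
boundaries: [air, air]
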