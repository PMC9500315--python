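# Worked ACDF example: synthetic C2-T2 spine, three-spacer + plate + 8-screw
# construct, per-region BMD material card, four motion load cases.
# Units are fixed: mm / N / MPa / N*mm (field names spell them out).
seed: 1
log_level: INFO

phantom:
  mesh_size_mm: 4.5
  disc_height_mm: 5.0
  np_area_fraction: 0.43
  np_volume_fraction: 0.45
  cortical_thickness_cervical_mm: 0.28
  cortical_thickness_thoracic_mm: 0.24
  facet_gap_mm: 0.3
  quadratic: true

instrument:
  spacer_heights_mm: [8.0, 8.0, 7.0]
  screw_diameter_mm: 4.0
  screw_length_mm: 15.0
  plate_length_mm: 55.0
  plate_span: [C2, C3, C4, C5]
  plate_standoff_mm: 0.0

# per-region volumetric BMD, mg/cc (central / exterior vertebral body)
bmd:
  - {level: C2, region: central_body, bmd_mg_cc: 200.4}
  - {level: C2, region: exterior_body, bmd_mg_cc: 135.2}
  - {level: C3, region: central_body, bmd_mg_cc: 242.1}
  - {level: C3, region: exterior_body, bmd_mg_cc: 99.7}
  - {level: C4, region: central_body, bmd_mg_cc: 319.2}
  - {level: C4, region: exterior_body, bmd_mg_cc: 185.9}
  - {level: C5, region: central_body, bmd_mg_cc: 301.3}
  - {level: C5, region: exterior_body, bmd_mg_cc: 251.5}
  - {level: C6, region: central_body, bmd_mg_cc: 262.6}
  - {level: C6, region: exterior_body, bmd_mg_cc: 141.8}
  - {level: C7, region: central_body, bmd_mg_cc: 229.1}
  - {level: C7, region: exterior_body, bmd_mg_cc: 124.7}
  - {level: T1, region: central_body, bmd_mg_cc: 165.7}
  - {level: T1, region: exterior_body, bmd_mg_cc: 55.1}
  - {level: T2, region: central_body, bmd_mg_cc: 187.4}
  - {level: T2, region: exterior_body, bmd_mg_cc: 140.4}

law_mode: as_used

load:
  body_mass_kg: 39.97      # reproduces the 30.7 N head weight at 7.83%
  head_fraction: 0.0783
  g_m_s2: 9.81
  strengths_nmm_per_kg:
    flexion: 418.0
    extension: 683.0
    lateral_flexion: 542.0
    rotation: 208.0

solver:
  rtol: 1.0e-8
  max_outer: 50

output:
  dir: results_run
  write_vtu: false
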