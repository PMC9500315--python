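# cervifem

Desk-scale finite-element pipeline for judging the mechanical safety of an
anterior cervical discectomy-and-fusion (ACDF) construct.  It is aimed at
biomechanics researchers and FE methodologists who want a fully
reproducible, parametric stand-in for patient-specific spine models: a
synthetic C2–T2 spine (vertebral bodies with central/exterior trabecular
regions and a cortical shell, NP/AF discs, six ligament groups as
tension-only trusses, inclined facet contact) carrying a three-spacer +
anterior-plate + eight-screw construct, loaded with the head weight and
isometric-strength-derived motion torques.

The science at the core:

- **Density → stiffness.**  Per-region volumetric BMD (mg/cc) maps to a
  Young's modulus via the power law `E = 10200 (BMD/1000)^2.01` MPa, so the
  model is patient-specific through its density card alone.
- **Loads.**  Head weight `HW = m·0.0783·g` on the C2 odontoid facets, and
  per motion a torque `T = strength × HW/g` (flexion 418, extension 683,
  lateral flexion 542, rotation 208 N·mm/kg) at a reference point coupled
  to the C2 spinous process.
- **Safety criterion.**  Per bone element, the principal-strain damage
  index `D = max(ε₁/1.5%, ε₃/−2.0%)` (ratios floored at zero); `D ≥ 1`
  means the element is regarded as broken.  The fixation verdict is PASS
  iff every checked region (central bodies, screw trajectories,
  spacer-contacting endplates) stays below 1 in all four motions and all
  facet slips respect the small-sliding assumption.
- **Kinematics.**  Segmental range of motion (ROM) is the relative
  best-fit rigid rotation between adjacent vertebrae, projected on the
  motion axis.

See `docs/methods.md` for the modelling choices, solver details and
limitations.

## Worked example

```
python examples/02_motion_loads.py
```

prints

```
head weight: 30.7 N  (= 39.97 kg x 0.0783 x 9.81 m/s^2)
flexion          strength    418 N*mm/kg  ->  torque  1308 N*mm
extension        strength    683 N*mm/kg  ->  torque  2138 N*mm
lateral_flexion  strength    542 N*mm/kg  ->  torque  1696 N*mm
rotation         strength    208 N*mm/kg  ->  torque   651 N*mm
```

i.e. the four moment magnitudes (N·mm) that drive the motion load cases
for a 39.97 kg body.  The full pipeline on the shipped configuration,

```
python examples/04_fixation_safety_run.py      # or: cervifem run --config examples/example_config.yaml
```

builds the instrumented phantom (~26k nodes), solves all four motions and
prints

```
PASS (max damage index 0.421 < 1)
head weight 30.7 N, torques {'flexion': 1308, 'extension': 2138, 'lateral_flexion': 1696, 'rotation': 651} N*mm
largest facet slip: 0.373 mm (small-sliding gate ok)

segmental ROM (degrees):
       flexion  extension  lateral_flexion  rotation  flexion_extension
C2-C3     0.17       0.41             0.16      0.10               0.59
...
C5-C6     3.93       2.27             6.10      2.96               6.20
...
```

The instrumented block (C2–C5) barely moves while the free junctions below
carry degrees of motion — the expected behaviour of a rigid fused segment —
and no bone region approaches the damage threshold, so the construct is
judged safe under daily neck loads.  Other examples: per-region
density-to-modulus mapping (`01`), synthetic disc composition (`03`).

A thin CLI mirrors the library: `cervifem phantom|solve|report|run`
(exit code 0 = PASS, 2 = FAIL, 1 = error).  Meshes and results are
exchanged as ASCII VTU (lossless round-trip including named sets), legacy
VTK, or an Abaqus-INP keyword subset for cross-checking in external
solvers.

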