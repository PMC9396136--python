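# Body-model configuration schema

`BodyModel.to_yaml` / `BodyModel.from_yaml` serialize the scaled model as
a YAML mapping. All lengths are metres, masses kg, inertias kg·m²,
moment-arm coefficients metres per (degree)^k. Top-level keys:

```yaml
segments:                 # exactly: pelvis, thigh, shank, foot
  thigh:
    mass: 9.2989          # > 0
    length: 0.4214        # > 0
    com_offset: 0.41      # COM as a fraction of length from the proximal end
    inertia: [ixx, iyy, izz]   # principal moments in the segment frame, > 0

muscles:                  # must include the four EMG-monitored muscles:
  vasti:                  # rectus_femoris, biceps_femoris,
    fmax: 6000.0          # tibialis_anterior, gastrocnemius
    arms:                 # DOF -> polynomial coefficients (c0, c1, ...):
      knee_flexion: [-0.048, 4.0e-5]   # r(theta) = c0 + c1*theta + ...,
      knee_adduction: [-0.025, 1.2e-3] # theta in degrees of that DOF,
    knee_axial_factor: 1.0             # signed per the fixed convention
                          # fraction of force compressing the tibia axially

markers:                  # marker name -> [segment, [x, y, z] local offset]
  KNEL: [thigh, [0.0, -0.4214, 0.05]]

hip_offset: [0.0, -0.03, 0.09]   # hip centre in the pelvis frame
foot_com_drop: 0.04              # foot COM drop below the ankle
tibial_plateau_width: 0.08       # contact points sit at 0.25 * width
weight_share: 0.5                # share of the supported load on this leg
scaled: true                     # set by scale_model / truth_model
scale_factors: {thigh: 1.02}     # per-segment factors applied, if any
```

DOF names: `hip_flexion`, `hip_adduction`, `hip_rotation`, `knee_flexion`,
`knee_adduction`, `knee_rotation`, `ankle_dorsiflexion`,
`subtalar_supination`. Sign conventions (positive direction first):
flexion/extension, adduction/abduction, internal/external rotation,
dorsiflexion/plantarflexion, supination/valgus.

Validation on load: positive masses/lengths/inertias/width, every marker
mapped to a known segment, the four EMG muscles present, and arm
polynomials only on known DOFs.
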