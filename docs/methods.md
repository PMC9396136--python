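# Methods

This note records the model, the synthetic-data design and the numerical
choices behind `squatmech`, in the spirit of a model-description appendix.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The musculoskeletal model

### Segments and joints

A single right-leg chain: a **pelvis+HAT** root segment (head, arms, trunk
and the contralateral leg lumped together), then **thigh**, **shank** and
**foot**. Generalized coordinates are the pelvis translation (3) plus
eight rotational DOFs: hip flexion/adduction/axial rotation, knee
flexion/adduction/axial rotation (the knee frontal and transverse DOFs are
deliberately free), ankle dorsiflexion, and subtalar
supination/valgus — the subtalar DOF is unlocked because rearfoot valgus
is the grouping variable. The ankle and subtalar axes are co-located at
the ankle joint centre; separating them changes moment arms by millimetres
and none of the downstream logic.

Sign conventions, fixed everywhere: flexion (+)/extension (−),
adduction (+)/abduction (−), dorsiflexion (+)/plantarflexion (−),
supination (+)/valgus (−), internal (+)/external (−) rotation. The lab
frame is X anterior, Y up, Z to the subject's right.

### Inertial parameters

Segment masses, lengths, COM offsets and radii of gyration follow
published adult anthropometric regression fractions of body mass M and
stature H (thigh 0.1416 M / 0.245 H, shank 0.0433 M / 0.246 H, foot
0.0137 M / 0.152 H; transverse radii of gyration 0.329/0.255/0.257 of
segment length). The pelvis+HAT segment takes the remaining mass
(0.8014 M), so the segment masses sum to the participant mass exactly.
Only half of the supported (HAT + barbell) load is routed through the
modelled leg (`weight_share = 0.5`, configurable), matching a bilateral
symmetric squat with one instrumented plate.

### Muscles

Fifteen rigid-tendon actuators (force = activation × Fmax) with explicit
signed moment-arm functions — constants or low-order polynomials in the
DOF's own angle in degrees. Wrapping geometry is intentionally out of
scope; arms are what the optimization and the contact balance consume.
Noteworthy arm choices, all with unit-bearing rationale:

* **Vasti / rectus femoris knee extension**: −0.048 m and −0.044 m with a
  small +4·10⁻⁵ m/deg flexion dependence (the extensor arm shortens in
  deep flexion).
* **Quadriceps frontal-plane (Q-angle) arm**: −0.025 m + 1.2·10⁻³ m/deg ×
  knee-adduction angle. The −0.025 m neutral value places the baseline
  medial compartment share near the ~25% the tibiofemoral contact-force
  literature reports; the alignment term encodes that a varus (adducted)
  knee rotates the extensor mechanism medially, shrinking its lateral
  pull. This single term is what lets frontal knee alignment shift medial
  loading in the analysis, independently of the external adduction moment.
* **Rectus femoris hip arm**: 0.040 m − 3·10⁻⁴ m/deg × hip flexion — RF's
  hip-flexor leverage fades as the hip flexes, so deep in the squat it
  works mainly as a knee extensor (and its EMG tracks knee-extensor
  demand).
* Hamstrings carry ±0.012 m knee frontal arms (lateral vs medial head);
  axial knee rotation has no dedicated muscle and is carried by reserve
  actuators.

Each knee-spanning muscle has an axial transmission factor (1.0
quadriceps, 0.9 hamstrings/gastrocnemius): the fraction of its force
compressing the tibiofemoral joint along the tibial long axis.

Default tibial plateau width: 0.08 m scaled with stature (H/1.72), so the
contact points sit at d = 0.02 m from the knee centre. Not reported per
participant anywhere; configurable.

## 2. Pipeline numerics

* **Filtering** — markers, GRF/COP and the IK coordinate trajectories all
  receive a zero-lag 4th-order Butterworth low-pass at 6 Hz (2nd-order
  design, forward–backward). Squat motion lives below ~1 Hz; filtering the
  coordinates and the force-plate streams before numerical
  differentiation is what keeps the double-differentiated accelerations,
  and with them the moment-curve extrema, from being noise-rectified.
* **IK** — per-frame Levenberg–Marquardt on the marker least-squares
  objective with an analytic geometric Jacobian (axis × lever columns),
  warm-started from the previous frame; objective tolerance 1e-8, max 200
  iterations, steps that would increase the objective are rejected with
  stronger damping, so the accepted-iterate objective is non-increasing by
  construction.
* **Inverse dynamics** — world-frame Newton–Euler recursion with segment
  angular velocity extracted from Ṙ Rᵀ and central-difference
  accelerations (one-sided at the ends); g = 9.81 m/s². Joint moments are
  projected onto the exact DOF axes of the kinematic chain, so reported
  torques are conjugate to the joint angles, and the moment-balance
  constraints handed to static optimization are consistent with the
  moment arms.
* **Static optimization** — with reserve torques r (cost weight 1000) the
  per-frame problem min Σa² + 1000 Σr² s.t. A a + r = τ, 0 ≤ a ≤ 1
  reduces, after eliminating r, to bound-constrained least squares:
  solved by an exact minimum-norm/ridge `lstsq` fast path when the
  unconstrained optimum respects the bounds, else scipy's BVLS. With
  reserves disabled the equality is hard; frames whose moment deficit
  exceeds 1e-6 N·m raise, naming the DOFs. The knee ab/adduction DOF is
  excluded from the constraint set: its moment is carried by the condylar
  contact forces (next section), not by muscle recruitment.
* **Contact decomposition** — M_frontal = (external knee ab/adduction
  moment from inverse dynamics, i.e. the negated internal torque, inertia
  included) + Σ (frontal arm × muscle force) over knee spanners,
  adduction-positive. The 2×2 balance gives
  F_med = (F_tot + M_frontal/d)/2; a negative condyle is clamped to zero
  with the full load on the other side and a lift-off flag. Conservation
  F_med + F_lat = F_tot holds identically, clamped or not.
* **Moment-table semantics** — rows follow the result-table conventions of
  the squat literature: sagittal/transverse rows are the signed
  convention extrema (net extensor moments are negative); the ankle
  plantarflexion and subtalar valgus rows are reported as magnitudes; and
  the knee adduction row is the peak **external** frontal moment
  (medial-loading positive) — the quantity usually called "peak KAM" and
  the only reading consistent with a positive printed value alongside a
  raised medial contact force. `MOMENT_ROW_SIGNS` documents every row.
* **EMG** — the printed 100–500 Hz band edge touches Nyquist at the
  1,000 Hz sampling rate, so the realizable filter is the zero-phase
  4th-order 100 Hz high-pass (`strict=True` raises instead); amplitude by
  moving-window RMS (100 ms window, 50% overlap); normalization by the
  MVC-bout RMS, clamped to [0, 1].
* **SPM** — pointwise pooled-variance two-sample t-curve; residual
  smoothness by the normalized-residual gradient (element-wise resel
  density, summed); critical |t| from the 1-D Euler-characteristic
  expectation of a t-field at α/2 per tail (brentq root solve, bracket
  widened at very small df); maximal suprathreshold runs reported as
  integer %-cycle intervals. A seeded label-permutation max-|t| threshold
  is the selectable fallback. No correction across metrics or loads — the
  per-comparison α = 0.05 matches how such tables are usually reported,
  and is a documented caveat.
* **Cycle grid** — 101 samples, descent mapped to 0–50 and ascent to
  51–100 by piecewise-linear interpolation anchored at the deepest frame
  (global knee-flexion maximum, earliest on ties; upright threshold 10°),
  so sample 50 is exactly the deepest value and interpolation can never
  overshoot a sampled extremum.

## 3. The synthetic cohort generator

The generator emulates the study conditions: two groups of 10 (standing
rearfoot valgus drawn uniformly in (6°, 30°] vs [0°, 5°)), loads 0/30/70%
1RM, three trials per condition, anthropometrics around 65.67 kg / 1.72 m
(SDs 11.38 kg / 0.07 m), 1RM ≈ 1.2 × body mass, markers at 100 Hz, EMG at
1,000 Hz, trials ≈ 4 s.

* **Kinematic template** — knee flexion follows a C²-smooth sin⁴ pulse
  (zero velocity *and* acceleration at the quiet-standing boundaries, so
  filtering and double differentiation stay benign) from upright to a
  subject-specific depth (~134° ± 5°) and back; dorsiflexion shares the
  pulse and hip flexion is knee − dorsiflexion, which keeps the foot flat
  on the plate exactly. Frontal/transverse excursions are small (hip
  abduction ~8°, knee frontal ~2°, axial rotations ~10°): squatters keep
  the knee near the ground-reaction line, and it is this choice that keeps
  frontal moments at the N·m/kg-in-tenths scale of real squat data.
  Subject-level traits (depth, tempo, frontal posture, adduction-moment
  baseline) are drawn once per participant from the cohort seed, so a
  subject's trials are correlated; trial jitter is small on top.
* **Ground reaction** — the exact Newtonian resultant of the moving leg
  segments plus the routed share of the (pelvis+HAT + barbell) point load
  at the hip; the anterior COP drifts heelward with depth (giving
  tibialis anterior a dorsiflexion demand at the bottom). The
  mediolateral COP is solved in a second pass so that the external knee
  adduction moment equals the target pulse exactly: a baseline inverse
  dynamics with the COP on the knee line, then the per-frame offset from
  the torque's linear sensitivity to a mediolateral COP shift. This makes
  the injected adduction-moment effect immune to the frontal-plane
  geometric couplings of the template.
* **Group effects (defaults, valgus − normal)** — +10° peak knee flexion,
  +4° dorsiflexion (hip flexion +6° follows from the flat-foot
  constraint), +4° knee adduction, +0.12 N·m/kg external knee adduction
  moment (additive offsets; subject baseline KAM 0.22 N·m/kg × a
  ±20% subject factor), and ~2° less hip abduction. The medial
  contact-force effect is *not* a separate dial: it emerges from the
  adduction-moment offset through the contact balance and from the
  knee-adduction angle through the alignment-dependent quadriceps frontal
  arm — the two mechanical routes by which frontal alignment shifts
  medial loading.
* **Noise defaults** — marker 3 mm, GRF 5 N, COP 2 mm (all Gaussian),
  EMG carrier floor 5% of the MVC scale. Chosen so the scaling/IK gates
  (< 0.02 m RMS) are attainable with margin while still exercising the
  filters.
* **EMG synthesis** — ground-truth activations are the static-optimization
  solution on the ground-truth torques; each channel is a unit-RMS
  100–450 Hz band-limited carrier amplitude-modulated by its activation,
  plus an MVC bout (modulation 1) processed identically to give the
  normalization reference. By construction the MVC-normalized envelope
  estimates the generating activation, which is why envelope-vs-model
  agreement is high on synthetic data.
* **Determinism** — every stream derives from `CohortSpec.seed` through
  SHA-256-hashed SeedSequence children; the same spec produces
  byte-identical cohorts and pipeline tables.

### What the generator does *not* emulate

Soft-tissue artefact (noise is white, not correlated with pose), marker
occlusion/gaps, trunk lean and lumbar loading, bounce or tempo asymmetry,
force-plate drift and free moments, EMG crosstalk and electrode placement
variability, and any left–right asymmetry. Passing the recovery and
effect-direction tests therefore shows the *pipeline* is correct and the
statistics calibrated under the stated conditions — not that real squat
data would be this clean, nor that the effect magnitudes would transfer to
a clinical cohort.

## 4. Problem sizes

The default cohort run processes 20 participants × 3 loads × 3 trials
(180 dynamic trials of ~400 frames) in a few minutes on one core; the SPM
null calibration uses 1,000 replicates of 10-vs-10 curves (101 samples,
FWHM ≈ 15); recovery checks use single noise-free trials. These sizes were
chosen to mirror the study design while keeping a full run interactive.

## 5. Known limitations

* The pelvis does not rotate (no trunk lean); hip moments therefore fold
  the trunk's contribution into the point-load approximation at the hip.
* Contact magnitudes are quadriceps-force driven and land in the 4–7
  body-weight range the contact-force literature reports for deep squats;
  they are higher than some modelling studies print, and the medial/total
  ratio is sensitive to the Q-angle arm default.
* The subtalar "foot valgus" angle during motion is only loosely coupled
  to the standing valgus classification (0.3 × static angle + a common
  excursion), mirroring the observation that in-squat foot posture
  discriminates the groups weakly.
* Random-field-theory thresholds assume smooth Gaussian residual fields;
  the permutation fallback is the robust check when that is in doubt.
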