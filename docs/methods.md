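# Methods

`zygosim` simulates the software core of an automated pronuclear
microinjection system against a synthetic microscope. This note records
the models, their assumptions, the calibrations behind the defaults, and
what the synthetic setting does and does not establish.

## Coordinate conventions

Chamber frame in micrometres: x toward the injection pipette (image
right), y down in the image, z up the optical axis; the zygote's local
origin is its centre. Images are 8-bit grayscale with 0-based pixel
indices, pixel centres at integer coordinates, and the image centre
mapped to chamber (0, 0); the default scale is 0.5 µm/px.

## Ground-truth scenes

A scene is a rigid arrangement: cytoplasm sphere (radius default
38–42 µm) inside a zona pellucida shell (9–11 µm), holding one pronucleus
(radius 10–12 µm; two supported for target-selection studies) that
carries 1–4 nucleoli (radius 1.5–3.5 µm). Containment invariants
(`|offset| + r ≤ R` at each level) are enforced at construction and are
preserved by rotation, which is applied as one proper rotation about the
zygote centre to every internal offset (nucleolus offsets rotate with
their pronucleus, so the body is rigid by construction).

Generator defaults are the study conditions and are fixed:

* pronucleus centre offset: uniform per axis on ±15 µm (ball-rejected).
  Pronuclei sit mid-cytoplasm rather than against the cortex; 15 µm also
  keeps the depth offset within reach of the ±12 µm height calibration
  plus the ±7 µm mechanical tolerance.
* nucleolus offset: uniform per axis on ±1 µm. Nucleoli cluster near the
  pronucleus centre; the value is consistent with the 2 µm lateral
  insertion tolerance (the nucleolus is the landmark that stands in for
  the pronucleus centre).
* nucleoli count: P(1..4) = 0.4/0.3/0.2/0.1.

All randomness flows through one explicitly passed seeded generator; no
global state.

## Renderer

The renderer is a stylized brightfield model, not physical optics. Its
contract is that pronucleus height is *recoverable* from nucleolus
appearance in a single image, which is what the 3D localization pipeline
calibrates against. Layers, painted on a 180-intensity background:

* zona band at 166, cytoplasm interior at 160 (compact smoothstep level
  edges of half-width 1 µm — the strongest circular contour is the outer
  zona rim, which is what zygote detection reports, radius ≈ 50 µm);
* pronucleus membrane as a thin Gaussian dip ring (depth 12, σ 0.8 µm);
* each nucleolus as a composited disc with interior level
  `bg·(1 − α) + a·Δz` (α = 0.45, a = 2.0 intensity/µm, Δz = nucleolus z −
  focus z) and a compact smoothstep edge of half-width
  `w(Δz) = w₀·(1 + |Δz|/σ_dof)` (w₀ = 0.5 µm, σ_dof = 4 µm);
* optional Gaussian pixel noise (σ = 2.0), then rounding and clipping to
  [0, 255].

The compact (finite-support) edge keeps the disc interior an exact
plateau, so the closed forms hold exactly on noise-free renders: interior
mean 99 at focus, and a mean difference of `2·a·Δz` between ±Δz. Edge
*width* carries |Δz|; the *signed mean* carries the sign — together the
feature pair is injective, and with the asymmetry coefficient set to zero
the calibration correctly refuses to build ("height ambiguous").

An edge half-width growing from σ_dof itself was rejected: at 4 µm it
exceeds the nucleolus radius, erasing the interior plateau that both the
calibration and the closed-form checks rely on.

Feature measurement is shared verbatim between calibration and
detection: interior mean over d ≤ 0.5 r, local background over the
1.6–2.2 r annulus, and edge contrast as the maximum radial slope (0.5 px
bins) normalized by (ring − interior). The normalization makes contrast
independent of the local background level, so the calibration — built on
a canonical centred 4 µm nucleolus — transfers to nucleoli seen against
the cytoplasm interior. Contrast is even in Δz only up to 8-bit
quantization (~0.01), which is why tests assert evenness at 0.02 rather
than machine precision.

## Circle detection

Both the zygote and the nucleoli are found with a generalized Hough
transform specialized to circles: Sobel gradients above the 90th
percentile of the ROI (floored at 0.5 intensity/px) vote at `p − r·ĝ`
for each candidate radius. Three choices matter:

* **single polarity** — every rendered circle is darker inside than
  outside, so only the dark-interior vote direction is cast; this
  removes the outer phantom-ring peaks that two-sided voting creates;
* **magnitude-weighted, circumference-normalized votes** — a peak reads
  as mean edge strength per perimeter pixel. Unweighted counting biases
  the radius of a defocused disc toward the largest radius covered by
  its blurred edge band (every radius in the band votes; circumference
  then decides);
* **non-maximum suppression** within (detected radius + smallest search
  radius) of each peak — a disc's own edge also votes phantom centres at
  smaller radii just inside its rim, beyond a minimum-radius separation.

Acceptance thresholds (zygote 0.2, nucleolus 3.0) sit mid-gap between
the measured noise-only ceilings (0.034 / 1.23 across seeds) and the
noisy-signal floors (0.55 / 24.6). Peaks are read off 3×3-summed
accumulators; candidate ordering is fully deterministic (score, distance
to the zygote centre, y, x). The zygote sweep uses a 2 px radius step
(tolerance is ±2 px; the vote peak fixes the centre independently).

Height estimation inverts the defocus LUT by minimizing a scaled squared
feature distance over the ±12 µm grid (0.5 µm step), refined by local
quadratic interpolation. The mean-intensity scale is the LUT column
standard deviation; the contrast scale is the column deviation divided
by 0.03, i.e. the contrast term is strongly downweighted: the interior
plateau makes the mean feature exact under sub-pixel centre quantization,
whereas measured contrast can drop ~40 % for a half-pixel centre error
near focus and would otherwise bias the estimate by ~2 µm. The reported
uncertainty is the half-width of the distance valley at twice its
minimum, floored at half the grid step; features farther than 3 scaled
units from every LUT entry raise "out of calibration range". Residual
noise-free inversion error is ≤ 0.1 µm over ±10 µm; under default pixel
noise the full render→detect→invert pipeline is ≈ 0.2 µm RMS.

## Virtual rig

Rotation maneuvers emit the micro-step events of the physical procedure
(raise pipette over the zygote, drop holding pressure, lower pipette —
the zygote rolls, regrip, retract) and apply their net effect as one
rigid rotation. Lateral rotation is target-seeking: it maps the
*estimated* target direction onto the injectable-box direction (+x in
the focal plane), so estimation error propagates into residual
misplacement exactly as a closed-loop system would re-observe it.
Vertical (blind) rotation is a fixed 60° step about the holding axis.
Gaussian execution noise (default σ = 10°) perturbs the planned angle.
A target already at the centre (direction undefined) rotates by zero.

Insertion succeeds iff the tip — placed at the planar fix and at
`focus + ẑ` (3D) or `focus` (2D) — is within 2 µm laterally and 7 µm
axially of the true pronucleus centre. These mechanical tolerances, the
clog probability (0.02) and the rotation noise are simulation
conventions, not measured rig properties.

The expansion model `V/V₀ = 1 + k(P)·t` is anchored at
k(30 hPa) = 0.18 s⁻¹ (so 30 hPa for 2.0 s gives 136 % of the original
volume) and k(45 hPa) = 0.36 s⁻¹ (so 45 hPa for 0.8 s matches 30 hPa for
1.6 s); k is linear in pressure between and beyond the anchors (clamped
at 0), the minimal model consistent with both anchors given that
injected volume is *not* proportional to pressure × time. Survival is a
hinge-exponential, flat at 0.98 for P ≤ 35 hPa and t ≤ 2.0 s and
decaying at λ_P = 0.03 hPa⁻¹ / λ_t = 0.5 s⁻¹ beyond the knees — a
qualitative calibration chosen to reproduce the observed thresholds
(survival falls when pressure exceeds 35 hPa or time exceeds 2.0 s), not
a fit to measured curves. On a successful insertion the pronucleus
radius is updated to the cube root of the expanded volume; a clog is an
independent Bernoulli event.

## Sequencer

`fsm_step` is a pure, total transition function over the enumerated
input space; undefined combinations raise rather than pass silently.
Recovery policy: detection failure → up to 3 holding-height steps (+8,
−16, +24 µm, a blind sweep covering ±16 µm), then up to 2 blind vertical
rotations; a detected but unreachable target gets up to 3 lateral
rotations. Exhaustion releases the zygote flagged `not_detected` (or
`failed_insertion` for rotation exhaustion) and the batch continues. A
clog stops the run, purges, and restarts with the next zygote — the
clogged one is marked `skipped_clog_restart` and not retried (bounded
work per zygote). Counters never reset, so each record's retry counts
are bounded by the configured maxima.

`run_batch` re-renders and re-detects after every scene-changing action;
the event log is a pure function of (scenes, config, seed) and replays
identically.

The insertion benchmark abstracts the same geometry to closed form: true
depth ~ U(±10 µm), tolerance ±7 µm, 3D residual error ~ N(0, 3.72 µm).
The 2D success probability is 7/10 = 70.0 % and the 3D probability
2Φ(7/3.72) − 1 ≈ 94.0 %; the depth range, tolerance and residual sigma
are benchmark calibrations (configuration, not measured quantities)
chosen so the simulated contrast matches the observed 70 % → 94 %
improvement.

## Outcomes and statistics

Downstream biology is modelled as chained Bernoulli trials per injected
zygote — survive, reach the 2-cell stage, transfer (all 2-cell embryos
are transferred), offspring, modification given offspring — with arm
probabilities defaulting to the published empirical rates of the three
chemistries (traditional DNA injection, piggyBac transposon, CRISPR
knock-in, each with manual controls). These rates are inputs, not
predictions: the simulation's claim is only binomial consistency with
its parameters. Rate tables print one-decimal percentages rounded
half-up (exact `decimal` arithmetic; denominator = embryos transferred),
verified cell-by-cell against the published table. Replicate summaries
are mean ± SEM (sample SD/√n); comparisons use the equal-variance
two-sided Student t-test with significance at P < 0.01. No normality
test is applied before the t-test, and dose–response in DNA
concentration is a configuration lookup, not a fitted curve.

## Problem sizes

Defaults keep everything desk-scale: 512² px renders (256² in most
tests), 49-entry calibration table, 100 000-draw benchmarks, batches of
~20 zygotes, 500-draw noise studies. These sizes give 3-SE statistical
margins far smaller than the effects asserted.

## What passing tests do and do not show

The synthetic microscope guarantees that appearance determines height by
construction. Real brightfield defocus is not linear in brightness, is
contaminated by neighbouring structure, debris and illumination drift,
and real nucleoli are neither perfectly spherical nor uniformly dark.
Passing tests therefore validate the *software contracts* — detection
accuracy against ground truth, calibration invertibility, FSM
correctness, model arithmetic, statistical procedure — not biological
performance. Wet-lab rates (survival, development, modification) enter
only as simulation parameters. Hardware control, fluidics, deformable
mechanics and zona drilling are out of scope.
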