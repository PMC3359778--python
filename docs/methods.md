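# Methods

## The measurement model

Shimmering is observed as grayscale video of the nest surface at 60 fps
(frame interval 16.67 ms), with a metric scale of ~0.30 mm/px (a 700 mm
field over a 2352 px sensor), so a bee's 6 mm abdomen spans ~20 px. Each
identified surface bee ("agent") carries a tracked thorax position; the
stereo segmentation/tracking that produces such tracks on real footage is
outside this package — tracks are an input, and the simulator produces them.

**Motion strength.** Consecutive frames are subtracted pixel-wise. The
subtraction is taken as the absolute difference so that values stay on the
0–255 grey scale regardless of sign of the luminance change. Summing over
the 60×60 px window centred on the thorax (the window of the *later* frame
of each pair, where incident onsets are defined) and dividing by 10⁴ yields
`rel_XYmov`. The normalisation makes the quiescent level ≈ 1.08 (3 grey
levels per pixel × 3600 px = 1.08·10⁴) so that all thresholds below are on
one scale. Windows that would leave the frame are excluded rather than
clipped: partially observed motion sums are not comparable with full ones.

**Incident detection.** The participation threshold is a supra-baseline
excess of 1.0 normalized unit (10⁴ raw units). The published threshold
"Δws = 10" is dimensionally ambiguous against a metric whose quiescent
level is ~1 and whose maxima are ~20; we read it as 10·10³ raw units, which
places it exactly at the first line of the threshold grid used for the
transfer-time analysis (rel_XYmov = 1.0) — the value is configurable
(`detect_threshold`). An incident requires ≥ 5 consecutive supra-threshold
frames (noise exclusion); its t₁ is the first such frame and t₀ = t₁ − 1.
Supra-threshold runs with onsets closer than the refractory window (default
800 ms = 48 frames) are merged: a bee cannot re-join within its refractory
phase, so a second run that soon is the damped tail of the same flip.
Baselines are per-agent medians over a declared quiescent window; without
one, the global quiescent level 1.08 is used (a whole-trace median would be
biased high in sessions dominated by waves).

**Strength levels.** The mapping from peak `rel_XYmov` to the eight ordinal
levels c_ws = 1–8 is not published; we use lower bounds at
{1.5, 2, 3, 4.5, 6.5, 9, 12, 16} × baseline (half-open intervals, below the
first bound ⇒ c_ws = 0). The geometric-ish progression spans quiescent to
~tenfold-quiescent and places default simulated waves at mid levels
(c_ws = 2–4), the mode observed in field histograms. Fully configurable.

**Sectors and triggers.** Eight 45° sectors in image coordinates
(x rightward, y downward), numbered clockwise from "from Right" (centre 0°);
half-open boundaries (22.5° belongs to sector 2). Key wave directions 1–4
(R→L, B→T, L→R, T→B) correspond to origin sectors 1, 3, 5, 7. The trigger
of a focus bee is the spatially closest near neighbour (< 40 mm, strict)
that joined the same wave 1–5 frames earlier; ties break on earlier t₀,
then lower agent id (the source data are silent on ties; the rule makes
assignment order-invariant). 5 frames at 60 fps is 83.3 ms; the published
"≤ 88 ms" appears to include part of the frame interval — we implement the
frame rule. Incidents without a qualifying trigger are "untriggered-active"
and excluded from directional statistics. Waves are delimited by temporal
clustering: a gap > 48 frames between successive onsets starts a new wave.
Wave direction is labelled automatically by least-squares plane fit
t₀ ≈ a + bx + cy; the wave comes from the direction opposite the gradient
(b, c), snapped to the nearest key direction. Manual labels can override
(`wave_dir_overrides`), preserving the visual-labelling workflow; degenerate
fits (simultaneous onsets, < 10 incidents) are flagged undefined.

## The bucket-bridging statistics

**Linearity.** Focus incidents pooled over c_ws = 1–6 are counted per
(wave direction, trigger sector) and normalized to max = 1 within each wave
direction. The *coincidence test* asks whether the supra-median trigger
mass falls in the wave-origin window (origin sector ± 45°, three sectors —
the manual direction labels carry similar tolerance). With eight distinct
values exactly four sectors lie strictly above the median, so literal
containment in a three-sector window is unattainable; we declare
coincidence when the maximum sector lies in the window and the supra-median
excess inside the window strictly exceeds the excess outside. A degree-4
polynomial fitted over the (circularly unwrapped, origin-centred) sector
angles defines the "fuzziness" floor; *estimate A* integrates the
normalized excess above that floor, *estimate B* above the median level,
both as percentages of the stratum's summed normalized rates. The
polynomial degree only enters through the fitted minimum, so the estimates
are insensitive to it; B ≤ A whenever the floor is below the median.

**Continuity.** For each focus incident, far neighbours (< 100 mm) that
joined the same wave 1–15 frames earlier (250 ms — the span of the passive
pre-onset build-up) are binned by the angular offset of their sector from
the trigger sector (45° bins, −135°…+180°). Counts are averaged per focus
incident within each c_ws stratum and normalized to max = 1. The *excess
rate* is (central bin − mean of the two adjacent bins) / central bin × 100;
the published adjacent/peak ratios are not mutually consistent to the last
digit, so this reading is documented rather than asserted as the original
construction. The same 15-frame pre-onset window is applied to both the
direct- and the opposite-sector graduality analysis (the sources imply but
do not state the latter).

**Graduality.** Per focus incident, the direct-sector (ds) statistic is the
mean peak `rel_XYmov` of qualifying far neighbours in the trigger sector;
opposite-sector (os) uses the sector 180° across. The strength entering the
regressions is the incident's peak `rel_XYmov`, not its ordinal level.
Pearson r and the least-squares slope k are computed per condition
(default: per c_ws stratum); r values are summarised as mean ± SE over
conditions with a paired ds-vs-os t-test (identical series ⇒ t = 0, P = 1
by convention, since the paired test is degenerate). Shares of agents are
100·r². The ds regressor is a sector *mean*, which attenuates slopes
(errors-in-variables); the trigger-neighbour regression (focus peak on the
assigned trigger's own peak, the near-neighbourhood analysis) has no such
attenuation and is the estimator used for coupling-coefficient recovery.

**Time courses.** Incident-aligned trace segments are averaged on the frame
grid over a −200…+600 ms window with per-point n bookkeeping (truncated
segments stay honest at the edges). Neighbour ensembles take the assigned
trigger's trace aligned to the *focus* bee's t₀, restricted to triggers of
the same strength level. Transfer time: for each of 14 thresholds
(rel_XYmov 1.0–2.3, step 0.1), the rising-phase crossing of each ensemble
is linearly interpolated; Δt = t_fb − t_nb, reported as mean ± SE over
usable thresholds. A curve already above a level at window start has no
observable onset there; such thresholds are excluded and counted, and
estimates with < 3 usable thresholds are flagged unreliable. A
cross-correlation lag of the curves' first differences (flank matching,
parabolic sub-frame refinement) is provided as an independent cross-check;
the published "weighted interpolation" is not defined precisely enough to
reproduce, so both estimators are reported. Speed = mean focus–trigger
distance / transfer time (mm/ms ≡ m/s), SE propagated first-order.

## The synthetic wave generator

The simulator emulates the study conditions, not a particular recording:

- **Lattice**: jittered hexagonal grid, default spacing 29 mm over
  600×600 mm (~500 agents). The published near (5–7 agents < 40 mm) and far
  (20–30 agents < 100 mm) occupancies are mutually inconsistent for any
  uniform density; we match the near count (6 at spacing 29 mm) because the
  near neighbourhood drives trigger assignment, and document the resulting
  far count (~40). Jitter displacements are truncated so pairwise distances
  never fall below 10 mm. The lattice is offset 20 mm from the image origin
  so every ROI fits in rendered frames.
- **Dynamics**: waves start at a generator cohort — the edge strip of
  agents on the side the wave comes from (no quantitative generator-bee
  criterion exists in the source; cohort placement is a simulator choice).
  An inactive, non-refractory agent joins `latency_frames` (default 3,
  = 50 ms, matching the observed ~47 ms step transfer) after a near
  neighbour joined; its pulse is a raised cosine of 200 ms (12 frames)
  with a damped oscillation tail (20 % amplitude, 150 ms period, 120 ms
  decay — the post-flip resonance of the bee curtain), followed by an
  800 ms refractory phase. Peak excess couples to the mechanical trigger's
  peak: E = k·E_trig + (1−k)·E_base with per-incident base amplitude
  N(2.5, 0.6²) (mid strength levels). Gaussian trace noise (sd 0.05)
  models residual motion.
- **Attribution vs mechanics**: `p_directed` controls only the *recorded*
  trigger attribution (nearest qualifying neighbour vs a uniformly random
  sector), not the joining dynamics — it is the knob that degrades the
  directedness statistics the way undirected field triggering does, while
  the wave still crosses the lattice. Recovery tests of the directedness
  statistics therefore run on the truth's recorded attributions; the
  trigger-assignment recovery test runs the full pipeline at
  `p_directed = 1`, where both coincide.
- **Rendering**: agents are drawn as thorax + abdomen ellipses (20 px
  abdomen width); the abdomen tip lifts 12 px per normalized strength unit,
  capped at 24 px so the glyph never leaves the ROI (beyond the cap,
  increasing strength saturates rather than reduces the difference sum).
  Background per-pixel noise sd 2.66 makes the quiescent difference image
  average ~3 grey levels per pixel (E|a−b| = 2σ/√π), i.e. a quiescent ROI
  sum of ~1.08·10⁴.

What the simulator does **not** emulate: saltatoric daughter waves (beyond
random attribution), wasp-stimulus geometry, multiple curtain layers and
z-motion, curved or spiral wave fronts, and the heterogeneous individual
response biases of real bees. Passing recovery tests therefore shows the
*pipeline* is correct and well-calibrated, not that field data would be as
clean: on real footage the directedness shares are far smaller and the
detection threshold matters more.

## Numerical and validation choices

- All frame indices are 0-based; intervals are half-open; distances are
  strict inequalities at both radii. Coordinates: pixel origin top-left,
  y downward, shared by mm and px frames.
- Seeded runs are bit-reproducible end to end; every result file carries
  the hash of the producing configuration.
- Detection onset lags true onsets by the threshold-crossing delay of the
  pulse flank (~2 frames at default amplitudes) — uniform across agents,
  so relative quantities (trigger windows, transfer times) are unaffected.
  Amplitude heterogeneity makes that delay vary by ~±1 frame; the
  noiseless trigger-recovery condition therefore switches off both trace
  noise and amplitude spread.
- Problem sizes in the validation suite (a ~500-agent lattice, a few
  hundred simulated waves across the recovery tests, ≤ 50-agent instances
  for brute-force oracle comparisons) were chosen as the smallest at which
  the Monte-Carlo error of each recovered parameter is well below its
  tested tolerance.
- Known limitations: the transfer-time estimator needs both ensembles to
  cross a threshold on the rising flank, so very weak strata are dropped;
  the plane-fit direction label assumes an approximately planar front and
  flags (rather than guesses) degenerate waves; `repetition_rate` estimates
  the refractory phase only under saturation driving — under sparse driving
  it reports the drive interval, as the worked example shows.
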