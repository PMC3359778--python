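# shimmerwave

Single-agent analysis of **shimmering** — the collective defence waves of
giant honeybees (*Apis dorsata*), in which surface bees flip their abdomens
in Mexican-wave-like cascades across the nest. The package quantifies how
such a wave propagates bee-to-bee ("bucket bridging": each agent passes the
cue to the next member of a chain) and ships an agent-based wave simulator
with known ground truth, so every analysis stage can be validated without
field video.

It is aimed at behavioural ecologists and collective-behaviour modellers
working with overhead video of dense animal groups.

## What it computes

Given per-agent motion traces (from video or simulation) and agent positions:

1. **Motion metric** (`motion`) — per-bee motion energy `rel_XYmov`:
   absolute pixel-wise luminance difference of consecutive 8-bit frames,
   summed over a 60×60 px region of interest (18×18 mm at 0.30 mm/px) around
   the thorax and divided by 10⁴. A quiescent bee sits at ≈ 1.08 (3 grey
   levels per pixel); massive shimmering reaches roughly tenfold.
2. **Incident detection** (`detect`) — a *wave incident* starts at t₁, the
   first of ≥ 5 consecutive frames whose supra-baseline excess exceeds the
   participation threshold (1.0 normalized = 10⁴ raw units); time zero is
   t₀ = t₁ − 1. Peak strength maps onto eight ordinal wave-strength levels
   c_ws = 1–8. Inter-incident intervals yield the wave repetition rate and
   a refractory-period estimate (~800 ms).
3. **Neighbourhoods and triggers** (`neighborhood`) — near (< 40 mm) and far
   (< 100 mm) neighbourhoods, eight 45° angular sectors ("from Right" = 1 at
   0°, numbered clockwise with y pointing down), trigger assignment (the
   closest near neighbour that joined the same wave ≤ 5 frames earlier),
   and automatic wave-direction labelling (plane fit of t₀ over position;
   dir_WAV = 1–4).
4. **Bucket-bridging statistics** (`wavestats`, `graduality`, `timecourse`):
   - *Linearity*: are focus bees triggered from the direction the wave came
     from? Sector histograms normalized per wave direction, a coincidence
     test against the wave-origin window (±45°), and directedness shares
     above the polynomial-minimum "fuzziness" level (estimate A) and above
     the median level (estimate B).
   - *Continuity*: do most previously active far neighbours sit in the
     trigger sector? Sector-offset profiles and the excess of the central
     bin over its neighbours.
   - *Graduality*: does a focus bee's strength follow her neighbours'?
     Direct-sector vs opposite-sector regressions (r, slope k), R² shares
     (r = 0.16 ⇒ R² = 0.0256 ⇒ 2.56 % of agents), and the
     trigger-neighbour regression that recovers the coupling coefficient.
   - *Time courses*: ensembles synchronized at t₀ (mean ± SE), transfer
     time from 14 threshold crossings (rel_XYmov 1.0–2.3), propagation
     speed (62 mm / 47.29 ms ⇒ 1.311 m/s).
5. **Hallmarks report** — exact chained percentages (participation × focus
   share × criterion shares) down to fractions of all surface bees.

The simulator (`synthetic`) generates jittered hexagonal agent lattices
(29 mm spacing: 6 near neighbours), excitable-media waves with 200 ms
raised-cosine pulses, damped oscillation tails, an 800 ms refractory phase,
a tunable directed-vs-random trigger attribution (`p_directed`) and strength
coupling (`k_couple`), and can render 8-bit grayscale frame stacks.

## Worked example

```python
import shimmerwave as sw

agents = sw.build_lattice((600, 600), spacing_mm=29.0, jitter_sd=2.0, seed=1)
params = sw.WaveParams(dir_true=3, p_directed=1.0, k_couple=0.5, seed=2)
strengths, truth = sw.simulate_wave(agents, params, n_waves=2)

model = sw.ShimmeringModel.from_simulation(agents, strengths, truth=truth)
results = model.fit()
print(results.summary())
```

prints

```
Shimmering-wave bucket-bridging analysis
========================================================
agents: 504   frames: 306   incidents: 1006   waves: 2
config hash: 42d409197e6a
--------------------------------------------------------
participation: 100.00% of agents
focus share:   96.42% of incidents
linearity estimate A: 100.00%  B: 91.86%  coincidence: 100%
continuity excess rate: 25.85%
graduality r_ds: 0.1213+-0.1921  r_os: 0.0299+-0.0704  P=0.5900
transfer time: 46.74+-3.52 ms (n=2 strata)
propagation speed: 0.596+-0.045 m/s (mean step 27.9 mm)
repetition rate: 0.417 Hz   refractory ~ 2383 ms
```

Two fully directed left-to-right waves sweep a 504-agent lattice: every
agent participates, 96 % of incidents are trigger-attributable (the rest are
the generator cohort), the trigger-direction histogram coincides with the
wave origin in all strata (estimate B ≈ 92 % directedness — field data are
far fuzzier), and the recovered transfer time of ≈ 47 ms per ~28 mm step
matches the injected 3-frame latency. The repetition interval here is the
inter-wave drive spacing, not the refractory phase; drive at saturation
(`drive_interval_frames=params.refractory_frames`) to recover the 800 ms
refractory period.

The same analysis runs from rendered video via
`ShimmeringModel.from_frames(stack, tracks)`, and from the shell:

```bash
shimmerwave simulate --extent 600 600 --seed 1 --out sim/
shimmerwave analyze --traces sim/strengths.csv --agents sim/agents.csv --out results.json
shimmerwave report  --traces sim/strengths.csv --agents sim/agents.csv --out hallmarks.csv
```

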