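# Methods

## The model

`queencourt` simulates a honeybee queen and her retinue ("court") on one
face of a brood comb. The comb is discretised into 1 × 1 cm patches that
carry two scalar fields; agents (one queen, N = 100 workers by default)
live in continuous 2D space on top of the lattice and sense the patch they
stand on.

**Temperature field (static).** The brood nest is warm in its centre
(~36–38 °C) and cool at the comb rim (~24–26 °C). Model units map linearly
to physical degrees: rim = 0.0 (~25 °C), thermotaxis threshold
Θ_temp = 1.0 (~31 °C), centre = 2.0 (~37 °C). The field is built once by
clamping a brood disc (default radius 8 cm around the comb centre) at the
centre value and the boundary ring of patches at the rim value, then
relaxing an 8-neighbour averaging diffusion to steady state (largest
per-patch change < 1e-8). The result is maximal at the brood centre,
radially non-increasing, and never changes during a run.

**Pheromone field (dynamic).** The queen deposits E = 10 pheromone units
per step onto her patch. Each step the whole field then decays
proportionally by μ = 5% and diffuses with a conservative 8-neighbour
stencil: every patch exports a fraction D = 1.0 of its content, split
equally among its *existing* neighbours (no-flux boundary), keeping the
rest. The update order within a step is emit → decay → diffuse, which makes
the single-step mass after one default step 10 × 0.95 = 9.5. Around a
stationary queen the closed loop approaches the geometric-series fixed
point: the per-cycle peak (post-emission) mass converges to E/μ = 200
units and the post-step mass to E(1−μ)/μ = 190 units. We quote the
post-emission phase when citing "the" fixed point because that is the phase
at which the mass equals the closed-form E/μ.

**Behaviors (per step, in order).**

1. *Thermotaxis* — every agent whose local temperature is below Θ_temp
   turns toward the centre of the warmest Moore-neighbour patch with
   probability p_thermotaxis = 0.125. This keeps all agents inside the warm
   brood area.
2. *Chemotaxis* (workers only) — pheromone below the sensory threshold
   Θ_min = 2.5 is not sensed and triggers no chemotactic turn of either
   sign; this gate matters (see "Design choices"). Sensed pheromone at or
   above the worker's adaptive threshold Θ_taxis(i, t) triggers an uphill
   turn toward the highest-valued neighbour patch (positive response);
   sensed pheromone below Θ_taxis triggers a downhill turn.
3. *Correlated random turn* — with probability p_turn = 0.6 the heading is
   deviated by Uniform(±15°).
4. *Motion* — with probability p_move = 0.3 an agent attempts a forward
   step of v_Q = 0.9 cm (queen) or v_W = 0.6 cm (worker). The move succeeds
   only if the target stays inside the arena and the target patch is not
   occupied by another agent on the same comb side (at most one agent per
   patch; see "Design choices"). Motion attempts are resolved in a freshly
   shuffled agent order each step.
5. *Habituation / dishabituation* — a worker that responded positively this
   step raises Θ_taxis by λ_habituation = 0.005; a worker that sensed no
   pheromone above Θ_min lowers it by λ_dishabituation = 0.05; a worker
   that sensed pheromone but did not respond positively leaves it
   unchanged. Θ_taxis is clamped to [0, 10] pheromone units. These inverse
   reinforcement signs produce the characteristic on/off attendance: a
   worker joins the court, habituates over ~minutes, turns away, leaves the
   plume, resensitises quickly, and eventually returns.

Headings are degrees, 0° = +x (east), counterclockwise; neighbour-turn
targets are the 8 compass directions, with ties broken deterministically in
the order N, NE, E, SE, S, SW, W, NW. One step corresponds to 0.25 s
(100,000 steps ≈ 7 h), which converts every second-denominated observable.

**Randomness.** A run draws everything (placement, headings, initial
thresholds Uniform(0, 10), all Bernoulli gates, turn angles, agent
ordering) from one seeded numpy Generator; identical seeds give
bitwise-identical runs. Sweep replicates derive their seeds deterministically
from (base seed, speed index, replicate).

## Observables

* **Resting event** — maximal run of ≥ 5 consecutive steps in which the
  queen did not translocate; it ends as soon as she moves forward once.
* **Court size** — workers on the queen's side within 2.5 cm
  (centre-to-centre, inclusive) of the queen; for event statistics it is
  sampled at the event midpoint step, and summarised as mean, median and
  IQR (linear-interpolation quartiles).
* **Time budget** — steps inside runs of *more than 5* consecutive
  translocations count as displacement; all other steps (full stops and
  short wiggles) count as resting.
* **Rest→walk transitions** — resting events terminated by a forward move;
  an event still open at the end of a series is not counted.
* **Worker-speed sweep** — independent seeded replicates across v_W values,
  reporting per-run mean court size (over all steps) and transition counts.
* **Imprint rendering** — every stamp interval, eligible workers (near the
  queen and/or still for a minimum time) add a low-alpha body-disc imprint
  to a raster; dense marks show long residence, the halo of a stable court.

On the empirical side, queen-court events (QCEs) are detected on tracked
trajectories (default 4 s frame interval, ~5 px/mm) as maximal runs of
inter-sample speeds below 1 px/s lasting strictly longer than 48 s
(an inclusive-duration switch exists; speeds are raw consecutive-sample
displacements, unsmoothed). Event frame stacks are cropped to 360 × 360 px
windows clamped at frame borders, jointly normalised to the global
min/max, median-projected per pixel, and histogram-equalised; a fully
constant stack maps to mid-gray by convention. Court-size samples are
compared with a two-sided Mann–Whitney U test (exact for combined n ≤ 20
without ties, otherwise the tie-corrected normal approximation without
continuity correction so identical samples give p = 1).

## Design choices where the rules were genuinely open

* **Sensory gating of chemotaxis.** Gating only the *downhill* branch by
  Θ_min is catastrophic: dishabituation drags every worker's threshold
  below its local trace concentration, the entire colony becomes
  permanently uphill-oriented and the simulation gridlocks (verified:
  colony-wide translocation ceases within ~30k steps). Gating *both*
  branches — pheromone below Θ_min is simply not sensed — yields the
  intended rhythmic attendance and is what the field's description of a
  sensing threshold implies.
* **Blocking granularity.** Occupancy is per patch (one agent centre per
  1 × 1 cm patch), not per body disc. Hard-disc blocking at realistic radii
  caps the court at ~8 bees within the 2.5 cm counting radius (a single
  contact ring), which contradicts observed court sizes of up to 13; patch
  occupancy gives a capacity of ~20 and reproduces the observed range.
  Body radii (worker 0.55 cm, queen 0.9 cm) are kept for wall margins and
  rendering.
* **Dishabituation trigger.** By default the intermediate regime (sensed
  but not positively responding) leaves Θ_taxis unchanged, so a worker must
  physically leave the plume before resensitising — this produces the
  away-excursions. A config switch (`dishabituate_when_not_responding`)
  enables the alternative reading.
* **Comb geometry.** Default 40 × 30 patches with the brood disc (radius
  8 cm) at the centre. The criterion was thermotactic containment: the
  Θ_temp contour must sit several cm inside the walls so the cool moat can
  steer the queen back before she reaches the boundary, where pinned
  headings plus a blocking court can otherwise deadlock her. At a height of
  25 cm the moat is ~2.5 cm and the queen spends up to ~17% of her time at
  walls; at 30 cm the moat is ~4.5 cm and wall time drops to ~0.3%.
* **Threshold update timing.** The habituation update uses the pheromone
  concentration sensed during the orientation phase of the same step (the
  stimulus that drove the decision), not the post-diffusion field.
* **Two-sided mode.** Optional; two identical comb faces with per-side
  pheromone fields and no mass exchange. An agent whose move enters the
  horizontal crossing band from outside switches side with position and
  heading preserved (occupancy is checked on the destination side).
  Validation runs are single-sided.

## What the defaults reproduce, and what they do not

With all published parameters (E = 10, μ = 5%, D = 1.0,
p_thermotaxis = 0.125, Θ_temp = 1.0, Θ_min = 2.5, p_turn = 0.6, ±15°,
p_move = 0.3, v_Q = 0.9, v_W = 0.6, λ = 0.005/0.05, N = 100) the simulator
reproduces, qualitatively and robustly:

* dynamic courts that assemble around a resting queen, churn member by
  member (court size swinging by ≥ 5 bees within single long events, in the
  observed 5–13+ range), dissolve, and re-form elsewhere;
* per-worker alternation between attendance epochs (mean distance to queen
  < 5 cm) and away-excursions (> 10 cm), for every worker, within 50k steps;
* the macroscopic sweep trends: faster workers → larger courts (sublinear,
  saturating) and fewer rest→walk transitions.

Quantitatively, the stationary court-size distribution at resting-event
midpoints is wider and heavier than the published one (mean ≈ 9.5–10.3
bees, IQR ≈ 15 across seeds, versus 7.4 and 3): long blockade events
saturate the patch capacity around the queen (~15–20 bees) while travel
phases scatter micro-rests with courts near zero. Likewise the queen's
displacement share under the literal "> 5 consecutive translocations" rule
is ≈ 0.01% rather than ≈ 8%: with an independent Bernoulli motion gate of
p_move = 0.3 per step, the expected fraction of steps inside ≥ 6-success
runs is bounded by ~0.3% *regardless of blocking*, so the published figure
requires motion persistence (behavioral walk/rest states of the queen) that
the written rule set does not contain. Both gaps point at the same missing
ingredient — the queen's wiggle/rest/walk state structure, which is only
shown as an unreadable figure in the source material and is deliberately
not invented here. The affected headline statistics are reported as
computed, without adjustment.

## Synthetic data

The fixtures module generates every input the empirical pipeline needs:

* **Scripted trajectories** — alternating rest/walk segments sampled at the
  4 s frame interval with optional Gaussian positional jitter; the exact
  rest intervals are returned as ground truth. With zero jitter and walking
  at ≥ 2× the speed threshold the QCE detector recovers the script exactly;
  jitter of a few px at 4 s spacing raises apparent speeds above 1 px/s and
  blinds it, which documents the detector's sensitivity to tracking noise.
* **Image stacks** — a static disc pattern (queen plus court stand-ins)
  with per-frame random distractor blobs and Gaussian pixel noise, plus the
  static mask. These are abstract discs, not rendered bees; the median
  stack procedure is content-agnostic.

What the generators do *not* emulate: real IR illumination gradients,
comb texture, partial occlusions, or tracking dropouts. Passing the
fixture-based tests therefore validates the algorithms' logic, not their
robustness on real hive footage.

## Numerical notes and problem sizes

* Temperature relaxation: Jacobi iteration to 1e-8, typically a few
  thousand sweeps on the 40 × 30 grid, computed once per run.
* The motion resolver and the per-step gradient maps are numba kernels;
  a default step costs ~0.13 ms, so a simulated day (350k steps) takes
  under a minute.
* Test and acceptance problem sizes: one 350,000-step default run backs the
  court statistics (~1,700 resting events after a 5,000-step burn-in), the
  time budget and the dynamics envelope; the sweep uses v_W ∈
  {0.1, 0.3, 0.5, 0.7, 0.9} × 10 replicates × 30,000 steps.
* Degenerate inputs are defined, not left to chance: empty event lists and
  empty samples are rejected; a constant image stack equalises to mid-gray;
  crop windows clamp at borders; capacity violations at initialisation
  raise immediately.

## Known limitations

* No egg-laying, brood-pattern feedback, contact-borne or footprint
  pheromone transport, feeding/licking interactions, or queen behavioral
  states — single-rule queen locomotion only.
* Pheromone is a single abstract scalar; no chemical calibration.
* One agent per cm² is a coarse packing model near walls and in dense
  courts.
* The empirical pipeline expects already-tracked positions; no bee
  detection or video decoding.
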