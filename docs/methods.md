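# Methods

## Ingestion and conditioning

Tracking exports are one subject per CSV (`fish_id,t_s,x_m,y_m`; column
names remappable, multiplicative unit conversion to m/s on read). All
internal computation is SI. Frames outside the declared arena are dropped
and treated as tracking gaps rather than clamped — a tracking jump snapped
to the wall would manufacture wall-hugging, which is itself a behavioral
variable here. A subject is rejected when more than 20% of frames are
dropped (configurable).

Gaps up to `max_gap_s` (default 0.5 s, brief occlusions at 30 fps) are
filled by linear interpolation at the modal frame interval; longer gaps
become recorded segment breaks, and no step, speed or turn computation ever
bridges a break. Linear interpolation cannot leave a convex arena when both
gap endpoints are inside it, so filling never produces out-of-bounds
points in the tank; in the Y-maze the same holds per convex zone.

## NTT endpoints

* **distance traveled / absolute turn angle** use a minimum-displacement
  filter: displacement is accumulated from an anchor point and registered
  once it exceeds the noise floor (default 0.002 m); the registered
  displacement vectors define both the path length and the headings whose
  absolute changes are summed (degrees). This is the convention of
  commercial tracking software; summing raw frame steps instead would let
  sub-millimeter centroid jitter dominate both endpoints at 30 fps, and
  dropping sub-floor steps entirely would erase smooth slow swimming.
* **maximum speed** is the maximum frame step length over step duration,
  within segments.
* **distance from bottom** is the duration-weighted (trapezoid) mean of the
  vertical coordinate — robust to uneven frame intervals, unlike a plain
  frame average.

## Boldness index and classification

Components are min–max normalized over the analyzed cohort, making 0 and 1
the attainable extremes and the 0.67/0.33 weights directly interpretable;
the index is therefore invariant to affine unit rescaling of the raw
endpoints. A z-score normalization would preserve rank order but not the
[0, 1] anchoring. A constant component is an error (ranking impossible),
not silently zero.

The phenotype split sorts fish by (index, normalized distance from bottom,
subject id) descending and labels the top ⌊n/2⌋ bold: equivalent to a
median split with a deterministic tie rule, balanced for even cohorts, the
median fish of an odd cohort going to the shy side. Classification is
permutation-invariant and every bold fish's index is ≥ every shy fish's.

## Tetragram analysis

Overlapping windows of four turns, stride 1: `n − 3` tetragrams for `n ≥ 4`
turns. Percentages are over **total tetragrams**, not total turns — the
only denominator under which the 16 pattern percentages sum to 100; the two
differ by at most 3 counts (≤ 3/(n−3) relative). Alternations =
LRLR + RLRL, repetitions = LLLL + RRRR.

Per-bin ("immediate strategy") profiles recompute tetragrams inside each
10-min bin so windows never span a boundary and each bin is
self-contained; the global profile uses the unbroken session. Bins with
fewer than four turns report zero tetragrams and undefined percentages.

Arm entries are registered when the centroid penetrates an arm ≥ 0.01 m
past the center triangle and dwells ≥ 0.2 s (debouncing); same-arm
re-entries collapse. Chirality: arms labelled counterclockwise from above,
counterclockwise transition = L. The study-level summaries are invariant to
this convention by L↔R symmetry, which the tests assert.

## Statistical models

Standard machinery, delegated: scipy (KS, Bartlett, pooled t), statsmodels
(OLS + Type-II `anova_lm`, Tukey HSD), pingouin (mixed ANOVA). Choices
where the analysis plan is open:

* **Type-II sums of squares** — the designs are balanced by construction,
  where the SS types coincide; Type II remains sensible under the mild
  imbalance of an n = 11/12 split.
* **ANCOVA** in homogeneity-of-slopes form (no factor × covariate term).
  A constant covariate degrades gracefully to the plain two-way ANOVA
  (noted in the result), collinearity with the design is an error.
* **RM-ANOVA sphericity**: Greenhouse–Geisser correction applied when
  Mauchly's test rejects at 0.05 (`pingouin` `correction='auto'`);
  incomplete subjects are listwise-deleted and named in the result notes.
* **Degenerate fits**: when residual variance is at roundoff scale relative
  to the response (constant response, exactly collinear covariate), all F
  and p are reported as NaN with a note instead of 0/0 noise.
* Assumption checks are reported, not gating. α = 0.05 throughout; no
  multiplicity control beyond Tukey.

## Synthetic cohort: what it emulates, what it does not

**NTT**: correlated random walk — per-frame heading N(0, 0.6 rad) random
walk, speed |N(0.03, 0.015)| m/s, 30 Hz, 360 s, reflecting walls, start at
bottom center. A constant vertical drift of +2.5e-3 m/s (bold) or −2.5e-3
(shy), with 2e-4 between-fish SD as the continuous latent trait, against
the walk's effective vertical diffusion (~5e-5 m²/s; heading persistence
correlates increments) yields top-fifth vs. bottom-fifth stationary
occupancy and mixes within a session (column crossing ~40 s). The drift was
calibrated once so the boldness classifier operates in its stated
large-effect regime (≥ 90% latent-phenotype agreement); an early weaker
value (4e-4 m/s) is a worked counter-example — the tank fails to mix in
360 s and classification collapses to chance.

**Y-maze**: Poisson turn times at 6 turns/min (≈ 360 turns/h, typical of
hour-long maze sessions); first token a fair coin; each later token
alternates with probability a(t). Baselines a = 0.70 (bold) and 0.80 (shy)
put control alternation percentages near a³ = 34% and 51% and repetitions
near (1−a)³ = 2.7% and 0.8%. Under acute stress a(t) dips by up to 0.25
(clipped to [0, 1]) in a Gaussian bump (SD 300 s) centered on bin 5
(40–50 min) for bold fish and bin 6 for shy — the bold repetition peak one
bin earlier. Between-fish SD of a is 0.02.

These defaults reproduce, at n = 11–12 per phenotype × treatment cell,
every qualitative effect the analysis is designed to detect: stress raises
repetitions in both phenotypes, stressed bold fish alternate least, and
the bold repetition peak precedes the shy one. What the generator does
**not** emulate: burst-and-glide locomotion, habituation within the NTT,
higher-order choice dependence, inter-turn interval structure beyond
Poisson, sex effects, or the original study's effect magnitudes — a green
pipeline test certifies the machinery and the direction structure, not the
published F statistics, which require the original recordings.

## Numerical conventions

* Timestamps strictly increasing; equality comparisons on arena bounds use
  1e-12 m tolerance.
* Tetragram percentage conservation is exact to 1e-9.
* Turn events exactly on the session end fall into the last bin.
* Seeds: a cohort is a pure function of (config, seed); per-fish streams are
  spawned from `numpy` `SeedSequence(seed)` so fish are independent and the
  cohort is reproducible bit-for-bit.

## Known limitations

* The boldness normalization is cohort-relative: indices are not comparable
  across cohorts, only ranks within one.
* Arm-entry detection assumes reasonably clean top-view tracks; heavy
  dropout inside the center zone can merge visits.
* The RM-ANOVA drops fish with any empty bin rather than imputing.
* With fewer than ~5 fish per group the inferential stage refuses to run
  (insufficient-data errors propagate as pipeline failures by design).
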