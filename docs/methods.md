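# Methods

## The measurement model

A sled friction test tows a pair of stem segments across a roughened
card substrate at constant speed `v = 3 mm s⁻¹` for `L = 20 mm`,
sampling the pulling force at `r = 50 s⁻¹` (one sample per 0.06 mm).
The trace is analysed as two phases:

1. **Static phase.** Force rises roughly linearly while the sled is
   stationary (the compliance of thread and microspine bed acts as a
   spring). The first local maximum with sufficient topographic
   prominence is the static friction force; its distance `d_peak` marks
   slip onset.
2. **Sliding phase.** The analysis window is the half-open interval
   `(d_peak, d_peak + 15 mm]` — the static-peak sample itself is
   excluded. Within it the package measures the mean force, the
   coefficient of variation, the stick–slip peaks, their density per
   mm, and the mean of the 10 highest raw peak forces.

### Peak identification

The sliding signal is a drifting baseline plus sawtooth events plus
sensor noise. Identification proceeds in three steps:

- **Extrema.** Sign changes of successive differences give alternating
  maxima/minima. Zero differences inherit the previous nonzero sign, so
  a plateau contributes one extremum at its last sample — a
  deterministic tie-break that makes the output independent of float
  idiosyncrasies.
- **Detrend.** A least-squares straight line through all extrema
  (maxima and minima jointly) tracks the midline of the stick–slip
  envelope; subtracting it removes drift. With fewer than two extrema
  the fallback is the segment mean. A line through the extrema rather
  than through all samples was chosen because extrema weight the
  envelope rather than the dwell times of the signal; the construction
  is a design choice, as is the joint (rather than per-envelope) fit.
- **Peaks.** Local maxima of the detrended signal qualify when their
  topographic prominence reaches a threshold and survive a greedy
  minimum-separation filter (higher peak wins; earlier on ties).

Defaults, all config-exposed:

| parameter | default | rationale |
|---|---|---|
| static-peak prominence | max(5% of global max, 3× median \|Δforce\|) | rejects noise blips on the loading ramp |
| peak prominence | max(1.5× MAD of detrended signal, 3× robust noise sd) | MAD term scales with stick-slip amplitude; the noise floor (σ̂ = 1.4826·MAD(Δ)/√2) rejects pure-noise maxima |
| minimum peak separation | 3 samples (0.18 mm) | instrument resolution; two anchorage events closer than this are not distinguishable at 50 s⁻¹ |
| top-k peaks | 10 | the "mean of the 10 highest peaks" summary |

Top-k peak forces are read from the **raw** trace at the identified
positions; detrending is used only to locate peaks, not to value them.

Truncated windows (static peak later than 5 mm) are analysed with the
frequency normalised by the actual window length and flagged
`TRUNCATED_WINDOW`; below 10 mm they are additionally flagged
`SHORT_WINDOW` so downstream summaries can exclude them from top-k
statistics.

## Normal-force calibration

`normal_force_from_mass(m)` returns `(m/2)·9.8` mN for `m` in grams: a
searcher attached at its base and resting on a support near its apex
loads the support with about half its weight. Cane-like climbers rest
one stiff internode at a time, so `normal_force_cane(m, k)` divides the
whole mass by the internode count instead; the internode count is a
required user input. `g = 9.8 m s⁻²` exactly — the published
gram-to-millinewton conversions are exact multiples of 9.8, which
9.80665 would not reproduce.

## Anisotropy

Per test, anisotropy is the basal/apical ratio of static (or sliding
mean) force. The species-level summary is the **mean of per-test
ratios** with a t-based 95% CI, not the ratio of mean forces: published
species-level anisotropies exceed the ratio of the corresponding mean
forces, which identifies the averaging order. A Wilcoxon signed-rank
test of ratio − 1 tests for directionality.

## Statistical layer

- **Omnibus:** one-way ANOVA gated by Shapiro–Wilk (pooled residuals)
  and Levene tests at α = 0.05; on failure the analysis switches to the
  tie-corrected Kruskal–Wallis test and records the switch. All values
  tied defines H = 0, p = 1.
- **Post hoc:** Tukey HSD (Tukey–Kramer under unequal n, via scipy's
  studentized-range implementation) at family α = 0.05. The compact
  letter display assigns one letter per maximal clique of the
  non-significance graph (Bron–Kerbosch enumeration), so two groups
  share a letter **iff** their pairwise p ≥ α; letters follow
  descending group means. When the nonparametric branch was taken, the
  comparisons run on pooled mid-ranks and the hybrid is noted.
- **Paired tests:** Wilcoxon signed-rank, two-sided; zero differences
  dropped; exact enumeration for n ≤ 25 without ties in |d|, otherwise
  the normal approximation with continuity and tie correction. All
  differences zero returns p = 1 with a note.
- **Correlation/regression:** Spearman ρ with tie-corrected p; OLS with
  slope t-test and R²; standardized major axis (SMA) with slope
  `b = sign(r)·s_y/s_x`, intercept through the centroid, and the
  classical CI `b·(√(B+1) ± √B)`, `B = F₁,ₙ₋₂(1−α)·(1−r²)/(n−2)`. The
  "major axis" fit is implemented as *standardized* major axis; exact
  zero correlation is an error since the slope sign is undefined.
- Two-sided tests throughout; no multiplicity correction beyond Tukey's
  family control.

## Synthetic-trace generator

The generator is phenomenological — it reproduces the statistical
structure the pipeline assumes, not microspine contact mechanics
(no hook bending or interlocking model).

- **Ramp:** `force = k·d` up to the grid point where the
  direction-scaled static force is reached; that sample is set to the
  static force exactly, so the noise-free trace has a local maximum
  equal to it.
- **Post-peak drop:** `post_peak_drop` is the fraction of the
  static-to-sliding drop taken instantly at slip (default 1 = drop
  straight to the sliding level); any remainder relaxes linearly over
  0.5 mm. The "fraction retained" reading of this knob would contradict
  the noise-free ramp-then-constant limiting behaviour, so the
  fraction-of-drop reading was adopted.
- **Events:** positions follow a homogeneous Poisson process on the
  post-peak span. The hard-core minimum separation (4 samples) is
  imposed by the shrink-and-spread construction — draw
  N ~ Poisson(λ·ℓ), place N uniforms on the interval shortened by
  N·τ, spread by τ — which preserves the exact Poisson count law
  (naive dead-time thinning would bias the realised rate ~15% low at
  λ = 1.5). Positions are snapped to the sampling grid: an event
  registers at the sample where the transducer sees it, and snapping
  keeps the slip apex representable in the sampled trace. Four samples
  rather than the analyser's three because localisation can shift a
  detected peak by one sample.
- **Event shape:** an asymmetric triangle — linear rise over
  `event_shape = 0.8` of the gap to the left neighbour, linear collapse
  over the remaining fraction of the gap to the right — the canonical
  slow-load/fast-release stick–slip form. Amplitudes are lognormal.
- **Anisotropy:** one multiplicative factor applied in the basal
  direction to the static force, the sliding baseline and the event
  amplitudes. Scaling the static force too (not only the sliding
  quantities) is required for the basal/apical static ratio to estimate
  the factor, which is the point of the knob.
- **Noise:** additive white Gaussian noise everywhere (default
  σ = 1 mN, a free choice — the transducer's noise figure is not
  published); forces are clipped at zero (tension-only transducer).
- **Presets:** a weak close twiner (static 10.5 mN, λ = 0.7, anisotropy
  1.4) and a strong scrambler (static 31 mN apical, λ = 1.5, anisotropy
  5.6) bracket the observed force range (~8–175 mN basal).

What the generator does *not* emulate: substrate wear across repeated
tests, within-species parameter heterogeneity, event-amplitude/rate
coupling, non-Gaussian sensor artefacts, or speed dependence. Passing
recovery tests therefore show the pipeline is correct under the model's
assumptions, not that real traces satisfy them.

## Validation experiments and problem sizes

- **Oracle equivalence:** extrema and peak identification against
  brute-force enumeration on 1000 random segments of ≤ 30 samples.
- **Parameter recovery:** 100 replicate studies, 2 species × 25 paired
  tests, sensor noise 1 mN, event amplitudes with median 10 mN
  (noise = 10% of the median amplitude, the regime where events are
  identifiable at this sampling density), rates 0.7 and 1.5 mm⁻¹ and
  anisotropies 3.0 and 1.0 spanning the observed range. Measured:
  static-force error (≲0.4%), event-rate error, anisotropy CI coverage.
  The event-rate estimate is biased a few percent low at λ = 1.5:
  events closer than the separation filter, sub-threshold amplitudes
  and unsampled valleys between overlapping events are structural
  losses at 50 s⁻¹, documented rather than hidden by tuning.
- **Statistical layer:** exact Wilcoxon vs full sign enumeration for
  every n ≤ 10; Kruskal–Wallis null rejection over 2000 simulated
  datasets (10 × 20); the SMA closed-form identity on random samples;
  SMA recovery of a true slope 1.6 at n = 250 with CI excluding 1.

These sizes keep the whole suite near 30 s on one CPU while leaving
Monte-Carlo error well inside the tolerances tested.

## Known limitations

- The detrending line is global per window; strongly curved drift
  (e.g. progressive substrate wear within one pass) is only removed to
  first order.
- Peak localisation at sparse rates wanders a few samples around the
  true apex when the rise slope is comparable to the noise.
- The anisotropy knob cannot represent species whose static and sliding
  anisotropies differ (published tables show they do); one factor
  drives both.
- Exact Wilcoxon switches to the approximation in the presence of tied
  |differences| regardless of n.
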