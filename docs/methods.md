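# Methods

## Scope and data model

The pipeline starts from tracked coordinates, never video. A `Trajectory`
holds one fish's per-frame time (s), position (arena-local millimetres)
and a tracking-success flag, with a nominal frame rate (25 fps for all
packaged paradigms). Rectangular arenas use a lower-left origin;
circular wells are centred on the origin, y increasing upward. Pixel
inputs must be calibrated to millimetres upstream; the tracking CSV is
the exchange format (`trial_id, fish_id, t_s, x_mm, y_mm, valid`).

Trajectory hygiene: invalid frames inside dropouts of at most 1 s are
bridged by linear interpolation; frames in longer dropouts are excluded
from both dwell-time and distance accrual, and any distance bin with more
than 20 % excluded frames is flagged and omitted from window means. The
1-s/20 % thresholds are package defaults chosen to tolerate the brief
occlusions commercial trackers produce without inventing movement across
long blackouts.

## Metric conventions

* Distance is the sum of Euclidean step lengths between consecutive
  usable frames; a step belongs to the time bin (and the spatial zone) of
  its starting frame, which makes bin sums conserve total path length
  exactly.
* Dwell time is frame count × frame interval.
* Zones are pairwise-disjoint shapely regions; a point on a shared
  boundary belongs to the first zone listed in the partition, a
  deterministic and order-documented tie-break.
* The open-field periphery/centre split is *equal-area* (central
  rectangle scaled by 1/√2 per side, or central disc of radius r/√2).
  An equal-border-width split would move the unbiased-walker expectation
  away from 0.5 and make thigmotaxis values incomparable across tank
  sizes; the choice is configurable via a custom partition.
* The juvenile social sectors are the two chord bands of the well cut
  perpendicular to the social axis at ±d/4 from the centre (the quarter
  zones nearest the conspecific and the empty stimulus wells); the middle
  half of the well counts toward neither sector and is excluded from the
  SPI denominator. The adult test compartment is split into two equal
  sectors parallel to the divider.
* The visual motor response is the after/before mean-speed *ratio* over
  30-s windows around each transition, averaged per fish over the three
  same-direction transitions. A ratio with zero pre-transition speed is
  undefined and excluded from the mean rather than imputed. The ratio
  convention is documented deliberately: published descriptions of a
  "rate of velocity change" do not pin down a formula, and the ratio is
  dimensionless, scale-invariant, and monotone in the startle effect the
  assay targets.
* Mean speed within a window divides accrued distance by accrued *step*
  time (not frame count), so constant-speed segments are recovered
  without an end-frame bias.

## Trajectory simulator

The generator is a discrete-time correlated random walk at the assay
frame rate (Δt = 1/fps). Speed follows an Euler-discretised
Ornstein–Uhlenbeck process, clipped at zero, relaxing toward

    mu_target(t) = mu_speed · (g_dark if dark else 1) · (1 + startle_gain · e(t)),

where `e(t)` sums `exp(−Δt′/tau_startle)` over past illumination
transitions (both directions). Heading accumulates wrapped-Gaussian turn
noise with standard deviation `(1 − kappa_heading) · π · √Δt` per step,
plus turn-rate biases of `BIAS_GAIN · kappa · wrap(bearing − heading)`
rad/s toward the nearest wall (`kappa_wall`), toward the wall point
nearest the conspecific sector (`kappa_social`, active only in the test
period of a social trial), and toward the instantaneous group centroid
(`kappa_cohesion`, shoals). Walls reflect position and heading; a
reflected step can never leave the arena.

`BIAS_GAIN` = 0.1 keeps order-one kappas below the regime where the
walker pins to its target: over `kappa_wall` ∈ {0, 0.5, 1, 2} the mean
peripheral time fraction rises ≈ 0.49 → 0.71 → 0.93 → 0.98, a usable
dynamic range with strict monotonicity.

Determinism: each fish consumes only its own `numpy` Generator stream
(initial state first, then one speed/turn normal pair per step), seeded
per fish (`seed + fish_index` in groups). A fish's track is therefore
bit-identical whether simulated alone or batched, which the cohort
helpers exploit for vectorised multi-fish stepping.

### Genotype presets

Presets encode the knockout line's reported effect *directions* —
homozygotes slower, more wall-attracted, more startle-reactive, less
socially attracted, less cohesive; heterozygotes intermediate. Baseline
speeds come from the printed per-genotype group means (larvae
81.5/63.8/54.9 mm per 30 s → 2.72/2.13/1.83 mm/s; adults 155/123 mm per
30 s → 5.17/4.11 mm/s, HET interpolated at 4.60). The remaining
magnitudes are implementer choices fixed once: `kappa_wall` 0.7/0.8/1.1
(yielding open-field time ratios near the reported 0.83/0.92),
`startle_gain` 1/1.5/2 (larvae; halved for adults), `kappa_social`
2/1.2/0.5, `kappa_cohesion` 1.5/1.0/0.4, `g_dark` = 3 for larvae (dark
phases are several-fold more active than light in this assay),
`sigma_speed` = 1 mm/s (larvae) / 2 mm/s (adults), `tau_speed` = 2 s,
`kappa_heading` = 0.85, `tau_startle` = 10 s.

### What the generator does and does not emulate

It reproduces the statistical structure the metrics must detect:
genotype-dependent mean speed, wall bias, dark gain, transition startle,
social-side attraction and shoal cohesion, inside the real arena
geometries at the real frame rate. It does not model burst-and-glide
swimming, freezing bouts, body shape, tail kinematics, hydrodynamic
interactions, depth, or between-fish personality variance beyond the OU
noise. Passing direction-of-effect tests therefore shows the
metric + statistics pipeline recovers effects of this kind and size from
trajectory data — not that real mutant fish would produce these exact
numbers.

## Statistics

Normality gating is per-group Shapiro–Wilk at α = 0.05 (any rejection, or
a zero-variance group, routes the metric to the rank branch). Two groups:
Student's *t* or Mann–Whitney U (the rank fallback is flagged in reports
as an extension, since the conventional scheme names only the *t*
family). Three or more: one-way ANOVA with Dunnett's test against the
wild-type reference (scipy's implementation, quasi-Monte-Carlo seeded for
reproducibility) or Kruskal–Wallis with Dunn's test. Dunn's comparisons
use pooled mid-ranks with tie correction,

    z = (R̄_ref − R̄_g) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_ref + 1/n_g)),

two-sided normal p, Bonferroni-adjusted over the comparisons against the
reference. Paired designs use the paired *t*. Summaries are mean ± SEM
(SEM = sd/√n, n−1 denominator) or median with a seeded 10⁴-resample
percentile-bootstrap 95 % CI; the bootstrap choice for the CI is
documented rather than prescribed by any source. Count tables render
`n/N (p%)` with one-decimal half-up rounding, integral percentages
without the decimal.

## Problem sizes

Tests and the acceptance script shrink recordings, not effects or group
sizes: 5-min open field, a 9-min light/dark schedule with the same
8-epoch structure (60-s cycle epochs), 4+4-min social trials, 4-min
shoals, with group sizes 25/33 (open field, light/dark), 17/17 (juvenile
social) and 9/10 shoals of six. The two simulator calibration checks run
at full assay length (30 min, 45 min; 20 seeds each). Effect directions
are duration-independent in this generator; shorter recordings only
widen per-fish variance, which the stated group sizes absorb comfortably.

## Known limitations

* Entry counts ("frequency of contact") are deliberately secondary: no
  formula-defined published counterpart exists, so they are not part of
  SPI.
* Dunnett p-values carry ~1e-5 quasi-Monte-Carlo quadrature noise;
  equality comparisons against other implementations are meaningful only
  to ~1e-3.
* The reader validates the canonical CSV dialect only; proprietary
  tracker exports need a `column_map`.
* Binned-distance input supports activity profiles only — zone- or
  speed-resolved metrics require full trajectories and refuse binned
  input.
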