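# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `ethosleep`, in the order data flows through the
package.

## Time conventions

All timestamps are seconds since recording start. Zeitgeber time is
`zt(t) = ((t − lights_on_s)/3600) mod 24`, with ZT0 = lights-on and day
boundaries at ZT0. Binning is half-open `[start, end)` everywhere; every
module consumes time through `ethosleep.io.zt` / `day_index` so the
convention exists in exactly one place. Positions are mm from the food end
(food = 0).

## Sleep and state scoring

* **Immobility** is `v_max < T_v` per 10-s epoch, strict. `T_v` is a
  property of the upstream tracker's velocity calibration and has no
  universal value; the default is 1 mm/s and every entry point takes it
  explicitly.
* **Stimulus masking**: epochs overlapping `[onset, onset + 6 s)` of a tube
  rotation are masked, because the spin itself registers as velocity.
  Masked epochs are *neutral*: excluded from sleep scoring but not treated
  as movement. Treating them as mobile would let the stimulus protocol
  trivially abolish every immobility run and with it all residual sleep of
  non-compliant animals, which contradicts what chronic-deprivation sleep
  traces show.
* **Sleep (5-minute rule)**: a candidate run is a maximal stretch of
  immobile-or-masked epochs trimmed to its first and last genuinely
  immobile epoch. Runs strictly longer than 300 s are sleep bouts, asleep
  in full (first 300 s and interior masked epochs included). A bout of
  exactly 300 s is not sleep.
* **Minute states**: minutes are anchored at recording start (six 10-s
  epochs; an incomplete trailing minute is dropped). Quiescence requires
  every epoch immobile — velocity alone decides, displacement is not
  additionally checked. Otherwise the within-minute path length
  `Σ|Δx|` (five epoch-to-epoch differences) below `T_d` = 15 mm is
  micromovement, at or above it walking. `T_d` reflects the empirical
  bimodality of per-minute displacement in tube-housed flies.
* **Position normalisation** uses the 1st/99th percentiles of the animal's
  full recording rather than min/max, so spurious detections beyond the
  tube's physical limits do not stretch the scale; outputs may slightly
  exceed [0, 1] by construction. Quantiles are computed per recording
  session.
* **Virtual beam monitor**: activity = change of side relative to the tube
  midline between consecutive epochs; crossing-free intervals longer than
  300 s count as sleep in full. Since micromovement never crosses the
  midline, this bounds ethogram sleep from above whenever walking does
  cross — which the simulator's walking emission guarantees.

## Homeostatic rebound

`H_i = R_i − (α + β B_i)` with `(α, β)` the population-covariance OLS of
rebound on baseline window sleep in the control group; the covariance and
variance use the same 1/n normalisation, so the factor cancels. Windows
default to ZT0–3; the baseline day is configurable (the same window on the
last pre-treatment day). Controls are the same-run undisturbed animals by
default. The group CI is a basic bootstrap (n = 1000) that resamples
*both* groups and refits `(α, β)` per replicate — resampling treated
residuals alone ignores the calibration uncertainty and undercovers badly
(0.79 observed vs 0.95 nominal in 500-replicate null simulations; the
two-group form achieves 0.958). Significance is "CI excludes zero"; no
p-values anywhere, matching estimation-based practice.

## Fingerprints

Behavioral distributions are built from minute states (time *spent* in a
state), pooled across days into 96 quarter-hour ZT intervals
(average-then-distance). The Bhattacharyya coefficient is clipped to
[0, 1]; BC = 0 (disjoint supports) would give infinite distance and is
capped at −ln(1e-6) ≈ 13.8, preserving ordering while keeping UPGMA
finite. BD is a divergence, not a metric — the suite demonstrates a
triangle-inequality violation. UPGMA uses classical size-weighted
arithmetic-mean linkage, node heights at half the merge distance, and
breaks ties by the lexicographically lowest leaf label so trees are
deterministic; Newick branch lengths are height differences.

## Circadian variance decomposition

Classical additive seasonal decomposition (centered moving average over one
24-h period; per-phase means of the detrended series, re-centered;
residual = remainder), delegated to `statsmodels.tsa.seasonal_decompose`
and cross-checked against a hand-rolled moving-average oracle in the test
suite. This form was chosen over LOESS variants for exactness and
testability. Variance fractions are `Var(component)/Var(observed)` on the
trimmed support where the trend is defined — the only definition under
which the three fractions can sum near one. Default bin width 30 min;
period fixed at 24 h (no period estimation). A constant series yields all
fractions 0 with a `degenerate` flag.

## Population statistics

* **Basic bootstrap**: `(2θ̂ − q_{1−α/2}, 2θ̂ − q_{α/2})`, n = 1000,
  seeded; a vectorised path for the mean.
* **Kaplan–Meier** via lifelines; the median CI intersects the log(−log)
  Greenwood confidence band with 0.5 (Brookmeyer–Crowley style), which is
  the censoring-aware construction. The median is the first time with
  S(t) ≤ 0.5 — for ten uncensored lifespans 1..10 this is 5, where
  S(5) = 0.5.
* **Lifespan regression**: `lifespan ~ sleep × sex` as a full factorial
  OLS; per-sex slopes (equal to per-sex simple regressions) carry basic
  bootstrap CIs resampling animals within sex. Filters, applied and
  audited: untreated animals only, right-censored excluded, lifespan
  ≥ 20 days (removes the moribund period); sleep is the mean over the
  recording's initial days as provided in the cohort table.

## The simulator

An alternating-bout semi-Markov process. At each bout start a state is
drawn with weights `w_Q/g(zt)`, `w_M·g(zt)`, `w_W·g(zt)` where the
circadian gain `g` is 1 plus two von-Mises bumps (κ = 4) at ZT0 and ZT12
scaled by `circadian_amplitude`: the clock both drives dawn/dusk activity
and gates sleep propensity, giving realistic bimodal profiles
(`amplitude = 0` emulates clock-mutant / constant-dark flatness). After a
quiescence bout an active bout always follows (when active weights are
nonzero), so quiescence runs are single bouts and the analytic calibration
below is accurate. Durations are lognormal per state — quiescence
heavy-tailed (σ = 1) so sleep episodes beyond 300 s and bouts matching
triggers up to 1000 s occur naturally.

Emissions per epoch: quiescence — sub-threshold velocity, frozen position;
micromovement — supra-threshold velocity, ±1 mm jitter, relocated to
within 4 mm of the food with probability `food_attraction`; walking — a
tube-spanning zigzag crossing the midline every epoch. Mating doubles the
micromovement weight and shifts `food_attraction` up by 0.3. A lognormal
per-individual multiplier on the quiescence weight (σ_ind) gives stable
individual sleep propensity; `indiv_effect` lets two recordings share one
fly's multiplier.

**Closed loop**: once continuous immobility reaches `trigger_s`
(optionally only inside a deprivation window) a 1-s rotation is logged.
With probability `compliance` the bout ends and the fly startles into
`post_rotation_arousal_s` (default 30 s) of locomotion; otherwise the bout
continues and the immobility clock restarts after the rotation. The
30-s startle guarantees an unmasked mobile epoch after every compliant
rotation; with arousal 0 and quiescence-only weights the process
degenerates to the exact 21-s cycle (trigger 20 s + 1-s rotation), i.e.
171 rotations per hour. Rotations spin the tube about its axis: position
is unchanged, measured velocity spikes (masked downstream).

**Calibration**: the expected scored-sleep fraction has a closed form —
renewal occupancy of the one-quiescence-bout cycle on a fine circadian
grid, the lognormal partial expectation `E[d·1(d>c)]` for the strict
300-s rule (c = 300 s + half an epoch), minus one epoch per scored bout
for edge quantisation — and is inverted by Brent's method to hit a target
fraction. Recovery error is below 0.01 at targets 0.05/0.30/0.60.

**Defaults as study conditions** (chosen once, for realism): female
weights Q/M/W = 1/4/1.2 with quiescence median 360 s; male 1/1.6/1 with
median 520 s — scoring to ≈297 and ≈640 min sleep/day and strongly
female-biased micromovement. Compliance 0.9 (animals occasionally sleep
through a rotation). Lifespans are sex-specific Weibull (shape 5, scales
49.5/44 days, medians ≈46/41 days) shifted by `sleep_effect` (default 0:
sleep does not causally move lifespan) days per hour of daily sleep.
Cohort seeds derive from the master seed by `SeedSequence.spawn`, so
cohorts are reproducible under appending flies at the end.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: no homeostatic drive (rebound machinery is
validated on injected surpluses, and ladder runs show H ≈ 0), no
long-range fatigue trend in chronic deprivation (the trend variance
fraction is near zero where real flies show a slow decline), no tracking
noise or arousal-threshold modulation, no feeding/egg-laying mechanism
behind micromovement, and near-total sleep loss under short triggers
(scored residual sleep requires a bout to survive ~14 consecutive ignored
rotations, so any compliance above ~0.25 abolishes it — real recordings
retain a few percent).

## Problem sizes

The test suite simulates at desk scale: 30 flies × 3 days for sleep-target
recovery, 100 flies × two 3-day recordings for persistence, 50 females ×
2 days for scoring-platform dominance, 10+10 flies × 2 days for the
fingerprint split (one day per animal is too noisy at quarter-hour
resolution for reliable separation), 6 flies × 14 days for the clockless
chronic scenario, 12 flies per trigger over 54 h for the ladder, 100
replicate 60-fly cohorts for regression coverage and 500 replicates for
rebound coverage. `scripts/acceptance.py` uses 15–80 flies per quantity
with 1–10 day recordings and a 228-h chronic protocol pooled over 20 flies
per sex.

## Flatness testing

A chi-square uniformity test on binned activity is anticonservative for
bout processes (counts are overdispersed relative to Poisson by roughly
the squared coefficient of variation of the bout cycle), so the
flat-profile check uses a circular-shift permutation test: each day
profile is rotated by an independent random offset, preserving the bout
autocorrelation while destroying phase locking; the statistic is the
variance of the mean profile.
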