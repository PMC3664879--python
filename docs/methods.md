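# Methods

## The task and the model

The package models a two-interval forced-choice (2AFC) heterogeneity
detection task: both intervals show the same configuration of Gabor patches
sampling a contour, but in one interval a single patch is rotated away from
its base orientation by an orientation increment, and the observer reports
which interval contained it. Performance is summarized by the 75%-correct
increment threshold.

The core hypothesis is that sampled contours are represented by a
population of *arc units* (V4-like units tuned to curvature at a polar
angle relative to the shape's centre). Each arc — a contour segment over
which signed curvature keeps its sign — drives one arc unit; the unit pools
its elements' local responses multiplicatively, so one misaligned element
depresses exactly one unit. Performance is limited by strong *late* noise
at the arc-unit stage, and the decision follows a min rule: report the
interval whose weakest arc-unit response is weaker. Probability summation
over S independent noisy units then makes log thresholds rise linearly in
log S with a slope near 0.3, which motivates the closed-form threshold
equation

    T_x = T_base · S_x^0.3 · (C_avg,x / C_circle)^1 · (λ_x / λ_base)^0.5

with the effective arc count S_x, the shape's average unsigned curvature
C_avg,x, and the mean inter-element spacing λ_x.

## Geometry

Shapes are radial-frequency patterns R(φ) = r0·(1 + A·sin(Nφ + θ)); the
canonical study shapes are a circle (r0 = 2.7°), an RF4 with A = 0.18 and
an RF8 with A = 0.1, both high-amplitude, i.e. containing concavities.
Signed curvature uses the polar-curve formula
κ = (R² + 2R′² − R·R″)/(R² + R′²)^{3/2}, positive on convex segments
(1/r0 for a circle). Inflections are bracketed on a uniform grid of at
least 512 samples per modulation period (4096 minimum overall) and refined
by bisection to ~1e-13; a shape "contains concavities" iff min κ < 0 on
that grid. Arc segmentation cuts the contour at the inflections: 1 arc for
a circle or low-amplitude RF, 2N alternating arcs for a high-amplitude
RF N; a partial span keeps its fractional end arcs with their actual arc
lengths.

**Element placement.** "Equally spaced" means equal arc-length intervals
along the contour (uniform sampling density); the spacing covariate λ is
always the straight-line (chord) centre-to-centre distance, which is what
makes 5 equally spaced elements on the 2.7° circle come out at 3.2°.
Partial contours are built by a deterministic greedy walk: each successive
element is placed at the first contour point whose chord distance from the
previous element equals the target spacing (bisection on the arc-length
parameter). A walk that would wrap past a full revolution raises an
infeasible-spacing error.

**Jitter.** Each element is shifted forward along the contour by a polar
angle δ_i = δ_max·rand with rand ~ U(0,1) i.i.d. and
δ_max = 0.4·360°/n − 3°; for n > 48 the bound is negative and is clamped to
zero with a warning. Because δ_max depends only on n, it can exceed the
polar-angle gap between neighbours on densely sampled *partial* contours;
to keep element ordering intact in all cases each shift is additionally
capped at 95% of the gap to the next nominal element. The cap never binds
for closed equally spaced layouts (δ_max < 0.4 of the gap there).

**Curvature averaging.** The average unsigned curvature is computed by
numerical integration on a 2^16-point grid, by default weighted by the
contour line element (arc length): this is the convention the
curvature-discrimination literature describes ("average of local curvature
along the length of the contour") and gives 0.3704, 0.6186 and 1.1616 1/deg
for the circle, RF4 and RF8. A φ-uniform weighting is also available and
gives 0.6224 / 1.2169 for the RF shapes. Reference values of 0.6033 and
1.1795 have circulated for these two shapes; neither weighting reproduces
them (they correspond numerically to φ-uniform averaging of a contour with
r0 ≈ 2.786° rather than 2.7°, a convention we could not trace), so the
package reports its own well-defined quantities. The choice barely matters
downstream: the curvature covariate enters the threshold equation as a
ratio, and both weightings are scale invariant (C_avg·r0 is independent of
r0), which is what makes the predicted thresholds scale invariant.

## Threshold equation details

* `T_base = 7.4°`, the measured threshold for a 25-element circle, is the
  single empirical anchor; everything else is relative to it.
* `λ_base` is the chord spacing of 25 equally spaced elements on the 2.7°
  circle, 2·2.7·sin(π/25) ≈ 0.677°. This is ~6% below the nominal
  5-carrier-wavelength spacing (5/7° ≈ 0.714°) of the fixed-spacing
  experiment; the baseline is deliberately the 25-element circle itself.
* Effective arc count: a shape without concavities engages exactly one arc
  unit at any sampled length; a high-amplitude RF N engages 2N when closed
  and coverage·2N when partial (coverage = arc length from first to last
  element over the perimeter), floored at 0.05 so S stays positive for very
  short spans. The floor never binds for the experiment designs shipped
  with the package.
* Experiment designs: *shape alignment* (closed contours, n = 3…40, spacing
  co-varies with n), *spacing* (n = 7, chord spacing 0.4–2.3°, i.e. 3–16
  carrier wavelengths), *set size* (spacing fixed at 5 wavelengths,
  n = 3…25). In the set-size design the spacing covariate is held at the
  nominal experimental constant for every condition, and a walk that would
  wrap (the 25-element circle) degrades to the closed layout with
  coverage 1 — this keeps the circle's predicted set-size slope exactly
  zero and the RF slope versus arc count exactly 0.3.
* The spacing exponent is the only free parameter. With everything else
  fixed, least squares on log thresholds reduces to a one-parameter
  regression through the origin with a closed-form solution;
  `SpacingExponentModel.fit()` returns it with a standard error from the
  residuals. With a single distinct spacing the parameter is unidentifiable
  and the model refuses to fit.

## Observer simulation

`ObserverParams` has two mechanistic knobs: the Gaussian orientation-tuning
width of the local response, g(Δθ) = exp(−Δθ²/2σ²) with σ = 15° by default,
and the late-noise SD per arc unit. The noise scale is calibrated
analytically: for the baseline condition (one arc unit) the min-rule 2AFC
reduces to comparing two noisy draws, P(correct) = Φ(d/(σ_n√2)), so σ_n is
solved so the anchor increment of 7.4° sits at 75% correct. The default
tuning width of 15° is a conventional mid-range orientation bandwidth; it
was fixed once, and the calibration keeps the baseline anchored for any
choice.

Noise is i.i.d. across arcs, intervals and trials (no element-level noise —
the late noise is assumed to dominate). Non-integer effective arc counts
are rounded up to a whole number of simulated units. Ties under the min
rule are broken by a fair coin, which guarantees exactly 50% correct in
expectation at zero increment.

**Transducer.** Two mappings from orientation increment to the signal
decrement of the affected arc unit are provided. The default is a
baseline-calibrated *linear* transducer, d = inc·d75/(T_base·factor)
saturating at 1, where d75 is the decrement one unit needs for 75% correct
and `factor` is the condition's curvature·spacing factor; this keeps
simulated thresholds proportional to the threshold equation across
conditions (measured log-log slope of simulated on predicted thresholds
over the set-size design: ~1.0). The alternative Gaussian-tuned transducer,
d = (1 − g(inc))/factor, is quadratic at small angles, which compresses
large predicted thresholds (slopes ~0.75–0.85) — useful for exploring
tuning-limited behaviour, but not for quantitative comparison with the
threshold equation. A heavy-lower-tail "weibull-tail" late-noise family is
available besides the Gaussian.

**Set-size benchmark.** `simulate_sdt_setsize` is the pure
signal-detection version: S independent unit-noise channels, one carrying a
decrement proportional to the stimulus level, min rule, Weibull threshold
per S, OLS slope of log threshold on log S. With S ∈ {2, 4, 8, 16} and
2000 trials per level it lands at ~0.25 (seed-to-seed spread roughly
0.24–0.28), inside the 0.20–0.35 probability-summation band. Stimulus
levels are laid out geometrically (7 levels, ×0.25 to ×4) around the
analytic single-unit threshold scaled by S^0.3, which brackets every
psychometric function without using any simulation outcome.

## Psychometrics

The 2AFC Weibull P(x) = 1 − 0.5·exp(−(x/α)^β) is fitted by maximizing the
binomial log likelihood with the guess rate fixed at 0.5 and no lapse
parameter. The optimizer is multi-start Nelder–Mead on (log α, log β): six
log-spaced α starts spanning the tested levels crossed with β ∈ {1, 3},
β bounded to [0.2, 20], convergence at 1e-8 on the log likelihood. Datasets
that do not bracket 75% correct are reported as censored ("> max level" or
"< min level") with `converged=False` and are excluded from slope fits.
Thresholds are read at 75% (α·ln2^{1/β}) or any probability via the closed
form. Power-law slopes are ordinary least squares on log10–log10 axes
(statsmodels OLS, slope standard error included).

## What the simulations do and do not show

The synthetic data are generated by the package's own observer under the
study's stimulus parameters (shapes, spacings, set-sizes, jitter rule,
trial counts), so green tests demonstrate internal consistency: the
geometry feeds the threshold equation the covariates it expects, the
simulated observer reproduces the equation it was calibrated to, and the
fitting machinery recovers known parameters at realistic trial counts
(median |α̂/α − 1| < 0.1 at 6 levels × 40 trials). They do not validate the
model against human observers beyond the single 7.4° anchor: absolute human
thresholds, individual differences, lapses, learning, and the
random-orientation condition (whose set-size effect the arc-unit model
deliberately does not cover) are all outside what passing tests can show.

## Problem sizes

Default computations are small by construction: curvature averages use a
2^16-point grid (< 10 ms), inflection finding a 4096-point bracket + root
polish, observer simulations are vectorized over trials (a full set-size
benchmark at 2000 trials/level runs in well under a second). The whole test
suite, including 500-replicate exponent-recovery calibration and
200-dataset Weibull recovery, runs in about half a minute on one CPU.

## Known limitations

* The image-domain front end (centre/size extraction from pixels, the
  oriented-filter curvature bank) is not implemented; the model consumes
  analytic geometry, and stimulus rendering exists for stimulus generation
  and inspection, not for driving the observer.
* The mechanistic locus of the curvature and spacing factors in the
  simulator (a gain on the signal decrement) is a stand-in: the data the
  model summarizes constrain the factors' effect on thresholds, not their
  mechanism.
* The pattern-pair task used for random-orientation stimuli has no
  mechanistic observer here; random-orientation *stimuli* are fully
  supported.
* Monitor calibration, temporal presentation and masking hardware are
  recorded as metadata at most; rendered images are normalized luminance.
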