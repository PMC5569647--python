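# Methods

## The six measures and their identities

A point in demographic time carries six measures, all in years: three
*events* in calendar time — birth cohort C, period (observation time) P,
death cohort D — and three *durations* — chronological age A = P − C,
thanatological age (time to death) T = D − P, and lifespan L = D − C.
Any two members of a triad identity determine the third:

    APC: A = P − C    TPD: T = D − P    TAL: L = A + T    LCD: L = D − C

`complete()` applies these four equations to a fixpoint.  Because the
equations are linear and consistent, the fixpoint is unique and reached
in at most a handful of passes; completion is idempotent and independent
of rule order.  Of the 15 unordered pairs of measures, 12 generate a
third measure and three (L&P, C&T, A&D) generate nothing — a fact the
package derives from graph structure rather than a lookup table: in the
measure graph (a complete graph on 4 vertices, event edges fanning out
of a hub), a dyad is informative exactly when its two edges share a
triangle.

Knowing a full triad identity derives nothing further (TAL has no
calendar anchor), while any other triple of measures determines all six.

### Degenerate and invalid inputs

Supplied measures that contradict an identity by more than `eps`
(default 1e-9 years) raise an inconsistency error naming the identity;
derived negative durations raise a domain error (the general event
machinery in `demotime.events` permits negative durations; the
demographic layer does not).  Right censoring is encoded by an absent
death time — never a sentinel — and propagates as absence: a censored
lifeline yields only A, P, C.

### Calendar-year precision

Events given as ISO dates convert to decimal years on a 365.25-day
year.  Events known only to a calendar year follow a completed-year
convention: an opening event "in year y" is y.0; an event that *closes*
a completed duration in year y (a death in December y with a completed
lifespan) is carried at the boundary y+1.  Completed-year inputs
therefore carry up to a year of ambiguity, which the package documents
but does not model.

## Plane mappings and the tetrahedral embedding

Cartesian plane mappings send each axis measure to its axis at unity
aspect; the derived measure then runs diagonally, one unit covering
√2 spatial units.  Isotropic mappings put the axes at 60°, making all
three triad unit steps spatially equal (ternary-coordinate style).

The hexad embeds in 3-D as position = P·e_P + A·e_A + T·e_T with unit
basis vectors pairwise at 60° — a regular-tetrahedron vertex fan.  The
six tetrahedron edge directions {e_P, e_A, e_T, e_A−e_P, e_T−e_P,
e_T−e_A} correspond one-to-one with {P, A, T, C, D, L} and all have
unit length, so a year of any measure is the same spatial step.  Faces
carry the triads; coordinate cross-sections parallel to the faces are
isometric copies of the 2-D isotropic planes (fixed T → APC, fixed A →
TPD, fixed P → the synthetic TAL triangle; the outer face is spanned by
the C and D directions of LCD).  The (P, A, T) parameterization is a
design choice: the trio is an independent spanning set, and fixing e_P
along x with a right-handed basis makes output reproducible.  Any
rotation or reflection would be equally isotropic.  Note that under
this parameterization birth-cohort TAL sections are affine planes but
not isometric copies; the period section plays that role.

## Surfaces

Observations resolve against their lifelines to full coordinates, then
bin half-open, floor-based, `[k·width, (k+1)·width)` — standard
completed-years classification; an observation exactly at death falls
in the T = 0 row.  Cells are squares (both axis measures), horizontal
parallelograms (y measure × derived) or vertical parallelograms
(x measure × derived).  Per-cell counts and (optionally weighted) means
are kept separately; observations on censored lifelines cannot be
placed on death-anchored planes and are dropped *and counted*, so
`counts + dropped` always equals the input size.  Weights default to 1
(unweighted); a per-observation weight is accepted because survey data
usually carries one.

`variation_direction` summarizes a mean surface by a one-way
variance decomposition in each classifying measure: the count-weighted
between-group variance of cell means (grouping cells by row, then by
column) divided by the total count-weighted variance of cell means.
Both shares lie in [0, 1]; a flat surface returns 0/0 → 0 by
convention, and a single-populated-cell grid is an error.  On a TAL
surface, share(T) ≫ share(A) is the quantitative counterpart of
"contour lines run horizontally": prevalence is a time-to-death, not an
age, pattern.

## Health expectancies

Lifetables are single-year, closed out at ω (default 110) with
q(ω) = 1, and use midpoint conventions throughout: deaths at interval
midpoints, person-years Lx = l(x+1) + d(x)/2, e(x) = Σ Lx / l(x).
Abridged tables must be graduated upstream.

Two estimators of unhealthy life expectancy at age x0:

* **Sullivan**: UHLE = Σ_{a≥x0} Lx(a)·π(a) / l(x0), with π an
  age-prevalence curve.
* **Time-to-death**: UHLE = Σ_{a≥x0} [d(a)/l(x0)]·G(a−x0), where
  G(k) = Σ_{t<k} g(t) + g(k)/2 is the unhealthy time lived by a death
  in interval x0+k under the same midpoint convention, and g is
  prevalence by completed thanatological age.

HLE is defined as e(x0) − UHLE, so complementarity is exact.  The
half-interval term in G is chosen so that a constant g = p yields
UHLE = p·e(x0) in closed form — the behaviour the time-to-death model
logically requires (pure time-to-death morbidity means added longevity
is added healthy time).  Prevalence schedules shorter than the needed
range are extended with their final value, with a logged warning.

`implied_age_prevalence` converts a fixed g into the age curve it
induces in the stationary population: π(a) = Σ_t [d(a+t)/l(a)]·g(t),
a death-time mixture, defined up to the last age with survivors.
Feeding that curve back into the Sullivan formula on the same lifetable
is *not* identical to the time-to-death estimator, because π is a
point-prevalence at exact ages while Lx weights person-years.  The
package documents the bound

    |UHLE_Sullivan(implied π) − UHLE_TTD| ≤ ½·TV(g) + ½·g_max·d(x0)/l(x0)

where TV(g) = Σ_t |g(t+1) − g(t)|: the two conventions relocate at most
half a year of person-years per survivor across each unit
thanatological-age boundary, and UHLE responds to such a relocation in
proportion to the prevalence increment across that boundary, plus a
half-interval boundary term at the starting age.  The bound is tight in
the limit of a step-function g on a short lifetable and is verified on
random lifetables in the test suite.  For smooth, slowly varying g the
observed discrepancy is an order of magnitude below the bound.

`compare_scenarios` contrasts projecting morbidity under mortality
change by (i) holding g fixed and (ii) holding the baseline implied
Sullivan curve fixed.  With g decreasing in t and mortality improving,
route (ii) projects a systematically larger rise in unhealthy years —
longer lives spend more time far from death, where prevalence is low,
which a frozen age curve cannot represent.  The test suite checks this
ordering across 100 randomized Gompertz improvement pairs.

## Synthetic data

The generator emulates a mortality follow-up panel: uniform birth times
within a cohort window, lifespans drawn by exact inverse transform from
Gompertz survivorship S(x) = exp(−(a/b)(e^{bx} − 1)) (an optional
Makeham constant enters as a competing exponential, which is exact for
additive hazards), interviews at fixed wave spacing inside an
observation window while alive, and a binary indicator drawn with
probability g(T) at the exact time to death of the interview,
g logistic: g(t) = g_max / (1 + e^{k(t−t50)}).

Defaults, chosen once as a plausible late-life morbidity setting:
a = 1e-4, b = 0.1 per year (modal adult age at death ≈ 69, expectancy
at birth ≈ 63 years), birth cohorts 1905–1925 observed 1980–2010 at
biennial waves (so the observed cohorts are largely extinct inside the
window and mortality follow-up is complete), and g_max = 0.6, k = 0.8
per year, t50 = 3 years (prevalence near 60% in the last year of life,
falling below 10% beyond ~5 years from death).  The discrete schedule
fed to the estimators samples g at mid-interval (t + ½), matching the
completed-age meaning of the bins.

What the generator does *not* emulate: survey nonresponse and
weighting, proxy interviews, imperfect death follow-up, heterogeneity
in frailty, or morbidity that depends on age as well as time to death.
Passing recovery tests therefore show the estimators are correct under
the stated model, not that real panel data satisfies it.

### Recovery check

The end-to-end test simulates 20,000 lifelines, bins quinquennial-cohort
TAL surfaces, and compares every cell mean (cells with ≥ 30
observations) with its true conditional mean — the average of g over
the observations actually in the cell, which removes discretization
bias from the comparison.  Agreement is judged at the 3σ-equivalent
level with exact binomial (Clopper–Pearson) intervals rather than
normal-theory standard errors, which are meaningless in deep-tail cells
whose true prevalence is ~1e-4.  The variance-share diagnostic must
attribute more variation to T than to A on every well-populated
surface.  Problem sizes (20k lifelines, ~50k interviews, ~700 tested
cells) keep the full suite in single-digit seconds while leaving the
binomial checks well-powered.

## Numerical choices

* Events and all measures are continuous decimal years; difference
  matrices are integer-typed so translation invariance is exact.
* `eps` (identity tolerance) defaults to 1e-9 years — appropriate for
  exact or near-exact inputs; set it to ~1 day (0.003) or coarser for
  survey-resolution data.
* Duration ordering is fixed to the grouped pair order (1,2), (1,3),
  …, (n−1,n); alternative orderings are row permutations and yield the
  same duration set.
* Floating-point: completion residuals on calendar magnitudes (~2000)
  carry ~1e-12 rounding; the default eps leaves three orders of margin.
  HLE + UHLE re-addition can differ from e(x0) by one ulp.

## Known limitations

* No estimation: the package completes and structures time measures but
  does not identify APC effects, impute censored deaths, or smooth
  surfaces.
* Single-decrement, single-state lifetables only; no abridged-table
  graduation; no confidence intervals for health expectancies.
* The plotting helpers are presentation-only and untested.
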