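# Methods

## Scope and model

`lactacurve` computes eight blood-lactate-threshold concepts on graded
exercise test (GXT) curves and compares them on repeatability and
predictive validity. A curve is the ordered sequence of (power, lactate
[, VO₂]) samples of one subject-visit, one sample per 5-min stage plus an
optional *terminal* sample drawn immediately after exhaustion at the power
held at termination. Terminal samples are part of the curve by default —
they anchor the Dmax chord's "last measurement" — and can be excluded with
a flag. Curves with fewer than four samples, or non-increasing powers, are
excluded as non-analysable; removing samples can never make a curve
analysable.

## Cubic fitting layer

Concepts LT3, LT5, LT-4mmol, Dmax and Dmax-mod operate on an ordinary
least-squares third-order polynomial of lactate (or a lactate equivalent)
versus power. Powers of order 10² make a raw cubic Vandermonde badly
conditioned, so the fit is computed on a centred/scaled abscissa and
converted back; reported coefficients are in raw units. With exactly four
points the cubic interpolates (r² = 1); zero-variance ordinates yield a
degenerate-fit flag.

Numerical choices:

* **Level crossings** (LT3, LT-4mmol) come from the companion-matrix roots
  of p(x) − level, restricted to the fit domain, filtered to rising
  (p′ > 0) crossings and polished with Brent's method to |p − level| ≤ 1e-6.
  With several rising crossings the smallest power wins — the physiological
  rising limb reaches the level there first.
* **Minimisation** (LT3's p(x)/x, LT5's ratio cubic) compares analytic
  stationary points against the interval endpoints; the generic fallback is
  a 2049-point grid with bounded refinement to ~1e-6 W. Minima at the
  domain edge are flagged `boundary_min` but still carry a power: a
  monotone lactate-equivalent legitimately minimises at the first stage.
* **Chord-gap maximisation** (Dmax, Dmax-mod) solves p′(x) = m (quadratic)
  analytically and compares endpoints; with two in-domain roots the larger
  perpendicular gap wins, exact ties go to the smaller power. Chord
  endpoints are the *measured* first/last points, not fitted values, and
  the gap is evaluated in raw axis units; the 1/√(1+m²) scaling does not
  move the argmax but is included so the reported gap is a distance.
* All searches are confined to [first fitted power, last fitted power]:
  thresholds are never extrapolated beyond intensities actually ridden.

LT1 is historically a multi-rater visual judgement; for reproducibility the
package uses a deterministic surrogate (resting level = minimum lactate of
the first three samples; LT1 = first sample ≥ resting + 0.5 mmol/L) and
accepts per-curve annotations that override it verbatim, so rater-consensus
data keep full fidelity when available. LT3 minimises the lactate
equivalent *on the BLC's own fitted cubic* (the threshold is then located
back on that same curve), whereas LT5 fits a fresh cubic to the
lactate/VO₂ ratio data — the two concepts are deliberately not symmetric.
LT4 requires the rise after the qualifying ≥1 mmol/L rise to also be
≥1 mmol/L; a qualifying rise in the last interval has no successor and does
not count.

Failures are statuses (`not_reached`, `undefined_rule`, `missing_vo2`), not
exceptions: one degenerate curve must not hide the other concepts.
`boundary_min` results are treated as usable measurements downstream.

## Reliability statistics

The weighted intra-subject CV pools per-subject sample variances (n−1
denominator) with weights equal to each subject's measurement count:
V̄ = Σ vᵢ nᵢ / Σ nᵢ, CV = 100·√V̄ / grand mean of all included values.
Subjects with fewer than two values are excluded from sums and grand mean.
Cronbach's alpha treats visits as items, α = k/(k−1)·(1 − Σ var_j /
var_total) with var_total the variance of per-subject row sums; the default
missing-data policy is complete-case (an available-case option drops
all-missing visit columns first). The 95% CI is Feldt's F interval with
(n−1, (n−1)(k−1)) degrees of freedom, the classical psychometric choice;
under the compound-symmetry model it is exact, and Monte-Carlo coverage in
the test suite sits at 95 ± 3%.

## Validity statistics

Thresholds from the GXT closest in time to each endurance test are paired
per subject (defaults TT1↔visit 1, TT2↔visit 4, RR↔visit 5); arms are
pooled, since a threshold should predict performance regardless of
treatment. Pearson r carries a two-sided p from the t transform on n−2 df;
the mean difference is endurance − threshold (negative ⇔ threshold power
higher); the OLS regression of endurance on threshold satisfies
r² = (Pearson r)² to 1e-10 by construction, which the tests assert. The
"all p < 0.0002" style statement is exposed as a flag derived from the
p-value, not a separate statistic.

## Synthetic study generator

The generator provides a full trial with known ground truth:

* **Population** — weight ~ truncated normal 76.9 ± 9.0 kg on
  [59.2, 95.6]; maximal power-to-weight ~ uniform [4.03, 5.18] W/kg;
  VO₂max ~ truncated normal 55.7 ± 4.6 mL/min/kg. Max power =
  weight × W/kg; the latent 4-mmol power P4 sits at 0.82 of max power plus
  N(0, 12 W) between-subject jitter.
* **Curves** — bLa(P) = b₀ + (4 − b₀)·exp((P − P4)/τ) with b₀ = 1.0 mmol/L
  and τ = 45 W, so bLa(P4) = 4 exactly and the baseline/terminal lactates
  of a median subject are ≈1.3 and ≈12 mmol/L. Stages run from 175 W in
  25 W steps up to the visit's max power; the last stage carries the
  terminal sample. Each visit draws one N(0, 8 W) shift applied to *both*
  max power and P4, translating the whole curve — the simplest mechanism
  that produces concept-agnostic test-retest variance. Lactate gets
  mean-one lognormal noise with CV 3%; VO₂ is linear in relative power
  with 1 mL/min/kg noise.
* **Endurance** — TT/RR mean power = 20 + 0.9·P4 + noise, with the noise
  SD derived at run time from the configured target correlation (0.9 TT,
  0.7 RR) and the analytic between-subject SD of P4 (truncated-normal ×
  uniform moments). The road race is noisier than the ergometer trials by
  construction.
* **Missingness** — whole GXTs drop with p = 0.10, a curve's VO₂ column
  with 0.05, road-race power with 0.20; half the subjects are labelled
  placebo. Everything is reproducible from the single config seed.

What the generator does **not** emulate: the exponential family rises from
the very first stage, so the lactate/VO₂ equivalent usually minimises at
the 175 W boundary — real athletes' equivalents dip before rising, giving
interior LT5 minima with high test-retest variability. Passing tests
therefore show LT5 is the lowest-power concept (as in real data) but not
that its CV is the highest. The cubic is a deliberate model mismatch to
the exponential truth: on a zero-noise typical-length curve, LT-4mmol
recovers P4 to ~0.4 W; very short curves (≤6 stages) can show ~1–3 W of
cubic-vs-exponential bias. There is no pacing, cadence or lactate-kinetics
modelling, and no treatment-effect simulation.

## Problem sizes and tolerances in the test suite

Oracle-agreement tests compare the analytic threshold routes with 10⁵–10⁶
point grid/bisection oracles at 0.01 W on 100 random analysable curves.
Reliability recovery simulates 24 subjects × 5 visits (between-SD 30 W,
within-SD 10 W about 280 W): 500 replicates for the CV (target 3.57%) and
alpha (Spearman–Brown target 0.978 ± 0.02), 1000 for Feldt coverage.
Validity recovery uses 500 replicates at n = 40 per target correlation
ρ ∈ {0.6, 0.75, 0.9}, compared against the attenuation-adjusted expectation
ρ·σ_P4/√(σ_P4² + σ_within²) within 0.03. The qualitative-ordering check
runs 60 subjects × 5 visits (300 curves). The full pipeline on the default
48-subject design completes in a few seconds.

## Known limitations

* The LT1 surrogate is systematically earlier than human raters tend to
  pick on steep curves; annotations should be preferred when rater data
  exist.
* Alpha's complete-case policy discards subjects with any missing visit;
  with heavy missingness the available-case option (or an explicit
  imputation upstream) is more efficient.
* The weighted CV is a pooled *within*-subject CV; it is not comparable to
  a between-subject CV and assumes roughly homogeneous within-subject
  variance across the mean range.
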