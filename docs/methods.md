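# Methods

## The quantity being estimated

Whole-grain intake is measured in grams of whole-grain *ingredient* per
day on a dry-matter (DM) basis. The DM basis matters because grains differ
in water content — wholemeal wheat is taken to hold 14 % water and whole
oat 8.9 % — so wet-basis percentages are not comparable across foods. A
food's content is stated as grams of whole grain (grain DM) per 100 g of
the food in its registry form; for recipe foods it is derived from the
grain ingredients as

    fresh mass / 100 g food × (1 − water %/100) × (1 − processing loss %/100),

summed per grain type. The registry is the single source of all content
figures, water contents and loss factors; nothing is hard-coded in the
pipeline.

## Cooked foods and the registry basis

Some foods are consumed in a cooked state whose mass differs from the form
the content percentage refers to. The registry supports two conventions:
a cooked item can be its own record (content already per cooked 100 g), or
it can reference an uncooked parent together with a cooking-loss percent.
In the second case a consumed portion *m* is mapped back to the registry
basis as *m/(1 − loss/100)* before the parent's percentage applies —
85.4 g of toast at 14.6 % loss is scored as 100 g of the bread it came
from. The cut-off tier for such foods compares the *effective* as-eaten
percentage, parent % ÷ (1 − loss/100): cooking concentrates the grain, and
grams-per-100 g-as-eaten is the physically meaningful food-level content.
This is one consistent reading of how loss factors interact with the
food-level cut-offs; the alternative (comparing the parent's uncooked
percentage) would classify a food differently depending on which registry
convention stored it, which we considered a defect.

## Scoring pipeline

Per participant: sum occasion whole-grain grams over foods meeting the
tier threshold, divide by the number of diary days (3 or 4; diaries are
taken at face value), and energy-adjust by ×10/E for reported mean daily
energy E (MJ). Three tiers are computed throughout — any content, ≥10 %
and ≥51 % whole grain — giving a monotone non-increasing triple per
person. Serving classes use 16 g/serving with half-open intervals closed
below ([16, 32) is one serving) and exact zero as a dedicated
non-consumer class; zero-intake participants stay in all medians and
IQRs, which is why medians sit well below means in this kind of data.
Intakes are carried at full precision; rounding happens only in reports.

Non-registry food codes are not errors: a real diary is dominated by
non-whole-grain foods, so they are retained (and flagged at load time)
while contributing zero grams. Composite foods are split into component
codes by a user-supplied fraction map before scoring; fractions must be
positive and sum to ≤ 1.

## Survey statistics

All descriptives are survey-weighted. Quantiles use the type-1
(left-continuous) definition — the smallest value whose cumulative
normalised weight reaches q — chosen because it equals the type-1 quantile
of the weight-expanded sample for integer weights, which makes it directly
oracle-testable; note that at exact cumulative-weight boundaries other
conventions (which interpolate) give different medians.

The comparison tests are implemented in the package rather than delegated,
with scipy supplying only the normal, chi-square and t survival functions:

* **Mann–Whitney**: U = #{x>y} + ½·ties via midranks; exact two-sided p by
  complete enumeration of rank assignments when n_x+n_y ≤ 12 (the
  two-sided region is |U − n_x n_y/2| ≥ observed deviation), otherwise a
  tie-corrected normal approximation without continuity correction.
* **Kruskal–Wallis**: H from pooled midranks with the standard tie
  correction, referred to chi-square on k−1 df.
* **Linear trend**: closed-form weighted least squares of individual-level
  intake on an ordinal age-band index, two-sided t test for zero slope on
  n−2 df. Individual-level regression (not band medians) preserves n.

Rank tests run unweighted by default — the transparent, oracle-testable
choice. To approximate design-aware behaviour, expand the samples with
`expand_by_weight` (integerised-weight replication) first; this is an
approximation, not a variance-correct complex-survey procedure (Taylor
linearisation and replicate weights are out of scope). No multiplicity
correction is applied; p-values are reported as-is at α = 0.05.

Default age bands are 1.5–4, 5–12, 13–17, 18–24, 25–34, 35–44, 45–54,
55–64, 65+ — a configurable package default, not an assertion about any
particular survey's banding. NS-SEC-stratified summaries silently exclude
the ~2 % of participants with missing class, who remain in all other
strata.

## Synthetic diary-survey generator

The generator emulates the statistical structure the analysis assumes so
the whole pipeline is testable offline:

* **Population**: ~49 % children/teenagers (1.5–17 y), 44 %/51 % male
  among adults/children, NS-SEC classes 1–8 from a plausible household
  distribution with a 2 % missing rate, lognormal survey weights
  (σ = 0.3), and 4-day diaries with a 2 % share of 3-day diaries.
* **Zero inflation**: each participant is an absolute non-consumer with
  probability 0.18 (adults) / 0.15 (children), graded linearly over NS-SEC
  classes (more non-consumers in less advantaged classes) with the
  gradient mean-normalised so the stratum marginal is preserved exactly;
  consumers whose Bernoulli draws happen to produce an empty whole-grain
  diary are redrawn, so "consumer" and "non-zero intake" coincide by
  construction and the stated probability is the exact marginal.
* **Consumption**: per day and food group, a Bernoulli eat/skip draw with
  probabilities in which bread and ready-to-eat cereals dominate, scaled
  by an age-band factor that is lowest for 13–34-year-olds and rises
  through middle age; portion grams are lognormal per food group
  (right-skewed and positive, the simplest shape consistent with skewed
  intake data; σ = 0.5 is a free parameter, as published medians/IQRs do
  not pin down the full distribution). Males and more advantaged classes
  receive small log-scale portion shifts; children eat ×0.65 portions.
  Energy intake is normal per age/sex stratum (adult men 9.0 ± 1.6 MJ/d,
  women 6.9 ± 1.3, children 6.8/6.1 ± ~1.5), floored at 2 MJ/d.
  Non-whole-grain filler occasions (Poisson, mean 2/day, codes unknown to
  the registry) exercise the zero-contribution path.
* **Determinism**: every participant draws from an independent
  `numpy` PCG64 stream keyed by (seed, participant index), so a fixed
  seed gives byte-identical datasets and the first k participants are
  invariant to the total n.
* **Ground truth**: expected per-person intakes per tier are recomputed by
  a deliberately separate plain loop over raw registry fields (its own
  cooked-form resolution, thresholding and day-averaging), giving an
  independent oracle the pipeline must match exactly.

What the generator does **not** emulate: real food-name vocabularies and
brand granularity, day-of-week/seasonal structure, within-person
usual-intake variance, misreporting, and correlations between energy and
whole-grain consumption beyond the stratum means. Passing tests therefore
demonstrate correctness of the *estimation machinery* under a realistic
zero-inflated skewed consumption structure — not agreement with any real
population's intake.

## Calibration

`calibrate` sets the non-consumer probabilities directly from the targets
and tunes the per-stratum lognormal portion location by a monotone
multiplicative search: intake scales linearly with portion mass, so after
each full generate-and-score round the shift moves by
log(target/achieved). Default targets are a 20 g/d adult and 13 g/d child
weighted median with 18 %/15 % non-consumers, at a default tolerance of
±10 % of the target median; convergence typically takes 2–4 iterations
and raises (reporting the best achieved medians) after 12.

## Problem sizes and numerical choices

The shipped registry holds 18 illustrative foods spanning all nine food
groups and eight grain types, with tier-straddling contents (5.5 % to
83 %) so the three tiers genuinely differ. Simulation-based checks use
100 surveys of n = 200 for structural invariants, n = 5000 for
calibration-target recovery (binomial 99 % intervals for non-consumer
fractions), and 2000 replicates for the rank tests' type-I error —
sizes chosen to make stochastic checks decisive at conventional
confidence while remaining quick on one core. Percent vectors are checked
to sum to 100 within 0.01; float comparisons elsewhere use relative
tolerances around 1e-12 where exactness is expected. The attribution of
an empty stratum is flagged (n = 0, undefined percents) rather than
silently zeroed, and a zero-whole-grain grain-share query returns an
empty map.
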