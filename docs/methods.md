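# Methods

## Response model

Disease activity is the DAS28-CRP composite,

DAS28 = 0.56·√T28 + 0.28·√S28 + 0.36·ln(CRP + 1) + 0.014·VAS + 0.96,

which is bounded below by 0.96 (all components zero) and treats CRP in the
unit the caller declares (`crp_unit`, default mg/dL, recorded in the run
manifest and never converted). The 0.014 coefficient corresponds to the
standard 100-mm VAS convention, so VAS is validated on a 0–100 scale.

A patient's trajectory is the piecewise-linear interpolant through the
visit scores. The windowed area under it is computed by the trapezoidal
rule on the visit knots plus the two window edges; an edge that falls
between visits takes the linearly interpolated value, and extrapolation
beyond the first or last visit is refused (a coverage error) rather than
guessed. This makes the area additive over abutting windows and exactly
linear in the scores.

The improved area over (0, T) is `10·T − AUC`: improvement relative to a
reference trajectory held at DAS28 = 10, the score's practical ceiling.
The reference normalizes for heterogeneous baselines — two patients
reaching the same trajectory from different starting points earn the same
improved area. Values above the reference (possible only through noise)
yield a negative improved area, which is reported with a warning, not
clipped. Index R divides the improved area by cumulative dose; cumulative
dose converts months to weeks at exactly 4 weeks/month, so a 3-month
window holds 12 weekly doses (a calendar-exact 365.25/12/7 ≈ 4.35
weeks/month factor is available via the `weeks_per_month` argument).
Index R is homogeneous of degree −1 in dose and invariant to refining a
dose interval into sub-intervals at the same level.

## Disease-control rule

Good control over months 6–12 requires (i) a single weekly dose level
across every dose interval overlapping the window (when
`require_fixed_dose`), and (ii) an exceedance count — visits with DAS28
above the threshold, default 2.0 — below the budget. Two readings of
"exceeded less than once per month" are implemented because both
circulate: the default budget is `1/month × window length` (strictly fewer
than 6 over a 6-month window), and `strict_mode` allows none at all. The
strict good-set is always a subset of the default good-set, and the mode
in force is written to the manifest. Visits at the window edges count as
inside. A patient with no visits in the window raises an indeterminate
error; the pipeline logs and excludes such patients from the comparison
per-analysis instead of imputing anything.

## Genotype grouping

Each SNP collapses to the binary contrast its analysis uses: RFC1 80 G/G
vs A-allele carrier; FPGS 1994 G-allele carrier vs A/A; GGH −401 C/C vs
T-allele carrier; MTHFR 1298 A-allele carrier vs C/C; TYMS 3′-UTR −6/−6 vs
+6-allele carrier. Calls are canonicalized first (unicode dashes to ASCII,
allele order fixed per SNP, so "A/G" ≡ "G/A"); anything else is a parse
error carrying the offending string. "GGH 452" is accepted as an alias for
GGH −401 because both labels appear in published tables for rs3758149.

## Statistics

Two-group comparisons use the two-sided Mann-Whitney U test. For pooled
samples up to `exact_cap` (default 25) the p-value is exact: the null is
every assignment of the pooled observed values to the two group sizes, and
the p-value is the fraction of assignments whose |U − n₁n₂/2| reaches the
observed deviation. Tie-free nulls are counted by the classical subset-sum
recursion over rank sums (equivalent to full enumeration at polynomial
cost); tied samples are enumerated directly over mid-ranks (capped at
2×10⁶ assignments). Deviations are compared on the doubled-U integer
scale, so the exact path involves no floating-point tolerance. Larger
samples use scipy's normal approximation with tie-corrected variance and
continuity correction. Two samples with all values identical return p = 1
with an explanatory note. No multiple-testing correction is applied by
default, matching the single-comparison reporting convention of small
pharmacogenetic studies; the p-values are emitted per comparison so any
correction can be applied downstream.

Summaries are median (25th–75th percentile) with linear interpolation
between order statistics at position 1 + (n−1)·q — numpy's default — and
the rule is echoed in the manifest so alternative conventions are
auditable.

## Synthetic cohorts

The generator emulates a small observational MTX cohort: by default 21
patients, 7 destined for good control and 14 for poor, monthly visits over
months 0–12, baseline DAS28 ~ N(4.0, 1.0) clipped to [1, 9], and one
weekly dose level per patient drawn from {6, 8, 10} mg (0–3-month
cumulative doses of 72–120 mg, bracketing the 96–118 mg range typical of
low-dose regimens). Trajectories decline linearly at a group rate — 0.5
DAS28/month for good (crossing the control threshold before month 6 from a
median baseline), 0.15 for poor (staying above it through month 12) —
floored at zero, with i.i.d. Gaussian measurement noise per visit. Half of
the poor patients additionally receive a +2 mg/week dose increase at a
random month in 7–10, the dose instability that marks poor control;
dose changes are never injected before month 6, so the 0–3 and 0–6-month
cumulative doses stay schedule-driven.

Scores are never injected. Each visit's noisy target is back-filled into
components: VAS ≈ 10× the target and CRP follows exp(0.2·target) − 1
(≈1.2 mg/dL at a baseline score of 4), each with jitter whose sd scales
with the measurement-noise parameter, so a zero-noise configuration is
fully deterministic; the joint-count terms absorb the remainder with
tender = swollen, counts are rounded into [0, 28], and the ground-truth
DAS28 is recomputed from the rounded components — the formula stays the
single source of truth. Rounding quantizes the realized score by up to a
few tenths of a unit, an extra discretization noise the tests account for.

Genotypes are sampled independently per SNP at the carrier-group level
with the cohort's observed margins (15/21 RFC1 A-carriers, 4/21 FPGS A/A,
10/21 GGH T-carriers, 2/21 MTHFR C/C, 13/21 TYMS +6-carriers), then
rendered as a concrete diploid call uniformly within the group; no
per-allele Hardy–Weinberg structure is modelled because the analysis only
ever sees the binary grouping. `genotype_effect_on_R` multiplies the
decline rate of a SNP's carriers; through the zero floor the induced
effect on index R is monotone but sub-linear, which is enough for the
null (effect = 1) and power experiments the package runs.

What the generator does not emulate: real visit-schedule irregularity,
within-patient correlated measurement error, informative dropout,
toxicity-driven discontinuation, and any linkage between SNPs or between
genotype and dose assignment. Passing tests therefore certify the
pipeline's arithmetic and its statistical calibration under these idealized
conditions, not clinical validity on real cohorts.

## Experiment sizes and calibration checks

The test suite's calibration experiments use: 1000 replicate 21-patient
cohorts for the null (no-genotype-effect) type-I error of the per-SNP
index-R comparisons, pooled over all computed comparisons — the exact
test's discreteness at these group sizes (a singleton group can never
reach p < 0.05 two-sided, and the 2/21 MTHFR margin often produces one)
makes the attained level ≈ 0.04, conservative of nominal 0.05; and 200
replicates for label/effect recovery under well-separated conditions
(decline rates 1.0 vs 0.02 DAS28/month, zero noise, baseline sd 0.3, a
single 8 mg/week dose level so the index-R contrast is not confounded by
random dose assignment). The AUC oracle compares the trapezoidal rule to a
100 000-step midpoint Riemann sum on 200 random trajectories; the exact
Mann-Whitney is checked against brute-force enumeration on 200+ random
tied and tie-free samples with pooled size ≤ 10.

## Known limitations

* The trajectory model is linear-with-floor; real DAS28 courses flare and
  remit, so absolute power numbers from the simulator do not transfer.
* Index R inherits the reference-area assumption (ceiling of 10); cohorts
  measured on other DAS variants need a different reference.
* The exact test enumerates assignments, not patient-level covariate
  structure; confounding between dose and response is reported, not
  adjusted for.
* Missed visits inside the control window are not modelled; the rule
  counts observed visits only, and the visit count is reported alongside
  the label.
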