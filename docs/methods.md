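# Methods

This note records the models implemented in `caprilact`, the defaults and
their rationale, the numerical choices, and what the synthetic herd
generator does and does not emulate.

## Yield standardization

Total milk yield per lactation is standardized to 210 days in milk (DIM)
with the interval-weighted Fleischmann rule used by ICAR milk recording:

    Y210 = M1·d1 + Σi ½(Mi + Mi+1)·(di+1 − di) + (210 − dlast)·Mlast

where Mi is the daily yield at the i-th control, di its DIM, and d1 the
interval from kidding to the first control.  Controls recorded after day
210 are dropped before the summation, so the estimate depends only on
in-horizon controls (this makes the truncation property exact: appending
post-horizon records never changes the result) and the last in-horizon
control is extended at its own daily yield to day 210.  The rule is linear
in the yields and non-negative for non-negative yields.  DIM is the
integer day count from kidding, 1-based on the first day after kidding;
no AM/PM correction factors are applied.  The whole rule is isolated in a
single function so an alternative standardization is a local change.

## Lactation-curve models and fitting

The registry ships seven classical models.  The two used downstream by
default are

* **Ali–Schaeffer** (milk yield and components):
  y(t) = b0 + b1·x + b2·x² + b3·ln(1/x) + b4·ln²(1/x), x = t/T.
  The scaling horizon defaults to T = 340 days, the constant in the
  model's original formulation; every downstream property used here
  (fitted values, RSS, ranking, shape ANOVA) is invariant to T, which
  only reparametrizes the coefficients.  T is configurable.
* **Parabolic yield-density** (somatic cell count):
  y(t) = 1/(b0 + b1·t + b2·t²), defined where the denominator is
  positive.  SCC's rise over lactation and strictly positive range suit
  the reciprocal-quadratic form.

Fitting is per lactation per trait (one curve per lactation, matching a
test-day design in which each lactation contributes ~5 controls).  A
Levenberg–Marquardt minimizer runs from each point of a small moment-based
start grid — for linear-in-parameter models the first start is the
ordinary-least-squares solution, so the iterative optimum coincides with
the closed form; for Wood the grid is a factorial perturbation of the
log-linearized estimate; for the reciprocal-quadratic family it comes from
regressing 1/y on (1, t, t²).  Convergence uses relative tolerances of
1e-8 with at most 2000 function evaluations.  Divergence of every start
yields a `converged=False` result rather than an exception; n < k raises
an insufficient-data error.

## Selection criteria

Least-squares information criteria are used (no likelihood constant, which
cancels across models fitted to the same data): AIC = n·ln(RSS/n) + 2k,
AICc = AIC + 2k(k+1)/(n−k−1), BIC = n·ln(RSS/n) + k·ln n, MSPE = RSS/n,
adjusted R² = 1 − (1−R²)(n−1)/(n−k−1).  A perfect fit (RSS = 0) returns
−∞ for the AIC family with a warning.  Criteria require n ≥ k + 2.

No single aggregation rule is canonical for multi-criterion model choice;
the package excludes any model that failed to fit 100 % of lactations and
ranks the rest by the sum of their ranks over mean MSPE (↓), mean adjusted
R² (↑), and mean AIC/AICc/BIC (↓), breaking ties by fewer parameters and
then lexical id.  The rule respects dominance and is invariant to
candidate order; alternative weightings can be applied to the returned
table.

The Durbin–Watson statistic DW = Σ(eₜ−eₜ₋₁)²/Σeₜ² is computed on residuals
averaged by day in milk across lactations (a per-day mean residual curve),
since a per-lactation series of ~5 points carries too little information
about first-order autocorrelation.  No DW p-values are produced.  The
Shapiro–Francia statistic is the squared correlation between the ordered
sample and Blom scores Φ⁻¹((i−3/8)/(n+1/4)); its p-value uses Royston's
normal approximation for ln(1−W), valid for 5 ≤ n ≤ 5000.

## Curve-shape parameters

Ali–Schaeffer: peak = b0, persistency = (b1, b2).  Parabolic
yield-density: peak = −b1/(2·b2) and persistency = 2·b0·Days + b1 with
Days = 210 by default.  Note that −b1/(2b2) is mathematically the
*time* at which the curve 1/(b0+b1t+b2t²) is extremal; the conventional
"peak" label is kept without a units claim.  Both read-ins are isolated in
`shape.py` so an alternative interpretation (for instance Days equal to
each lactation's own length) is a one-line change.

## Haplotype statistics

Input haplotypes are phased and token-delimited; alleles are single bases,
the deletion token `.-`, or multi-base insertions (e.g. `AATC`).
Concatenated display strings are ambiguous once indels appear and are not
parsed.  The default casein-complex layout has 48 SNPs over the four loci
(CSN1S1 18, CSN1S2 18, CSN2 8, CSN3 4, the last including one indel
site); block definitions are data, not code, and can be replaced.

MAF is the frequency of the minor allele pooled over phases, with
variants below 0.05 flagged rare and monomorphic columns flagged rather
than failing.  LD between two biallelic SNPs is computed directly from
the phased haplotypes (no EM step is needed because phase is input):
D = p_AB − p_A·p_B, D′ = |D|/D_max with D_max = min(p_A·p_b, p_a·p_B) for
D > 0 and min(p_A·p_B, p_a·p_b) otherwise, and r² = D²/(p_A p_a p_B p_b).

Animals are grouped by full-complex haplotype variant.  A heterozygous
animal contributes its records to the group of **both** carried variants
(the natural reading of a per-haplotype factor); because that duplicates
observations across groups, the t/F calibration of downstream tests is
then slightly conservative.  A `homozygous_only` switch restricts the
analysis to homozygous carriers, giving disjoint groups and exact
calibration — the calibration and power analyses in the acceptance suite
use this switch.

## One-way Bayesian ANOVA

For each trait level (one value per test-day record) and each curve-shape
parameter (one value per lactation) the haplotype factor is tested three
ways.

**Frequentist.** SS_between = Σ n_j(ȳ_j − ȳ)², SS_within = ΣΣ(y_ij − ȳ_j)²,
df J−1 and N−J, F = MS_between/MS_within with the F-distribution p-value.
`f_from_ss` reproduces F from any printed SS/df decomposition exactly.

**JZS Bayes factor.** The group-effects model places a Jeffreys prior on
the grand mean and error variance and a g-prior N(0, g·σ²·I) on J−1
orthonormalized sum-to-zero group contrasts, with g ~ InvGamma(1/2, r²/2)
— the mixture representation of a Cauchy prior of scale r (default r = 1)
on standardized effects.  Conditional on g, the Bayes factor is available
in closed form; the package evaluates it through a rank-(J−1) Woodbury
identity (so cost scales with groups, not observations) and integrates
over g by adaptive quadrature on the log scale after locating the
integrand's mode.  Observations are internally standardized first, which
is harmless because the JZS formulation is location-scale invariant, and
keeps the quadrature well-conditioned when BF₁₀ is astronomically large.
Unbalanced groups, including singletons, are handled by the full
linear-model marginal likelihood.  Reproduced BF magnitudes from other
software may differ (different contrast conventions and prior scales are
common); the F/p arithmetic is the exact surface, and the BF is validated
against a brute-force Monte-Carlo marginal-likelihood estimate computed
through an independent N-dimensional eigendecomposition route.

**Group posteriors.** Under the homoscedastic reference prior the
deviation δ_j = μ_j − Σ_k w_k μ_k (w_k = n_k/N) has an exact Student-t
posterior with N−J degrees of freedom, centred at ȳ_j − ȳ with scale
s_p·√c_j, c_j = (1−w_j)²/n_j + Σ_{k≠j} w_k²/n_k.  The 95 % credible
interval is the central interval; a group is significant when 0 falls
outside.  This posterior is exactly frequentist-calibrated: under a null
herd the flag fires for 5 % of groups.  Groups with n < 2 are skipped
with a warning but still enter the grand mean and pooled variance.

A note on degrees of freedom: a one-way layout always has
df_within = N − J.  Published tables sometimes pair many between-groups
df with very few within df (e.g. 86 and 15), which cannot arise from any
one-way grouping of more observations than groups; the package always
reports the df implied by the supplied grouping.

## Synthetic herd generator

Defaults emulate the structure of a real Murciano-Granadina milk-recording
sample: 159 goats on 28 farms; lactations per goat drawn as
round(N(3.91, 2.01²)) clipped at 1; lactation lengths uniform on 210–240 d;
first control at round(N(21, 3²)) clipped at 5 d; subsequent controls at
uniform 28–42 d intervals (4–6 weeks) up to 5 controls; 86 distinct
casein haplotypes over 48 biallelic SNPs (one CSN3 indel site) with
smoothly decaying frequencies, assigned to animals as i.i.d.
Hardy-Weinberg diplotype draws.  That yields ≈ 3,100 records over ≈ 620
lactations per herd.

Trait values are the Ali–Schaeffer base curve (milk ≈ 2.2–2.7 kg/day
peaking near day 60; components mildly convex around their typical
levels) plus i.i.d. Gaussian noise per control; SCC follows the parabolic
yield-density curve (≈ 530 rising to ≈ 870 ×10³ cells/mL) with
multiplicative lognormal noise, keeping it positive and right-skewed.
Residual SDs (0.35 kg milk; 0.45/0.25/0.60/0.20 points for fat, protein,
dry matter, lactose; lognormal σ = 0.5 for SCC) are generator choices on
the scale of test-day repeatabilities, not estimates from any study.
Haplotype effects act additively on the level parameter b0, once per
carried copy; for the reciprocal SCC curve a b0 shift moves 1/y, so SCC
effects should be specified with that in mind.

What the generator does **not** emulate: animal-level random effects
(permanent environment, repeatability across a goat's lactations), farm,
parity or season effects on the curve, haplotype effects on curve *shape*,
genotyping error, pedigree, or phasing uncertainty.  Consequently, passing
calibration tests show the statistics are correct under exchangeable
within-group sampling; they do not demonstrate robustness to the
clustered, confounded structure of real herds, where a mixed model would
be the appropriate extension.

One deliberate consequence of the design: a planted level effect does not
leak into the shape tests.  Interpolating 5-point lactations with the
Ali–Schaeffer basis amplifies residual noise on the fitted b0 several
hundredfold, so per-lactation fitted peaks are dominated by sampling
noise, while record-level means resolve effects of a few tenths of a kg.
This is why level tests can be decisively significant while shape tests
sit at their nominal error rate — a pattern the acceptance suite checks
explicitly.

## Pipeline and reproducibility

The pipeline pins the model choice per trait by configuration
(Ali–Schaeffer for milk and components, parabolic yield-density for SCC)
rather than re-running selection on every herd, because a small synthetic
herd can legitimately rank another 3-parameter model first; `"select"`
per trait switches the full ranking on.  All randomness flows from one
root seed; identical config + seed produce byte-identical output tables
(fixed row order and float formatting; the manifest carries no
timestamps).  Every ANOVA output row is audited for ms = ss/df and
f = ms_between/ms_within before writing.

Problem sizes in the acceptance suite (herds of 60 goats, 200 null and
100 planted-effect replicates, 10⁶ Monte-Carlo draws for the BF oracle)
are the package's chosen trade-off between statistical resolution and a
test suite that runs in well under a minute per property.
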