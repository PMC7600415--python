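# caprilact

Lactation-curve modelling and casein-complex haplotype association testing
for dairy-goat test-day milk records.

`caprilact` is aimed at quantitative geneticists and milk-recording analysts
who want to ask: *do the haplotypes of the goat casein complex (CSN1S1,
CSN1S2, CSN2, CSN3 on chromosome 6) shift milk yield, milk composition, or
the shape of the lactation curve?*  It provides a tested, reusable pipeline
for the whole chain:

1. **Records** — read/validate test-day controls (daily milk kg; fat,
   protein, dry matter, lactose %; SCC ×10³ cells/mL), group them into
   lactations, and standardize total milk yield to 210 days in milk with the
   interval-weighted Fleischmann rule
   `Y = M₁·d₁ + Σᵢ ½(Mᵢ+Mᵢ₊₁)·Δᵢ + (210 − d_last)·M_last`.
2. **Curves** — fit per-lactation curve models by multi-start
   Levenberg–Marquardt least squares (tolerance 10⁻⁸, ≤ 2000 iterations).
   Built-ins include the five-parameter Ali–Schaeffer polynomial
   `y(t) = b₀ + b₁x + b₂x² + b₃ln(1/x) + b₄ln²(1/x)` with `x = t/340`
   (the standard choice for yield and components) and the parabolic
   yield-density curve `y(t) = 1/(b₀ + b₁t + b₂t²)` (suited to SCC), plus
   Wood, Wilmink, quadratic, inverse-quadratic and mixed-log forms; the
   registry is user-extensible.
3. **Selection** — RSS, MSPE, adjusted R², AIC/AICc/BIC, Durbin–Watson and
   Shapiro–Francia diagnostics, and a rank-sum model ranking restricted to
   models that fit 100 % of lactations.
4. **Shapes** — peak and persistency read-outs per fitted curve:
   Ali–Schaeffer peak = b₀, persistency = (b₁, b₂); parabolic yield-density
   peak = −b₁/(2b₂), persistency = 2·b₀·Days + b₁.
5. **Haplotypes** — token-delimited phased haplotype I/O (alleles may be
   single bases, the deletion token `.-`, or insertions such as `AATC`),
   minor allele frequency with the MAF < 0.05 rare-variant flag, observed
   heterozygosity, pairwise D′/r² linkage disequilibrium, and grouping of
   animals by full-complex haplotype variant.
6. **Association** — one-way Bayesian ANOVA per trait × parameter: the
   classical SS/df/MS/F/p decomposition, the default JZS Bayes factor
   BF₁₀ (Cauchy prior of scale r = 1 on standardized effects, computed by
   deterministic quadrature over the g mixing parameter), and per-group
   posterior deviations from the grand mean with 95 % credible intervals —
   a group is flagged significant when 0 lies outside its interval.

Because milk-recording data sets are rarely public, the package ships a
first-class synthetic herd generator whose defaults emulate the structure
of a real Murciano-Granadina study population (159 goats, 28 farms,
3.91 ± 2.01 lactations per goat, ≈ 5 controls per lactation starting
≈ 21 d after kidding, 86 casein haplotypes over 48 SNPs), with optional
planted haplotype effects and full ground truth for power studies.

## Worked example

```python
from caprilact import PipelineConfig, SimConfig, run

cfg = PipelineConfig(
    simulate=SimConfig(
        n_goats=40, n_farms=6,
        haplotype_freqs=[("A", 0.5), ("B", 0.5)],
        effect_sizes={"B": {"milk_kg": 0.7}},   # +0.7 kg/day per copy
    ),
    traits=("milk_kg", "scc"),
    homozygous_only=True,
    outdir="example_out",
    seed=42,
)
report = run(cfg)
```

`example_out/anova.csv` then contains (milk rows, abridged):

```
trait    parameter       source    ss        df   ms         f        p          bf10
milk_kg  level           Between   206.44    1    206.44     1241.19  3.1e-129   2.3e+125
milk_kg  level           Within    72.02     433  0.166
milk_kg  peak            Between   93463.0   1    93463.0    1.384    0.243      0.232
milk_kg  persistency_b1  Between   288055.3  1    288055.3   1.372    0.245      0.231
```

Reading: the planted level effect is overwhelmingly detected — homozygous
carriers of haplotype B average 3.89 kg/day against 2.50 kg/day
(F = 1241, BF₁₀ ≈ 10¹²⁵, and both group deviations have 95 % credible
intervals excluding 0) — while the curve-shape parameters (peak,
persistency) show F ≈ 1.4 and BF₁₀ < 1: a level shift does not masquerade
as a shape change, because per-lactation fitted shape parameters carry far
more sampling noise than record-level means.

The same run is available from the shell:

```bash
caprilact run --config config.yaml --seed 42 --outdir example_out
caprilact simulate --seed 1 --goats 159   # records.csv + haplotypes.csv
caprilact select records.csv --trait milk_kg
caprilact assoc haplotypes.csv
```

## Layout

```
src/caprilact/
  records.py     test-day records, lactations, 210-d standardization
  curves.py      model registry + Levenberg–Marquardt fitting
  selection.py   criteria, Durbin–Watson, Shapiro–Francia, ranking
  shape.py       peak / persistency read-outs
  haplotypes.py  haplotype I/O, MAF, heterozygosity, D'/r², grouping
  anova.py       F/p, JZS Bayes factor, group posteriors
  simulate.py    synthetic herd generator
  pipeline.py    end-to-end orchestration
  cli.py         `caprilact` command-line interface
docs/methods.md  model and design notes
```
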