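# Methods

## The evaluation procedure

The pipeline quantifies germination-stage salt tolerance of a germplasm
panel screened under a control (water) and a salt treatment, replicated
dishes of N seeds each, with germination recorded daily for one week and
seedling biomass measured at day 7.

**Traits.** Per replicate, germination rate GR = G₇/N, energy GE = G₁/N and
index GI = Σₜ₌₁..₇ G_t/t are computed from the *cumulative* counts G_t and
then averaged over replicates. Treating the recorded counts as cumulative
is the default; a `daily_new` switch cumulates per-day counts on ingest,
since both conventions occur in germination datasets. Endpoint measures are
averaged over the replicates in which they could be measured; water content
is the ratio of replicate-mean weights, (mean FW − mean DW)/mean FW, rather
than the mean of per-replicate ratios (the two differ under unequal
replicate weights; the ratio-of-means is the estimator consistent with
pooling all seedlings). The vigor index GVI multiplies the mean GI by the
*same-condition* average fresh weight: the salt GVI uses salt-grown
seedling weight. The published reference values (e.g. STI_GVI = 0.193 for
germplasm 152505 while STI_FW = 1.087) are consistent only with this
condition-specific choice.

**Tolerance indices.** STIᵢ = Vᵢ,salt/Vᵢ,control per trait. Values above 1
are legitimate (fresh weight and water content are occasionally slightly
increased under salt). Missingness policy:

- `zero_fill` (default): a line with zero salt germination has no
  measurable traits; all seven STIs are set to 0 so it enters the panel as
  a maximally sensitive row. The published reference panel handles its four
  non-germinating lines exactly this way (their MFVs are 0.000 on every
  trait). Lines that germinate but produce no measurable seedling get STI 0
  for the affected biomass traits. Every filled value carries a provenance
  flag for auditing.
- `exclude_trait`: unmeasurable traits stay missing; such lines still
  contribute their measured traits to the panel extremes but receive no
  composite score.
- A missing *control* value (the denominator) cannot be meaningfully
  zero-filled and stays missing with its own flag; panels are pre-screened
  for >99% control germination, so in practice this does not occur.

**Membership and grading.** MFV = (STI − min)/(max − min) with extremes
taken over present values in the panel; a trait whose panel min equals its
max is an error rather than being silently dropped, because dropping would
change the meaning of the seven-trait mean. MFVs are stored as fractions
in [0, 1]. The composite score is the unweighted mean of the seven MFVs.
Grades cut at panel mean ± 1 SD and ± 1.64 SD of the composite (1.64 is the
normal 95th percentile, so each extreme grade captures ~5% of an
approximately normal panel); grade lower bounds are inclusive. The sample
SD (ddof = 1) is the default; ddof is configurable since the convention is
ambiguous in screening reports and the difference is ~0.1% at panel sizes
in the hundreds.

**Tolerance model.** OLS of the composite score on the seven STIs with
intercept, solved by numpy's SVD-based least squares. On a complete panel
the composite is affine in the STIs by construction,

    mean MFV = Σᵢ (STIᵢ − minᵢ) / (7·(maxᵢ − minᵢ)),

so the fit is exact: βᵢ = 1/(7·rangeᵢ), intercept −Σᵢ minᵢ/(7·rangeᵢ)
(zero when every trait's panel minimum is 0, which zero-filling guarantees
whenever any line fails to germinate), R² = 1 and residuals at
floating-point noise. This explains why the published model's constant is
−3.33e−16 and its |Y − mean MFV| differences are ~1e−3: the residual error
in the published fit comes only from the 3-decimal rounding of its inputs.
Rank-deficient designs (a constant trait, collinear columns) are rejected
by name. Significance testing and variable selection are deliberately out
of scope — all seven traits are kept; the reported diagnostics are the
8×8 Pearson matrix, per-trait simple-regression R² against the composite
(= squared Pearson r), and standardised coefficients βᵢ·sd(STIᵢ)/sd(Y).

The published 552-line sunflower model is available as
`published_model()` with coefficients (0.143, 0.146, 0.152, 0.213, 0.369,
0.119, 0.088) and grade cuts (0.5216, 0.4302, 0.1446, 0.0532), letting a
user grade new germplasms against the published panel without rescreening.

## The synthetic panel generator

A single latent tolerance θ ∈ [0, 1] per germplasm, Beta(0.9, 2.1)
distributed (right-skewed: most lines moderately sensitive, a thin tail of
highly tolerant lines and appreciable mass near 0), drives every trait.
A common factor plus trait-specific noise is the simplest structure that
reproduces the strong positive inter-trait STI correlations real screens
show.

Per seed: control germination is Bernoulli(0.995) — panels are pre-screened
for seed-lot vigor — with germination day on {1, 2, 3} at probabilities
(0.6, 0.3, 0.1). Under salt, germination is Bernoulli(σ(−4 + 7θ)) and the
day is the control day plus a Poisson(3.5·(1 − θ)) delay, censored at day
7 (a seed germinating later is indistinguishable from one that never
does); day-1 germinations are further thinned by a factor 0.9. Together
the delay and thinning make day-1 germination under salt nearly absent:
the default panel-mean STI_GE is ≈ 0.05, matching the order observed in
real screens (≈ 0.06), and a few lines per hundred fail to germinate under
salt entirely. Replicate biomass is the control mean (RL 5 cm, FW 0.4 g,
dry-matter fraction 0.10) times a monotone response floor + gain·θ^p
(RL: 0.03 + 0.97·θ^1.5; FW: 0.05 + 1.00·θ^1.2, topping out slightly above
1 so tolerant lines occasionally show STI_FW > 1) with mean-1 lognormal
noise of CV 0.20; the dry-matter fraction rises by 0.12·(1 − θ) under
salt, lowering water content in sensitive lines. Dishes with zero
germination yield missing endpoint measures. All draws come from one
`numpy` Generator seeded by `rng_seed`; identical configs produce
byte-identical panels.

What the generator does *not* emulate: genetic or pedigree structure,
trait distributions of any particular real panel beyond the qualitative
features above, seed-to-seed biomass variation within a dish (biomass is
drawn per replicate), dormancy, or fungal loss. Passing tests therefore
show the pipeline's correctness and its ability to rank a one-dimensional
latent tolerance under realistic noise — not that any particular crop's
tolerance is one-dimensional.

## Validation harness

`recover_tolerance` runs the full pipeline on a synthetic panel and
reports Spearman rank correlation between the latent θ and the composite
score (and the fitted Y, which equals the composite on complete panels).
On default panels of 100 germplasms the correlation is ≈ 0.97, and stays
above 0.9 across seeds. The residual disagreement is Monte-Carlo noise:
finite seed counts (11 per dish × 4 replicates) and biomass noise, mostly
affecting the crowded low-θ region.

## Numerical choices and degenerate inputs

- All computation is full precision; the conventional display rounding
  (3 decimals for STI/MFV, 5 for Y) is opt-in at write time. CSV floats
  are written with `%.17g` and read with round-trip parsing so write/read
  is lossless.
- A trait with equal panel min and max, a zero panel SD, a constant or
  collinear design column, and an all-missing trait are errors with the
  offending trait named, never silent drops.
- Stochastic tests average over ≥ 10 generator seeds with stated
  tolerances; problem sizes (panels of 40–200 lines, 10 seeds) keep the
  full suite in seconds while leaving Monte-Carlo error well inside those
  tolerances.

## Known limitations

- The zero-fill value for partially measurable lines (germinated, no
  seedling) is a modelling choice; real screens are ambiguous here, which
  is why the provenance flags exist.
- The grading assumes the composite score is roughly unimodal; cuts at
  mean ± SD are not robust to heavy multimodality.
- The published model transfers to new germplasms only insofar as the new
  material's STI ranges resemble the published panel's; an STI far outside
  those ranges extrapolates linearly without warning.
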