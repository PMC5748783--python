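# Methods

This note documents the models implemented in `protswap`, the choices
made where the design was genuinely open, and what the synthetic survey
does and does not emulate. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and units

The pipeline estimates the prevalence of inadequate protein and
indispensable-amino-acid (IAA) intake in an adult survey population and
simulates graded substitution of animal by plant protein. Units are
fixed package-wide: composition in g/100 g and kcal/100 g, IAA
composition in mg/g protein, daily intakes in g/day, kcal/day and
mg/day, requirements and per-kg intakes in g/kg body weight/day
(protein) and mg/kg body weight/day (IAA). The nine IAA are histidine,
isoleucine, leucine, lysine, the pooled sulfur amino acids (met + cys),
the pooled aromatic amino acids (phe + tyr), threonine, tryptophan and
valine — pooled the same way average requirements are defined.

## Screening

Adults above 65 y are excluded (their protein reference intake differs);
the bound is exclusive, so age 65.0 is retained, and both the bound and
the rule live in `ScreeningConfig`. Energy misreporters are excluded by
the Goldberg cut-off in Black's confidence-limit form: the ratio of mean
reported daily energy intake (alcohol included — misreporting concerns
total energy) to the Henry-equation BMR must lie in
`PAL · exp(∓z·s/100)` with `s = sqrt(CV_wEI²/d + CV_wB² + CV_tP²)`,
using the conventional constants CV_wEI = 23%, CV_wB = 8.5%,
CV_tP = 15%, z = 1.96, and PAL 1.4/1.6/1.8 for low/moderate/high
activity. Henry BMR coefficients (adult bands 18–30, 30–60, 60–70 y,
weight-only and weight-and-height variants) are shipped as a YAML asset;
the weight-only variant is the default since the original survey's
choice of variant is not recorded. Screening is idempotent by
construction: the retained set passes its own screen.

## Daily intakes and the digestibility penalty

Each food's protein (crude, N×6.25) is split into animal and plant parts
by its `animal_protein_fraction`. The plant part of protein *and* of
every IAA is multiplied by 0.95 — a 5% penalty for the lower real ileal
digestibility of plant protein — before any adequacy arithmetic. All
substitution bookkeeping that must balance exactly (Model P's protein,
Models A/B/C's energy) is done on the crude (pre-penalty) scale; the
penalty is then applied uniformly when intakes are evaluated.

## Usual intakes (simplified Multiple Source Method)

Protein and IAA are consumed every day, so no consumption-probability
model is needed and no covariates are used. Per nutrient:

1. **Box-Cox transform** of the pooled daily intakes; λ is fitted by
   profile likelihood on a grid over [−1, 2] in steps of 0.1, with ties
   (within 1e-9 of the maximum) broken toward λ = 1 and non-positive
   data forcing λ = 1.
2. **Variance decomposition** by unbalanced one-way ANOVA
   (method of moments): σ̂²_w = MSW, σ̂²_b = max(0, (MSB − MSW)/n₀).
3. **BLUP shrinkage**: tᵢ = μ̂ + (x̄ᵢ − μ̂)·σ̂²_b/(σ̂²_b + σ̂²_w/Dᵢ),
   where Dᵢ is the individual's number of recorded days.
4. **Back-transform with bias correction**: the usual intake targets the
   long-run *mean* of daily intakes, so the estimate is
   g⁻¹(tᵢ) + ½·(g⁻¹)″(tᵢ)·σ̂²_w (for λ = 1 the transform is affine and
   no correction applies).

If a nutrient has (near-)zero variance across all individual-days the
estimator degenerates to individual means with a warning. Deterministic
given the data. The estimator contracts: the variance of usual intakes
never exceeds the variance of the raw D-day means, with equality only
when σ̂²_w = 0.

## Adequacy (probability approach)

Individual requirements are Normal(EAR, cv·EAR) with cv = 0.125 for
protein and every IAA. The probability of inadequacy at usual intake y
(per kg) is Φ((EAR − y)/(cv·EAR)) — exactly 0.5 at y = EAR, and
1 − Φ(2) ≈ 2.28% at y = EAR·(1 + 2cv). The conventional description of
that point as "97.5% adequate" is an approximation; the implementation
follows the exact CDF. Default EARs: protein 0.66 g/kg/d; his 10,
ile 20, leu 39, lys 30, SAA 15, AAA 25, thr 15, trp 4, val 26 mg/kg/d —
all configurable in `EARTable`.

Population prevalence is the survey-weighted mean of individual
probabilities (the full-probability estimator, not an EAR cut-point
count). The 95% CI is the Wald binomial interval
p ± 1.96·√(p(100 − p)/n) computed on the *unweighted* n and clipped to
[0, 100]; weights therefore move the point estimate but not the CI
half-width — a documented simplification consistent with how such
intervals are usually reported at this design.

## Substitution models

All models act on each individual's mean daily food pattern (the 7-day
mean grams per food). A step s ∈ [0, 1] multiplies the grams of every
*substitutable* food by (1 − s), which removes the fraction s of
substitutable animal protein while keeping the protein shares among the
individual's animal foods constant. Animal protein embedded in mixed
dishes is not substitutable, which is why the attainable plant share
saturates below 100%. The removed quantity Q is crude protein (Model P)
or non-alcohol energy (Models A/B/C) and is returned via plant foods:

* **Model P** — Q(protein) through the individual's pure-plant
  protein-bearing foods, each scaled equally, so plant-protein shares
  are preserved and total crude protein is conserved exactly.
* **Model A** — Q(energy) through the individual's pure-plant
  energy-bearing foods (including protein-free ones such as added fats
  and drinks: the energy pattern is what it is), conserving non-alcohol
  energy exactly.
* **Model B** — Q(energy) through a fixed legumes/nuts/seeds (LNS) mix
  whose shares are the population's observed LNS intake on a non-alcohol
  energy basis (switchable to a protein basis; the substitution currency
  stays energy).
* **Model C**(λ) — λ·Q via the LNS mix, (1 − λ)·Q via the Model-A
  pattern; λ = 0 and 1 recover Models A and B.

Conservation (protein for P, energy for A/B/C) holds to machine
precision at every grid point; the test suite asserts 1e-9 relative.
Individuals with no plant pattern to scale under P/A raise an error
directing the caller to λ > 0.

Each individual's substituted pattern yields a deterministic nutrient
delta, which is added to their usual intakes — a deterministic shift
leaves within-person variance unchanged, so the usual-intake estimation
is not re-run per step. Curves report, per step, the survey-weighted
mean plant-protein share (the x-axis of all crossing estimates), the
weighted mean non-alcohol energy, and the prevalence of inadequacy with
CI for protein and all nine IAA. Crossings are located by linear
interpolation between adjacent grid points (default grid: 0 to 1 in
steps of 0.02); a level never bracketed returns an absent value rather
than an error.

## Descriptives

The contribution table gives each food group's percentage contribution
to (penalized) protein and lysine intake, normalized to 100% within each
individual, then weighted mean ± SD by sex (weighted population SDs).
Whole foods are attributed to their own group, so a mixed dish's animal
protein counts in the dish's group — unlike a recipe-decomposed
analysis; the acceptance script therefore measures "cereal share of
plant protein" from the source-aware accounting instead. Regressions
are OLS of the usual intake:EAR ratio on the plant-protein share in
percentage points, optionally adjusted for age, sex, BMI
(weight/height², m) and non-alcohol energy; slopes are reported per
point and per 10 points.

## Synthetic survey

The generator is the package's study-conditions module, not a fixture.
Defaults: 1678 adults (717 men, 961 women), 7 days, mean protein intake
1.34/1.25 g/kg/d (men/women) on the penalized scale, 31% plant protein,
cereals 67% of plant protein, meat 59%/51% of animal protein, 5% of
animal protein embedded in a mixed dish, within-person day-to-day
CV 0.25 and between-person CV 0.20 (the source survey publishes no
variance figures; these are field-typical values exposed in
`SurveyConfig`).

The 27-food reference composition table is a curated constant spanning
all 19 food groups, anchored to the study's stated benchmarks: cooked
pasta at ~15% protein:energy and lysine 28 mg/g protein, red meat at
~61% protein:energy and lysine 90 mg/g protein, legumes at 26–30%
protein:energy and lysine ~70 mg/g protein. Each individual's mean
daily pattern is built analytically: anthropometry and activity are
drawn first; energy closes onto Henry-BMR × PAL (lognormal noise,
CV 7%); the drawn protein level and plant share are hit exactly by
construction, with food-level allocation shares jittered per individual
(lognormal, CV 25%, renormalized). Plant-heavy diets are tilted to
about −4.5% protein per +10 percentage points of plant share, matching
the reported −0.06 g/kg/d-per-10-points association, so the descriptive
regressions have a real signal to find. Daily records are the mean
pattern times one lognormal day factor (mean exactly 1), independent
across days — the estimator's independence assumption is thus true by
construction, and day-to-day autocorrelation (records are consecutive
days in real surveys) is an acknowledged omission. Survey weights are
lognormal with mean 1 and carry no informative structure.

What passing tests on this generator do **not** show: robustness to
recipe-decomposition error, to correlated day-to-day intakes, to
informative sampling weights, or to food lists with hundreds of items;
the generator reproduces the stated population moments, not the
microstructure of any real consumption survey.

## Numerical choices and problem sizes

* Exchange files are CSV with 15-significant-digit floats; write/read
  round trips are the identity to better than 1e-12 relative.
* Probabilities are exact normal CDFs; the Monte-Carlo check in
  `mc_oracle_probability` exists only as a test oracle.
* Degenerate inputs: zero-variance nutrients warn and fall back to
  means; prevalence of an empty population, non-positive weights, and
  unknown food ids raise errors naming the offender.
* Test problem sizes: unit tests run at n = 60; conservation and
  recovery checks at n = 200–500; the full-scale curve checks and the
  acceptance script at the default n = 1678 with a 0.02–0.05 substitution
  grid — the whole suite runs in well under a minute.

## Known limitations

* The usual-intake estimator omits covariates and measurement-error
  deconvolution beyond the one-way BLUP; it is a deliberate
  simplification of the full Multiple Source Method.
* Requirement distributions are normal only; no intake–requirement
  correlation, no protein-quality scoring (DIAAS/PDCAAS).
* Substitution behaviour is homogeneous across individuals by design;
  no diet optimization, cost or environmental accounting.
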