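# Methods

## Scope and model

The package implements summary-level two-sample Mendelian randomization:
variant–exposure associations from one GWAS, variant–outcome associations
from another, combined per variant as Wald ratios and pooled across
instruments. The identifying assumptions are the usual instrumental-variable
triplet — relevance (enforced by the *P* < 5×10⁻⁸ / F-statistic funnel),
independence (unverifiable from summary data; the *APOE*-region mask removes
the most notorious locus-level violation for dementia-related outcomes), and
exclusion restriction (probed, not guaranteed, by the pleiotropy battery:
Cochran Q, the Egger intercept, robust estimators, and lead-variant
exclusion). Estimates assume a linear exposure–outcome relationship on the
log-odds scale; non-linear effects are out of scope.

## Data model

Summary statistics are pandas DataFrames with canonical columns wrapped in
`SummaryStats` (trait name, unit ∈ {mmHg, SD, logOR}, fallback sample size).
Coordinates are 1-based, intervals closed on both ends — the convention in
which GWAS papers print region bounds. The genome build is whatever the
inputs use; it is carried as metadata and never converted. Readers drop
rows violating the per-variant invariants (se ≤ 0, p ∉ (0,1], identical
alleles, frequency outside [0,1]) with a logged count, and resolve duplicate
rsIDs by keeping the smallest p-value (deterministic, favors the strongest
signal). Outcome-side allele frequency may be missing; such variants cannot
enter palindrome inference and are dropped if palindromic.

The LD reference is a sparse pairwise r² table plus a variant position
index. Absent pairs are r² = 0, r²(v,v) = 1, cross-chromosome pairs are
independent, and pairs farther apart than the window (default 1 Mb) are
treated as uncorrelated. This is panel-agnostic: any LD panel reduced to a
three-column table works.

## Instrument selection

Significance filtering is strict (*p* < threshold). Clumping is the
standard greedy algorithm: sort by ascending p-value (ties by chromosome,
then position — a total order, so output is invariant to input row order),
repeatedly take the best remaining variant as an index, and remove
remaining variants within ±1,000,000 bp whose r² with the index is at or
above the threshold. "1 Mb window" is read as ±1 Mb around the index (a
2 Mb span), matching common clumping-tool semantics; both the radius and
the r² cutoff are configurable. Variants missing from the LD position index
are treated as independent, with a warning — a conservative failure mode
for significance filtering but the only option without positions.

Instrument strength: F = (β/se)², the square of the Wald z, and two
variance-explained formulas — `f_based`, R² = F/(F + n − 2), needing only
the summary row; and `freq_beta`, R² = 2f(1−f)β², needing an SD-scale beta
(or a phenotypic SD to standardize by). `f_based` is the default because
exposure betas arrive in mm Hg and per-cohort phenotypic variances are
generally unavailable. The two formulas agree closely at GWAS sample sizes
but are not identical; which one a given paper used is rarely stated.

## Harmonization

For non-palindromic single-nucleotide variants, allele-label alignment is
exact: same orientation (kept), swapped orientation (outcome beta negated,
frequency complemented), strand-complemented labels (relabelled, then
oriented), or irreconcilable (dropped). Palindromic variants (A/T, C/G)
carry an irreducible ambiguity because strand complementation equals
orientation swap. The rule set, in order:

1. exposure-side MAF > 0.42 (strict) → dropped as unresolvable;
2. missing outcome frequency → dropped (no basis for inference);
3. otherwise infer strand by frequency concordance: after nominal label
   alignment, compare the outcome frequency with eaf and 1−eaf of the
   exposure; the closer match decides the sign. An exact tie → dropped.

MAF is computed from the exposure side (the better-powered study). The
inference step is the standard behavior of harmonization tools; a design
alternative (keep low-MAF palindromes as-is without inference) would differ
only for variants whose studies genuinely disagree on strand. Indels and
multi-allelic records are dropped as mismatches: the instrument sets this
pipeline consumes are SNVs by construction of LD panels. Harmonization is
idempotent and gauge-invariant (relabelling outcome alleles and negating
the beta changes nothing downstream); both properties are tested.

## Estimators

All estimators consume the harmonized (β_X, se_X, β_Y, se_Y) table and use
first-order weights w = β_X²/se_Y², ignoring exposure-side sampling error —
appropriate when instrument F statistics are large (here ≥ 30), and the
convention of standard IVW implementations.

* **IVW**: weighted mean of ratios, equivalently weighted least squares of
  β_Y on β_X through the origin (verified against a direct normal-equation
  solve to 1e-10 relative). "Random effects" is the *multiplicative* model:
  the fixed-effect se is inflated by √(Q/df) floored at 1. This is the
  default in standard MR software; an additive DerSimonian–Laird variant
  sits behind a flag (`additive=True`) since published analyses rarely say
  which flavor they used. The floor makes the test mildly conservative
  (measured type-I error ≈ 0.045 at nominal 0.05, J = 100).
* **MR-Egger**: instruments are first oriented so every β_X ≥ 0 (the
  intercept is only meaningful in a fixed orientation gauge), then weighted
  regression with free intercept; standard errors inflated by the weighted
  residual variance with J−2 df, floored at 1. Wald tests use normal
  quantiles by default, t(J−2) behind a flag.
* **Weighted median**: ratio estimates ordered, cumulative weight
  percentiles p_j = (S_j − w_j/2)/S_J, linear interpolation at 0.5.
  Standard error by parametric bootstrap (θ_j resampled from
  Normal(θ̂_j, se_j²), default 1000 draws); the seed is a required argument
  — there is no silent nondeterminism anywhere in the package.
* **Scaling**: OR per k-unit *decrease* = exp(−kθ̂), CI bounds mapped and
  re-ordered; k = 10 (SBP, mm Hg), 5 (DBP, mm Hg), 0.5 (SD-scale
  exposures, since 10 mm Hg ≈ half an SD at SD = 20 mm Hg).
* **Multiplicity**: strict *p* < α; α defaults to 0.007 when exactly seven
  outcomes are configured (the convention of correcting 0.05 across seven
  phenotypes, with no extra correction across the two correlated BP
  exposures), else 0.05/m.

## Sensitivity analyses

`exclude_near_leads` removes instruments within a closed ±500 kb window of
supplied outcome-GWAS lead variants (reverse-causality guard). Both
operating modes are supported: a list of designated loci, or every lead
variant of the outcome GWAS — the list of loci travels in the
`ExclusionSpec` itself, so no external lookup is needed. Instruments whose
positions cannot be resolved are excluded conservatively.
`rerun_with_exposure` re-executes the entire pipeline with an alternate
exposure GWAS (e.g. one without BMI adjustment, reported on the
inverse-normal SD scale), routing SD-unit exposures through half-SD
scaling so runs stay comparable.

## Synthetic data generator

Per candidate variant: f ~ U(0.05, 0.5); true exposure effect γ (mm Hg per
allele) either rescaled draws of a standard normal so that
Σ 2f(1−f)γ²/SD² hits the target variance explained (default 0.044), or — in
the study-mimic preset — derived from a per-variant noncentrality
λ = 30 + Exp(36), which produces the right-skewed F distribution real
instrument sets show; β̂_X ~ N(γ, se_X²) with se_X = SD/√(2f(1−f)n_X);
pleiotropic effect α ~ N(μ_α, σ_α²), optionally correlated with |γ|
(`inside_rho`, a deliberate InSIDE violation) and optionally carried by
only a fraction of variants; β̂_Y ~ N(θγ + α, se_Y²) with
se_Y = 1/√(2f(1−f) n_Y φ(1−φ)) for case fraction φ. LD blocks are realized
as satellite variants with stored within-block r² and attenuated (r·γ)
effects; distinct loci are placed ≥ 3 Mb apart so they never share a
clumping window. Defaults mirror the emulated study design: n_X = 1,028,980;
n_Y ≈ 7,400 with per-phenotype sizes and case fractions from the published
phenotype table; phenotypic SD 20 mm Hg (so 10 mm Hg = half SD; the source
cohorts' actual SD is not published — 20 is a package default, not a
reported value); 10% palindromic variants. All randomness flows from a
single seeded generator; outputs are bit-reproducible from (config, seed).

What the generator does *not* emulate: individual-level genotypes, ordinal
phenotype models (outcome betas are drawn directly on the log-OR scale —
exactly what the pipeline consumes, so nothing downstream is untested, but
proportional-odds model misspecification cannot arise here), realistic
human LD maps, winner's curse from discovery = analysis sample, sample
overlap between the two GWAS, and the antihypertensive-medication
correction applied upstream of the real exposure GWAS (+15/+10 mm Hg to
SBP/DBP; it changes the phenotype, not the summary-statistics format, and
is documented in the simulation manifest). Passing tests therefore
demonstrate correctness of the pipeline's statistics under its stated
assumptions, not robustness to these real-data features.

The study-mimic preset was calibrated once so that the selected-instrument
count and mean F land near the emulated study's reported values (~831
instruments, mean F ≈ 70); the realized total variance explained (~5.7%)
follows from those two choices via R² ≈ J·F̄/n and is reported in the
manifest rather than forced — the triplet (831, 70, 4.4%) is not jointly
attainable under the f-based formula.

## Numerical and design choices

* Wald-test p-values from the simulator are clipped to the smallest
  positive double rather than reported as 0, so strict thresholding stays
  well-defined.
* Degenerate inputs raise typed errors: IVW with one instrument signals
  that the Wald ratio is the estimator to use; Egger requires three
  instruments and non-degenerate exposure betas; the weighted median
  requires three instruments and ≥ 100 bootstrap draws.
* Equality comparisons at thresholds are strict everywhere (*p* < 5×10⁻⁸,
  MAF > 0.42, *p* < 0.007), matching how the rules are stated in the MR
  literature; boundary behavior is pinned by tests.
* The harmonization action vocabulary includes
  `dropped_palindromic_ambiguous` for palindromes unresolvable for reasons
  other than high MAF (missing outcome frequency, exact frequency tie), so
  reports distinguish the two failure modes.
* Under one-sided contamination the weighted median has a finite-sample
  bias of roughly one weighted-quantile shift (the median lands at the
  0.5/(1−S) quantile of the valid ratio distribution, S the invalid weight
  share, ≈ 1 sd of per-ratio noise), plus occasional breakdown when the
  realized invalid weight share crosses 50%. Its validity test therefore
  runs in the consistency regime (strong instruments, large outcome
  sample, offset ≫ ratio noise), where its bias is ~9% of θ against IVW's
  ~90%. At the emulated autopsy-study sample size its advantage over IVW
  is real but much smaller — worth knowing when interpreting real-data
  robustness batteries.
* Simulation scales in the test suite and acceptance script (replicate
  counts of 100–2000, 100–200 variants per replicate, 25–50 end-to-end
  runs) were chosen to give Monte-Carlo error comfortably inside each
  assertion's band while keeping a full run to a few minutes on one core.

## Known limitations

No proxy-variant substitution for instruments missing in the outcome (they
are dropped, as in the emulated design, which restricted to variants
present in all datasets); no MR-PRESSO, mode-based, or non-linear
estimators; no Steiger directionality filtering; no colocalization; no VCF
or dosage input; no liftover. The LD model is block-diagonal with exact
stored r² — adequate for testing clumping logic, not a substitute for a
real reference panel.
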