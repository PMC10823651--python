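# Methods

## The estimation problem

The package asks whether maternal pre-/early-pregnancy BMI causally affects
a roster of binary pregnancy/perinatal outcomes (and four continuous birth
traits), expressing every effect as an odds ratio (or SD-unit slope) per SD
of maternal BMI.  Because each single design is fallible — regression to
residual confounding, Mendelian randomisation (MR) to pleiotropy and weak
instruments, the paternal comparison to assortative mating — the package
runs all three and classifies each outcome by their agreement.  Since the
individual-level data such analyses use in practice are access-restricted,
the package ships a generator of synthetic mother–father–offspring cohorts
whose parameters place each bias into the data on demand; analyses never
read the generator's latent variables.

## Simulation model

Genotypes. `n_snps` independent biallelic variants (default 97) with allele
frequencies fⱼ ~ U(0.1, 0.9), coded 0/1/2 on the BMI-increasing allele.
Parents are independent Hardy–Weinberg draws Binomial(2, fⱼ); the offspring
receives one Mendelian allele per parent (Binomial(1, g/2)), so a
homozygous parent's transmission is forced and offspring–parent allele
scores correlate 0.5.

Maternal BMI (SD units):

    bmi_m = Σⱼ αⱼ (g_mj − 2fⱼ) + λ_U·U_m + λ_S·S + Σₖ cₖ·zₖ + ε

with U_m ~ N(0,1) an unmeasured confounder, S ~ N(0,1) a couple-shared
factor, zₖ standardized measured covariates, and ε sized so the theoretical
variance is 1 (configurations whose variance components reach 1 are
rejected).  Paternal BMI is generated analogously from the father's own
genotypes, confounder and covariates, sharing only S.  Because each parent
loads λ_S on the same standard-normal factor, corr(bmi_m, bmi_p) = λ_S²;
the calibration routine therefore sets λ_S = √ρ for a target spousal
correlation ρ (0.17–0.24 is the empirically reported range; 0.24 is the
default target).  SNP effects αⱼ are drawn half-normal and rescaled so that
Σⱼ 2fⱼ(1−fⱼ)αⱼ² equals a configurable total R² (default 2.7%, the
instrument strength reported for the 97-SNP BMI score in ~172k women, which
with that sample size yields a mean F near 36).

Outcomes.  Binary outcomes are Bernoulli draws from

    logit P(Y=1) = β₀ + θ_m·bmi_m + θ_p·bmi_p + γ·U_m + γ_S·S
                   + δ·score_off + Σⱼ πⱼ(g_mj − 2fⱼ) + Σₖ bₖ·zₖ

where score_off = Σⱼ αⱼ(g_offj − 2fⱼ) carries the inherited-allele
(fetal-genotype) path, πⱼ ~ N(μ_π, σ_π) is per-SNP horizontal pleiotropy
(drawn once per configuration so all cohorts share it), and β₀ is found by
Brent root-finding so the mean of expit(β₀ + lp) over the simulated linear
predictor hits the target prevalence to ~1e-10 (no thresholding of latent
variables).  Continuous outcomes use the same linear predictor plus unit
normal noise, so configured effects are in SD-of-residual units and slopes
are recovered directly.  Covariates: age ~ N(30, 4.7²) years, parity ~
Poisson(0.8), education ordinal 0–3 (0.2/0.3/0.3/0.2), smoking ~ Bern(0.2),
alcohol ~ Bern(0.3), offspring sex ~ Bern(0.5); fathers get their own
age/education/smoking/alcohol.  Because no coefficients for covariates are
published, the loadings used in the recovery scenarios are package defaults
(BMI loadings 0.05–0.15 SD, outcome log-ORs |b| ≤ 0.25), fully
configurable.

The reference exposure GWAS is simulated at summary level: β̂ₓⱼ ~
N(αⱼ, sⱼ) with sⱼ = 1/√(2fⱼ(1−fⱼ)·n_ref) (standardized-trait
approximation), independent of every cohort — the two-sample structure.

One integer seed determines everything: cohorts use SeedSequence children
keyed by cohort index, SNP parameters and pleiotropy use fixed-purpose
children of the configuration seed, so identical configs are bit-identical
and cohorts are reproducible individually.

What the generator does *not* emulate: linkage disequilibrium between
instruments, genuine mate-choice assortment (spousal genotypes stay
independent; only the phenotypic couple factor is shared), non-European
frequency spectra, gene–environment interaction, missing data, and
non-linear BMI effects.  Passing recovery tests therefore show the
estimators are correct under their stated assumptions, not that real
cohorts satisfy those assumptions.

## Analysis arms

Regression engine.  Logistic fits use Newton/IRLS to a score tolerance of
1e-8 (max 50 iterations); SEs from the inverse Fisher information.
Frequency weights make per-SNP scans exact on aggregated genotype×outcome
cells (≤ 6 cells unadjusted, ≤ 18 with offspring adjustment), which is what
keeps 97-SNP scans over 400k mothers fast.  Perfect separation raises an
error (detected by diverging or saturated coefficients) rather than being
penalised: a silently penalised estimate would enter downstream
meta-analysis with a wrong weight.  Rank-deficient designs raise an error
naming the first dependent column.  Fits with fewer than 10 cases (or
controls) are refused.

Multivariable arm.  BMI is standardized within cohort (mirroring per-study
modelling before pooling); minimal adjustment is maternal age + offspring
sex, full adjustment adds education, parity, smoking, alcohol.  Offspring
sex is included everywhere for efficiency.

Negative-control arm.  The paternal model regresses the outcome on paternal
BMI per SD adjusted for maternal BMI, paternal age/education/smoking/
alcohol, number of children, and offspring sex; the maternal comparator is
additionally adjusted for paternal BMI and the paternal covariates.  Under
a pure couple-factor confounding structure the two estimates converge; a
maternal-specific effect separates them.

Meta-analysis.  Fixed effect: wᵢ = seᵢ⁻², pooled SE (Σw)^(−1/2);
DerSimonian–Laird: τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) with re-pooling on
(seᵢ² + τ²)⁻¹; Q is always computed about the fixed-effect mean, flagged at
p < 0.05, and reported even for two studies.  Per-SNP cross-cohort pooling
joins on variant id and pools each SNP over the cohorts that measured it
(recording per-SNP k), so 12-SNP-subset cohorts contribute where they can.
No Hartung–Knapp small-study correction is applied.

MR estimators.  IVW is the sy⁻²-weighted regression of outcome betas on
exposure betas through the origin; the main analysis uses fixed-effect
weighting, with a multiplicative random-effects variant (SE inflated by
max(1, √(Q/df))) behind a flag since published analyses rarely state which
variant was used.  MR-Egger re-orients all instruments to positive exposure
beta (required for an interpretable intercept), fits with an intercept, and
scales SEs by max(1, √(Q/(k−2))).  The weighted median uses weights
βₓⱼ²/σᵧⱼ² (the first-order inverse variance of each Wald ratio), linear
interpolation at the 0.5 crossing of the midpoint cumulative weights, and a
seeded parametric bootstrap SE (default 1,000 draws).  The weighted mode
maximises a normal-kernel weighted density over the Wald ratios with
bandwidth φ·0.9·min(sd, IQR/1.349)·k^(−1/5) (φ = 1 by default).  Ratios
with |βₓ/σₓ| < 1 are *not* filtered — instrument selection is taken as
given.  Harmonisation aligns outcome to exposure effect alleles: swapped
alleles negate the beta and flip the frequency, strand flips resolve via
base complements, palindromic variants (A/T, C/G) are kept only when both
frequencies are at least 0.08 from 0.5 and concordance decides orientation;
otherwise they are dropped and counted in the log.  The 0.08 band is a
common convention; the source analyses do not state their palindromic rule.

## Verdict rules

Directions are read off log-scale Wald CIs (positive / negative /
null-compatible).  An outcome is `supported` when regression and MR share a
non-null direction and the paternal arm is null-compatible or attenuated
below half the mutually adjusted maternal effect (log scale);
`not_supported` when every arm is null-compatible and the MR CI is narrower
than log 4 (so the null is informative); otherwise `inconclusive`, with
rationale codes (direction_agreement, arm_conflict, paternal_attenuation,
mr_imprecise, arm_missing).  The 0.5 attenuation factor and log-4 width
are explicit operationalisations of a narrative rule — no formal version is
published — chosen to reproduce the qualitative calls on the worked
gestational-hypertension example, and both are configurable.  The
offspring-genotype-adjusted MR is reported as a diagnostic beside the
verdict, not as a fifth arm.

## Numerical and design choices

- The scalar IVW/meta formulas are implemented directly (closed form);
  tests cross-check them against QR-based weighted least squares and
  brute-force optimisers, and the logistic IRLS against an independent
  BFGS likelihood maximiser and statsmodels.
- Egger recovery simulations draw instrument effects lognormal(0, 0.7):
  selected genome-wide-significant instruments have certain signs (so
  re-orientation never interacts with pleiotropy) and heavy-tailed
  strength, giving the between-instrument spread (high I²_GX) Egger needs;
  with near-null or nearly-equal instrument effects the Egger slope is
  materially attenuated, a real limitation users should expect.
- The two-sample IVW recovery experiment is expected to land a few percent
  below the simulated causal OR: per-SNP marginal log-ORs are slightly
  non-collapsible relative to the conditional model, and first-order
  weak-instrument dilution at mean F ≈ 36 contributes ~1/F̄.  Both effects
  are inherent to the design being emulated.
- Problem sizes in the shipped recovery scenarios (200k mothers for the
  regression arm, 400k for the MR outcome sample, 100k couples, 50k for
  the correlation calibration; 500-replicate calibration loops at n=3,000
  × 15 SNPs) were chosen to give Monte-Carlo error comfortably inside each
  check's tolerance while keeping a full run on a single CPU in minutes.
- Pipeline stages are pure functions of (config, workdir): cohorts are
  regenerated deterministically from the seed hierarchy wherever needed,
  which is what makes staged CLI runs byte-identical to `run-all`.
- Complete-case analysis only; the simulator generates no missingness.

## Known limitations

Independent instruments only (no LD-aware methods); no MR-PRESSO, Steiger
filtering, multivariable MR or non-linear MR; no correction for the small
exposure/outcome sample overlap such designs can carry; binary-outcome
effects are conditional ORs whose marginal counterparts differ slightly at
high prevalence; the verdict rule is one defensible operationalisation
among several — its thresholds are exposed precisely so sensitivity to them
can be checked.
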