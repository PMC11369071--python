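# Methods

`comorbkit` implements the four analysis arms of a genetically informed
comorbidity study — familial co-aggregation, twin variance decomposition,
polygenic-score association, and LD-score regression — together with
synthetic-data generators that stand in for the register, twin-cohort and
GWAS summary inputs such studies consume. This note records the models, the
numerical choices, and what the synthetic validation does and does not
establish.

## Liability-threshold kernel

Binary traits are modelled as indicators that a latent standard-normal
liability exceeds a threshold `t = Phi^-1(1 - K)` set by the prevalence `K`
(upper-tail convention throughout: affected = liability above threshold).
Every likelihood in the package reduces to orthant probabilities of a 2- or
4-dimensional normal:

* **dim 2** — exact closed form via Owen's T function
  (`scipy.special.owens_t`). Removable singularities at `h = 0` or `k = 0`
  are handled by an epsilon nudge (continuity error < 1e-13) and `|rho| = 1`
  by degenerate closed forms.
* **dims 3–4** — a deterministic conditioning reduction: the one or two
  tightest-constrained variables are transformed onto the unit cube (their
  normal densities and limits absorbed exactly, as in sequential-conditioning
  methods for MVN rectangle probabilities), and the remaining bivariate
  orthant is evaluated in closed form on a tensor Gauss–Legendre grid. A
  smoothstep change of variables (`u = 3v^2 - 2v^3`) suppresses the mild
  endpoint singularities of the transform; at the default 48 nodes per
  conditioned dimension the worst-case absolute error against a
  high-effort QMC reference is ~1.6e-7 (median ~4e-10), comfortably inside
  the 1e-6 budget, and the integrand is a smooth function of model
  parameters, which the quasi-Newton fitters require. Joint cell
  probabilities over all above/below patterns come from Möbius inversion of
  the marginal upper-orthant probabilities, so cells are consistent and sum
  to one by construction.
* A batched variant shares one variable ordering across many threshold
  vectors (used by the covariate-adjusted per-pair likelihoods); its
  worst-case accuracy is ~1e-5, ample for likelihood contributions.

Observed-scale to liability-scale heritability uses the standard
case-control correction `h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2)`
with `z` the normal density at the threshold; the conversion is exactly
invertible and both directions are exposed.

## Tetrachoric correlation

Maximum likelihood over the 2x2 multinomial with bivariate-normal cell
probabilities, optimized jointly in `(atanh r, t1, t2)` from a start at the
margin-implied thresholds and the Pearson phi coefficient. Wald intervals
are built on the atanh scale from the observed information (numerical
Hessian, central differences). Degenerate tables are not continuity-
corrected — corrections bias `r` — but flagged as boundary results, with
`r` pinned at ±1 for perfectly concordant/discordant tables and undefined
when a margin is empty. Twin correlations double-enter each pair (and pool
the two orderings for cross-twin cross-trait tables) so estimates are
invariant to twin labelling; the reported uncertainty is rescaled by
sqrt(2) so it reflects unique pairs, not doubled entries.

## Twin variance decomposition

Univariate and bivariate ACE/ADE/AE/CE/E liability models with the
classical sharing rules (MZ share A and D fully and C fully; DZ share A
one-half, D one-quarter, C fully; E is never shared). Bivariate models use
the correlated-factors parameterization: per-trait variance proportions
plus factor correlations `r_a`, `r_c` or `r_d`, `r_e`; the implied 4x4
liability correlation (ordered twin1-trait1, twin1-trait2, twin2-trait1,
twin2-trait2) feeds the 16-cell orthant multinomial.

Estimation choices:

* Optimization on unconstrained transforms — softmax over variance
  proportions, atanh for correlations, free thresholds — with L-BFGS-B and
  five seeded random restarts (best likelihood kept). Variance proportions
  are therefore nonnegative by construction; boundary solutions surface as
  estimates numerically equal to zero.
* Without covariates the data are collapsed to sufficient cell counts
  (3 exchangeable cells per zygosity univariately; 16 cells bivariately).
  Expected (non-integer) counts are accepted, which is how the
  parameter-recovery oracles enter: fitting to exact expected counts must
  return the generating parameters to numerical precision.
* Covariates enter as linear threshold shifts on the probit scale (the
  standard liability treatment), switching the likelihood to per-pair
  orthant probabilities evaluated with the batched kernel. Categorical
  covariates should be dummy-encoded by the caller.
* Wald CIs on the natural scale by the delta method through a numerical
  Hessian (central differences, step 1e-5 on the transformed scale),
  deliberately untruncated so interval bounds may cross zero.
* Model selection: AIC ranking plus likelihood-ratio tests restricted to
  nested pairs (AE in ACE/ADE, CE in ACE, E in all). At a true boundary
  (`d2 = 0` or `c2 = 0`) the LRT statistic is a half-chi-square mixture, so
  AIC picks the larger family in a minority (~8–20%) of samples; the
  selection test asserts a clear majority across seeds, not unanimity.
* Thresholds are common across zygosity groups (and subcohorts are not
  modelled separately); no sex-limitation models are fitted.

## Familial co-aggregation

Typed proband–relative pairs are constructed from a pedigree by
parent-sharing rules: full siblings share both parents, maternal (paternal)
half-siblings share exactly the mother (father), and all ordered pairs are
kept. Associations are logistic regressions of the outcome trait in the
relative on the exposure trait in the proband (within-individual "self"
pairs being the degenerate case), with a cluster-robust sandwich estimator
— clustered on the shared parental unit (parent couple for full sibs, the
shared parent for half-sib and parent pairs) with the G/(G-1) small-sample
factor — because one family contributes every ordered pair of its members.
Adjustment levels: crude; plus sex, standardized birth year and parity
(parity dummy-encoded 1/2/3+, omitted for parent pairs where it is
undefined); plus the exposure trait in the relative. A single filter step
applies birth-year-window and exclusion-flag removals with before/after
counts logged.

## Polygenic scores

Shrinkage-based weights are consumed, not computed. The MHC add-back rule:
shrunken rows inside the MHC window (default chr6:25–34 Mb, GRCh37,
configurable) are dropped and the single most significant raw-GWAS variant
in the window is appended with its unshrunk effect (ties broken by larger
|effect|, then id, and logged). Scoring sums effect-allele dosages times
weights with allele harmonization (swapped alleles flip the dosage to
`2 - d`; strand-ambiguous A/T and C/G variants and irreconcilable
mismatches are dropped with a warning; missing dosages are mean-imputed per
variant) and standardizes within the scored set. The association model is a
generalized estimating equation with logit link and independence working
correlation — implemented as the logistic point estimate with a
cluster-robust sandwich covariance on twin-pair clusters, which is the same
estimator — reporting a per-SD odds ratio.

## LD-score regression

Univariate: two-step weighted regression of `chi^2 = z^2` on the LD score,
weights `1 / (l * max(1, E[chi^2])^2)` updated once from a first pass;
slope times `M/N` is the observed-scale heritability, the intercept is free
by default (constrainable to 1), and `M` defaults to the number of
regression variants. Bivariate: the `z1*z2` regression slope gives the
genetic covariance, and `r_g = gencov / sqrt(h1^2 h2^2)` re-estimated in
full for every delete-a-block jackknife replicate (200 contiguous blocks
standard, 20 for small simulated panels). Alleles are harmonized on merge
(swapped pairs sign-flip `z`). Liability-scale conversion takes `K` and `P`
as explicit inputs. Negative fitted heritabilities are reported as-is with
a warning flag.

## Synthetic data: what it emulates, and what it does not

All generators are seeded and bit-reproducible.

* **Twin pairs** draw liabilities from the exact zygosity-implied 2- or
  4-variate normal, so the empirical tetrachoric structure converges to the
  analytic one; covariate effects shift liabilities linearly. Default
  prevalences mirror the registry values the package's validation targets
  use (IBD-like 0.7%, asthma-like 18%, rhinitis-like 30.6%, eczema-like
  16.3%).
* **Family cohorts** build mother-centred sibships (offspring count
  1 + Poisson with mean 2.2, so ~2.2 children per family; a later child
  switches father with probability 0.12, and a family reuses an earlier
  family's father with probability 0.04 — rates chosen to give half-sib
  pair counts of the same order as register studies report relative to full
  sibs). Two trait models: a liability variant with kinship-correct
  additive transmission (child A = midparent A + segregation noise of
  variance a2/2, mother-household shared C) for co-aggregation gradients,
  and a direct logit variant whose conditional within-individual odds ratio
  equals the stated parameter — the registry ORs are conditional logistic
  quantities, so the OR-recovery targets use the logit variant. Covariate
  effects default to log-OR 0.2 for sex and 0.1 per SD of birth year,
  typical magnitudes for register confounders; intercepts are solved
  numerically so marginal prevalences hit their targets.
* **Summary statistics** draw LD scores from a shifted gamma
  (`1 + Gamma(2, 40)`, right-skewed with mean ~81, the shape of genome-wide
  LD-score distributions) and z-scores with variance
  `intercept + N h^2 l / M`. Noiseless mode places chi-squares exactly on
  the polygenicity line; the bivariate noiseless construction uses matched
  variant duos sharing an LD score whose within-duo means sit exactly on
  all three regression lines, turning regression recovery into a linear
  identity. Stochastic mode draws correlated z pairs per variant.
* **PRS cohorts** draw standardized scores (within-pair correlation 0.5
  when twin clustering is on, between the MZ and DZ expectations for a
  polygenic score) and outcomes from a logit model with the stated per-SD
  OR; optionally a dosage matrix and weight table are emitted whose
  computed score reproduces the stored one exactly.

What passing recovery tests shows: the estimators are correct for data
generated under their own assumptions at registry-like sample sizes. What
it does not show: robustness to real-data violations — misclassified
phenotypes, ascertained twin samples, LD structure beyond the marginal
LD-score distribution, population stratification, or genuine non-normal
liabilities. The generators make no attempt to emulate haplotype-level LD,
imputation error, or survey-response ascertainment.

## Problem sizes and determinism

The validation suite fits expected-count oracles at 1e6 pair-equivalents
per zygosity (univariate) and 1e7 (bivariate), simulates ~2e6 probands for
the co-aggregation recovery, 2e5 twins for the PRS recovery, and 5e4
variants for the LD-score recoveries — sizes at which sampling error is
well inside the acceptance tolerances while the full suite runs in a few
minutes on one CPU. Deterministic stages (expected-count fits, noiseless
regressions) depend on the seed only through optimizer restart draws and
return identical estimates across seeds; stochastic stages derive
per-stage child seeds from the single user seed.

## Known limitations

* Orthants above dimension 4 (larger sibships in one likelihood) are out of
  scope; co-aggregation handles larger families pairwise with cluster
  robust errors instead.
* Bivariate fits with covariates are supported but slow at scale (per-pair
  4-dimensional orthants); the validation exercises the covariate-free
  collapsed-count path at scale and the per-pair path at small n.
* The tetrachoric SE under double entry uses the sqrt(2) unique-pair
  rescaling, which is exact for within-trait tables and a good
  approximation for pooled cross-trait tables.
* Opposite-sex DZ pairs are pooled with same-sex DZ pairs; sex-specific
  thresholds are supported only through explicit covariates.
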