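# Methods

`reactnorm` implements a two-step reaction-norm analysis of genetic
sensitivity to environmental variation for a single-record growth trait
(post-weaning weight gain, PWG, adjusted to a 300-day period), followed by
a weighted single-step genomic association analysis on the reaction-norm
coefficients. This note documents the models, the estimation machinery,
the synthetic-data generator, and the numerical and design choices.

## The two-step reaction-norm model

**Step 1 — environmental gradient.** The environmental descriptor is
derived from the data: contemporary-group (CG; herd-year-season-sex-
management class) effects are estimated as BLUEs from a baseline animal
model

    y = CG + age (linear, quadratic) + a + e,   a ~ N(0, A sigma2_a),

and standardised over CG levels to zero mean and unit sd; the standardised
value w is the gradient. Standardisation is unweighted over CG levels with
the population-sd convention (divide by n); at the reported precision the
back-transformed extremes are identical under either sd convention. The
baseline model's variance components are estimated with the same REML
engine as step 2 (a single-coefficient model) rather than assumed. CG
effects are identified by omitting a global intercept, so BLUEs stay on
the kg scale of the trait. Records from CGs more than 3 sd *above* the
mean are discarded before step 2 — only the favourable tail, where a few
extreme management groups would dominate the regression slopes; the harsh
tail is the phenomenon under study.

**Step 2 — reaction norms.** Each animal j carries a vector of random
regression coefficients b_j; its genetic merit at gradient w is z(w)'b_j.
Five model kinds are supported (see the table in `rnm.py`): linear with
homoscedastic or heteroscedastic residuals, quadratic, and two spline
variants with a single knot at the average environment (k = 0), where the
spline basis uses w* = w·1[w >= k], so the second-segment slope is the
derived quantity b1seg2 = b1 + b1*. Coefficients are distributed
N(0, A ⊗ K) with A the pedigree relationship matrix, and residual
variance is log-linear in the same basis, sigma2_e(w) = exp(eta'z_r(w)).
Models are compared by AIC/BIC, counting dispersion parameters only
(q(q+1)/2 elements of K plus the residual coefficients; 4/5/9/9/20 for
the five kinds), with n = records after filtering in the BIC penalty.

Because the gradient is constant within a CG and CG effects are fitted as
fixed, the overall fixed regression on w (and its spline/quadratic
companions) is exactly collinear with the CG dummies. The design builder
therefore keeps a single deterministic fixed-effect basis — CG dummies
plus centred linear/quadratic period terms — and drops the redundant
curve columns. This matters beyond rank: the restricted likelihood
depends on the *basis* of the fixed-effect matrix (through log|X'V⁻¹X|),
so cross-model AIC/BIC comparisons are valid only when all models share
the same X. Slope variance is then identified purely through families
whose members are recorded in different environments — which is exactly
the data structure (heavily used AI sires with progeny spread across the
gradient) the analysis presumes.

## REML estimation

With a single record per animal, the marginal phenotypic covariance is

    V = (W K W') ∘ A22 + diag(exp(Zr eta)),

where W stacks z(w_i)', A22 is the relationship block among recorded
animals and ∘ is the Hadamard product. The engine maximises the
restricted likelihood directly in this marginal form; non-recorded
relatives are marginalised exactly and their coefficient solutions are
recovered afterwards by kriging through the pedigree
(b_hat = A[:,rec] diag(Py) W K). Two exact, interchangeable backends
evaluate the likelihood and the average-information (AI) quantities:

* a dense backend forming V explicitly (any relationship structure, up to
  a few thousand records);
* a Woodbury backend for half-sib designs, where A22 = diag(d0) + FF'
  with one factor column per shared (founder) parent; all products reduce
  to O(n (qm)²) with m the number of shared parents, so a 5000-animal
  fit costs a few seconds. The two backends agree to machine precision
  and are cross-checked in the test suite.

The optimiser parameterises K through its Cholesky factor (K = LL'), so
positive semi-definiteness is structural rather than enforced by
projection; eigenvalue bending is used only to repair an indefinite
starting value. Updates are damped AI-Newton steps (Levenberg damping,
trust-region cap at five scale units per parameter, step halving on
likelihood decrease), alternating with an L-BFGS polish in the same
parameterisation when Newton progress stalls. The alternation matters:
near the psd boundary the likelihood forms long curved valleys in which
damped AI steps creep (observed: ~1e-4 logL per iteration) while
quasi-Newton descent does not, and conversely. Plain AI-REML with
eigenvalue bending — the textbook recipe — was tried first and verified
to stall against a derivative-free optimiser on the same likelihood;
the Cholesky/alternation scheme reproduces those reference optima.
Convergence is declared when the expected gain of a damped Newton step
falls below 0.02 logL units, or when neither a Newton line search nor the
polish can improve the likelihood (a boundary-stationary point; the AI
matrix is an *average* information and overestimates achievable gain
there, so achieved — not forecast — improvement is what decides).
Non-convergence within the alternation budget raises an error carrying
the likelihood trajectory. A relative ridge of 1e-10 on K keeps the
Woodbury form smooth when the optimiser walks onto the boundary. Model
ladders (homo → hete → quad/spline) are warm-started by embedding the
parent fit, which also makes the nesting inequality
logL(larger) ≥ logL(smaller) hold structurally.

Within-CG identification limits are intrinsic at moderate scale: with the
study's strong intercept–slope correlation (0.86) the truth lies near the
psd boundary, and slope-variance estimates at n = 5000 are right-skewed
(the constraint |K01| ≤ sqrt(K00·K11) truncates the sampling distribution
from below). The recovery tests measure this honestly rather than hiding
it; see Limitations.

## Weighted single-step association

With components fixed at their REML estimates, GEBVs are predicted under
the same reaction-norm model with the pedigree block replaced by the
blended genomic relationship G_b = (1-ε)G + εA22 (VanRaden first-method
G = ZZ'/(2Σp(1-p)), Z = M - 2p, allele frequencies from the genotyped
set; ε = 0.05 by default for invertibility). The package implements both
a sparse mixed-model-equation solve with an arbitrary inverse
relationship (A⁻¹ or H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ - A22⁻¹]) for the general
case, and a dense equivalent-model path used when every phenotyped animal
is genotyped — the two agree to solver precision. SNP effects are
back-solved as u = D Z' G_w⁻¹ g / (2Σp(1-p)); when G is rank-deficient
(fewer SNPs than animals) the minimum-norm solve is used, which is exact
because the GEBVs lie in the range of G and Z' annihilates its null
space. Weights d_i ∝ u_i² 2p_i(1-p_i) (normalised to mean one, floored
at 1e-8) are recomputed for two additional rounds (three total); each
reported coefficient gets its own weighted evaluation driven by its own
effects, since nothing in the source procedure specifies how one weighted
relationship could serve several coefficients at once. For spline models
the reported coefficients include the derived segment slopes (b1s2 GEBV =
b1 + b1* GEBVs) back-solved like any other contrast.

Association signal is summarised as the percentage of the coefficient's
genetic variance (the corresponding quadratic form of the fixed K — not
the realised GEBV variance) explained by sliding segments of five
adjacent SNPs: 100·Var_animals(Σ_w Z u)/c'Kc, assigned to the window's
first SNP (centre assignment available), never spanning chromosomes.
Windows at or above 0.5% are extended 200 kb both ways and merged per
chromosome across coefficients into candidate regions, each carrying its
leading window percentage per coefficient. Genes overlapping a region
(1-based inclusive coordinates; BED input converted at the reader) are
annotated, and gene-set overrepresentation uses the upper-tail
hypergeometric test with Benjamini–Hochberg correction across sets,
against the full annotation as default background.

## The synthetic-data generator

No public data accompany this analysis, so every stage is exercised on
synthetic data whose generative model mirrors the fitted spline model —
the choice that makes parameter recovery a well-posed check:

    y = CG effect + age effects + z(w)'b + e,  e ~ N(0, exp(eta'z_r(w))).

* **Pedigree**: paternal half-sib families from heavily used AI sires;
  every mating uses a fresh founder dam (dams in these populations rarely
  have a second recorded calf). Defaults: 100 sires × 50 progeny = 5000
  recorded animals, one generation; multi-generation male lines are
  supported. This is also the structure that admits the exact factored
  A22 used by the fast REML backend.
* **Environments**: CG effects ~ N(93.7, 28.16²) kg over 200 groups —
  the location and spread reported for CG solutions in large Nellore
  post-weaning-gain recording schemes —
  with animals assigned to groups at random, so each sire family spans
  the gradient. The true gradient is the standardised true CG effect.
* **Coefficients**: defaults K = [[90, 16.3, 0], [16.3, 4, 0], [0, 0, 16]]
  (b0, b1, b1* basis, kg²) and eta = (log 250, 0.3, −0.15) — magnitudes
  matching the study's linear-heteroscedastic estimates with a
  spline-deviation variance of the reported size. The coefficient vector
  is the sum of a causal-SNP part (a configurable fraction of each
  coefficient's variance, rescaled to the realised variance, with
  cross-coefficient effect correlations matching corr(K)) and a polygenic
  part drawn by recursive pedigree sampling (founders ~ N(0, K_poly),
  descendants mean-parent plus Mendelian deviation — exact A ⊗ K_poly
  covariance by construction).
* **Genotypes**: founder allele frequencies uniform on the configured MAF
  range, Mendelian gene-drop with unphased transmission probability
  g/2 (exact for 0/1/2 data), evenly spaced map (40 kb) on 10
  chromosomes. Linkage beyond pedigree-induced co-segregation is not
  simulated.
* **Planted QTL**: a single large variant can be planted on one (possibly
  derived) coefficient; for segment quantities it loads on the deviation
  coefficient only, so a "segment-2" QTL leaves segment 1 untouched by
  construction. Its share is removed from the polygenic block to keep the
  total on target.
* **Ages**: weaning and long-yearling ages uniform in the recording
  windows (90–300 and 310–730 d, minimum 150-d period), with small
  linear/quadratic period effects (0.02 kg/d, −5e-5 kg/d²); raw gains are
  stored over the actual period and re-adjusted to 300 d by the QC step.

What the generator does **not** emulate: linkage disequilibrium beyond
family co-segregation, selection and assortative mating, genotyping error
and imputation artefacts, sex-linked inheritance, and heterogeneity of CG
sizes and recording depth found in field data. Passing tests therefore
show internal consistency of the estimation machinery under the assumed
model, not robustness to these field realities.

## Problem sizes and study conditions

Simulation studies run at 5000 recorded animals in 200 CGs (REML
recovery and model comparison; 20 replicates) and 3000 genotyped animals
× 2000 SNPs (association; 10 replicates); the acceptance script uses
6 and 3 replicates at the same sizes. Two findings from these studies are
worth stating plainly, because they are properties of the method at this
scale rather than implementation defects:

1. **BIC cannot resolve the spline at moderate n.** The spline-vs-linear
   likelihood separation measured under the default generator is
   2·ΔlogL ≈ 1–8 at n = 5000, while the BIC penalty for the four extra
   parameters is 4·ln(5000) ≈ 34. The same arithmetic applied to the
   published full-scale analysis (AIC improvement of ~507 for the spline over
   the linear model at 421,585 records, i.e. ~0.0012 per record) gives
   2·ΔlogL ≈ 6 at n = 5000: the effect sizes in question are simply not
   BIC-detectable much below ~10⁵ records. The model-comparison
   machinery is checked in the direction that is decidable (the simpler
   truth is recovered essentially always).

2. **Window percentages do not transfer across marker densities.** A
   5-SNP window is 0.0012% of a 412k-SNP panel but 0.25% of a 2000-SNP
   panel, so a fixed 0.5% threshold is ~400× the mean window share in
   the former and only 2× in the latter; after three weighting rounds
   even null coefficients produce windows above 0.5%. In addition, the
   strong prior intercept–slope correlation couples the two spline
   slopes at moderate n: a deviation-only QTL leaks into the segment-1
   slope windows (measured leak ratio ~2 in percentage terms, driven by
   the 5× smaller segment-1 denominator; setting cov(b0,b1) = 0 in the
   generator drops the ratio five-fold). Clean segment-specific region
   calling of the kind reported at full scale therefore does not
   reproduce at 3000 animals / 2000 SNPs; the association tests document
   the detection half (the QTL is found for the segment-2 slope) and the
   sharpening of the weighting rounds.

## Numerical choices and degenerate inputs

* Convergence: expected-Newton-gain tolerance 0.02 logL units; Newton
  phase tolerances 1e-6 (logL) and 1e-8 (relative parameters); polish
  budget 100 function evaluations per round, scaled up for the
  20-parameter spline; at most 8 Newton/polish cycles.
* K bending on starts: eigenvalues floored at 1e-6 of the largest.
* Residual exponents clipped at ±40 to avoid overflow; zero-variance
  coefficients yield NaN correlations (flagged, not raised).
* Monomorphic SNPs are a hard error in G construction (QC must remove
  them); a singular blended G raises with advice to increase ε.
* Chromosomes with fewer than five (kept) SNPs contribute no windows and
  are logged.
* CG-size QC iterates to a fixpoint (dropping a group cannot re-trigger
  the other filters, but the loop guards the general case).
* Seeded runs are bit-reproducible end to end.

## Limitations

* REML slope-variance estimates at n ≈ 5000 are right-skewed when the
  true intercept–slope correlation is near ±1 (psd-boundary truncation);
  means over 20 replicates can sit ~2–4 SE above the truth for the
  segment-1 slope variance. This is the estimator, not the optimiser:
  the same skew appears when the engine is run on data simulated by an
  independent brute-force multivariate-normal generator.
* The marginal-likelihood formulation assumes one record per animal
  (true for this trait); repeated records would need the MME route.
* The fast REML backend requires the phenotyped cohort to be progeny of
  founders (the AI half-sib design); other pedigrees fall back to the
  dense backend, practical to a few thousand records.
* The dense equivalent-model GWAS path requires every phenotyped animal
  to be genotyped; the general sparse H⁻¹ route covers mixed cohorts but
  at small scale only.
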