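# Methods

## Model and likelihood

A haplotype block is an ordered set of L biallelic SNPs; alleles are
oriented at load time so 1 is the sample minor allele (ties: the
lexicographically larger allele name). The block's haplotype list holds
the K+1 distinct haplotypes retained for analysis, ordered by
descending estimated frequency with lexicographic tie-break; the most
frequent haplotype is the baseline (index 0). The latent variable per
individual is the unordered diplotype Z; its population probability is
Hardy-Weinberg over the haplotype frequencies f, optionally with an
inbreeding coefficient d (default 0, fixed): f_j² (+ d-correction) for
homozygotes, 2 f_j f_k (1−d) for heterozygotes.

Disease odds are logistic, log θ_Z = α + X_Z β, with X_Z the
additive/dominant/recessive coding over non-baseline haplotypes. The
case-control stream is modelled retrospectively:
P(Z|Y=1) ∝ [θ_Z/(1+θ_Z)]·P(Z) and P(Z|Y=0) ∝ [1/(1+θ_Z)]·P(Z), each
normalised over the complete pair set. This normalisation is the
single most consequential modelling convention in the package and is
isolated in `likelihoods.retro_prob` so an alternative can be swapped
in. Trios ascertained through an affected child contribute
P(Z_child|Y=1)·P(Z_untransmitted), the factorisation licensed by
allelic exchangeability; the untransmitted pair enters at its plain
population probability, with no conditioning on the child's phenotype.
The composite log-likelihood is the exact sum ℓ_cf = ℓ_c + ℓ_f.
Observed-data versions marginalise over all genotype-compatible
diplotypes (subjects) and over all parental phase/transmission
configurations consistent with the three genotypes (trios). All
arithmetic is on the log scale with log-sum-exp.

Individuals may legitimately appear in both streams (trio members
extracted from the same pedigrees as subjects); the dependence this
creates is exactly what the adjustment corrects, so the engine warns on
id overlap but does not deduplicate. The PED loader, however, follows
the convention that members of an extracted trio do not re-enter the
case-control stream.

## Magnitude adjustment

With dependent units ℓ_cf overstates information. The correction
rescales: ℓ* = k·ℓ_cf with k = p/Σλᵢ, the λᵢ being eigenvalues of
H⁻¹J, solved as the generalized symmetric eigenproblem J v = λ H v
(equivalently k = p/trace(H⁻¹J)).

Design choices:

* **Adjusted block**: (α, β) only, p = K+1. Haplotype frequencies are
  held fixed while differentiating — numeric Hessians across the
  simplex are unstable and the inferential targets are the β's.
* **Derivatives**: central finite differences of the observed-data
  (phase-marginalised) composite log-likelihood; step 1e-5·max(1,|x|)
  for gradients and 1e-4·max(1,|x|) for second differences (second
  differences amplify rounding by 1/h², so the larger step keeps the
  Hessian noise near 1e-6 relative).
* **J**: units (each subject, each trio) are grouped by pedigree id;
  J = Σ_c s_c s_cᵀ over cluster-summed score contributions. This
  uncentred empirical form estimates Var[score] only where the total
  score vanishes, so H and J are evaluated at the composite MLE of
  (α, β) — never at an arbitrary chain state, where the mean-score
  term grows with the squared distance from the optimum, sends k → 0
  and collapses the tempered posterior onto the prior (tried and
  rejected).
* **Plug-in frequencies for k**: by default the MLE (and H, J) use the
  chain-initial EM frequency estimate rather than the current
  frequency draw. Evaluating at the chain's random f turned k into a
  noisy random multiplier of the tempered target (observed swings of
  ±30% within one run), which both miscalibrates posterior spread and
  wrecks cross-fit comparability; at a fixed plug-in point k is a
  per-dataset constant, which is also the adjustment literature's
  convention. `k_at_current_freqs=True` restores state-tracking
  updates for sensitivity analysis.
* **MLE robustness**: the retrospective likelihood flattens as
  α → −∞ (α cancels from the limiting model), a plateau that can
  strand a single quasi-Newton run; the solver therefore starts from
  both the previous optimum and the origin and keeps the better.
* **Regularisation**: H's eigenvalues are floored at 1e-8 of its
  largest before inversion; Σλ ≤ 0 raises an adjustment error, and a
  failed update leaves the previous k in place (the adjustment is a
  rescaling, not a likelihood component).
* **Schedule**: k is recomputed every iteration by default;
  `k_update_every` trades cost for staleness, and a test verifies the
  posterior is insensitive to the schedule beyond Monte Carlo noise.

## MCMC

The target is the k-adjusted posterior over (Z, α, β, λ_s, f); every
conditional raises its likelihood factor to the power k so a single
tempered target is sampled (as k → 0 phase draws become uniform over
the compatible set — tested). Sweep order: phases (Gibbs from each
unit's compatible set, drawn for all units in one vectorised
cumulative-sum pass), α (random-walk MH, Normal(0, σ_α²) prior,
σ_α = 10 by default), each β_j (random-walk MH, Laplace(0, rate λ_s)
prior), a block of joint (α, β) adaptive-Metropolis steps, λ_s (exact
Gibbs from Gamma(a+K, b+Σ|β_j|)), f (MH with a Dirichlet proposal
centred at the current value, flat Dirichlet prior; proposals that
strand an assigned haplotype at zero support auto-reject), then the k
update.

Because the retrospective likelihood identifies α only weakly, the
(α, β) posterior is strongly ridged and component-wise random walks
mix slowly. Two remedies are built in: proposal scales (and the
Dirichlet concentration) adapt in Robbins-Monro batches toward
standard acceptance targets during burn-in only, so the post-burn-in
kernel is a fixed valid MH transition; and the joint steps propose
from a Haario-style empirical covariance of (α, β) estimated from
burn-in draws and frozen thereafter. Both are on by default
(`adapt_proposals`, `n_joint_steps`).

Hyperparameter defaults follow the conventions of this model family:
a = b = 20 (prior mean shrinkage rate 1, informative enough to shrink
noise effects), ε = log(1.1) for the Bayes-factor null {|β| ≤ ε} ("OR
within 10% of 1"). The BF is the posterior-to-prior odds of |β| > ε:
the posterior mass is the chain fraction (clipped to
[1/(M+1), M/(M+1)]), the prior mass integrates the Laplace tail
exp(−λε) over the Gamma hyperprior by 1-D quadrature (closed form
(b/(b+ε))^a serves as a test oracle). Credible intervals are 95%
equal-tailed on exp(β) draws. Significance = BF > 2 and CI excluding 1.

Chains are seeded from deterministic substreams of one master seed;
identical inputs give bitwise-identical output. With ≥ 2 chains,
split-free Gelman-Rubin R̂ and effective sample size are computed via
arviz; R̂ > 1.1 produces a warning in the result, not a failure.
`fix_alpha` / `fix_freqs` / `fix_shrink` / `fix_k` freeze components,
which reduces the model for oracle comparisons (e.g. k≡1 with no trios
is plain case-control logistic-LASSO haplotype regression) and for
sensitivity analyses. Under the retrospective likelihood α is only
weakly identified; with the default diffuse prior its chain is
prior-dominated, which is harmless for the β's but worth knowing when
reading trace plots.

## Haplotype list construction and pooling

Candidate haplotypes are the union of all diplotype completions of the
observed genotypes (a sub-hypercube per genotype: fixed where dosage is
0 or 2, free at heterozygous/missing SNPs). Gene-counting EM over the
candidates — treating trio members as unrelated, for initialisation
only — gives frequencies used to order the list. `pool_threshold`
(default 0 = no pooling) folds haplotypes below the threshold into the
baseline *as a fallback*: units are enumerated against the retained
list first, and only a genotype with no retained-list diplotype has its
full-list completions mapped onto the baseline category. Mapping every
completion (not just the orphaned ones) was tried and rejected: it
hands ambiguous genotypes a spurious baseline-homozygote phase and
biases the frequency posterior upward at the baseline.

Missing genotypes are handled by completion enumeration with a
per-subject cap of 2 missing SNPs; subjects over the cap are dropped
and logged.

## Simulator

The generators emit data under exactly the model assumed: whole-block
haplotypes drawn from the pool (carrying LD implicitly), logistic
penetrance, Mendelian transmission, rejection ascertainment
(case/control quotas; trios kept only when the child is affected). The
pedigree mode gene-drops a replicated family template — default: two
founders, two offspring, a married-in founder and one grandchild, the
smallest structure yielding cases, controls and a trio from one family
— and extracts every phenotyped member into the case-control stream
plus every affected child with both parents present as a trio, all
under a shared pedigree id. True diplotypes are retained on each record
for recovery tests.

The 7-SNP `block_pool()` fixture has four common haplotypes (0.40,
0.20, 0.1663, 0.15) and two rare (0.0437, 0.04); the 0.1663 entry is
fixed by design and the rest are the package's one-time choice of a
realistic spread. What the simulator does *not* emulate: genotyping
error, within-block recombination, population stratification, missing
genotypes, or ascertainment beyond simple rejection — so passing tests
demonstrate correctness of the inferential machinery under the model's
own assumptions, not robustness to real-data artefacts.

## Numerical and scale choices

* Rejection-sampling draw budgets guard infeasible penetrances
  (explicit simulation-infeasible errors, never silent loops).
* The type-I-error harness stratifies per-haplotype significance calls
  by the generating-pool frequency (< 0.05 = rare); haplotypes absent
  from the pool (phase artifacts that survive pooling) are counted in
  the rare stratum since their true frequency is 0. Failed replicates
  are excluded and reported with reasons.
* Study problem sizes are chosen so each check measures what it claims
  at desk scale: adjustment laws and the information identity at 500
  units; recovery at 500+500 subjects and 100 trios over 20 replicates
  with 20000-iteration chains and a shared haplotype list across the
  joint and case-control-only arms (the chains are sized so Monte
  Carlo error in the posterior-sd estimate sits well below the
  few-percent width reduction trios contribute, and a shared list
  makes the comparison contrast data rather than model dimension);
  null calibration at 120 replicates per arm with
  400-iteration chains and k updated every 25 iterations. The
  "calibrated level" of the BF & CI rule is not an analytic constant,
  so calibration is measured by running the identical null study on an
  independent-units template and comparing common-haplotype rejection
  rates within two pooled binomial standard errors.

## Known limitations

* Single block per fit; no cross-block phasing, no covariates, no
  quantitative traits, no reference-panel imputation.
* The retrospective normalisation and the trio factorisation are
  modelling conventions; other normalisations would change numbers.
* α is weakly identified (see above); its posterior reflects the prior.
* Finite-difference H/J cost grows as p²; for large K prefer
  `k_update_every` > 1 and pooling of ultra-rare haplotypes.
* VCF input is out of scope for this version; PED/MAP covers the
  array-genotype use case and is the extension point.
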