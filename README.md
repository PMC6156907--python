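# haplasso

Bayesian LASSO haplotype association for mixed study designs: jointly
analyse unphased **case-control** and **case-parent trio** SNP data
within a haplotype block, with a composite-likelihood correction for
familial dependence among the sampled units.

## Who this is for

Statistical geneticists following up regions flagged by a genome-wide
single-SNP scan who want haplotype-level effects — including **rare
haplotypes** tagged by common SNPs — and whose samples mix unrelated
cases/controls with affected-child trios extracted from the same
pedigrees. Analysing either stream alone wastes information; naively
multiplying their likelihoods misstates it.

## The model

Within a block of L SNPs an individual carries an unordered haplotype
pair (diplotype) Z, observed only through the dosage genotype G
(many-to-one). Disease odds follow a logistic model

    log θ_Z = α + X_Z β,          θ_Z = P(Y=1|Z) / P(Y=0|Z),

with X_Z the mode-of-inheritance coding (additive/dominant/recessive)
over the K non-baseline haplotypes. Sampling is retrospective:

    L_c(φ) = ∏_i P(Z_i | Y_i, φ)                  (case-control)
    L_f(φ) = ∏_i P(Z_ic | Y_ic=1, φ) P(Z_iu | φ)  (trios: child + untransmitted pair)
    L_cf   = L_c × L_f                            (composite likelihood)

where P(Z|Y) ∝ penetrance × Hardy-Weinberg diplotype probability,
normalised over the full pair set. Because cases, controls and trios
can come from the same pedigrees, L_cf is misspecified; inference uses
the **magnitude-adjusted** log-likelihood

    ℓ*(φ) = k · log L_cf(φ),      k = p / Σᵢ λᵢ,

with λ₁…λ_p the eigenvalues of H⁻¹J, H = −E[∇²ℓ_cf] (sensitivity) and
J = Var[∇ℓ_cf] (variability, estimated by summing score contributions
within pedigree clusters). Independent, well-specified data give k ≈ 1;
shared-pedigree dependence drives k below 1, deflating the effective
information. An MCMC sampler with Laplace (LASSO) shrinkage priors on β
explores the adjusted posterior over latent phases, α, β, haplotype
frequencies and the shrinkage rate; a haplotype is reported significant
when its Bayes factor exceeds 2 **and** the 95% credible interval of
OR = exp(β) excludes 1.

## Worked example

```python
import numpy as np
import haplasso as hp

hl, fv = hp.block_pool()                      # 7-SNP pool, 6 haplotypes
reg = hp.RegressionParams(alpha=np.log(0.2), beta=np.zeros(5))
spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                         n_cases=90, n_controls=140, n_trios=20,
                         pedigree_template=hp.default_template(), seed=7)
cc, trios = hp.simulate_pedigrees(spec)       # shared pedigree ids
cfg = hp.MCMCConfig(n_iter=400, n_burn=120, n_chains=1, seed=5,
                    pool_threshold=0.01, k_update_every=25)
res = hp.run_mcmc(cc, trios, cfg)
print(f"k = {res.k_trajectory[:, 120:].mean():.3f}")
print(res.summary.to_frame().round(3).to_string(index=False))
```

prints

```
k = 0.592
haplotype  freq    OR  ci_lower  ci_upper    BF  significant
  0101010 0.221 0.758     0.440     1.244 0.535        False
  0010001 0.182 0.932     0.563     1.389 0.263        False
  1100000 0.216 0.765     0.365     1.271 0.550        False
  1011010 0.054 1.071     0.476     2.722 0.214        False
  1111111 0.032 1.510     0.572     4.044 0.390        False
```

The data were simulated under the null (β = 0): no haplotype is called
significant, and k ≈ 0.59 quantifies how much the overlapping pedigree
extraction (every family contributes subjects *and* trios) inflates the
naive composite information. Each row gives the haplotype's posterior
frequency, posterior mean odds ratio, 95% equal-tailed credible
interval, and Bayes factor for a non-null effect.

The same pipeline is available from the shell:

```bash
haplasso simulate --config sim.yaml --out-prefix data --seed 11
haplasso fit --ped data.ped --map data.map --out results.tsv --seed 5
haplasso study --config null.yaml --out rates.tsv --seed 1
```

`fit` reads linkage PED/MAP (phenotype 2/1/0 by default, 1/0 dialect
available), applies the MAF ≥ 1% screen helpers, auto-extracts complete
affected-child trios, and writes a TSV of per-haplotype summaries plus
a JSON provenance log (inputs, seed, config hash, k trajectory).

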