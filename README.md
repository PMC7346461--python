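# snakedent

Phylogenetic comparative analysis of snake maxillary dentition.

Rear-fanged ("opisthoglyphous") snakes carry enlarged, often grooved teeth at
the posterior end of the maxilla, but the phenotype has resisted
quantification: the teeth are small, the species are rare, and "rear-fanged"
has never had an agreed operational definition. This package provides the
statistical toolkit for treating fangs as continuous characters on a
phylogeny: it derives species-level dental traits from per-tooth measurement
tables, corrects them for cranium size, measures phylogenetic signal, relates
dentition to prey-subjugation mode and diet, and reconstructs ancestral fang
states. It is aimed at researchers in squamate macroevolution and at anyone
who needs a self-contained, tested Python implementation of the underlying
comparative methods.

## The statistics at the core

**RPTL (relative posterior tooth length)** — the fang-size statistic for
non-front-fanged snakes. Many species show a background anterior-to-posterior
increase in tooth size, so enlargement is measured against that gradient: fit
OLS of tooth length on position for all measurable teeth except the three
posterior-most, predict those three from the line, and report the median
residual. Positive RPTL = rear-fang enlargement; negative = reduction.

**Phylogenetic covariance** — every analysis conditions on C, with
C_ij = shared root-to-MRCA branch length of species i and j, the trait
covariance implied by Brownian motion. Pagel's λ multiplies the off-diagonal
of C (λ = 0: star phylogeny, λ = 1: Brownian), estimated by maximizing the
multivariate-normal likelihood profile; Blomberg's
K = (MSE₀/MSE) / E_BM[MSE₀/MSE] has expectation 1 under Brownian motion, with
a tip-permutation p-value.

**GLS machinery** — phylogenetic residuals
β = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y (the size-corrected traits used downstream), PGLS
regression with F, R² and p under the λ-scaled covariance, independent
contrasts (x_L − x_R)/√(v_L + v_R) with through-origin contrast regression,
and phylogenetic PCA on the evolutionary covariance
R = (X − 1a)ᵀC⁻¹(X − 1a)/(n − 1).

**Simulation-null phylogenetic ANOVA** — the classical one-way F referred to
a null distribution of F from Brownian simulations on the tree (rate
estimated from the data), with Holm-corrected simulation-based post-hoc
pairwise tests. This protects against group differences manufactured by
phylogenetic clumping of the groups.

**Diet association** — an 11-category diet count table becomes a bipartite
diet graph and a dissimilarity matrix (Euclidean or Gower); the Mantel
correlation of diet and dentition distances is tested with free or
phylogenetically weighted permutations (swap probability ∝ exp(−d/τ),
τ = median patristic distance).

**Ancestral fang states** — two routes on a 3-state
(unmodified/grooved/hollow) or 4-state (+tubular) coding: exact marginal
reconstruction under the equal-rates Markov model at the ML transition rate
(P_same(t) = 1/k + (k−1)/k·e^(−kqt)), and the quantitative-genetic threshold
model (Brownian liability crossing ordered thresholds) sampled by
Gibbs/Metropolis MCMC.

A synthetic-data generator (`snakedent.simulate`) produces trees, tooth
tables and ecology tables with the statistical structure the analyses assume
— planted posterior enlargement, phylogenetically clumped subjugation modes,
Brownian-logit diets with optional planted diet-dentition association — so
every stage is testable without museum data.

## Worked example

Size-correct a dental trait and regress fang size on it (from
`examples/04_size_correction_pgls.py`):

```text
PIC screen: slope = 0.541, F = 222.5, p = 5.9e-27 -> trait scales with cranium size
phylogenetic residuals: mean -1.06e-01, sd 0.552 (the size-corrected trait used downstream)
PGLS: slope = -0.464, F(1,98) = 33.1, R^2 = 0.253, p = 9.9e-08
```

The contrast regression confirms maxilla length scales with cranium size, so
the trait is replaced by its GLS residuals; the PGLS slope of −0.46 then says
that species with shorter-than-expected maxillae carry relatively larger
posterior teeth — the rear-fang syndrome. Each `examples/` script
demonstrates one capability the same way (simulation, trait derivation,
signal, ANOVA, diet, ancestral states, full pipeline).

The full pipeline runs over a bundle directory, from Python
(`run_full_analysis`) or the shell:

```sh
snakedent simulate --seed 1 --n-species 145 bundle/
snakedent run-all bundle/ --seed 7
```

writing per-stage CSVs plus a `manifest.json` that records every seed,
parameter and output checksum; re-running a manifest's config reproduces all
outputs byte-for-byte.

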