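# Methods

This note documents the models, estimators, numerical choices and
limitations of the snakedent toolkit. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Trees and covariance

Trees are rooted, with branch lengths in arbitrary time-like units; tips are
always ordered by post-order encounter (left-to-right in the Newick), so all
derived matrices are bit-reproducible. The Brownian covariance C has
C_ij = shared root-to-MRCA path length; pruning a tree keeps the original
root, so the covariance of a pruned tree is exactly the corresponding
submatrix of the full one. Pagel's λ multiplies the off-diagonal of C and is
capped at 1 (not the larger algebraic bound): this matches conventional
usage and keeps C positive semidefinite on every tree. Zero-length terminal
branches are legal but flagged; duplicate tip labels are rejected because
they are the one case where zero branches make C singular. Polytomies are
accepted everywhere C is used directly, but independent contrasts reject
them (the pruning recursion is defined for bifurcations; degree-1 nodes,
which pruning can create at the root, are passed through with their branch
variance accumulated). Taxon-name reconciliation is never guessed: a user
joining external tables to a tree must supply matching labels.

## Trait derivation

A tooth row records every ankylosed tooth position of one maxilla, including
socket-inferred missing positions; replacement (non-ankylosed) teeth never
enter the table. Derived traits:

- tooth count includes socket-inferred missing teeth; its log (natural) is
  the analyzed scale;
- fang size is the longest measurable tooth, its position counted including
  missing-socket positions, ties resolved to the most posterior position
  (the conservative choice in a rear-fang context) with a logged warning;
- groove width per tooth is the mean over the five semilandmarks, and the
  species value is the mean over grooved teeth (the nesting is a package
  choice; the alternative — pooling all semilandmarks — differs only when
  grooved teeth differ in size);
- RPTL uses the three posterior-most *positions* (missing teeth included in
  the count of three) but only measurable teeth enter the OLS fit and the
  median residual. At least 2 measurable anterior and 1 measurable posterior
  teeth are required; otherwise RPTL is undefined for that species, which is
  logged and the species dropped from RPTL analyses. This deliberately
  leaves RPTL undefined for front-fanged morphologies (e.g. a viper maxilla
  with a single fang), matching its role as a rear-fang statistic.

Multiple specimens of a species are combined by mean for continuous traits
and mode for counts/flags/positions, ties resolved to the larger value.

## Signal, GLS, ANOVA, pPCA

λ is estimated by maximizing the profile log-likelihood (mean and rate
profiled out analytically) over [0, 1]: a deterministic 0.01-resolution grid
followed by bounded scalar refinement (tolerance 1e-8) around the grid
optimum, which is robust to the flat likelihoods common near the boundary.
The p-value is a likelihood-ratio χ²(1) test against λ = 0. Two caveats are
worth knowing: λ = 0 reduces exactly to the iid-normal likelihood only on
ultrametric trees (otherwise the diagonal of C is unequal), and the LR test
is conservative at the λ = 0 boundary in finite samples — the reference R
implementation behaves identically — so its size is well below the nominal
α. Blomberg's K uses the phylogenetically corrected mean in both mean
squares and is normalized by its Brownian expectation
(tr C − n/1ᵀC⁻¹1)/(n − 1); its permutation p-value shuffles tip values and
uses the add-one rule (b + 1)/(nperm + 1), so the smallest attainable p with
999 permutations is 0.001. All permutation/simulation p-values in the
package use the add-one rule, and ties count as exceedances.

PGLS defaults to fixed λ = 1 (the convention of the standard R
implementation), with ML-λ optional; `phyl_resid` is by construction the
residual vector of the λ = 1 PGLS. F uses (1, n − 2) df; R² is computed
against the GLS intercept-only model. The PIC screen regression is forced
through the origin (contrasts have mean zero) with residual df =
(#contrasts − 1); its slope equals the PGLS slope exactly, which the tests
verify on random trees.

The phylogenetic ANOVA estimates the Brownian rate from the data by the mean
squared standardized contrast (REML-like; GLS quadratic form on trees with
polytomies), simulates `nsim` Brownian traits on the tree at that rate by a
single Cholesky factorization, and refers the classical F to that null.
Post-hoc pairwise pooled-variance t statistics get p-values from the same
simulations, Holm-corrected. All simulation seeds are mandatory inputs and
are recorded in results.

pPCA computes the evolutionary mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and evolutionary
covariance R = (X − 1a)ᵀC⁻¹(X − 1a)/(n − 1) (correlation-rescaled on
request), eigendecomposes R with a deterministic sign convention
(largest-magnitude element of each eigenvector positive), and reports both
the orthonormal eigenvectors and display loadings as Pearson correlations
between scores and raw traits — the near-±1 values conventional in the
field's tables. Rank-deficient inputs get clipped zero eigenvalues and a
warning. Scores are the centered (standardized, in correlation mode) data
rotated onto the eigenvectors; their GLS covariance is diagonal with the
eigenvalues, which the tests assert.

## Ecology and the Mantel test

Diet uses a fixed 11-category vocabulary (reptiles, reptile eggs, birds,
bird eggs, mammals, fishes, amphibians, annelids, arthropods, mollusks,
other); main-prey ties break by this order with a logged flag. Diet
dissimilarity is computed on proportions by default (raw counts optionally),
because sampling effort differs wildly across species; Gower dissimilarity
is range-normalized mean absolute difference with constant columns dropped.
The Mantel statistic is the Pearson correlation of lower triangles, tested
two-sided on |r|. Besides free permutations, a phylogenetically weighted
scheme performs n label swaps per permutation with partner probability
∝ exp(−d_patristic/τ), τ = median patristic distance; the scheme id is
recorded and the pipeline always reports the free-permutation test
alongside. The weighted scheme is the honest null when both matrices carry
phylogenetic structure — the free test can reject on phylogeny alone.

## Ancestral states

The equal-rates model uses the closed-form transition probability
P_same(t) = 1/k + (k − 1)/k·e^(−kqt) inside Felsenstein pruning with
per-node rescaling, a uniform root prior, and a bounded log-scale ML search
for q (upper bound 100/tree height; all-one-state data give q̂ = 0 flagged
as a boundary). Marginal node probabilities come from the up/down algorithm,
equivalent to rerooting at every node; they are verified against brute-force
enumeration over all ancestral assignments on small trees (the oracle is
capped at 6 tips / 3 states to stay enumerable).

The threshold model fixes the liability's Brownian variance at 1 and the
first threshold at 0 for identifiability; the remaining thresholds are
uniform on the ordered set within (0, T_max], T_max = 6·√(tree height) —
about ±6 liability SD at the tips — so the posterior is proper. The sampler
alternates (i) Gibbs updates of internal-node liabilities from their exact
normal full conditionals, (ii) vectorized truncated-normal updates of tip
liabilities within their observed state's interval, and (iii) random-walk
Metropolis on each free threshold, whose acceptance under the flat prior
reduces to an indicator that all tip liabilities stay in their intervals;
the step size adapts toward ~30% acceptance during burn-in only. Node state
posteriors are post-burn-in interval frequencies; a thinned trace (every
10th generation) of the root liability and thresholds is kept, and a split
R-hat above 1.2 on the root liability attaches a convergence warning to the
result. The default chain is 100,000 generations with 20,000 burn-in; the
test suite and acceptance script use 20,000/4,000, which the recovery tests
show is sufficient at the 100-tip scale. State order defaults to the
biologically motivated unmodified < grooved < hollow (< tubular) — groove
deepening toward an enclosed canal — and is always a configurable input.

## Synthetic data

The generator's defaults emulate the study conditions: 145 species (a few
with unknown prey-subjugation mode — 4 by default — to exercise the study
filter), a unit-rate Yule tree, Brownian latent traits driving cranium size
(~27 mm), maxilla length (~35% of cranium), tooth count (17 ± 4, clipped to
8–30), posterior enlargement c (0.4 ± 0.8 mm) and grooving propensity
(logit around 0.35); anterior tooth lengths are baseline 1.2 mm + 0.06
mm/position with 0.05 mm measurement noise, teeth go missing (socket
recorded) at 8%, and venom-using modes shift the dental traits (venom-MS:
c + 1.2 mm, −4 teeth, −15% maxilla) to mimic the rear-fang syndrome.
Subjugation modes are assigned by cutting an independent Brownian liability
at its quintiles — so groups are phylogenetically clumped, which the ANOVA
null calibration requires to be honest — and diet counts are multinomial
draws (~25 records/species) from Brownian-logit profiles, optionally mixed
with a rank-1 dentition term of weight a ∈ [0, 1] to plant a diet-dentition
association. Families are monophyletic clades from a depth cut targeting
~10 groups; the two smallest play the front-fanged roles (tubular/hollow
states), the three largest play the colubrid subfamilies.

What the generator does not emulate: measurement covariance between traits
of one specimen, ontogenetic variation, biased sampling of rare taxa,
non-Brownian evolution (OU attraction, rate shifts), and real diet-record
heterogeneity. Passing tests therefore demonstrate the correctness and
calibration of the estimators under their own assumptions, not robustness
to violations of those assumptions in real museum data.

## Pipeline

The pipeline derives traits, screens each focal trait for cranium-size
scaling by PIC regression (gate α = 0.05, configurable; significant traits
are replaced by GLS residuals, and fang size is log-transformed before
residualization by default — the transform-then-residual order is a config
switch), builds the signal table, runs the all-species pPCA on the five
focal traits and per-subfamily pPCAs with RPTL substituted for fang size,
colubrid-only PGLS among trait pairs, mode ANOVAs (after removing
unknown-mode species; the family-level palatine/pterygoid comparisons use
the same simulation-null ANOVA after dropping single-species families),
diet analyses, and both ancestral-state reconstructions under the 3- and
4-state codings. Species missing groove width enter the all-species pPCA
with groove width 0 (no groove = zero width on the trait scale). Every
stage seed derives deterministically from the master seed; the manifest
records config hash, input checksums, per-stage parameters, seeds, output
checksums and warnings, and contains no timestamps, so a re-run is
byte-identical. Missing ecology data skips the dependent stages with an
explicit SKIPPED status.

## Problem sizes

The test suite and acceptance script use 20–200-tip trees, 100–1000
null simulations/permutations per test, and 20,000-generation MCMC chains;
these sizes are where the calibration bands (e.g. mean K within 0.9–1.1,
ANOVA type-I error within 0.03–0.07) are tight enough to be informative
while each check stays at desk scale.

## Known limitations

- No Ornstein–Uhlenbeck or multi-rate trait models; no measurement-error
  models; no stochastic character mapping or model averaging for discrete
  states.
- The λ likelihood-ratio test is boundary-conservative (see above); treat
  its p-values as upper bounds on the evidence against signal absence.
- The threshold sampler updates internal liabilities one node at a time;
  mixing degrades on very large trees (thousands of tips) where a blocked
  sampler would be preferable.
- The phylogenetically weighted Mantel permutation scheme is one reasonable
  choice among several published ones; results report which scheme was used
  and the free-permutation test is always given alongside.
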