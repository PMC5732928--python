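# Methods

`riverkin` implements the statistical core of a conservation-genetics
workflow for small, fragmented riverine fish populations held partly as
captive broodstock: within-population diversity from microsatellites,
between-population differentiation from microsatellites and mtDNA,
demographic-history inference, individual-based cluster analysis, and a
kinship-based mating advisor. Because individual-level genotypes of such
studies are rarely published, the package ships first-class simulators that
reproduce the statistical structure every downstream method assumes; all
calibration claims are made against those simulators and are re-derived at
run time by the test suite and `scripts/acceptance.py`.

## Simulators

**Neutral coalescent loci.** Each microsatellite locus is an independent
Kingman coalescent for `2n` genes with time in units of `2N` generations;
mutations fall on branches as a Poisson process of rate `θ/2` per unit, so
`E[S] = θ·Σ 1/i` (Watterson) and, under the infinite-alleles model,
`E[K] = Σ θ/(θ+i)` (Ewens). Allele states are realized per model:

* **IAM** — every mutation creates a never-before-seen allele (codes spaced
  ≥10 apart so identity-in-state equals identity-by-descent);
* **SMM** — ±1 steps on an integer ladder rooted at 100 (a reflecting floor
  at 1 keeps codes positive; untriggered at realistic θ);
* **TPM** — per mutation, a single ±1 step with probability `p_single`
  (default 0.70) and otherwise an IAM-type novel allele. This per-mutation
  mixture is the `tpm_variant="mixture"` dialect of the classic 70% SMM /
  30% IAM two-phase model; a geometric multi-step variant is deliberately
  not implemented because no variance parameter is part of the model
  definition used here.

**Bottlenecks.** An equilibrium population of `n_base` diploids (default
200) is crashed to `round(n_base·crash_factor)` diploids and drifted
forward by mutation-free Wright–Fisher sampling for `generations_since`
generations before sampling. Mutation is negligible over the few
generations a "recent bottleneck" spans, which is the regime the
heterozygosity-excess test targets.

**Structured demes.** An ancestral equilibrium sample is partitioned into
isolated founding pools of `2·deme_size` genes which drift independently
for `round(divergence·2·deme_size)` generations (pure drift, no
migration). `divergence` is therefore drift time in coalescent units of the
deme size.

**mtDNA control region.** A coalescent genealogy with finite-sites
mutation: each mutation picks a uniform site and is a transition with
probability `ts_bias/(ts_bias+1)`. Defaults emulate a ~791 bp fragment of
70 fish with ~38 segregating sites and a 34:7 transition:transversion
ratio and the empirical A/C/G/T composition. Multiple hits at a site are
possible and slightly depress the realized ts:tv ratio below the
per-mutation value.

**Pedigree pairs.** Relationship categories are generated by explicit
parental construction — founders drawn gene-by-gene from supplied
frequencies, offspring by Mendelian segregation (full sibs share two
parents, half sibs one, parent–offspring is a founder and its child) —
never by sampling IBD states directly. Founder genes carry hidden ancestry
labels, so realized k-coefficients are observable; tests verify e.g.
k̂₂ ≈ 0.25 for full sibs. The reference condition throughout is 5,000 pairs
per category at 20 loci of 10 equifrequent alleles, matching the scale of
broodstock evaluation studies.

What the simulators do **not** emulate: genotyping error, null alleles and
stutter, linked loci, migration, selection, and uneven real-world sampling.
Passing calibration therefore demonstrates correctness of the estimators
under their own model assumptions, not robustness to those artefacts.

## Diversity statistics

Per locus: allele count `A`; rarefied allelic richness
`Ar = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)]` (hypergeometric expectation of alleles
in `g` genes; `g` defaults to the full sample, where `Ar = A` exactly, and
in multi-population comparisons should be set to the smallest
per-population gene count); observed heterozygosity `Ho`; Nei's unbiased
gene diversity `He = (2n/(2n−1))(1 − Σp²)`; `F_IS = 1 − Ho/He`, undefined
at monomorphic loci. The multi-locus `F_IS` is the ratio of sums
`Σ(He−Ho)/ΣHe`, which is stable when some loci have near-zero diversity.

**Exact HWE test.** The chain swaps the contents of two random allele
slots per step, holding allele counts fixed. Over ordered slot assignments
the walk is uniform, and a genotype table `T` corresponds to
`n!/Πn_ij!·2^h` assignments, so the induced table distribution is exactly
Levene's conditional distribution without any accept/reject step. The
p-value is the chain fraction of tables whose conditional probability is
≤ the observed one (probability-test dialect, two-sided by construction);
batch means give the Monte-Carlo SE. Defaults follow common practice:
1,000 dememorization steps, 100 batches of 10,000 iterations. Validated
against complete enumeration of Levene's distribution at two alleles.

**Linkage disequilibrium** uses the G statistic of the two-locus genotype
contingency table with a permutation null (one locus' genotypes shuffled
among individuals) and the add-one p-value rule; ties count as ≥ observed
(conservative).

## Differentiation

**Jost's D.** Per locus
`D = [(Ht−Hs)/(1−Hs)]·k/(k−1)` with the nearly unbiased estimators
`Hs = (2ñ/(2ñ−1))(1 − meanⱼ Σᵢ p²ᵢⱼ)` (harmonic-mean sample size ñ) and
`Ht = 1 − Σᵢ p̄ᵢ² + Hs/(2ñk)`. Because of the small-sample correction,
identical samples yield a value at or marginally below zero rather than
exactly zero; the uncorrected plug-in estimator would be exactly zero
there, but the corrected form is the one in standard use and is kept.
Multi-locus D is the arithmetic mean of per-locus values
(`combine="harmonic"` is available); the bootstrap null resamples each
population's genes from the pooled frequencies and uses the add-one rule
(minimum 99 resamples).

**AMOVA ϕ_ST.** Pairwise nucleotide-difference counts over
complete-deletion sites serve as squared molecular distances; two-level
sums of squared deviations give variance components σ²ₐ (among) and σ²_b
(within) and `ϕ_ST = σ²ₐ/(σ²ₐ+σ²_b)`. Negative estimates are reported as
computed. Significance permutes individuals among populations, 10,000
permutations by default. No substitution-model correction is applied to
the distances (none is defined for the workflow this mirrors); populations
of one sequence participate in pooled comparisons but contribute no
within-group degrees of freedom.

## Clustering

The individual × (locus, allele) dosage table holds allele fractions
(copies/2); missing genotypes are imputed with column means, the
centring-neutral choice. DAPC centres and scales the table, reduces by
PCA, and runs LDA on the a-priori site labels. Membership probabilities
are a softmax over −½·squared Euclidean distance to group centroids in
discriminant space — a documented dialect; other implementations derive
them from the discriminant eigenbasis slightly differently. The retained-PC
count `n_pcs="auto"` maximizes the α-score (observed correct-reassignment
proportion minus its mean over 10 seeded label randomizations) over
1..min(20, rank).

Neighbor joining follows Saitou–Nei agglomeration with two deterministic
conventions: Q-matrix ties break to the smallest index pair, and negative
branch lengths are clamped to zero with the length transferred to the
sibling edge (preserving the pair's summed length). On additive matrices
the generating tree is recovered exactly; scikit-bio's NJ serves as an
independent cross-check in the tests.

## Bottleneck test

For each polymorphic locus with `k` alleles in `2n` genes, the equilibrium
distribution of `He` conditional on `k` is simulated. How θ enters the
conditioning matters:

* **IAM** — the allele configuration given `K = k` is independent of θ
  (sufficiency of `K` in the Ewens sampling formula), so per-`k`
  conditioning is exact: bisection on θ targeting `E[K] = k`, then
  rejection sampling keeping exact-`k` replicates. Validated against
  exact enumeration of the Ewens conditional distribution.
* **SMM / TPM** — no such sufficiency holds: `He | k` increases with θ
  (homoplasy hides mutations). Matching θ per locus so `E[K] = k` biases
  `Heq` low for loci with below-average `k` and high for above-average
  `k`, asymmetrically enough to inflate the test's one-sided type-I error
  several-fold (measured ≈0.18 at nominal 0.05 in calibration). The test
  therefore estimates a single multilocus θ̂ from the dataset's mean
  allele count (bisection on `E[K]`, pilot simulations) and bins
  equilibrium `He` by realized `k` from simulations at θ̂ — the correct
  conditional distribution up to θ̂'s sampling noise, which is
  second-order. `heq_distribution` still exposes the per-`k` search for
  direct study of the conditional moments.

`DH = He_obs − mean(Heq)` is reported per locus, but the one-tailed
Wilcoxon signed-rank test (exact null up to 25 loci; zeros dropped) is
applied to the probability transform `u = F_Heq(He_obs) − ½`, the
mid-rank empirical CDF of the simulated conditional distribution. The
reason: `Heq | k` is strongly left-skewed (skewness ≈ −1.1 to −1.5 under
SMM at n = 50), so raw `DH` has a *positive median under the equilibrium
null* — the signed-rank symmetry assumption fails, and calibration runs
measured a ≈0.13 type-I rate at nominal 0.05 even with exact-θ
conditioning. Under the null `u` is uniform on (−½, ½), hence symmetric,
and the same calibration design yields a pooled type-I rate of 0.050
(1,500 equilibrium datasets) with power ≈0.8 against a 20-fold crash
five generations back. Median-centring `DH` was also tried and
over-corrects (≈0.025): a skewed, median-zero variable still violates
signed-rank symmetry, conservatively for this tail.

The conditional distribution depends only on `(model, θ̂, 2n, k)` — θ̂
quantized on a ×1.1 log grid — so a cache may be shared across loci and
datasets; this is what makes 500-replicate calibration studies cheap,
and it does not change any distribution.
The report also prints the SD of `DH` across loci per model. Note the
model ordering: conditioning on `k` under SMM implies a higher θ than
under IAM (homoplasy hides mutations), so equilibrium `He|k` is *higher*
under SMM and the SMM test is the conservative variant.

## mtDNA statistics

`Hd = (n/(n−1))(1 − Σf²)` with Nei's sampling variance; `π` is the mean
pairwise difference per usable site with the standard total
(stochastic + sampling) variance. Fu's `Fs` uses `θ̂ = π̂` in absolute
pairwise differences and the Ewens sampling distribution — `S′ = Pr(K ≥
k_obs | θ̂)` via exact unsigned Stirling numbers of the first kind —
giving `Fs = ln(S′/(1−S′))`; haplotype excess drives `Fs` negative.
`R2 = sqrt(meanᵢ (Uᵢ − k/2)²)/S` with `Uᵢ` the singleton mutations carried
by sequence `i` (minor-state count 1, outgroup-free) and `k` the mean
pairwise difference. Coalescent p-values condition on the observed `S`
(mutations placed multinomially on a constant-size genealogy's branches);
both statistics use `p = Pr(sim ≤ obs)`, the direction sensitive to
demographic expansion. θ-conditioned null simulation is not offered; the
fixed-S convention matches the cited workflow's practice.

**Median-joining network.** Nodes are haplotype state vectors over the
polymorphic complete-deletion sites. The construction iterates: build the
ε-relaxed minimum spanning network (union of all MSTs at ε = 0, by
level-grouped Kruskal); for every connected triplet add its per-site
majority (median) vector when novel and strictly cheaper to connect the
triplet through than the triplet's own spanning tree; repeat to a fixed
point. Unsampled medians of degree ≤ 2 that do not lie on a shortest
connection between their neighbours are pruned. Sites with three observed
states use the same majority rule with ties resolved to the hub node's
state and are flagged on the graph (`multistate_sites`). ε defaults to 0.

## Relatedness and mating advice

Moment estimators (Queller–Goodnight symmetrized with ratio-of-sums
locus combination; Lynch/Li similarity against its exact unrelated
expectation; Lynch–Ritland with information weights, averaged over
reference directions; Ritland with `(k−1)` weights) follow their published
per-locus forms. The Wang-style estimator is a joint method-of-moments
fit: the dyad's similarity category (identical / one-shared-homozygote /
one-shared-heterozygotes / none) has exact probabilities under the three
non-inbred IBD modes, computed by enumeration per locus, and `(k̂₂, k̂₁)`
solve the weighted least-squares moment equations with `1/(2a₂−a₃)` locus
weights; published small-sample bias corrections are not reproduced.
Moment estimators are unbounded by design and routinely leave [0, 1] on
unrelated pairs.

The dyadic likelihood estimator treats the pair's per-locus genotype
probability as a mixture over IBD modes — `(k₂, k₁, k₀)` or, with
`allow_inbreeding`, the nine condensed Jacquard modes — with weights shared
across loci. The log-likelihood is concave in the weights, so EM converges
to the global maximum (tolerance 1e-8, five seeded restarts as a guard);
`r̂ = k₁/2 + k₂` is always in [0, 1]; the Jacquard form
`2Δ₁ + Δ₃ + Δ₅ + Δ₇ + Δ₈/2` (twice the kinship coefficient) reduces to
it on the non-inbred modes but can exceed 1 for inbred dyads. The
triadic (three-reference) likelihood estimator is out of scope; the
dyadic estimator is the likelihood-based advisor input.
Genotyping-error accommodation is fixed at zero (placeholder reserved).
Allele frequencies default to the full sample including the focal pair.

Relationship classification evaluates the four fixed pedigree categories
U = (1,0,0), HS = (½,½,0), FS = (¼,½,¼), PO = (0,1,0) and returns the
maximum-likelihood category, ties resolving to the less related
(conservative) one; loci excluding PO by Mendelian incompatibility force
its likelihood to zero.

The mating advisor enumerates all female × male crosses plus every pairing
involving an unknown-sex individual; the default listing double-counts
U–U pairs (once per U endpoint), reproducing the `F·M + U·(N−1)` screening
arithmetic, flags the duplicates, and offers `unique_pairs=True` for the
deduplicated count. Thresholds: `r̂ < 0.25` advisable, `0.25 ≤ r̂ ≤ 0.5`
marginal (closed interval — half-sib-level kinship), `r̂ > 0.5`
inadvisable. The consensus of two estimators takes the more severe
category; this severity-max rule is a design choice recorded in every
report header.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; the
pipeline derives one stream per stage from the master seed by hashing the
stage name, so results are stable under stage reordering. Permutation and
bootstrap p-values use the add-one rule throughout. The calibration
studies run at: 5,000 pairs per relationship category (20 loci × 10
equifrequent alleles); 500 equilibrium datasets of 25 individuals × 15
loci at θ = 5 under SMM with 1,000 conditional simulations per distinct
`(k, 2n)` for the bottleneck type-I check, and 60 crash datasets
(crash factor 0.05, 5 generations) for power; 20 replicates of the
3-deme × 25-individual structure-recovery check. These sizes were chosen
to bound Monte-Carlo error well below the effect sizes being verified.

## Known limitations

* `Heq` conditioning retains exact-`k` replicates by rejection; extremely
  atypical `(k, n)` combinations fall back to fewer retained replicates
  with a warning.
* The DAPC membership dialect and the Wang-style moment fit match their
  originals in expectation but not digit-for-digit.
* The median-joining ε > 0 relaxation is implemented but only ε = 0 is
  exercised by the tests.
* GenePop parsing covers the 2/3-digit diploid dialect only (no haploid
  blocks, no pop-name-after-POP extension).
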