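# Methods

This note documents the models implemented in sibtrace, the choices made
where the design was genuinely open, and what the synthetic-data validation
does and does not demonstrate.

## Pseudohaploid genotyping

`call_pseudohaploid` filters pileup observations by base quality (default
≥ 30), mapping quality (default ≥ 30) and distance from the read ends
(default: discard within 2 bases of either end, the standard guard for
UDG-half libraries whose damage is concentrated at terminal bases), then
draws exactly one surviving observation uniformly at random and calls the
individual homozygous for its allele. Bases matching neither panel allele
(including N) are recorded as missing — conservative, and consistent with
the downstream biallelic model. Trimming happens *before* the draw; the
draw RNG is keyed by (seed, individual, site index), so calls are
bit-reproducible and independent of pileup iteration order. An optional
transversions-only mask removes C/T and G/A sites entirely, eliminating
deamination artefacts at the cost of roughly two thirds of a typical
panel. Individuals with fewer than 15 000 non-missing autosomal calls are
flagged by `qc_min_snps` as too sparse for population-genetic analysis.

## Sex determination

Coverage per chromosome class is reads per targeted site; x-rate and
y-rate are X and Y coverage relative to autosomes (XX expectation (1, 0);
XY expectation (0.5, 0.5)). Each class's read total is treated as Poisson
and propagated to first order: se_rate = rate·sqrt(1/n_reads_class +
1/n_reads_aut). The classification bands are this package's own:
XX requires x_rate − 2·se_x > 0.75 and y_rate + 2·se_y < 0.1; XY requires
|x_rate − 0.5| < 2·se_x + 0.1 and y_rate − 2·se_y > 0.3; meeting one of a
karyotype's two conditions yields a "consistent-with-" call and anything
else is undetermined. The bands are deliberately conservative: on
simulated 0.5× cohorts they produce no cross-assignments, pushing
ambiguity into the undetermined class instead.

## f-statistics

f3(C; A, B) averages (ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n_C−1) over sites where all
three populations are observed and the target has at least two allele
copies; the subtraction corrects the finite-sample bias of ĉ appearing in
both factors. For targets represented only by pseudohaploid individuals
the heterozygosity is inestimable, so the correction is omitted with a
warning — the statistic is then biased upward (toward "not admixed"),
which is the conservative direction for an admixture test. f4 needs no
correction. Allele frequencies count one observed copy per pseudohaploid
call and two per diploid call.

Standard errors use a weighted delete-one-block jackknife (Busing's
formula, which reduces to the textbook delete-one form at equal weights)
over contiguous 5 cM genetic-map blocks, never spanning chromosomes; a
mapless panel falls back to 700 equal-count blocks. Block weights are SNP
counts. Calibration on simulated replicate panels shows the jackknife SE
within a few percent of the empirical SD of the estimator.

## qpWave and qpAdm

Both consume the matrix X_ij = f4(L_i, L_0; R_j, R_0) with the target as
the left basis, each cell computed on its own maximal non-missing site
set ("allsnps") by default, and a jackknife covariance of vec(X) built
from exact per-block leave-one-out replicates (blocks shared across
cells; covariance symmetrized and eigenvalue-floored at 1e−12 of the top
eigenvalue before inversion, since jackknife covariances are
near-singular for large outgroup sets).

The rank test minimizes (vec(X−X̃))ᵀQ⁺(vec(X−X̃)) over rank-r matrices X̃
by alternating generalized least squares on the factors of X̃ = ABᵀ, with
5 seed-controlled restarts and objective tolerance 1e−10; dof =
(|L|−1−r)(|R|−1−r), the standard Wishart count (documented behaviour, not
claimed bit-identical to any other implementation). qpAdm weights solve
min_w (wᵀX)Σ_w⁺(wᵀX)ᵀ subject to Σw = 1 by fixed-point iteration: at each
step the covariance Σ_w of the projected vector wᵀX is re-estimated from
the block replicates, and the linearized problem has the closed form
w ∝ (XΣ_w⁺Xᵀ)⁻¹1. Convergence tolerance 1e−8 on ‖Δw‖, maximum 100
iterations. Weight SEs refit the whole procedure on each delete-one-block
replicate. The model's p-value is the rank-(k−1) test of the same matrix,
so a one-source model reduces exactly to a cladality test.

The search protocol fits the full source set against an ordered list of
outgroup sets; while the fit is non-rejected (p ≥ 0.05) but assigns some
source a negative weight, the most negative source is dropped and the
model refit; exhaustion moves to the next outgroup set. Once a feasible
model exists, smaller subsets of its sources are tried (smallest first)
and the minimal feasible model is reported; every attempt lands in a
ledger table.

The identifiability caveat: mixture weights are only estimable when the
right populations are differentially related to the sources. The
synthetic validation therefore uses two source clades each containing
related right populations — with star-shaped drift the rank test
correctly reports rank 0 and the weights are undefined.

## Weighted-LD admixture dating

For every intra-chromosome site pair within 30 cM, the pairwise-complete
sample covariance of target genotypes is weighted by δ(x)δ(y), where δ is
the allele-frequency difference between the two reference populations,
and averaged in 0.05 cM bins. Pseudohaploid 0/2 calls enter the
covariance unchanged: random read sampling adds noise but leaves the
expectation proportional to admixture LD. The curve is fitted above a
minimum distance of 1 cM by weighted least squares to A·e^(−g·d) + c (d
in Morgans; weights are pair counts); the affine term absorbs population
substructure and finite-sample background. Cross-chromosome pairs are
excluded.

Standard errors come from a delete-one-unit jackknife of the entire
pipeline (curve re-aggregation plus refit), where the units are
contiguous 20 cM map blocks with pairs assigned by their left site. On
real-scale data with many chromosomes these units are effectively
chromosome-scale; on the 3-chromosome validation panels, chromosome-level
deletion would leave only three resamples and an unusably noisy SE, which
is why the unit is a map block rather than a whole chromosome.

Calendar conversion: t = μ_s + generation_time·g years BP with
generation_time = 29 y and σ_t = sqrt(σ_s² + (29·σ_g)²); a modern target
uses μ_s = 0 ± 0.

Known bias: the simulator performs true meioses, so its LD decays as
(1−c(d))^g with c(d) the recombination fraction (even crossover counts
reunite segments), while the fitted model uses the small-d approximation
e^(−g·d). Over a 1–30 cM window this depresses ĝ by roughly 3–5% at
g = 17 — the same approximation error the exponential-decay model has on
real data. Validation at g = 17 (400 haplotypes, 3 × 100 cM, 15 000
sites) recovers the truth within 2 jackknife SEs in 90% of replicates.

## PCA projection

The reference PCA centers genotypes by 2p̂ and scales by sqrt(p̂(1−p̂))
(panel frequencies), drops monomorphic sites, mean-imputes the few
tolerated panel gaps (individuals must be < 5% missing) and
eigendecomposes via SVD, giving orthonormal site eigenvectors. Ancient
samples are projected by ordinary least squares of their normalized
genotypes on the eigenvectors at observed sites only — missing sites are
excluded, not imputed, which is what least-squares projection means. An
optional shrinkage correction multiplies projected scores by per-PC
factors estimated from leave-one-out projection of panel individuals
(mean ratio of projected to fitted score, clipped to (0, 1]); it is an
approximation to the unpublished reference behaviour, off by default.

## Supervised ancestry and contamination power

The decomposition maximizes Σ_s [x log(Σ_k q_k f_ks) + (m−x) log(1 −
Σ_k q_k f_ks)] over the simplex, with cluster frequencies f clamped away
from 0/1 (default 1e−3) to keep the likelihood finite. The likelihood is
concave in q, so the default solver is a constrained quasi-Newton step
(SLSQP with analytic gradient); the classical EM update is retained
(`method="em"`) for its per-step monotonicity guarantee, which the test
suite asserts. Multi-start from fixed-seed Dirichlet draws guards the
rare flat directions of near-collinear clusters.

The power experiment injects contamination into pseudohaploid calls:
each call is independently replaced by 2·Bernoulli(f_contaminant) with
probability r. Detection declares contamination when the summed weight on
clusters outside the individual's true ancestry exceeds the mean + 3 SD
of clean replicates (the decision rule is this package's, parameterized
in config). On the scaled-down design (six clusters at drift 0.15, a
contaminant at drift 0.2, 20 000 sites, 50 replicates per 1% rate step)
the smallest detected rate is 3–5%, and a contaminant drawn from the
individual's own cluster is undetectable at any tested rate — the method
has power against distant contamination only.

## Radiocarbon calibration

Flat prior on a 1-year calendar grid spanning the curve;
posterior ∝ exp(−(r−μ(θ))²/(2(σ_r²+σ_curve(θ)²))) with linear
interpolation of the curve between rows. The 95.4% highest-density region
admits grid years in decreasing density order (ties toward older years)
and reports contiguous runs as (older, younger) calBP intervals;
calBCE = calBP − 1950. More than 0.1% posterior mass within 5 years of
the grid edge raises a range error rather than silently truncating.
Published-curve comparisons require the user to supply the IntCal table;
it is not redistributed with the package.

## Synthetic data: what it does and does not emulate

Allele frequencies follow the Balding–Nichols model on a drift tree:
each population is a Beta draw around its parent's frequency with
variance F·p(1−p), admixture targets mix two parents then drift again.
Sites are unlinked for frequency-based analyses; the haplotype simulator
adds linkage by explicit random-mating generations with Poisson(1/Morgan)
crossovers on a uniform map (3 × 100 cM × 5 000 sites by default — chosen
for laptop-scale runtimes), breeding in a pool of at least 1000
haplotypes so that within-pool coalescence does not distort the admixture
LD the pipeline is meant to measure. Reads get Poisson depth, uniform
sequencing error, and 5′-terminal C→T deamination decaying geometrically
into the read (G→A mirrored on the minus strand), with damage applied to
the templated base before error.

Passing tests on these data show the estimators are correct under their
own assumptions: unlinked drift, uniform maps, single-pulse admixture,
site-independent error, no reference bias, no real LD background, no
ascertainment. They do not demonstrate robustness to non-uniform
recombination maps, multi-wave admixture (where the fitted g is a
non-arithmetic average of pulse ages), reference-alignment bias, or the
ascertainment of real capture panels.

## Numerical conventions

Coordinates are 1-based; genetic positions are stored in Morgans and
displayed in cM; X is chromosome 23, Y is 24; genotype values count
copies of allele1 with 9 as missing, identically on disk and in memory.
EIGENSTRAT round-trips are byte-identical on files the package writes.
All stochastic procedures take explicit seeds; per-site RNG keys make the
caller insertion-order independent.
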