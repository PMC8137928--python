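# Methods

This note documents the models, conventions and numerical choices behind
`urbansweep`, in the order the pipeline runs them.

## Data model and conventions

Phased biallelic haplotypes live in a `HaplotypePanel`: a sites × (2·n)
matrix of {0,1} with allele 1 always the ALT allele. SNP positions are
1-based; every interval (window, gene, merged region) is 0-based half-open,
and a SNP at position p belongs to [start, end) iff p−1 ∈ [start, end).
Missing genotypes are rejected at load time rather than imputed: silently
imputed calls would enter the haplotype statistics as fabricated identity
tracts, which is worse than failing fast. Chromosomes are classified
autosome/Z through an explicit sidecar table, never guessed from names; the
Z chromosome matters only as a separate standardisation class.

## The paired-deme simulator

`simulate_panel` runs a discrete-generation Wright–Fisher model: a burn-in
ancestral deme, a split into `n_localities` rural demes exchanging migrants
at rate `m_rr` (island model), and an urban deme per locality founded by
`founder_size` diploids drawn from its rural neighbour, thereafter
exchanging migrants with it at `m_ur`. Each offspring draws two parents
with probability proportional to fitness; each gamete recombines with
Poisson(ρ·L) crossovers and mutates per site at μ.

Standing variation is initialised from a 1/f-shaped site-frequency spectrum
(frequencies log-uniform on [0.05, 0.95]) instead of a mutation-only
burn-in; the burn-in then only has to build linkage disequilibrium, which
keeps runs in seconds. Planted sweeps are new mutations: the sweep site is
held absent from standing variation and enters as (by default) a single
copy among the urban founder haplotypes, so all carriers share one origin —
planting copies on independent backgrounds would create a soft sweep with a
much weaker haplotype signature. `condition_on_sweep` resamples the run
until no sweep allele is lost. A polygenic trait (additive over listed
loci) can be placed under Gaussian stabilising selection with the optimum
displaced by `optimum_shift` in urban demes only.

Default parameters are desk-scale study conditions, chosen for testability
and qualitative realism rather than inference about any real population:
demes of N = 200 with a mild founding bottleneck (100 of 200 diploids),
because urban bird populations retain diversity comparable to their rural
neighbours — a catastrophic bottleneck would make the whole urban genome
look swept; 40 + 60 + 45 generations of burn-in/split/urban phase;
m_rr = 0.01, m_ur = 0.005; μ = 1e-7. Recombination is ρ = 8e-7 per bp — high
per base pair because the chromosomes are shrunk to 5–10 Mb: what matters
is that the hitchhiking footprint of an s = 0.5 sweep, roughly
s/(ρ·ln 4Ns) ≈ 90 kb, is far smaller than a chromosome, the standard
rescaling when genome size is reduced. Sampling draws 10–16 diploids per
deme, the paired-study design range. Z-linked inheritance is not modelled;
the "Z" chromosome is an ordinary chromosome carried by all individuals and
serves only to exercise the separate standardisation class.

`sample_panel_from_frequencies` is a second, linkage-free generator: each
haplotype allele is an independent Bernoulli draw at a specified
per-population frequency. It exists for association calibration and power
experiments, where a planted |ΔAF| must be exact and haplotype structure is
irrelevant; anything touching EHHS/iES/nSL, F_ST dynamics or IBD uses the
forward simulator.

What passing tests on these synthetic data do not show: robustness to
genotyping error, missingness and imputation artefacts, ascertainment bias
of a SNP chip, real recombination-map heterogeneity, or sex-linked
inheritance — all absent from the generator by design.

## Urbanisation score

Per-site means of the three cover proportions (buildings, vegetation,
paved) enter a PCA on their correlation matrix; PC1 is the score, with the
sign fixed so built surface loads positive (preference order buildings,
paved, then vegetation negative — the rule survives any one variable being
constant, in which case that variable is dropped). Correlation rather than
covariance PCA makes the orientation rule stable under rescaling of any
cover variable. Per-site means (not per-cell rows) are used because one
score per site is the quantity consumed downstream. Repeatability over
replicate digitisations is the two-way mixed-effects, absolute-agreement,
single-measure ICC, ICC(A,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E +
k(MS_C − MS_E)/n), computed from the ANOVA mean squares.

## Diversity and structure

Weir–Cockerham (1984) θ̂ is computed per SNP from the two-population a, b, c
variance components with no inbreeding correction; SNPs monomorphic across
both populations are undefined and excluded, and the pair mean averages
max(θ̂, 0) (the negative-clamping convention). The permutation test permutes
individuals between the two populations on a SNP set thinned to the first
SNP per 50 kb bin (bins anchored at position 1 — the anchor is a choice the
source convention leaves open) and uses the (b+1)/(n+1) p-value estimator so
p is never zero. LD pruning is plink-style VIF pruning: within 50-SNP
windows advancing by 5, remove the highest-VIF SNP (VIF = diagonal of the
inverse correlation matrix, ridge 1e-8) until all fall below 2. PCA uses
dosages centred at 2p̂ and scaled by √(p̂(1−p̂)), with each axis's sign fixed
by its largest-magnitude loading. The Mantel test permutes rows/columns of
the second matrix jointly (own implementation so the seed is explicit;
cross-checked against scikit-bio in the tests); geographic distance is
haversine on a 6371 km sphere. IBD uses raw F_ST, not F_ST/(1−F_ST) — the
linearisation choice is unstated in the convention followed and raw values
were chosen.

## Environment association

The latent-factor route replaces an MCMC latent-factor mixed model with a
deterministic equivalent: centre the dosage matrix, project out the
environmental gradient, take the top-K left singular vectors as factors,
regress each SNP on [gradient, factors], and calibrate z² by genomic
control (λ = median z²/0.4549, the χ²₁ median) before χ²₁ p-values and
Benjamini–Hochberg FDR (<1%). Being deterministic, there is no
median-over-runs step. K defaults to 4 in the pipeline with a config
override; the PVE elbow of the factor SVD is the recommended guide when
choosing K for new data. The habitat-randomisation threshold permutes the
per-population gradient values across populations (default 20 times) and
takes the 95th percentile of the pooled null |z|.

The covariance-aware route estimates Ω̂ as the covariance, across LD-pruned
SNPs, of population frequency vectors standardised by √(p̄(1−p̄)), floors its
eigenvalues at 1e-6 of the trace, whitens by the Cholesky factor, and fits
frequency ~ intercept + gradient by least squares in the whitened space.
Evidence is the closed-form Zellner g-prior Bayes factor with g = n_pops
(unit information), BF = (1+g)^{(n−2)/2} (1+g(1−R²))^{−(n−1)/2}, reported
as 10·log₁₀BF deciban; dB > 20 is the decisive threshold. The Bayes factor
is invariant to affine rescaling of the gradient and equivariant under
population relabelling. Core SNPs are the intersection of the two
significant sets; enrichment is the hypergeometric upper tail plus a
without-replacement resampling p-value. The companion chi-square statistic
sometimes quoted for such overlaps has an ambiguous construction and is not
reported.

## Haplotype statistics

EHH, EHHS (Tang-style normalisation: pairs identical over the interval and
at the core, scaled to 1 at the core), iES, nSL lengths and the two
cross-population scans are implemented from scratch; definitions are in the
module docstring. Numerical conventions: iES integrates the EHHS curve by
trapezoid over physical distance, truncating at the first point below 0.05,
at an inter-SNP gap above 200 kb, or at the chromosome edge (cutoff and gap
follow the common defaults of the reference implementations; they are
configurable). The whole-chromosome scan computes, per haplotype pair, the
mismatch positions once, and reads every core's curve off the pair's
shared-segment bounds — an O(pairs·sites) pass proven equal to integrating
the per-core curves in the tests. The scan statistic is computed as
ln iES_u − ln iES_r (difference of logs, so swapping the populations negates
it exactly); Rsb standardises by median/SD, XP-nSL by mean/SD, each within
chromosome class, with all scores set to 0 when a class has zero spread.
SNPs with minor-allele frequency below 0.05 in both populations are not
used as cores (configurable guard); SNPs whose iES or mean pairwise length
is undefined or zero in either population are dropped and counted. nSL
lengths are in SNP units per their definition; no frequency-bin
normalisation is applied to XP-nSL because the cross-population ratio
already cancels the frequency dependence.

## Windows, regions, recombination proxies

Window starts run 0, step, 2·step, … while start < chromosome length, with
ends truncated at the length (so with the default 200 kb/50 kb geometry a
500 kb chromosome has 10 windows, the last 50 kb wide; non-sliding tiling
is step = size). Windows with fewer than 10 SNPs (5 in the desk-scale
tests, where SNP density is lower) are ineligible — an added guard so
1-SNP windows cannot dominate the percentiles. The dual criterion flags a
window when its mean score and its outlier-SNP proportion both reach the
class-wise 95th percentile (type-7 linear interpolation, ≥ comparison);
when every eligible window is identical the percentile equals the common
value and flags are suppressed. ZF_ST windows use the single rule z > 4
with population-SD (denominator n) standardisation. Merging joins flagged
windows whose gap is ≤ 200 kb. LD r² is the squared Pearson correlation of
dosages for SNP pairs within the same 200 kb tile; intronic GC assigns each
intron to the tile containing its midpoint, ignoring Ns. ("200 non-sliding
windows" in the source convention is read as 200 kb non-sliding windows,
matching the GC sentence beside it.)

## Effect decomposition and sharing

Per candidate SNP, dosage is decomposed by the two-factor crossed model
habitat + locality + habitat:locality with type-II sums of squares (suited
to the unbalanced 10–16-per-site design); the printed four-term model
formula in the source is read as this standard three-term model. Partial
η² = SS_term/(SS_term + SS_residual); a habitat effect exceeding the
interaction marks a consistent urban–rural shift. The same ANOVA applies to
the first PC axes of the candidate-SNP matrix. Minor-allele concordance
counts urban populations whose local minor allele (ties at 0.5 resolved
toward ALT, deterministically) matches the minor allele of the pooled urban
frequencies; direction concordance counts localities where the same allele
strictly increased urban-ward.

The sharing null draws, per replicate and population, n genes with
replacement from the SNP-linked universe (n defaulting to the observed set
size), reduces to unique genes and counts genes in ≥ k sets, k = 2..P
(the ≥ k reading of "shared"; the table reports every k so exactly-k is
recoverable by differencing). The 95% interval is the 2.5–97.5 percentile
of the null draws. `draw_counts` exists because a set *generated* by n₀
with-replacement draws has fewer than n₀ unique members; calibration
studies must resample with the generating n₀, and the package's own
coverage test does. Term overrepresentation is the hypergeometric upper
tail with BH FDR < 0.05, consuming any two-column gene↔term table.

## Pipeline, seeds, determinism

`run_pipeline` executes the stages in dependency order from one validated
config (unknown keys are rejected before any stage runs), writes TSV/BED
outputs plus a JSON manifest of per-stage seeds, wall times and output
digests. One global seed is expanded per stage through
`SeedSequence([seed, stage_index])`, so a stage rerun is reproducible
independently of the others; identical config and seed give byte-identical
outputs. The bundled demo problem size (9 pairs, ~3,000 SNPs on three
chromosomes, 10–16 diploids per site) runs end to end in about a minute;
the acceptance script's replicate studies (20 sweep replicates, 30 power
replicates, 100 coverage replicates) complete in a few minutes. The
planted-sweep recovery experiments use one locality, 1,500 SNPs on a 5 Mb
chromosome, and call a sweep recovered when the chromosome-maximum score
lies within 100 kb of the planted site (one hitchhiking footprint; also the
slack `truth_recall` uses for region distance).

## Known limitations

The simulator's demography is schematic (no growth, no continuous space,
schematic migration); its SFS initialisation is not an equilibrium
mutation–drift spectrum; hemizygous Z inheritance is not modelled.
The latent-factor and Bayes-factor associations are deterministic analogues
of MCMC methods — same inferential targets, but numbers are not expected to
match any specific MCMC implementation run for run. Gene annotation beyond
interval overlap (GO databases, semantic reduction) is out of scope;
`overrepresentation` consumes whatever gene→term map the user supplies.
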