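# Methods

`landgea` implements the inference chain used in landscape-genomics surveys
of crop landraces: starting from a filtered SNP panel and per-sample climate
extracts, it quantifies population structure, partitions genotype variance
among structure, geography and climate, scans for genotype–environment
associations (GEA) with three complementary detectors, and converts the
significant loci into candidate genomic intervals and gene lists. A
synthetic landscape generator with known adaptive loci makes the whole
chain testable end to end.

## Synthetic landscape model

Sites are laid out on a jittered latitude × longitude grid (default 30
sites) and individuals (default 200) are assigned round-robin. Genetic
groups (default 4) are spatially contiguous 2-D clusters of sites, so each
group spans part of every climate gradient — in a regional landrace panel
climate varies within gene pools, and a generator that nested groups inside
latitude strata would make structure and climate perfectly collinear,
leaving no GEA method anything to detect.

Neutral loci follow the Balding–Nichols model: ancestral frequency
p₀ ~ U(0.1, 0.9), group frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with
F = `fst_groups` (default 0.2). Adaptive loci (default 2% of 5,000) instead
take site-level frequencies on a logistic cline,
p(site) = logistic(logit(p₀) + β·z), where z is the standardized driver
climate variable at the site and β = `cline_effect` (default 1.5 per SD).

Genotypes are drawn with an inbreeding coefficient (default 0.9): a
fraction F_IS of lineages carries two identical-by-descent gametes, the
rest are Hardy–Weinberg draws. This emulates a predominantly selfing crop;
it is also what makes heterozygosity-based QC filters (het ≤ 0.2)
meaningful — under full outcrossing they would discard most intermediate-
frequency loci. Missing calls are MCAR (default 2%). Loci sit at sorted
uniform positions on 7 chromosomes of 0.5 Mb each (desk scale; lengths are
configurable).

Climate variables: the first variable is the cline driver — a unit-SD
latitudinal gradient plus site-level "microclimate" noise of SD 0.7. The
noise share matters: it decorrelates the driver from the broad-scale
structure axes so that the latent-factor and PC corrections do not absorb
the entire signal, which is the regime the recovery benchmarks assume.
Later variables come in pairs that share a noise base plus a 0.4-weight
gradient; the pair's own-noise scale is set so its expected correlation
clears the configured collinearity target (for exercising forward
selection's redundancy handling). Variables are then shifted/scaled to
plausible climate units.

What the generator does **not** emulate: linkage disequilibrium between
loci (loci are independent given structure; a separate Markov
haplotype-copying fixture generates distance-decaying LD for the LD-decay
estimator), admixture between groups, isolation-by-distance within groups,
genotyping error beyond MCAR missingness, and any realistic site-frequency
spectrum (p₀ is uniform, so genome-wide Tajima's D is strongly positive
even before MAF filtering). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not field
performance on real GBS data.

## QC, filtering, pruning

Two filter presets mirror the two analysis tracks: the *structure* set
(missing ≤ 0.2, het ≤ 0.2, MAF ≥ 0.1, inclusive keeps) feeds PCA,
clustering, Fst, AMOVA and forward selection after PLINK-style LD pruning
(`indep-pairwise` semantics: 150-SNP windows advancing by 5, removing the
lower-MAF member of any pair with r² > 0.5, sweeping to a fixed point);
the *outlier* set (MAF > 0.05, het < 0.2, missing < 0.2, strict keeps)
feeds the association scans. The boundary conventions differ deliberately:
each set keeps exactly what its usual description phrases as kept versus
removed. r² uses pairwise-complete observations; simple imputation
replaces missing calls by the locus mode, ties broken toward the dosage
nearest the locus mean, then toward the smaller dosage.

## Structure

Genotype PCA centers each locus at 2p̂ and scales by √(p̂(1−p̂))
(Patterson convention; unit scaling available). Cluster number is chosen by
k-means (20 restarts) over k = 1..k_max with BIC(k) = n·ln(WSS/n) + k·ln n.
The default selection is an **elbow rule** — the smallest k whose BIC
improvement toward k+1 drops below 25% of the largest single-step
improvement. The raw BIC argmin is available but not default: for
Gaussian-ish clustered scores the WSS drop from splitting a true cluster
always exceeds the ln(n) penalty, so the argmin runs to k_max; the elbow
rule reproduces the intended behavior (k=2 on two well-separated blobs,
k=4 on the 4-group benchmark panel).

Fst is the Weir–Cockerham (1984) estimator with multi-locus ratio-of-sums
aggregation. AMOVA is two-level on squared Euclidean dosage distances with
variance components from the mean squares and an unbalanced-design n₀;
Φ_ST significance comes from label permutations.

## Forward selection of climate variables

Stepwise RDA of the pruned genotype matrix on climate: at each step the
candidate with the best adjusted-R² (Ezekiel) gain is tested by a
vegan-style marginal pseudo-F with the residualized candidate permuted
across samples; it enters only if p ≤ α (default 0.05, 999 permutations)
and the running adjusted R² stays below the all-variables model's.
Geography is never offered. Defaults for α and permutation count are
package choices, configurable.

## pRDA variance partitioning and outlier scan

`fit_rda` residualizes response and predictors on the condition block, fits
by least squares, and takes the SVD of the fitted matrix; R² is always
fitted SS over the **unconditioned** centered genotype SS, so the four
partition models (full; structure|climate+geography; geography|…;
climate|…) yield comparable fractions with exact identities
(pure parts + confounded = full; full + unexplained = 1). Redundant blocks
are tolerated by projecting onto the joint column space with a tolerance
anchored to the pre-conditioning predictor scale.

The outlier scan takes per-SNP loadings on the first K = 4 axes of the
climate-conditioned-on-structure model, fitted to **per-locus standardized**
dosages (without standardization, loading magnitude tracks allele
frequency and the Mahalanobis tail is overdispersed — observed false
discovery roughly doubles). D² is the Mahalanobis distance to the
across-SNP center using, by default, the minimum-covariance-determinant
estimator with a fixed internal seed: the planted outliers being hunted
otherwise inflate a classical covariance and mask one another (classical
moments are available via `robust=False`, at roughly half the recall on
the benchmark panel). The genomic inflation factor λ = median(D²)/χ²-median
rescales D² before χ² tail p-values; df = K by default, with a df = 2 mode
provided because both conventions circulate for this statistic. Storey
q-values and a Bonferroni flag at α = 0.1 complete the scan.

## LFMM and EnvGWAS

LFMM default mode fixes the latent factors to the leading genotype PCs and
tests each locus by OLS on [env, factors] — deterministic, so the
five-replicate consensus (intersection of q < FDR across runs) degenerates
to a single run and is flagged as such. An alternating-minimization mode
(ridge effect updates, rank-K SVD factor updates) is provided for the
non-deterministic variant. z² statistics are GIF-calibrated
(λ = median(z²)/0.4549) and converted through χ²₁. For the 4-group
benchmark panels the tests use K = 3 = (groups − 1), the structure
dimension read off the PCA scree; the pipeline default is K = 2.

EnvGWAS treats each climate variable as the trait: per-SNP OLS of env on
dosage plus 2–4 genotype PCs, the PC count chosen per variable by λ closest
to 1 (an automated stand-in for QQ-plot inspection). It deliberately
replaces iterative multi-locus GWAS machinery (no kinship random effect,
no pseudo-QTNs); the downstream products — significant-locus lists under
Bonferroni/FDR thresholds and per-SNP partial R² — depend only on per-SNP
tests. The missing kinship term is a known limitation.

Calibration caveat: under a *structured* null (β = 0 but groups present),
per-locus group-frequency deviations are only approximately captured by K
factors; the GIF fixes the bulk of the statistic distribution but a slight
tail excess remains (measured family-wise hit rate ~16% rather than 5%
for LFMM q < 0.05 at the default design). Under exchangeable nulls
(environment permuted against the genotypes) both scans sit at the nominal
~5%. The χ²₁ conversion also assumes n large enough that t ≈ z; below
n ≈ 100 the tails are visibly anti-conservative.

## Windows, LD decay, candidate intervals

Sliding windows (20 kb / 10 kb) report segregating-site counts, π, θ_W and
Tajima's D with per-**segregating-site** normalization: window π is the
mean unbiased per-site heterozygosity over segregating sites and
θ_W = 1/a₁ at the window-average chromosome count. This is the only
normalization under which SNP-panel (not full-sequence) data produce θ in
the 0.1–0.2 range and π around 0.3; a per-bp mode exists as an option.
Tajima constants use n = rounded window-average non-missing chromosome
count. MAF filtering removes rare variants and therefore shifts window D
positive — a direction the suite checks explicitly.

LD decay bins pairwise-complete r² within 300 kb into 1 kb bins (5 kb in
the tests) and fits the Hill–Weir drift-recombination expectation by
nonlinear least squares. The decay distance is where the fitted curve
falls halfway between its value near zero and its asymptote (≈ 1/n);
a fixed-cutoff mode is available. Candidate intervals flank each
significant SNP by the chromosome-specific decay distance, clipped to the
chromosome; gene mapping lists overlapping genes plus the nearest outside
gene, with upstream/downstream resolved on the gene's strand. A SNP is
pleiotropic iff associated with ≥ 2 distinct climate variables in the
union across methods.

## Problem sizes and numerical choices

The benchmark panels are 200 × 5,000 (standard and null) with 100-replicate
loops at 200 × 5,000 for forward selection and the permuted-env EnvGWAS
null, and reduced permutation counts (99–199) in tests; the acceptance
script uses 20 forward-selection replicates. The χ²₁ median 0.4549 is
hard-coded to 4 decimals. Zero-variance loci are dropped with warnings;
all-missing loci are errors naming the locus. Seeds propagate explicitly:
identical configuration and seed give byte-identical pipeline outputs
(checksummed in the manifest).
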