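# Methods

`cryocomm` implements the statistical workflow used to characterise
seasonal dynamics of glacier-surface microbial communities: two marker-gene
communities (16S prokaryote, 18S eukaryote) sampled over three periods,
scaled to absolute abundance with qPCR, and interrogated for diversity
change, co-occurrence structure, community stability, phylogenetic assembly
mechanisms, and a link between a focal phylum (Cyanobacteria by default)
and nitrogen-metabolism functional potential.

## Absolute abundance integration

Relative fractions are computed per marker table and scaled by that
marker's qPCR measurement: prokaryote fractions by 16S gene copies/mL and
eukaryote fractions by 18S copies/mL, then row-concatenated.  Per sample
the merged table's total equals `copies_16S + copies_18S` exactly (to
1e-9 relative), which the tests assert.  This per-marker scheme is the only
arithmetic consistent with copies-per-mL measured per marker gene; copy-
number variation per genome is not corrected.  Organelle sequences are
removed beforehand by case-insensitive substring match of
chloroplast/mitochondria at any lineage rank.

Whether downstream diversity and ordination run on the merged 16S+18S
absolute table or on the prokaryote-only table is a config switch
(`merged_table`, default merged); the merged table is the more complete
description of the community, but per-marker analysis avoids mixing the two
amplicons' biases.

## SparCC correlation inference

The co-occurrence machinery is a from-scratch implementation of the SparCC
estimator for compositional counts.  For log-ratio variances
`t_ij = var(log x_i / x_j)` the identity
`t_ij = w_i + w_j − 2 ρ_ij √(w_i w_j)` holds for basis variances `w`.
Under the sparsity assumption the `w` solve the linear system
`[(D−2)I + J] w = t·1` (J the all-ones matrix); this system is exactly the
normal-equation form of least squares over all pair equations
`t_ij ≈ w_i + w_j`, which the test suite verifies against `numpy.lstsq` at
D=4 to 1e-8.  Strongly correlated pairs are then iteratively excluded
(default 10 rounds, threshold 0.1 on |ρ|): each excluded pair is removed
from the row sums and the coefficient matrix; a taxon excluded from D−3
pairs leaves the exclusion procedure.  Count uncertainty is propagated by
drawing per-sample fractions from a Dirichlet(counts+1) posterior and
taking the element-wise median over 50 iterations; `deterministic=True`
uses (counts+1) fractions in a single pass for exact unit arithmetic.
Estimates are noisy below ~20 samples; the function warns and proceeds.

Significance: each bootstrap resamples every taxon's counts independently
across samples, which preserves marginals while destroying inter-taxon
association, and recomputes ρ; two-sided p-values use the (1+m)/(1+M)
estimator so p ≥ 1/(1+n_boot).  Networks keep edges with |ρ| > 0.6 and
p ≤ 0.05 and drop isolated nodes.  The magnitude reading of the r filter is
deliberate: the cohesion and focal-association analyses need negative
edges.  Networks are built per period from that period's samples only.

## Network ecology

Topology indices (nodes, edges, mean degree, density, clustering
coefficient, modularity; path length and diameter on the largest connected
component with the coverage fraction reported) use networkx on the
unweighted simple graph.  Modules come from greedy modularity maximisation
(CNM), chosen because it is deterministic and standard.  Zi/Pi follow the
usual definitions — within-module degree z-score (z=0 when the module's
degree sd is 0) and `1 − Σ_m (k_im/k_i)²` — with the keystone rule applied
at inclusive boundaries: module hubs Zi ≥ 2.5 & Pi < 0.62, connectors
Zi < 2.5 & Pi ≥ 0.62, network hubs Zi ≥ 2.5 & Pi ≥ 0.62.

Cohesion: for each taxon, r̄⁺ is the mean of its qualifying positive
correlations (0 if none) and r̄⁻ the analogue over negatives; per sample
C⁺ = Σ p_i r̄⁺_i and C⁻ = Σ p_i r̄⁻_i over relative abundances p.  The
qualifying set defaults to the retained network edges; `qualify="all"` uses
the full correlation matrix.  Cohesion is linear in relative abundance, and
the removal analysis exploits the exact endpoints: fraction 0 reproduces
the unperturbed value and fraction 1 equals recomputation with the phylum
absent (both asserted exactly).  Removal trajectories delete uniform random
subsets of a phylum at fractions 0–1 (default 11 steps × 100 replicates),
renormalise, recompute cohesion, and summarise with the OLS slope of mean
cohesion on removal fraction — a more negative slope means the phylum
contributes more connectivity.

Focal association: a non-focal node connected to the focal set is
classified by the sign of the summed edge weights to focal nodes (an exact
zero sum — probability zero with continuous weights — classifies positive);
unconnected taxa are "none".  Abundance-weighted class fractions use
absolute abundances and, with the focal share, partition the community.

## Phylogenetic metrics

All metrics derive from a rooted tree with branch lengths (ultrametricity
not assumed).  Faith's PD spans the present tips and, by default, the path
to the root (`include_root=False` subtracts the MRCA-to-root path).  The
Helmus family uses the phylogenetic correlation matrix C (shared root-path
length scaled to unit diagonal, computed from tip depths and patristic
distances): PSV = (n·tr C − ΣC)/(n(n−1)), PSR = n·PSV, PSC = 1 − mean
largest off-diagonal C entry, and PSE the abundance-weighted PSV with the
N²(1−1/n) denominator — the form picante uses, against which all these
metrics were verified on a fixture tree (values frozen in the tests).

NRI/NTI are negated z-scores of MPD/MNTD against a tip-shuffle null
(equivalent to drawing random same-size subsets of the pool), so positive
values mean phylogenetic clustering.  betaNTI standardises the
(abundance-weighted by default) between-community mean nearest-taxon
distance against the null.  One numerical subtlety: a single joint
relabelling of the pool leaves every *shared* taxon at distance zero from
itself, which pins the null at zero for similar communities and makes the
score degenerate; the null therefore relabels the two communities
independently.  |betaNTI| > 2 is read, conventionally, as deterministic
assembly.

## Diversity, ordination, turnover

Shannon (natural log) and Gini-Simpson per sample; Welch t-tests between
periods with Benjamini-Hochberg correction.  Bray-Curtis on abundances and
Sørensen (Dice) on presence/absence via scipy's pdist.  PCA runs on
Hellinger-transformed profiles by default (raw and clr selectable), with
axis signs fixed so the largest-magnitude loading is positive.  PERMANOVA
is Anderson's pseudo-F computed directly from the distance matrix with
label permutations (implemented in-package for seed control; the F
statistic is asserted equal to scikit-bio's).  Procrustes uses the
symmetric superimposition — both configurations centred and scaled to unit
sum of squares — so M² = 1 − (Σ singular values)² lies in [0,1], with a
PROTEST-style row-permutation test; M² agrees with vegan's symmetric `ss`
and scipy's disparity.  All permutation p-values use (1+m)/(1+M).

Turnover pools each period's samples to presence sets and reports, per
phylum, (gained+lost)/(gained+lost+shared).  This is the Jaccard distance
of the pooled sets (it equals 2d/(1+d) for Sørensen dissimilarity d), an
identity the tests assert.  The three-period Venn partition counts the
seven exclusive regions, which sum to the union size.

## Nitrogen multifunctionality

Each enzyme's abundances are z-scored across samples (sample sd, n−1);
the per-sample index is the mean z-score, hence centred at zero.
Zero-variance enzymes are dropped with a warning and never affect the
remaining scores.  The focal phylum is removed from the community table
*before* function prediction so the index cannot trivially track focal
abundance.  The association is an OLS of index on focal absolute abundance
(slope, R², two-sided p).  The shipped 39-identifier enzyme panel is a
configurable placeholder of representative nitrogen-cycle enzymes, not an
authoritative pathway export; any enzyme × sample table can be supplied.

## Synthetic-data generator

The generator provides planted ground truth for every stage.  Defaults
mirror the emulated study design: 3 periods × 10 samples, ~5×10⁴
reads/sample, 60 prokaryote + 30 eukaryote taxa, a cyanobacterial focal
phylum whose latent abundance multiplier rises (1, 8, 25) across periods
while total 16S copies rise (1, 4, 10) around a 2×10⁸ copies/mL baseline
(lognormal noise, σ=0.25) — a bloom in both share and total.

Per sample, latent log-abundances are multivariate normal with unit-
diagonal covariance embedding the planted pairwise basis correlations (a
Gaussian copula; non-positive-definite specifications are rejected with
advice to shrink).  Counts are a multinomial draw of the softmax
composition at Poisson-distributed depth — deliberately the compositional
regime SparCC targets.  A keystone phylum receives dense positive
intra-block correlations (default ρ=0.75 among 8–10 taxa).  Optional
environmental filtering evolves a Brownian trait on the tree (standardised
across tips) and subtracts (trait − optimum)²/(2σ_env²) from the latent
mean, with period-specific optima (−1.5, 0, 1.5 by default, spanning the
trait range).  Filtering toward *extreme* optima produces phylogenetic
clustering at the nearest-taxon scale; a central optimum selects
convergent taxa from many clades and shows little NTI signal — the tests
therefore exercise tail optima.  Trees come from a pure-birth (Yule)
process with exponential waiting times; all randomness flows from one seed
through numpy `SeedSequence` spawning (one child stream per component), so
a fixed config is byte-identical across runs.

The function table is `α_e + β·z(focal) + N(0, σ)` per enzyme, shifted
non-negative; `beta_for_target_r2` inverts the population relationship
R² = β²/(β² + σ²/E) to plant a chosen effect size.

What the generator does *not* emulate: sequence-level error, taxonomy
misassignment, thousands of rare ZOTUs (taxon counts are desk-scale, so
presence/absence structure only appears when environmental filtering or
low depth makes communities sparse), copy-number variation, or any spatial
structure.  Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative model, not performance on real
amplicon data.

## Problem sizes and numerical choices

The test suite and the reproduction script run the workflow at reduced
resampling counts (bootstraps/permutations/null draws of 99–499 instead of
the 999 defaults) and desk-scale communities (40–90 taxa, 30–200 samples);
the pipeline stamps a reduced-precision banner into any report produced
with sub-default counts.  Basis variances from the SparCC solve are clipped
below at 1e-12 and ρ at ±1; zero-length branches are allowed (distance 0);
degenerate cases (all-equal samples, zero null sd, all-zero samples,
fewer than 2 taxa for PSV) raise or flag NaN rather than silently
continuing.  Keystone-recovery rates reported from the three-period study
run use only 10 samples per period per network and are accordingly noisy;
the dedicated recovery experiment (60 samples, single period) is the
calibrated check.
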