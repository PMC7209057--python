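# Methods

This note documents the statistical machinery, the choices made where
the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Data model

The pipeline operates on three validated containers: a taxa × samples
matrix of non-negative integer counts (`CommunityMatrix`, canonical
orientation taxa-on-rows, optional rank-labelled taxonomy with
`Unassigned` as the literal label for lineages that stop above the
requested rank), a rooted branch-length phylogeny over the taxon ids
(`PhyloTree`, a scikit-bio `TreeNode` behind a thin surface), and a
per-sample covariate table (`EnvTable`: area label, %TOC, CPE, %Mud in
[0, 100], no missing values). `align_inputs` intersects the three on
taxa and samples, logs every dropped id, and is idempotent. Counts are
integers by contract — the pipeline consumes rarefied read counts, and
fractional cells are treated as corrupt input rather than silently
rounded.

Rarefaction is a single multivariate-hypergeometric draw per sample
(sampling reads without replacement), not an average over draws: the
analysis consumes one rarefied matrix, and the seed is recorded in the
run manifest so the draw is reproducible. Rows left empty by
rarefaction are dropped with a log entry; a taxon observed nowhere
carries no co-occurrence or phylogenetic information.

## Co-occurrence statistics

For binary matrix rows i, j with row sums R_i, R_j sharing S sites,
C_ij = (R_i − S)(R_j − S); the C-score is the mean over all unordered
pairs and a checkerboard pair is a pair with S = 0 in which both taxa
occur. The null is sim2: within each row, the ones are re-placed
uniformly at random among the columns (occurrence frequencies fixed,
site richness free). Implementation detail: the ensemble is generated
by ranking i.i.d. uniforms per row, which yields an exactly uniform
arrangement and vectorizes over replicates.

Significance is reported three ways and all three are kept in the
output: ses = (obs − mean)/sd of the null sample; tie-inclusive
empirical tails p = (#{null ≥ obs} + 1)/(reps + 1) (and mirrored), the
+1 correction avoiding p = 0; and one-sample t-tests of the null sample
against the observed constant in each tail. The t-test view and the
empirical view answer slightly different questions for skewed nulls,
so neither is discarded. A null with zero variance is flagged
degenerate and ses is reported as 0 for the co-occurrence statistics.

Scales: the full unpooled matrix; replicates pooled by area with
union-of-presences (logical OR); and each area's replicates alone,
skipped with a warning below two columns. Taxa absent at a scale are
dropped at that scale only.

## Phylogenetic structure

PD is the total branch length connecting a taxon set to the root (the
root path is included, so singleton samples have a defined PD); MPD the
mean pairwise patristic distance; MNTD the mean distance to the
nearest co-occurring taxon. MPD/MNTD are undefined below two taxa and
reported missing. PD and UniFrac are computed from a branch × tip
incidence decomposition of the rooted tree, which turns both into
boolean matrix products and makes 999-replicate ensembles cheap.
Midpoint rooting delegates to scikit-bio and is verified in the test
suite against a brute-force all-pairs diameter search (the two deepest
tips must sit at diameter/2 ± 1e-9); two-tip trees are rooted by hand
because the library call degenerates there.

The seven null models follow the community-phylogenetics standard
(picante's vocabulary): label permutation on the distance matrix/tree
(`taxa.labels`); per-sample redraws of the observed richness from the
matrix taxon set (`richness`), the occupied set (`sample.pool`) or all
tree tips (`phylogeny.pool`); per-taxon redraws of the observed
occurrence count across samples (`frequency`); and fixed-fixed
checkerboard-swap chains (`independentswap`, `trialswap`).

Two facts about the swap chains that the test suite enforces rather
than assumes:

* **Parity.** A chain whose thinning counts successful swaps is
  periodic on instances where every swap flips a parity invariant
  (complements of permutation matrices are the smallest example); a
  fixed even stride would then sample a single parity class. Each
  thinning interval therefore adds a random extra 0/1 success.
* **Stationary law.** The trial-counted walk (one attempted 2×2 draw
  per step; failures are self-loops) is symmetric and uniform over the
  fixed-margin set. The success-counted walk is its jump chain, whose
  stationary weight is proportional to the number of swappable
  checkerboard submatrices of the state — it is *not* uniform, which
  is the classic trial-swap critique of the independent swap, and it
  is the behaviour of the standard implementations this module stays
  compatible with. Both laws are verified against exhaustive
  enumeration of a 4×4 fixed-margin set (90 matrices, two degree
  classes) by chi-square goodness of fit.

Defaults for the chains: burn-in 10 000 attempted swaps, thinning
10 × (number of ones) between saved matrices; both are parameters, and
scaled-down values are used in the large simulation studies (noted
below).

ses is (obs − mean)/sd over the null ensemble per sample × metric ×
model, with tie-inclusive empirical tails reported alongside; a
zero-variance null yields a missing ses with a degenerate flag. Per
area, the mean-ses-equals-zero test is a two-tailed one-sample t-test
when n ≥ 3 and the Shapiro–Wilk gate accepts normality at 0.05, and
the Wilcoxon signed-rank test otherwise. With n = 2 the Wilcoxon
two-sided p cannot fall below 0.5; the output carries that flag
explicitly instead of silently reporting an unreachable test.

Unweighted UniFrac between two samples is (branch length leading to
exactly one of the two communities)/(branch length leading to at least
one), in [0, 1], NaN against empty samples. PCoA double-centres −½D²,
takes the symmetric eigendecomposition, reports the full spectrum with
the share of the positive mass explained, and suppresses axes with
negative eigenvalues (no Cailliez/Lingoes correction — the plain
ordination is what the analysis calls for).

## Environment → diversity regression

The response (per-sample Faith's PD) is screened with a 3-sd outlier
rule, then fitted by OLS starting from
`PD ~ TOC + CPE + Mud_sqrt + all 2-way + the 3-way interaction`, where
`Mud_sqrt = sqrt(%Mud)`. At each step the non-protected term with the
largest p ≥ α (default 0.05) is removed and the model refitted;
marginality is respected (a term is protected while a retained
higher-order interaction contains it) because non-hierarchical models
are incoherent for this use. When n is too small for the full
factorial, the highest-order terms are shed first and logged with
p = NaN. An empty final model is a first-class outcome ("no
significant model"). Screening reports the Levene test of each
covariate across areas, the Pearson matrix, and VIFs from auxiliary
regressions (flagged at ≥ 10).

The outlier rule is implemented leave-one-out: a point's deviation is
judged against the mean and sd of the *other* points. The naive form
|x − mean| > 3 sd can never fire on small samples — the largest
attainable standardized deviation is (n − 1)/√n, below 3 for n ≤ 10 —
because a gross outlier inflates the sd it is compared against. The
LOO form preserves the rule's intent, converges to the naive rule for
large n, and its false-removal rate on clean normal data is the
t_{n−2} tail probability the test suite checks. The uncentred variant
(judging |x| itself) is available behind a flag.

## The synthetic benchmark

The generator emulates the statistical shape of a replicated abyssal
survey: six areas with (5, 4, 2, 4, 5, 3) replicate cores; a 200-tip
pure-birth (Yule, rate 1.0) ultrametric phylogeny standing in for the
regional ASV pool; a Brownian trait (rate 1.0) supplying the
phylogenetically conserved axis that filtering acts on; TOC and CPE
rising along an area productivity gradient with an independent
between-area CPE component (relative sd 0.30) so their correlation is
moderate rather than collinear (VIF ≈ 4, matching the screening
regime the regression assumes); Mud an independent percentage. Counts
put a lognormal (σ = 1.5) regional abundance on every taxon and draw
each sample multinomially at a Poisson depth (mean 20 000 reads), with
every member guaranteed one read so membership is crisp.

Assembly scenarios: **neutral** draws each sample's 25 taxa uniformly
from the whole pool — deliberately with *no* endemic overlay, since a
hard per-area pool restriction is itself a non-neutral mechanism and
induces shared-pool correlation that invalidates run-level tests.
**filtering** weights inclusion by exp(−(trait − optimum)²/2σ²) with
σ = 0.5 and area optima placed at trait quantiles 0.15–0.85 along the
gradient. **limiting_similarity** accepts taxa sequentially only
beyond a patristic-distance threshold (default: the 25% quantile of
pool distances). **habitat_blocks** confines taxa to one of two
area-blocks, making every cross-block pair a checkerboard by
construction. The structured scenarios add the rarity overlay: 65% of
the pool is endemic to a single home area, which reproduces the
single-area-ASV dominance such surveys report. Truth labels record
every construction detail.

What passing the benchmark shows — and does not. The generator
produces exchangeable, well-specified data: real metabarcoding tables
carry copy-number variation, chimeras, taxonomic misassignment and
spatial autocorrelation that no scenario here emulates, so the
recovery rates below speak to the correctness of the statistics, not
to field performance. Pool size (200) and depths are desk-scale
stand-ins for surveys with thousands of ASVs and tens of thousands of
reads; all simulation sizes in the test suite (e.g. 1000
self-consistency datasets at 20 taxa × 10 samples with 199-replicate
ensembles and swap thinning 2 × ones) are the package's own choices of
problem size for the properties being checked.

Verified properties include: exact agreement of C-score/CP, PD, MPD,
MNTD and UniFrac with brute-force oracles; conservation laws of every
null model on every draw; the two stationary laws above; mean ses
within ±0.1 and empirical type-I error within 0.05 ± 0.02 for data
generated by each null model; area-level "clustered" verdicts in ≥ 80%
of filtering runs with verdict-level false positives at the nominal
rate under neutrality; positive C-score ses in ≥ 90% of habitat-block
runs; and recovery of a planted TOC slope within ±3 s.e. Backward
elimination cannot be expected to return the exact term set {TOC} much
more often than (1 − α)⁶ ≈ 74% of runs — each spurious candidate
survives with roughly probability α — so exact-set recovery is
monitored as a majority property while slope recovery carries the
strict bound.

## Reproducibility

Every stochastic stage takes a seed; the pipeline splits one run-level
seed into named per-stage seeds (fixed spawn order: synth, rarefy,
cooccur, phylostructure) recorded in the run manifest together with
package versions and input digests. Stage outputs are cached on a hash
chain of parameters and upstream state, so re-running a config
recomputes only what changed. The swap-chain kernel uses numba when
importable (a pure-python fallback gives the same contracts; the
numerical streams differ between the two, so cross-machine bit
reproducibility assumes the same backend).

## Known limitations

Abundance-weighted MPD/MNTD and weighted/generalized UniFrac are out
of scope, as are tree inference and sequence-level processing — the
tree is an input. The regression offers no mixed-effects or spatial
terms; replicates are treated as exchangeable within areas. The
limiting-similarity scenario is generated but its detection (ses > 0
for MPD under strong competition) is weaker than the filtering signal
at the default bandwidth and is not part of the acceptance battery.
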