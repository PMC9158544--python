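# Methods

This note documents the models, algorithms, parameter choices and known
limitations of symbionet. Notation: the observed network is a count matrix
`a_ij` with plants in rows (I species), fungal OTUs in columns (J species),
grand total `F = Σ a_ij`, realized links `L = #{a_ij > 0}`, row totals
`r_i`, column totals `c_j`.

## Data model

Interaction counts are built from sample-level reads: each root sample is
rarefied to a fixed depth (default 3,000 reads) by multivariate
hypergeometric subsampling — draws without replacement, so a rarefied count
never exceeds the original and expectations are `depth · count/total`.
Samples below depth are excluded with a log notice; the alternative
(keeping them unrarefied) would re-introduce the sampling-effort bias that
rarefaction removes. Cell values are per-host means of rarefied counts,
rounded half-up: with round-half-even, a species observed once in one of
two samples (mean 0.5) would vanish from the network, which we consider
the wrong default for presence-sensitive metrics like connectance.

All-zero rows/columns are dropped with a warning: a species with no
interactions is not part of the network under analysis, and several metrics
(dependences, strength) are undefined for it. Labels sort lexicographically
everywhere so identical inputs give identical objects.

## Structural metrics

- **Connectance** `C = L/(I·J)`.
- **Evenness** `H = −Σ_{a_ij>0} p_ij log₂ p_ij / log₂ F`, `p_ij = a_ij/F`.
  The normalising constant is ambiguous in parts of the literature between
  the grand total F and the link count L; both are exposed
  (`denominator="grand_total"` default, `"links"` optional) and outputs are
  labeled. Zero cells contribute nothing.
- **Asymmetry**: for a realized pair, the plant's dependence is
  `s_ij = a_ij/r_i` and the fungus's is `s_ji = a_ij/c_j`;
  `d_ij = (s_ij − s_ji)/max(s_ij, s_ji)` and a species' asymmetry is the
  mean of `|d|` over its partners, so values lie in [0, 1]. The absolute
  value is a deliberate choice: it makes the guild mean a magnitude of
  imbalance (0 = every pairwise dependence mutually balanced) rather than a
  signed net direction.
- **Specialization H2′**: the two-dimensional Shannon entropy
  `H2 = −Σ p_ij ln p_ij` standardized between the entropy extremes
  attainable under the observed margins. `H2max` is the entropy of the
  independence table `r_i c_j/F` — the fixed point of iterative
  proportional fitting, and the analytic maximum (it equals the sum of the
  two marginal entropies). `H2min` comes from greedy packing: repeatedly
  allocate `min(largest remaining row margin, largest remaining column
  margin)` to that pair. The greedy minimum is a heuristic; tests compare
  it against exhaustive enumeration of all integer tables on small margins
  and require agreement of H2′ within 0.02. Results are clamped to [0, 1].
- **WNODF** (0–100): rows and columns are ordered by decreasing fill
  (number of links) with decreasing marginal total, then label, as
  tiebreaks. A species pair contributes only when the upper member has
  strictly more links; its score is the percentage of the lower member's
  links whose counts are strictly smaller than the upper member's counts in
  the same cells; WNODF is the mean over all row pairs and column pairs.
  This is the rule implemented by the standard R tooling (vegan's weighted
  `nestednodf`, which the bipartite package delegates to), and the test
  suite checks exact agreement with vegan through an Rscript oracle in
  addition to an independent in-Python direct-definition oracle.
- **Modularity**: Barber's weighted bipartite
  `Q = (1/F) Σ_ij (a_ij − r_i c_j/F) δ(g_i, g_j)`, maximised by alternating
  label propagation — each guild in turn takes, per node, the
  opposite-guild module label with the highest summed deviation score, or a
  fresh singleton when every score is negative (so updates never decrease
  Q) — followed by greedy module agglomeration, iterated to a fixed point.
  Restarts draw random initial row partitions over a random number of
  modules; the first restart uses the canonical one-module-per-row start.
  The search budget is `max_iter` propagation sweeps × `n_restarts`
  restarts (defaults 10⁴ × 100, a total budget of 10⁶ in the spirit of the
  step-count convention used for this algorithm family; analyses in this
  package's own pipeline use 10–40 restarts, which on the community sizes
  simulated here reaches the exhaustive-partition optimum in ≥99% of test
  cases). The returned Q is exactly recomputable from the returned
  partition; the single-module partition (Q = 0) is a floor.

## Null model and significance

Null networks preserve the three quantities that define the observed web's
sampling frame: row totals, column totals, and L. Each replicate starts
from a Patefield random fill of the margins (`scipy.stats.random_table`)
and is then driven to the target L by random 2×2 submatrix moves
(`+k, −k / −k, +k`), which conserve both margins for any feasible `k`;
extreme `k` zeroes cells (reducing fill), `|k| = 1` splits mass into empty
cells (raising it). Only moves that strictly improve `|L − target|` are
accepted; if the target is not reached within the move budget (default
10⁵ per replicate) an error names the budget rather than returning a
silently wrong replicate.

Significance uses the add-one permutation convention
`p = (1 + #extreme)/(n + 1)` — never exactly zero — doubled and capped at 1
for two-sided tests; the reported interval is the empirical 2.5–97.5
percentile range of the null replicates (both the interval and the raw
replicates are retained, so a CI of the null mean can be derived if
wanted).

## Assembly hypotheses and model selection

The five probability matrices are simplex-normalized over the I×J grid:
`Ab` is the outer product of relative abundances (invariant to rescaling
either vector); `Sp` normalizes the integer count of co-occupied quadrats
(any positive rescaling is equivalent after normalization, so a similarity
index would add nothing); `AbSp` renormalizes the elementwise product;
`Null` is `1/(I·J)`; `Obs` is `a_ij/F`. `Sp`'s zeros are intentional hard
zeros — no smoothing is applied at this stage.

The likelihood treats the observed network as a single multinomial draw of
F interactions over the cells:
`log L = ln Γ(F+1) − Σ ln Γ(a_ij+1) + Σ_{a_ij>0} a_ij ln p_ij`
(log-gamma throughout, so F ~ 10⁶ is safe). Cells observed where a
hypothesis puts zero probability falsify it: the default `strict` policy
returns −∞ (weight 0). An `epsilon` policy replaces zero entries with
(smallest positive p)/100 and renormalizes, for data sets where support
mismatches reflect occupancy undersampling rather than true impossibility;
the substitution is logged and reported.

AIC uses k = 0 parameters for every hypothesis: the candidate matrices are
fixed inputs, not fitted, so ΔAIC is a pure deviance difference and any
common k would cancel; k is configurable for users who prefer to charge
hypotheses differently. Akaike weights are `exp(−ΔAIC/2)` normalized.

## Constrained randomization (prediction)

`assign_interactions` works in two phases: (1) connectivity — cells are
drawn with probability `p_ij` and accepted only while they link a
so-far-unlinked row or column, until both guilds are covered (rejected
draws are discarded and do not count toward F); (2) the remaining
interactions are one multinomial draw. Both guilds are constrained in
phase 1. Supports are respected exactly; an all-zero row or column in p is
an error before any sampling. Per-replicate metric failures on degenerate
draws are excluded and counted rather than aborting a long run.

## Phylogenetic signal

Partner profiles are compared with Bray–Curtis dissimilarity (scipy);
phylogenetic distances are patristic (dendropy). The Mantel statistic is
the Pearson (optionally Spearman) correlation of off-diagonal entries, with
simultaneous row/column permutation of one matrix and the add-one rule
(default 999 permutations). Orientation: the pipeline tests phylogenetic
distance against partner *similarity* (1 − Bray–Curtis) with a one-tailed
"less" alternative, so related species with similar partners give a
negative r; outputs label the orientation explicitly since the opposite
convention (distance vs dissimilarity, tail "greater") is equally common.

The Brownian tip covariance V has `V_ij` = depth of the most recent common
ancestor (computed from tip depths and patristic distances; the root's stem
edge does not count). Blomberg's
`K = [(x−â)ᵀ(x−â) / (x−â)ᵀV⁻¹(x−â)] / [(tr V − n/(1ᵀV⁻¹1))/(n−1)]`
with â the GLS mean; K = 1 identically on an equal-branch star tree and in
expectation under Brownian motion. Its p-value shuffles tip labels and asks
how often the variance of phylogenetically independent contrasts
(Felsenstein pruning; polytomies resolved arbitrarily first) is as small as
observed, add-one, default 999 randomizations. Pagel's λ multiplies V's
off-diagonals (diagonal preserved); mean and scale are profiled out
analytically and the 1-D profile likelihood is maximised by bounded scalar
search on [0, λ_max] with tolerance 10⁻⁶, λ_max being the largest value
keeping every scaled covariance at most its paired tip variances (≥1 on an
ultrametric tree); endpoints are checked against the interior optimum. The
λ test is a likelihood ratio against λ = 0 on χ²₁. Both statistics
reproduce `phytools::phylosig` (K to 10⁻⁶, λ to 10⁻³ on the same data) in
the cross-validation test. Species absent from a tree are excluded from
signal tests only, with a warning.

## Synthetic communities

The generator produces what a plot census plus root sequencing would:

- **Abundances**: log-normal per guild (default meanlog 6, sdlog 1 for
  both), ceiling-rounded to ≥1 individual. sdlog 1 gives the right-skewed
  abundance distribution typical of forest plots and an abundance CV above
  1, which keeps the Ab hypothesis distinguishable from Null.
- **Occupancy**: each species receives cluster centres (count scaling with
  abundance, up to 8 for plants and 4 for fungi) on a 25 × 50 grid of
  20-m quadrats (a 50-ha plot) and occupies all quadrats within the
  guild's patch radius — 8 quadrats for plants (trees are widespread),
  3 for fungi (spatial autocorrelation over tens of metres). Clustered
  occupancy, rather than independent Bernoulli presences, is what makes Sp
  distinguishable from Null. Fungal centres are restricted to
  plant-occupied quadrats: root symbionts are observable only where hosts
  grow, and this guarantees the Sp hypothesis is feasible for every
  simulated fungus.
- **Networks**: the scenario's hypothesis matrix is built by the same
  builders the analysis uses, then sampled by the same constrained
  randomization (default F = 2,000 over 15 plants × 60 fungi); the
  generating model and probability matrix are recorded as ground truth.
- **Trees and traits**: Yule trees (unit depth, terminal branches extended
  by the waiting time to the next unrealized speciation so no branch is
  zero) with traits drawn from N(0, σ²·V(λ_true)) — exactly the model the
  λ estimator fits, making recovery a well-posed check.

What the generator does *not* emulate: OTU clustering artefacts, read
chimeras, environmental covariates, trait matching, point-pattern realism
beyond disc-shaped patches, or phylogenetic structure in abundances and
occupancy. Passing the recovery tests therefore shows the estimators work
when their assumptions hold — not that those assumptions hold in any
particular forest.

## Problem sizes and numerical choices

Default analysis sizes used by the package's own tests and acceptance
script: communities of 15 × 60 species at F = 2,000; 1,000 null or
predicted replicates; hypothesis-recovery runs of 50 replicates per
generating model; λ recovery at 64 tips × 200 replicates for
λ ∈ {0, 0.5, 1}; K calibration over 500 Brownian simulations; Mantel
calibration over 10⁴ null experiments at 199 permutations. These sizes give
Monte-Carlo standard errors comfortably inside the tolerances asserted
(e.g. ±0.1 on mean λ, ±0.01 on the Mantel type-I rate).

Ties and degeneracies: WNODF orders ties deterministically but tied pairs
score 0 regardless; label propagation breaks score ties by first index;
H2′ is clamped to [0,1]; probability matrices must sum to 1 within 10⁻¹²;
constant traits, degenerate margins, matrices with a single row/column and
under-depth samples raise typed validation errors rather than returning
NaN. All randomness flows through numpy Generators; pipeline stages derive
independent streams from one master seed via `SeedSequence` spawn keys, so
a full analysis is bit-reproducible from its config and seed.

## Known limitations

- The swap null's hill-climbing fill adjustment samples the
  margin-and-L-constrained table space without a proven uniformity
  guarantee (the same is true of the classic sequential swap family); the
  conservation contract itself is exact and tested.
- The greedy H2 minimum can sit slightly above the true integer minimum
  (bounded at 0.02 in H2′ on tested cases).
- Label propagation is a heuristic; global optimality is verified only on
  small matrices where exhaustive enumeration is possible.
- The λ=0.061-with-p<0.001 style of result reported for real fungal data
  (huge trees, heavily tied degree distributions) is not reproducible
  without that data; the package reproduces the *shape* of those tables on
  synthetic data with known truth instead.
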