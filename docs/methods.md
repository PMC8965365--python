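# Methods

`offsetlab` asks a simple question with an honest answer available: when we
predict how badly a population will be mismatched to a changed environment
("genomic offset"), which of the competing prediction metrics actually tracks
realized fitness? Because the populations here are simulated, the answer is
known exactly — every individual's fitness in every environment can be
computed — so the metrics can be scored against truth instead of against each
other.

## 1. The simulation model

### Landscape

A 10×10 stepping-stone grid of demes, row-major indexed (`deme = y*10 + x`).
Migration is backward: with probability `m` an offspring draws both parents
from one uniformly chosen rook-adjacent deme, otherwise from its own deme.
Deme sizes are restored exactly every generation (hard Wright–Fisher
constraint), and each deme always carries both sexes.

Environmental variables assign one value per deme:

- **Causal gradients** double as the phenotypic optima of the selected
  traits. Linear clines span −1..1 along columns or rows; the nonmonotonic
  variant is a tent (rise to +1 at the grid centre, fall back to −1), so the
  two ends of the axis — and all four corners when two orthogonal tents are
  combined — share the same environment.
- **Decoy variables** confound metrics that use every environment: one noisy
  copy of each causal gradient (per-deme N(0, 1.3²) noise, giving a Pearson
  correlation of ≈0.44 with the parent; closed form
  `sd_E / sqrt(sd_E² + 1.69)` with `sd_E² ≈ 0.407` for the −1..1 10-column
  cline) plus ten multivariate-normal fields whose pairwise correlations are
  drawn Uniform(−1, 1) and projected to the nearest valid correlation matrix.
  Two causal + twelve decoys = fourteen variables.

### Genomes and reproduction

Diploid individuals carry 10 linkage groups of 50,000 sites at full scale
(`r = 1e-5` between adjacent sites: 50 cM per linkage group; linkage groups
assort independently). Only segregating sites are stored, as a `(2N, S)`
haplotype matrix. Recombination generates sparse Poisson crossover events on
the physical map (Haldane model, no interference) and converts them to parity
flips at segregating columns; mutation adds single-copy columns at rate `mu`
per site per generation. Fixed or lost columns are pruned each generation; a
fixed QTN's effect moves into a constant phenotype offset so phenotypes are
unchanged by pruning.

Reproduction is fitness-weighted bi-parental Wright–Fisher: each offspring
draws one mother and one father within its (post-migration) source deme with
probability proportional to fitness.

### Genetic architectures

- **Neutral** (deme-size scenarios): no selection; `m = 0.05`.
- **Single locus** (antagonistic pleiotropy): one focal site with fitness
  `w = 1 + dE(g−1)` (`d = 0.45`, dosage `g`, environment `E`), seeded at 10%
  frequency where beneficial; `m = 0.05`.
- **Polygenic, two traits**: QTN mutations (rate `mu_qtn = 2.5e-6` at full
  scale, restricted to the first nine linkage groups; the last group is a
  neutral reference) carry bivariate N(0, 0.1²) effects; phenotypes are
  additive. Fitness is Gaussian stabilizing selection,
  `w = exp(−½[((P1−Θ1)/σ_K1)² + ((P2−Θ2)/σ_K2)²])`; `m = 0.2`. Standing
  variants at initialization receive effects with probability
  `mu_qtn/(mu + mu_qtn)`, their stationary origin share.

Initial variation is seeded from the neutral site-frequency spectrum
(`P(count i) ∝ 1/i`, Watterson's expected number of segregating sites) with
no spatial structure, in place of a coalescent burn-in. The multilocus
scenarios then run three phases: a homogeneous burn-in (all optima 0, weak
width `σ_S = 4`), a transition phase in which optima interpolate linearly to
the final clines, and a stable phase at the final clines with `σ_K = 1.25`
(4.0 for the weak-selection trait of Case 4).

### Scenarios

- `q1_equal` / `q1_increasing` / `q1_decreasing`: neutral loci; deme sizes
  constant within columns, each row summing to 1,000 at full scale
  (10,10,50,50,95,95,145,145,200,200 left-to-right, or reversed).
- `single_locus`: one linear gradient.
- `case1`: two orthogonal linear gradients. `case2`: two orthogonal tents.
  `case3`: trait-2 gradient narrowed to −0.25..0.25. `case4`: as Case 1 with
  trait-2 selection relaxed (`σ_K2 = 4`).

## 2. The turnover-function engine and GF Offset

For every SNP, an ensemble of regression trees is fit with per-deme allele
frequency as the response and the environmental variables as predictors
(bootstrap over demes; 1 candidate predictor per split for ≤2 predictors,
else ⌈K/3⌉; minimum leaf size 2). Each split contributes its impurity
(variance) reduction at the split threshold along the chosen predictor.
Performance is out-of-bag R².

Raw split importances are standardized by the empirical density of the
predictor's deme values at the split location, accumulated into a monotone
per-SNP cumulative-importance curve, scaled to `R² ×` the predictor's
importance share, and averaged over SNPs with positive R² into an aggregate
turnover function per predictor. Curves are right-continuous step functions,
clamped to the fitted range.

**Density standardization.** We use a Gaussian kernel density estimate
evaluated on a fine grid and floored at 5% of its mean density, rather than a
50-bin histogram. With only ten distinct environmental values per predictor
on the grid, tree split thresholds (midpoints between observed values) fall
almost entirely into empty histogram bins, which degenerates a binned
standardization (division by ~0); the smoothed density is well defined at
every threshold. This is a numerical choice of this package.

**GF Offset** between environments A and B is the Euclidean distance between
the vectors of aggregate cumulative importance evaluated at A and B. Offsets
are computed for four variants (all/causal loci × all/causal environments);
`gf_genome_all` — every SNP, every environment — is the realistic default.

Per-SNP random substreams are keyed on the SNP's name, so fitting any subset
of SNPs reproduces the identical per-SNP results.

## 3. Competing metrics

- **Weir–Cockerham F_ST** (1984 variance components, r = 2 populations,
  ratio of sums across loci) between every deme pair, over all MAF-filtered
  loci or the causal loci only. Negative multi-locus estimates are clamped to
  0 when used as offsets (the raw minimum is kept in metadata).
- **Environmental distance**: Euclidean and Mahalanobis (inverse covariance
  estimated once across demes), over all fourteen variables or the two causal
  ones.

## 4. Evaluation: in silico reciprocal transplant

Ten individuals per deme are sampled and filtered at minor-allele frequency
&gt; 0.01. Each sampled individual is "moved" to every deme's environment with
phenotype fixed — an immediate change with no evolutionary response — and its
relative fitness evaluated there; source-deme means give the 100×100
common-garden (CG) fitness matrix.

- **Local adaptation** = mean(diagonal) − mean(off-diagonal); **sympatric
  advantage** = mean(diagonal)/mean(off-diagonal) − 1.
- **Per-garden score**: Spearman correlation between each metric's offset
  column and the CG fitness column over a fixed 32-deme evaluation subset
  (quasi-uniform lattice: odd columns, row ≢ 2 mod 3, trimmed from 35 to 32
  by dropping the three demes nearest the grid centroid; the garden itself is
  excluded from its own sources). Gardens are split into range edge (outer
  ring) and range core (interior).
- **Deme-size confounding**: for the neutral scenarios, each deme's GF Offset
  against the environment one column toward the higher-environment side (the
  last column uses its lower neighbour) is correlated with deme size. A
  negative correlation means drift in small demes is being read as predicted
  maladaptation.

## 5. Desk scale

Full-scale runs (the `full` preset: N = 10,000, 500k sites, 3,000 multilocus
generations) take hours to days on one CPU. The `desk` preset is this package's scaled-down
configuration for interactive use and the test suite. We keep the 10×10 grid
— the deme-size schemes and the core/edge split are defined on it — with 20
individuals per deme, 5 linkage groups of 10,000 sites (`r` preserving 50 cM
per group), mutation rates giving a few hundred segregating sites, and phases
of 100/100/150 generations.

Two analysis-specific configurations were frozen after pilot calibration (run
before the acceptance tests were written, and not adjusted since):

- **Drift runs** (`q1_run_config`): deme sizes at half the full scale
  (5..100 per deme, N = 5,000), `mu = 1e-7`, 120 neutral generations, 20
  trees over ≤400 SNPs. Pilots at 30% scale lost the size–offset signal to
  sampling noise (smallest demes of 3 individuals); at 50% scale all ten
  pilot replicates gave negative correlations (−0.39 to −0.87), and
  equal-size pilots deviated from linearity by at most 11% of total
  cumulative importance.
- **Transplant runs** (`transplant_run_config`): the stock desk preset with
  30 trees over ≤400 SNPs. Case 1 pilots gave local adaptation 0.27–0.29,
  sympatric advantage ≈0.47, and the expected edge-garden metric ordering
  (causal environmental distance ≥ GF Offset ≥ all-variable distance and
  F_ST) in all pilots.

## 6. Known limitations

- The SFS-seeded initialization approximates, but is not, a coalescent
  equilibrium; early generations carry excess singletons and no linkage
  disequilibrium.
- Desk-scale demes are small, so drift is stronger than at full scale;
  quantities reported at desk scale are properties (signs, orderings), not
  the full-scale magnitudes.
- F_ST is not a metric (the triangle inequality can fail), so the distance
  axioms are asserted only for the environmental and turnover-based offsets.
- The 32-deme evaluation subset uses this package's own lattice convention;
  any fixed quasi-uniform subset serves the same purpose.
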