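# Methods

## The invasion model

`idroute.simcore` simulates a neutral (optionally costly) DNA transposon
spreading through diploid, randomly mating Wright–Fisher populations of
constant census size `N`.  Each generation executes, in order: (1) mate
pairs drawn with probability proportional to fitness `w = max(0, 1 − x·n)`
(`n` = diploid copy number; self-pairing excluded), (2) meiosis — per
chromosome a Poisson number of crossovers with mean `rr[cM/Mb]/100 ×
length[Mb]`, uniform crossover positions, free assortment between
chromosomes, (3) transposition into each gamete, (4) zygote formation,
(5) piRNA-cluster insertion counting, (6) fitness computation, (7) optional
migration, (8) output.

**Activity (trap model).**  A diploid's TEs are active iff it carries at
least one FL copy anywhere and no copy — FL or ID — inside a piRNA
cluster.  Clusters occupy the last `cluster_len` bp of each chromosome.
Activity is evaluated on the diploid parent at gamete formation; gametes of
inactive parents receive no new insertions.  Silencing is therefore first
carried by segregating cluster insertions (whose cluster-free offspring can
transiently reactivate) and becomes permanent once a cluster insertion
fixes.

**Transposition and internal deletions.**  Each gamete of an active parent
receives `Poisson(u·n/2)` new insertions at uniform unoccupied sites
(collisions are redrawn; at 5 Mb they are negligible).  The template copy
is drawn from the parent's copies with per-copy weight `fl_id` for FL and
`1 − fl_id` for ID copies, so `fl_id = 0.5` makes every copy an equally
likely template.  An FL template yields a brand-new ID with probability `c`
(two distinct uniform breakpoints on the TE consensus, ordered; equal draws
redrawn); an ID template propagates its breakpoints unchanged.  A copy
carries at most one deletion, IDs never revert, and every conversion event
creates a fresh variant id even when breakpoints coincide by chance, so
homoplasy is representable in the simulation truth while fingerprints merge
by breakpoints.

**Migration.**  The 1D stepping-stone driver seeds deme 1 with `n_fl_init`
FL copies at frequency `1/2N` each.  Every `migration_interval` generations
`migration_size` individuals are sampled without replacement from the most
recently invaded deme and *copied* over uniformly chosen individuals of the
next naive deme, keeping both censuses at `N`.  (Whether migrants should be
removed from the source is a free choice for a constant-`N` model; copying
keeps the source unchanged.)

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| genome | 5 × 1 Mb | chromosome lengths |
| `cluster_len` | 100 kb | terminal piRNA cluster per chromosome (10% of the genome) |
| `rr` | 4 cM/Mb | recombination rate |
| `u` | 0.1 | transpositions per copy per generation |
| `c` | 0 (runs use 0.005–0.05) | P(new copy is a fresh ID \| FL template) |
| `x` | 0 | per-copy fitness cost |
| `N` | 1000 | diploids per deme |
| `fl_id` | 0.5 | per-copy FL mobilization weight |
| `te_length` | 2907 | TE consensus length (bp) |
| `n_fl_init` | 300 (250 in multi-deme runs) | seed FL copies |
| migration | 100 / 300 gen | migrants per event / interval |

With these defaults invasions plateau at ~30–60 copies per diploid after
150–300 generations, with a few cluster insertions per individual — the
regime where the trap model stops an invasion.

### A structural property of per-event conversion

Under any model in which conversion happens with probability `c` per
transposition event, the expected plateau fraction of ID copies is
`f ≈ 1 − (1−c)^T`, where `T` is the expected number of transposition events
in the ancestry of a surviving copy.  `T` equals the log of the net
copy-number growth (≈ `ln(n_final/n_initial)` ≈ 4–5 here) regardless of
`u`: per-event conversion cannot push `f` above ≈ `c·ln(growth)` unless
copies also turn over.  Empirically the simulator gives `f ≈ 2–3%` at
`c = 0.005` and `f ≈ 16–19%` at `c = 0.05`.  Class-level mobilization
weighting (template class chosen with probability `fl_id` whenever both
classes are present) was evaluated as an alternative and amplifies young
IDs far more strongly (`f ≈ 0.3–0.5` for both rates); the per-copy
weighting is kept because it is the only reading under which `fl_id = 0.5`
means "all copies are equal templates".

## Fingerprint analysis

* **Support filter:** entries with fewer supporting reads than
  `min_support` are dropped (recommended 2 for experimental, 3 for natural
  pooled samples).
* **Breakpoint clustering:** exact `(start, end)` pairs are pooled across
  samples, then clustered greedily in decreasing order of total support
  (ties: smaller pair): a representative absorbs every unassigned pair
  within `tolerance_bp` (default 3) on *both* breakpoints.  Merged entries
  sum their frequencies within a sample.  Tolerance 0 is the identity
  grouping.
* **Private-ID removal:** alleles with nonzero frequency in exactly one
  sample are dropped; the FL column is recomputed as `1 − Σ retained f_i`
  so rows remain probability vectors.
* **FL reference:** an artificial sample with FL frequency 1 marks the
  invasion origin.
* **Jost's D:** the plain two-deme frequency formula (not the
  sample-size-corrected estimator — pooled read proportions are not
  genotype counts).  `D` is clipped into `[0, 1]` against floating-point
  error only; for two demes `H_T ≥ H_S` holds by convexity.

## Trees and nulls

* **BIONJ:** neighbor-joining selection criterion
  `Q_ij = (r−2)D_ij − S_i − S_j` with variance-weighted reduction; first
  order variances `V = D`; reduction weight
  `λ = ½ + Σ_k(V_jk − V_ik) / (2(r−2)V_ij)` clamped to `[0, 1]`; ties
  broken by the lowest index pair; negative branch lengths are kept (the
  consensus uses topology only).  On additive matrices the implementation
  reproduces the R/ape reference exactly; on non-additive matrices
  near-ties can reorder the final agglomerations, which shifts central
  branch lengths but not the topology (see `tests/test_trees.py`).
* **Splits:** canonical form is the side of a bipartition not containing
  the lexicographically smallest tip; trivial splits are excluded.
* **Random-tree nulls:** two generators.  `recursive-split` partitions the
  label set recursively by assigning each label independently to one of two
  sides (empty sides redrawn) — matching the widely used recursive
  generator, and the default for the null.  `uniform-addition` (stepwise
  addition onto a uniformly chosen edge) is uniform over labeled
  topologies; for 11 tips its expected shared-split count with the
  caterpillar has the closed form `Σ (2a−3)!!(2b−3)!!/17!! ≈ 0.1559`, which
  the generator reproduces.  The two generators differ slightly (posterior
  mean ≈ 0.022 vs ≈ 0.0195), which is why the choice is explicit.
* **Bootstrap consensus:** ID allele columns are resampled with
  replacement (same count); the FL column is recomputed as the complement,
  renormalizing a row if the resampled frequencies exceed 1.  Replicates in
  which all rows are identical are skipped (and counted); fewer than `B/2`
  usable replicates is an error.  Splits retained strictly above the 0.5
  majority threshold carry their support fraction as internal node labels;
  everything else multifurcates.
* **Posterior:** shared-split counts `k_t ∈ [0, n_max]` update a flat
  `Beta(1, 1)` prior to `Beta(1 + Σk, 1 + T·n_max − Σk)` — the exact
  conjugate form; no sampler is needed.
* **Classical MDS:** Torgerson double-centering via eigendecomposition
  (scikit-bio PCoA); only axes with positive eigenvalues are returned.
* **Mantel:** Pearson correlation of upper triangles, one-sided (positive
  association), simultaneous row/column permutations,
  `p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)`.
* **Clade permutation test:** the match of a random equal-size partition
  to the observed grouping is judged up to group relabeling; the exact
  probability is `g!·Π s_i!/n!` (for 15 samples in three groups of five:
  `6/756756 ≈ 7.9 × 10⁻⁶`), with a vectorized Monte-Carlo alternative.
* **PCA:** FL column excluded, constant columns dropped with a warning,
  unit-variance scaling, SVD scores; components oriented so the
  largest-magnitude loading is positive; per-allele contributions are
  normalized squared loadings.

## Synthetic fixture generator

`generate_fixture_fingerprints` emulates fingerprint tables of successively
invaded demes: each shared ID originates in one deme and is carried by all
later demes with Gamma base weights and lognormal per-deme noise; total ID
mass grows linearly along the chain (default 0.1 → 0.5); each deme also
receives private IDs.  It reproduces the two relational properties the
pipeline exploits (shared alleles decay with deme distance; ID mass encodes
direction) but none of the population-genetic detail — no drift, no
linkage, no copy numbers, no read-sampling noise.  Passing end-to-end tests
on fixtures therefore demonstrates that the pipeline recovers a gradient of
shared alleles, not that real pooled sequencing data meet the model's
assumptions.

## Problem sizes used in tests and acceptance runs

Replicated single-deme runs use the full default scenario (N = 1000,
500 generations, 10 replicates per conversion rate).  Stepping-stone checks
use ten replicates (tests) or five replicates (acceptance script) of the
full ten-deme, 3000-generation protocol.  Fast property tests use a reduced
scenario (two 200-kb chromosomes, N = 200) where only qualitative behavior
is asserted.  Random-tree nulls use 10,000 trees; the closed-form check for
the uniform generator uses 100,000.

## Known limitations

* No sequence-level read simulation; fingerprints from simulations carry
  exact breakpoints and copy counts, not split-read estimates.
* Selection on IDs beyond the uniform per-copy cost is not modeled, nor
  are insertion biases into piRNA clusters, 2D migration geometries, or
  maternal piRNA inheritance.
* The plateau ID fraction under per-event conversion is bounded by
  `c·ln(copy growth)` (see above); systems with substantially higher ID
  loads at small `c` require copy turnover or feedback mechanisms outside
  this model.
* Jost's D between a sample and the all-FL reference saturates quickly once
  fingerprints are ID-rich; the FL reference anchors the direction but its
  branch length is not interpretable.
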