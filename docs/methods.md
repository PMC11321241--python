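# Methods

## Pipeline model

`stemwalk` scores every gene in a cancer-specific molecular network by
its proximity to a set of known stemness genes, under the assumption that
genes tightly co-expressed or regulatorily coupled with the stemness
program are themselves candidates for that program. The score is the
stationary distribution of a random walk with restart (RWR):

    p_{t+1} = (1 − α) · M · p_t + α · p_0

where `p_0` puts mass 1/n on each of the n seed genes present in the
network and α is the probability of restarting at the seeds in each step.

### Operator orientation

The transition matrix is defined by row-normalizing the binary adjacency,
`w(i,j) = A(i,j)/Σ_j A(i,j)` with zero rows for isolated nodes. Applied
literally as `W·p`, a row-normalized matrix *pulls* mass into each node
from its neighbours' normalized rows and does not conserve total
probability on graphs with asymmetric degrees. We therefore propagate
with the transpose `M = Wᵀ` (equivalently, the column-normalized
adjacency), the standard random-walk convention under which mass flows
*out* of each node in proportion to its normalized weights and
`Σ p_t = 1` holds at every step on graphs without isolated nodes. On
degree-symmetric graphs the two conventions coincide. The literal form
remains available through `PropagationConfig(literal_update=True)` for
comparison.

### Edge weights, convergence, degenerate cases

Edges are unweighted (binary adjacency); a |PCC|-weighted mode exists but
is off by default since the network-construction thresholds already
select for correlation strength. Iteration stops when the L1 change
between successive iterates falls below `tol = 1e-10` (cap 1000
iterations); the update is a contraction with ratio ≤ 1 − α, so at
α = 0.5 convergence takes ≈ 35 iterations. Isolated nodes keep their
zero transition row: their score decays to α·p0, i.e. mass leaks away
from them each step. Seeds absent from the network are dropped with a
warning and 1/n is recomputed over the seeds actually present — keeping
them would leave `p_0` summing below one. `rwr_solve` computes the fixed
point `(I − (1 − α)M) p = α p_0` by dense LU; it is the independent
oracle for the iteration and, factorized once per network
(`RWRSolver`), the workhorse of the permutation loop on networks up to a
couple of thousand nodes.

## Network construction choices

* **Variance filter.** "Bottom 25%" is implemented as: keep genes whose
  sample variance strictly exceeds the linear-interpolation 0.25-quantile
  of all gene variances. With distinct variances this keeps exactly the
  upper three quarters; with ties it errs toward dropping, which also
  guarantees zero-variance genes (undefined under PCC) never reach the
  correlation step.
* **Per-category ranking and thresholding.** The four pair categories
  are ranked independently and thresholded independently; the top-k%
  count is `ceil(k/100 × category size)`, so even 0.1% of a small
  category keeps at least one pair. PCC ties break lexicographically by
  gene-id pair. Because thresholding is a prefix of a fixed ranking, edge
  sets nest exactly across cutoffs (0.1% ⊆ 1% ⊆ 5% ⊆ 10% ⊆ 20%) and
  network size grows monotonically with the cutoff.
* **Pair types.** lncRNA–lncRNA, miRNA–miRNA and lncRNA–miRNA
  co-expression pairs are not generated; the co-expression network is
  defined on the four canonical categories only, with TF collapsed into
  PCG. The regulatory network keeps TF distinct and permits all eight
  curated interaction types.
* **Regulatory intersection.** Matching is on unordered endpoint pairs,
  category-blind; curated direction is discarded because propagation is
  undirected. The co-expression pairs supplied to the intersection are
  unfiltered by seeds by default (seed filtering is a separate,
  composable step).

## Permutation significance

The null redraws `n_perm = 1000` (200 in the test/acceptance
simulations) pseudo-seed sets of the real seed count, uniformly without
replacement from all network nodes, and re-runs the walk. A node's
empirical p is the add-one proportion of its null scores at least as
large as its true score, so p ∈ [1/(m+1), 1] and never zero; a node is
significant at p ≤ 0.05, the per-node reading of a "top 5% of scores"
rule — propagation scores are strongly degree-dependent, so a pooled
global percentile would simply select hubs. The pooled reading remains
available via `mode="pooled"`.

One subtlety matters for calibration: in the draws where a node is
itself sampled as a pseudo-seed its null score is enormous (it receives
restart mass directly). Leaving those draws in would push every node's
95th null percentile above any non-seed score and silence the test
almost completely. Each node's null is therefore conditioned on the node
*not* being a pseudo-seed: only the draws that did not sample it are
counted (about (1 − n/N)·n_perm draws). Under exchangeable seeds this
makes the per-node p exactly uniform on its achievable grid, and the
significant fraction at level q matches q — verified empirically in the
calibration test (20 replicates × 45 non-seed nodes, binomial 3σ band
around 0.05). A biotype-stratified pseudo-seed mode preserving the real
seed set's biotype composition is provided for seed sets mixing PCGs and
ncRNAs.

## Differential expression and enrichment

Samples are split at the median stemness index; ties go to the high
group (deterministic), and each side must keep ≥ 2 samples. The DE
statistic is a two-sided Wilcoxon rank-sum test (distribution-free;
Welch t available by flag), with log2FC the ratio of group means under a
pseudocount of 1 expression unit, BH adjustment across all tested genes,
and the call `|log2FC| > 1 AND FDR < 0.05` with strict inequalities.
Genes constant across all samples get p = 1 and a `constant` flag.
Enrichment of predictions in DE ncRNAs is the one-sided hypergeometric
upper tail on the 2×2 table over the ncRNA universe, with a Haldane 0.5
correction on the odds ratio when a cell is zero.

## Synthetic data

The generator draws a latent per-sample stemness factor z ~ N(0, 1) and
plants a single-factor structure:

* signal genes (seed PCGs, true lncRNAs): `baseline + amplitude·(ρ·z + √(1−ρ²)·ε)`;
* true miRNAs: the same with the sign of the z-loading flipped
  (miRNAs repress, so stemness-driving miRNA activity appears as
  anti-correlation);
* background genes: `baseline + amplitude·noise_sd·ε`, independent noise;
* stemness index: `logistic(z)`, landing in (0, 1) with values near 1
  marking stem-like samples.

Any two signal genes then share population correlation ±ρ². Defaults are
the study conditions used throughout the tests: 200 samples, 30 seed
PCGs, 10 + 10 true ncRNAs, 400 background genes, ρ = 0.9,
`noise_sd = 0.8`, `baseline = 2`, `amplitude = 2`. `noise_sd < 1`
encodes that program-driven genes carry an extra biological variance
component on top of measurement noise — which is exactly the regularity
the bottom-quantile variance filter exploits; at ρ = 0 (null datasets
for calibration) signal and background variances coincide and the filter
becomes uninformative, as it should. `baseline`/`amplitude` place values
on a plausible log2-expression scale where a median split of the index
produces |log2FC| > 1 for signal genes under the pseudocount.

What the generator does **not** emulate: library-size and compositional
artifacts, heavy-tailed counts, batch structure, correlated background
modules, and biotype-specific dynamic ranges. Passing the planted-signal
tests therefore demonstrates that the pipeline recovers the co-expression
structure it assumes, not that it is robust to the full messiness of
real tumor expression data.

## Problem sizes in tests and the acceptance script

Simulations run at desk scale: oracle agreement on ~50 random graphs of
up to 200 nodes; calibration on 50-node Erdős–Rényi graphs with 200
permutations × 20 replicates; recovery on the 450-gene default dataset
with 5 replicates; DE operating characteristics on 210 genes × 40
samples × 10 replicates. These sizes give stable medians and tight
binomial bands while keeping the full suite in the low seconds; all
scale linearly in permutations and quadratically in gene count if
enlarged.

## Known limitations

* PCC is computed on all samples jointly; missing values are rejected at
  read time rather than pairwise-deleted.
* Counts of real-data artefacts (seed counts from signature snapshots,
  prediction totals) depend entirely on the supplied inputs and are not
  asserted anywhere.
* The permutation null permutes seeds, not network topology; it asks
  whether a gene is unusually close to *these* seeds, not whether the
  network itself is unusual. Degree-preserving rewiring nulls are out of
  scope.
* Propagation is undirected even on the regulatory network; a directed
  variant would require a direction convention the curated sources do
  not share.
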