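# Methods

## Model and procedure

The mirrortree score treats each protein family's phylogeny as a noisy
measurement of the evolutionary history the family traversed.  If two
families coevolve — because their products interact and constrain each
other — their histories coincide beyond the shared species phylogeny, and
their inter-sequence distance matrices are correlated.  The pipeline
estimates each family's distances, summarizes them as patristic distances
on a neighbor-joining tree, restricts both matrices to the organisms the
families share, and computes the Pearson correlation r of the two flattened
upper triangles.  Correlation (not equality) is the right comparison
because families evolve at different absolute rates: a family-wide rate
scalar rescales all distances and leaves r unchanged.

Significance is a Mantel-style permutation test.  The organism labels of
the second matrix are permuted jointly over rows and columns, which keeps
every within-matrix distance (the permuted matrices have exactly the same
multiset of entries) and breaks only the correspondence between the two
families.  That is the exchangeable null for "the two trees agree beyond
chance".  The p-value uses the add-one convention
p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + B), so p ≥ 1/(B+1) and the test is
exact-level for exchangeable nulls.  Two-sided extremeness on |r| is the
default; a one-sided variant is available.  The analysis requires at least
4 shared organisms (below that n ≤ 3 and r is nearly degenerate); the
floor is configurable.

## Distances

p-distance counts differing columns over comparable columns; a column is
comparable for a pair when both residues are standard amino acids ('X' and
'-' are missing data).  Two gap policies are exposed: `pairwise_deletion`
(per-pair column masks; the default for the mirrortree path, which keeps
more signal) and `complete_deletion` (drop any column with a gap anywhere;
the default for the consensus-phylogeny subcommand).  The Poisson
correction d = −(19/20) ln(1 − 20p/19) is exact for the simulator's
20-state equal-rates model and makes distances additive on the true tree;
it is the default correction.  Saturated pairs (p ≥ 19/20) have no finite
corrected distance and raise an error rather than returning a clipped
value — silently capping would flatten exactly the long distances the
correlation leans on.  Raw p-distance is kept as `correction="none"`;
whether a given distance server applies any correction is configuration,
not something this package guesses.

## Trees

Neighbor joining follows the Saitou–Nei Q-criterion.  Two conventions are
fixed for reproducibility because the literature leaves them open: ties in
the Q minimum are broken by the smallest (row, column) index pair, and a
negative estimated branch length is clamped to zero with the deficit moved
to its sister edge, preserving the joined pair's distance (this matters:
it changes patristic sums).  NJ is exact on additive matrices, which the
test suite exploits: on random additive inputs the recovered topology and
the patristic round-trip are checked to 1e-9.

Bootstrap replicates resample alignment columns with replacement and
rebuild distances and trees per replicate.  The consensus is
majority-rule extended: splits are ranked by bootstrap frequency (ties:
smaller split, then lexicographic) and greedily added while pairwise
compatible; edges whose support falls below the collapse threshold
(default 45%) are then contracted.  Supports are written as internal node
labels; consensus branch lengths are means over the replicates containing
the split (leaf edges: means over all replicates).

## Synthetic data

The generator draws a Yule (pure-birth) species tree: starting from the
root split, with k lineages the next split waits Exp(λk), and one more
waiting time elapses after the Nth lineage, giving expected height
Σ_{k=2}^{N} 1/(λk).  Sequences evolve site-independently under the
20-state Poisson model, so the expected p-distance after total path t is
(19/20)(1 − e^(−20t/19)) — a closed form the tests compare simulations
against.  Defaults define the reference condition: N = 20 organisms,
λ = 4 per lineage (expected root-to-tip depth ≈ 0.65 substitutions/site —
divergent but safely below saturation, as in an alignable homolog set),
length 200, and lognormal per-family rate scalars with log-sd σ = 0.3.
In coevolving mode both families evolve on the same tree; in independent
mode each gets its own tree over the same organism labels, so the shared
label set never confounds the comparison.  The `distant_clade` option
grafts a clade of 20% extra organisms on a stem 3× the tree height onto
the shared history, emulating the addition of remote but genuinely
interacting homolog pairs.

What the generator does *not* emulate: indels as an evolutionary process
(gaps are punched in at random cells), amino-acid exchangeability structure
(JTT-like matrices add no testable structure here), rate variation across
sites, horizontal transfer, and paralogy/misassignment of organisms.
Passing tests therefore show that the statistics behave correctly when the
model assumptions hold; they do not certify robustness to alignment error
or paralog contamination in real homolog sets.

## Numerical and design choices

* **Simulation studies run on uncorrected distances.**  At the reference
  condition the lognormal rate tail occasionally pushes deep pairwise
  p-distances past 19/20, where the Poisson correction (correctly) raises.
  The power and calibration studies therefore use the raw-p-distance path,
  which is also how classic distance servers operated; the equal-rates
  fidelity check (σ = 0, length 2000) uses the corrected path, where
  saturation cannot occur.
* **Distant-clade check at a shallow tree.**  Under raw distances the 3×
  stem saturates and compresses, flattening the clade's effect; under
  corrected distances the effect is cleanly positive but the default depth
  saturates the correction.  The monotonicity check therefore runs at
  λ = 8, σ = 0, length 400 with corrected distances, where the estimator
  is finite and the prediction (a shared long-branch clade adds shared
  variance and raises r) is observable.  This is a simulation property,
  not a theorem.
* **Degenerate inputs.**  Zero-variance distance vectors (all distances
  equal) raise rather than return r = 0/0; constancy is detected with a
  relative tolerance of 1e-12 because the mean of a constant float vector
  is not exactly the constant.  A sequence pair with no comparable columns
  raises naming the pair.
* **Coverage filter** is strictly greater-than: a hit at exactly the
  threshold (e.g. 60%) is excluded.  One representative per organism is
  chosen by highest bitscore, ties by coverage, then subject id — a stated
  convention, since databases do not dictate one.
* **Lipobox scanner** reports *all* overlapping (V/L)XXC matches whose
  cysteine lies within the N-terminal window (default 40 residues, a
  typical signal-peptide span); overlaps are real (LLGC and LGCC can
  coexist one residue apart) and suppressing them would hide matches the
  pattern defines.  Broader lipobox alphabets are deliberately not the
  default.
* **Seeding.**  Every stochastic stage takes an explicit seed; the CLI
  derives stage seeds from one master seed via
  `numpy.random.SeedSequence(master).generate_state(...)`, so identical
  configs reproduce artifacts byte-for-byte.

## Problem sizes

The test suite and the acceptance script use 20-organism families at
alignment length 200 (50 power replicates per mode; 200–500 null
replicates at B = 199 permutations), 2000 columns for the fidelity check,
and 5000 columns for the closed-form distance checks — sizes at which the
binomial and permutation tolerances quoted in the tests are meaningful
while a full run completes in seconds on one core.

## Known limitations

* NJ is the only inference engine; likelihood-based trees are out of
  scope, and the consensus is topological (its branch lengths are averages
  of replicate estimates, not re-optimized).
* The permutation null conditions on the two matrices as given; it does
  not subtract the background similarity all protein pairs share through
  the species tree, so on real data r conflates interaction-specific
  coevolution with shared speciation history.  Corrections of that kind
  are explicitly out of scope.
* The organism tag is a string; no taxonomy resolution is attempted.
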