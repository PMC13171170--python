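# Methods

## Scope

`substmat` implements the full path from structure-derived residue
correspondences to a BLOSUM-style substitution matrix, together with the
analytics used to compare matrices and to benchmark them on multiple sequence
alignment (MSA) reconstruction and remote-homology discrimination. Everything
operates on the 20 canonical amino acids in the fixed NCBI order
`A R N D C Q E G H I L K M F P S T W Y V`; extended codes (B, Z, X, J, U, O,
`*`) are dropped when matrix files are read.

## Matrix estimation

### Observations and weighting

The unit of observation is an aligned column of an ungapped pairwise
alignment (an `UngappedPairBlock`). Within a family of `n_k` members all
`C(n_k, 2)` pairs are enumerated; each pair's columns are weighted by

    w_k = 2 / (n_k (n_k - 1)) = 1 / C(n_k, 2),

so every family contributes the same total mass regardless of its size (a
family with three members and blocks of length `L` contributes exactly `L`).
Counting is unordered: a column `(A, R)` and a column `(R, A)` both add `w_k`
to the same cell `f_AR`. `n_k` is the retained member count of the family
(members present in the input), not the post-filter pair count; the build
report records both so the alternative bookkeeping is one change away.

Pairs with global-alignment sequence identity strictly above the redundancy
threshold (default 0.62) are removed before counting. Identity is computed by
affine-gap global alignment under BLOSUM62 with gap open 10 and extend 1, as
the number of identical aligned columns over all alignment columns. Whether
redundancy filtering should use sequence- or structure-based identity is
genuinely open; sequence identity is used because it is defined for every
pair, structures present or not.

### Log-odds

Scores follow the classical BLOSUM recipe. The 210 unique pair masses are
normalized to probabilities `q_ij`; marginals are
`p_i = q_ii + sum_{j != i} q_ij / 2`; expected frequencies are
`e_ii = p_i^2` and `e_ij = 2 p_i p_j`; and

    s_ij = round( (1 / scale_bits) * log2(q_ij / e_ij) ),

with `scale_bits = 0.5` (half-bit units, i.e. a factor of two on the base-2
log-odds). Rounding is half-away-from-zero, so an unrounded −4.64 becomes −5;
this is deterministic and avoids banker's-rounding surprises at `.5`
boundaries. Setting `rounding="none"` returns the real-valued matrix.

Zero cells are not addressed by the classical recipe. The default adds a
pseudocount of `1e-6` of the total mass to every unique cell before
normalization, which keeps small fixtures estimable while perturbing
well-observed cells negligibly; with `pseudocount=0` a zero cell between two
observed residues is an error naming the pair. Residues that are entirely
unobserved are excluded from the normalization and receive zero rows/columns
rather than poisoning the marginals.

### Structural correspondences

When family members carry 3D chains, pair blocks come from rigid
superposition. The published pipelines in this area rarely specify their
structural aligner precisely, so the extractor is a deliberately simple,
self-contained fixed-point scheme:

1. seed pairing from a global sequence alignment under the identity (1/0)
   unit matrix — matrix-agnostic on purpose, so the structure stage does not
   presuppose the substitution matrix being estimated;
2. Kabsch least-squares superposition (closed-form SVD with determinant
   correction) on the current pairs;
3. re-pair residues whose alpha-carbons are mutual nearest neighbors within
   the proximity cutoff (default 5.0 Å, a conventional contact scale), pruned
   to the longest strictly-monotone subset (ties broken toward smaller total
   distance), because ungapped sequential blocks are the target observation;
4. repeat until the pair set stabilizes, at most 20 iterations.

An empty correspondence is a valid outcome (chains that never come within the
cutoff). Correspondences from any external structural aligner can be imported
from TSV (`index_a`, `index_b`) and used in place of the built-in scheme.
Residues without an alpha-carbon, and non-canonical residues that cannot be
mapped to a parent amino acid, are dropped on reading and logged.

### Convergence diagnostics

`convergence_curve` rebuilds the integer matrix from random family subsets
(seeded) and reports the mean and standard deviation, per subset size, of the
total absolute difference over the 210 unique entries against the full-data
matrix. Per-family counts are computed once and reused across subsets — the
estimator is additive over families, so this is exact, not an approximation.

## Matrix analytics

* **Pearson correlation** defaults to vectorizing all 400 entries (what a
  whole-matrix `numpy.corrcoef` call computes); the 210-unique-entry
  vectorization is available as an option. The two conventions differ
  because the full vectorization counts off-diagonal entries twice; the
  published comparison tables this package reproduces use the full one.
* **Evolutionary distance** is `|mean(diagonal) / mean(off-diagonal)|`, a
  scale-invariant scalar locating a matrix on the conserved-to-divergent
  axis. It is undefined (reported as `None`) when the mean off-diagonal is
  exactly zero, as for the 5/0 baseline unit matrix.
* **Identical fraction** counts agreement over the 210 unique entries of two
  integer matrices.
* **PCA** embeds matrices as 210-dimensional unique-entry vectors,
  mean-centers, and projects on the top two principal components
  (scikit-learn, full SVD solver).

The embedded BLOSUM45/62/80 and PAM120/250 tables are the published NCBI
integer versions restricted to the canonical alphabet. BLOSUM80 exists in two
published scalings; the half-bit variant (the one BLAST distributes) is
embedded, not the 1/3-bit one, and its first diagonal entry (A,A)=5
distinguishes it at a glance.

## Alignment engine

Pairwise alignment is the three-state affine-gap global (Needleman–Wunsch/
Gotoh) recurrence, with terminal gaps penalized. A gap of length `L` costs
`open + (L − 1) · extend`; engines that charge `open + L · extend` can be
mimicked with `charge_extend_on_open=True`. Transitions between the two
insertion states are allowed and charged as a fresh opening. Traceback ties
are resolved deterministically: diagonal, then gap in the second sequence,
then gap in the first. The in-row insertion recurrence is solved with a
prefix-max scan so each DP row is a handful of vectorized operations.

`integer_scale` finds the smallest integer factor making all scores and
penalties integral (the benchmark grids use 0.5-step extension penalties);
alignment scores scale exactly by that factor, which is asserted in tests.

The same DP core aligns two profiles given a column-vs-column score table;
profile columns are scored sum-of-pairs via residue count vectors (gaps
contribute nothing), and gap penalties are charged once per column,
unweighted by profile depth.

## MSA benchmarking

`q_score` is reference-pair recall: the fraction of residue pairs co-aligned
in the reference that the test alignment also co-aligns. `tc_score` is exact
column recall: a reference column counts as reproduced only if a test column
carries exactly the same residue indices **and** the same gap pattern over
all sequences. All-gap reference columns are excluded from the TC
denominator; a reference with no residue pairs at all scores Q = 1 by
convention (there is nothing to recover). TC ≤ Q always; both metrics match
rows by identifier, so row order is irrelevant, and they error if the
stripped sequence content disagrees between test and reference.

`msa_stats` reports match, mismatch and residue–gap rates over all
within-column sequence pairs (gap–gap pairs ignored; the three rates sum to
one), mean pairwise identity of the stripped sequences (global alignment,
BLOSUM62/10/1; `identity_sample` caps or skips this for very wide
alignments), and mean stripped length.

The built-in realigner is progressive: UPGMA (average-linkage) guide tree on
`1 − identity` distances, then profile–profile merges in tree order. It is a
minimal stand-in for production progressive aligners — no iterative
refinement, no position-specific gap penalties — sufficient for strip-and-
realign benchmarking on synthetic references; any external aligner can be
injected as a callable wherever a realignment happens.

`gap_grid_search` evaluates the full (GOP, GEP) lattice — default GOP 0–10
step 1, GEP 0–5 step 0.5 — scoring mean Q and mean TC over the references,
and reports per-metric argmaxes with ties broken toward the smaller GOP, then
the smaller GEP.

## Homology benchmarking

`all_vs_all_scores` aligns every unordered pair (integer-scaling fractional
penalties and reporting scores back on the input scale) and flags pairs by
label equality. ROC AUC is the Mann–Whitney statistic (ties at half credit);
PR AUC uses step-wise average-precision integration, the conservative
standard, since linear interpolation in PR space is optimistic. Both
delegate to scikit-learn and are cross-checked in tests against a brute-force
pairwise win-rate oracle.

`nn_retrieval_auc` performs exact L2 nearest-neighbor retrieval (self
excluded) on precomputed vectors. Retrieval results are converted to
per-class scores as the indicator that the retrieved neighbor carries the
class label — one deterministic reading of "nearest-neighbor AUC" — and
summarized as micro-averaged one-vs-rest ROC AUC over the binarized labels.

## Synthetic data

The generators exist to give every pipeline stage a ground truth.

* **Substitution process.** Divergence is parameterized directly at the level
  of the joint per-column pair distribution,
  `Q = (1 − d)·diag(p) + d·p pᵀ`, interpolating between perfect conservation
  (d = 0) and independence (d = 1). This keeps the implied log-odds in closed
  form — no rate-matrix exponentials — at the price of not being a true
  time-parameterized evolutionary model. Members of a family are drawn
  conditionally independent given an ancestor column; two members of the same
  family therefore follow the joint with effective divergence `d(2 − d)`, and
  it is that pair-level process whose analytic log-odds a simulated family
  records as its recovery target. Default stationary frequencies are uniform;
  the `skewed_frequencies()` preset (linear ramp, ratio 3.5) is used in tests
  because uniform frequencies make all diagonal scores equal and would mask
  marginal-handling bugs.
* **Toy structures.** Chains lie on an idealized helix (2.3 Å radius,
  100°/residue, 1.5 Å rise) rescaled so consecutive alpha-carbons are exactly
  3.8 Å apart. A homolog is a copy with a contiguous deletion, isotropic
  Gaussian coordinate noise, and a random rigid motion; the true
  correspondence is recorded. Default conditions for recovery tests: length
  60, 5-residue deletion, 0.5 Å noise.
* **Reference MSAs** draw columns from the process and punch gaps
  independently per cell; **score/vector fixtures** are Gaussian populations
  and clusters with controlled separation.

Every generator is a pure function of (parameters, seed).

What passing on these fixtures shows — and does not. The synthetic families
have no indels, no phylogenetic tree structure, no length variation and no
domain architecture; the toy chains have no secondary-structure variety,
flexibility or multi-domain geometry. Green tests therefore certify the
estimator, the alignment engine and the metrics against their mathematical
definitions, not that any particular matrix built from real structural data
will rank well on real benchmarks such as BAliBASE, Pfam, CATH or SCOPe. The
harness accepts those datasets when the user supplies files, but no claims
about them are baked into the tests.

## Problem sizes used by the test suite

The suite exercises the estimator at the scale where its guarantees are
stated: parameter recovery uses 50 families × 3 members × 2000 columns
(1.5 × 10⁵ weighted columns — the ±1 half-bit tolerance needs the rare-cell
counts that scale provides), convergence uses 12 families × 300 columns with
50 replicates per subset size, and the brute-force alignment oracle covers
sequence pairs up to length 6 over a 4-letter sub-alphabet, where exhaustive
enumeration of alignment paths is feasible.

## Known limitations

* The progressive aligner is intentionally minimal (see above); measured Q/TC
  values under it are not comparable to ClustalW2 or MAFFT output on hard
  references.
* The correspondence extractor assumes a single rigid superposition relates
  the chains; flexible or multi-domain pairs will yield partial blocks.
* The divergence interpolation is not a Markov evolutionary model; it cannot
  generate realistic site-rate variation.
* `identical_fraction` requires integer matrices; real-valued matrices must
  be rounded explicitly first.
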