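# Methods

## Pairwise identity

All identities come from optimal pairwise alignment under BLOSUM62 with
affine gaps (open 11, extend 1; a gap of length L costs
`open + (L−1)·extend`). Local (Smith–Waterman) alignment is the default
for network edges; the redundancy step uses global (Needleman–Wunsch)
alignment when two sequences differ in length by less than 20% and local
otherwise, since a global alignment of very different lengths is dominated
by terminal gaps.

**Identity convention.** Identity is `identical columns / length of the
shorter sequence` (the CD-HIT convention), *not* identical columns over
the alignment footprint. The distinction matters for thresholding: two
unrelated random proteins typically share a short high-scoring local
footprint whose footprint identity averages 0.35–0.50 (with maxima at
1.0 for short exact word matches), while their shorter-sequence identity
stays near the ~5% random background. A 40% network threshold separates
families only under the shorter-sequence convention; under the footprint
convention the network would wire unrelated sequences together. The
footprint size is still reported (`aligned_columns`).

Co-optimal alignments can differ in their number of identical columns, and
which one a traceback returns depends on argument order. `align_identity`
therefore puts each pair into a canonical order before aligning, making the
function exactly symmetric; the optimal *score* is order-invariant anyway.
The test suite checks the aligner against an independently written
exhaustive Gotoh dynamic programme that enumerates the full set of
(identical, columns) pairs achievable by any optimal alignment.

## Redundancy reduction and the network

Redundancy reduction is greedy incremental clustering in decreasing length
order (ties by input order): a sequence joins the first representative at
or above the 0.80 identity cutoff, else founds a new representative. Full
alignment identity is used rather than k-mer prefilter heuristics —
correctness over speed at library scale. Postconditions (members ≥ cutoff
to their representative; representatives pairwise below cutoff) are
asserted in tests across seeds.

The network connects representatives at ≥ 40% identity. Connected
components with ≥ 2 nodes are *main clusters*, ranked 1..K by decreasing
size with ties broken by lexicographically smallest member id (so cluster
ids are stable under input permutation); single nodes are singletons and
carry no convergence ratio. The convergence ratio of a cluster is realised
edges over possible edges, in (0, 1]. The top-K clusters define the
supervised label space; smaller clusters and singletons stay unlabelled.

## Synthetic corpus model

Each family descends from an independent ancestor drawn uniformly over the
20 standard residues; members apply independent per-site substitution at
rate `p_sub`, replacing a hit site by one of the 19 other residues
uniformly. Two members of one family then agree per site with probability
`(1−p)² + p²/19` (≈ 0.724 at p = 0.15), giving closed-form expectations
for every identity threshold in the pipeline. No indels, no positional
rate variation, no BLOSUM-biased composition — deliberately, so the
expectations stay analytic. Defaults: 10 families × 40 members, length
120, `p_sub` 0.15, chosen so the within-family identity (~0.72) sits
between the network threshold (0.40) and the redundancy cutoff (0.80), and
the length comfortably exceeds the ~100 residues needed for between-family
identity to concentrate far below 0.40.

What passing tests on this generator do **not** show: robustness to
indels and length variation, to real amino-acid composition, to the
tree-structured (rather than star-shaped) relatedness of real families, or
to the much weaker separability of real subfamily boundaries. The
generator makes the pipeline's logic testable; it does not certify
real-data performance.

## The language model

The encoder is a BERT-style post-layer-norm transformer over a 26-token
vocabulary (PAD, MASK, CLS, EOS, UNK + 21 residue symbols), with learned
positional embeddings. Default configuration: 5 blocks, width 512, 8
heads, feed-forward 2048, context 1024 (~17 M parameters); desk-scale
tests use 2 blocks at width 64. Pre-training is masked language
modelling: 15% of residue positions are selected per epoch (dynamic
masking), corrupted 80/10/10 (MASK / random residue / unchanged), and the
model is trained by natural-log cross-entropy at the selected positions
under a 95/5 train/validation split. The validation corruption is drawn
once so per-epoch validation losses are comparable.

The classification head applies self-attention layers (attention +
residual + layer norm; 2 by default) to the per-residue states, mean-pools
over residue positions, and maps through 3 dense GELU layers to a softmax
over the K clusters. With attention width 192 and dense stack 384-256-128
on a 512-wide backbone the head holds ~0.6 M parameters. During
task-training the backbone is frozen by default (encoder states are then
computed once and cached); a flag enables joint training. The split is
stratified by label so small clusters are never emptied from the training
side.

The whole neural core is NumPy with hand-written backpropagation (checked
against central finite differences in the test suite) and Adam. Everything
is float32; training is deterministic for a fixed seed on one BLAS backend.

**Optimisation defaults.** Pre-training: Adam, learning rate 1e-4, batch
32. Head training: learning rate 3e-3 for 60 epochs — at desk-scale
corpus sizes (a few hundred labelled sequences) the head underfits badly
at smaller rates/budgets; these are config entries, not constants, and
every operation accepts explicit settings. Gradient clipping is off by
default. Pilot runs at higher pre-training rates reached lower MLM loss
but did not transfer more reliably to the classification task, so the
conservative rate stays.

## Evaluation

Accuracy is the fraction of held-out sequences whose argmax cluster equals
the truth (argmax ties break to the smallest cluster id). ECE is
`exp(mean −ln p(true label))` with natural log — the 1-to-K perplexity
range fixes the base — and probabilities are clamped at 1e-12 before the
log so a confidently wrong prediction yields a large finite value rather
than infinity. The one-hot baseline trains the identical head architecture
on `max_length × 21` one-hot matrices (zero rows beyond the sequence end),
isolating the value of learned representations. Embeddings for
visualisation are mean-pooled final-block states projected by UMAP with a
fixed seed and `min_dist = 0`, so identical sequences may coincide in the
layout.

**Splits.** The training side gets `floor(f·n)` items, clamped to
[1, n−1]; at n = 100 the 95/5 and 80/20 splits are exact. The stratified
variant reaches the same global count by largest-remainder allocation
across classes.

## Pipeline determinism

One global seed is fanned out per stage by hashing the stage name
(CRC32 ⊕ scrambled seed, reduced below 2³¹), so a single integer
reproduces simulation, splits, masking, initialisation and shuffling.
The run manifest (`report.json`) records the version, the global and
per-stage seeds, all parameters, and the held-out sequence ids, which
suffices to re-execute or audit a run. If fewer clusters than the
requested top-K survive, the pipeline clamps K to the available clusters
with a warning (erroring out would make every small simulated run fail);
zero clusters is an error.

## Problem sizes in the test suite

Test and acceptance runs use desk-scale problems chosen as the package's
own study conditions: 8 families × 25 members at length 200 for network
recovery; 10 families × 40 members at length 120 with a 2-block width-64
encoder, 20 pre-training epochs and frozen backbone for the
semi-supervised experiment (three seeds, with the one-hot baseline on the
same splits); 20 sequences of length ≤ 60 for exhaustive oracle
comparison. At these sizes the full suite runs in minutes on one CPU.

## Known limitations

- No indel support in the synthetic generator; alignment handles gaps but
  the generator never produces them.
- The aligner reports one optimal alignment; identity is made symmetric by
  canonical pair ordering, but a different co-optimal identity may exist
  (the score is always unique and exact).
- CPU-bound NumPy training: practical up to ~10⁵ parameter encoders and
  thousands of sequences, not to the million-sequence regime real protein
  language models train in.
- The pipeline's cluster labels are structural (network components), not
  experimentally validated function labels; on real data clusters
  approximate isofunctionality at best, and low-convergence clusters are
  explicitly expected to mix functions.
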