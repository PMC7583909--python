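# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic data used for testing, and the limits of what
the tests demonstrate.

## Sequence canonicalization

Sequences are uppercased and U is mapped to T, so every encoder works over
the strict alphabet {A, C, G, T}. Ambiguity codes (N, R, Y, ...) are
rejected with an error naming the offending character and position, rather
than dropped or imputed: all downstream encoders assume a 4-letter
alphabet, and silent repair would corrupt k-mer and CTD statistics. miRNA
records longer than 30 nt are flagged (but kept) since mature miRNAs are
20–25 nt and longer entries usually indicate precursor sequences.

## Phase decomposition

Each RNA is split into three reading-frame sub-sequences starting at
positions 0, 1 and 2. These are the *suffixes* `seq[p:]`, not every-third-
base strides: the suffix reading preserves local 3-mer context in every
phase, so all encoders stay applicable to each sub-sequence. Every feature
category is computed once per phase.

## Feature encoders

**k-mer spectrum.** Overlapping windows with step 1; each k-block holds the
4^k mer frequencies (count / number of windows, i.e. each block sums to 1)
in lexicographic order A < C < G < T; k = 1..4 for lncRNAs (340 dims),
k = 1..3 for miRNAs (84 dims; 4-mers are too sparse in a ~22 nt sequence).
Frequencies rather than raw counts make the features length-free, so
lncRNAs and miRNAs live on comparable scales.

**CTD.** 30 dims: composition count(x)/L for x in A, T, G, C; transition,
for unordered adjacent pairs in order AT, AC, AG, TG, TC, GC, the number of
adjacent positions whose two distinct nucleotides form that pair divided by
L−1; distribution, for each nucleotide the 1-based positions of its
occurrence ranks {1, ⌈0.25 n⌉, ⌈0.50 n⌉, ⌈0.75 n⌉, n} divided by L. The
first rank is pinned to 1 (the "0%" occurrence is the first one), which is
what reproduces the worked example exactly. A nucleotide absent from the
sequence contributes zero composition and five zero distribution values,
keeping the layout fixed at 30.

Note a known inconsistency in the 20-nt worked example circulating for this
descriptor: the printed A↔T transition value 2/19 is incompatible with the
printed sequence — exhaustively counting adjacent {A,T} pairs gives 4/19,
and the six printed transition counts sum to 17 rather than L−1 = 19. The
implementation follows the definition (all six transitions sum to the
number of unequal adjacent pairs over L−1); all other printed values are
reproduced exactly.

**doc2vec (PV-DM).** The sequence is tokenized into overlapping 3-mers and
embedded with distributed-memory paragraph vectors: a center token is
predicted from the average of the paragraph vector and the in-window
(window 5) context token vectors. Because the vocabulary is the fixed set
of 64 3-mers, the softmax over the vocabulary is computed exactly — no
negative sampling — and the gradients for one document reduce to a few
dense matmuls, applied per document for 40 epochs with a linearly decaying
learning rate (0.25 → 0.01). Inference for an unseen document runs the same
updates on a fresh paragraph vector with token vectors frozen. Dimensions:
128 (lncRNA), 64 (miRNA). Training and inference are bit-reproducible for a
fixed seed (single worker).

**LNS similarity graph.** Per RNA kind, the phase-0 k-mer | CTD | doc2vec
vectors are concatenated into union vectors (498 dims for lncRNAs, 178 for
miRNAs). Each sample is reconstructed from its k_nn = 15 Euclidean-nearest
other samples by minimizing ‖x_i − Σ_j w_ij x_j‖² over the probability
simplex (w ≥ 0, Σ w = 1), solved by projected gradient descent with the
exact Euclidean simplex projection, step 1/λ_max(G), at most 1000
iterations, tolerance 1e-8; constraint violation is kept below 1e-6 and is
property-tested. One neighborhood size (15) serves both the reconstruction
and the top-15 edge rule, so a single knob controls graph density. The
graph links each node to its up-to-top-15 highest-weight strictly positive
neighbors; edges are undirected (union of directed selections). A node's
degree can exceed 2 × top_k when many rows select the same hub — only the
out-selection is bounded.

**Role-based node embedding.** The original role2vec leaves the role
construction open; here roles are derived from attributes alone: the union
vector is randomly projected to at most 64 dims, each projected dim is
median-split into 2 bins on the fitted data, and the bit signature is
hashed into 32 role buckets. Order-1 (memoryless, uniform) random walks —
10 per node, length 40 — are rewritten as role sequences, and a skip-gram
model over roles yields 128-dim role vectors; a node's embedding is its
role's vector. Because the role vocabulary is at most 32, the skip-gram is
trained full-batch on the (center, context) role co-occurrence counts with
an exact softmax (200 steps, learning rate 0.5 → 0.01) — the same objective
as sampled skip-gram with the sum over identical pairs collapsed. Roles
being a pure function of attributes is what lets unseen RNAs be embedded
after fitting (role lookup), which cross-validation relies on. This role
scheme is a declared departure point from motif-based roles: it bounds the
role vocabulary at desk scale and keeps the embedder deterministic.

## Histogram fusion

How a per-phase vector family maps onto a 20×20 plane is the main open
reconstruction choice in this pipeline, and the convention here is declared
rather than inherited: for each category, the three phase vectors are
min-max normalized jointly to [0,1]; each feature dimension i contributes
one 2-D point per phase pair — (v_pa[i], v_pb[i]) for (pa, pb) ∈ {(0,1),
(0,2), (1,2)} — and the channel is the 2-D histogram of those 3 × dims(c)
points on a uniform 20×20 grid (right edge of the last bin inclusive). A
category whose values are all equal normalizes to 0 and lands in the corner
cell. Properties that follow and are tested: channel mass equals
3 × dims(c); invariance to permuting dimensions within a category; and
invariance to positive rescaling. The graph embedding has no phase
structure, so the single node vector is replicated across phases, making
its channel diagonal-concentrated. Normalization is per-RNA and
per-category, so encoding a single RNA needs no corpus-level state.

## Classifier

Two convolutional towers with identical architecture and separate weights
process the lncRNA and miRNA tensors; each block is conv(3×3, stride 1,
ReLU) → batch norm → dropout(0.25), with filter counts (32, 64); there is
no pooling (spatial reduction is left to flattening). Tower outputs are
flattened, concatenated, and passed through dense(128, ReLU) →
dropout(0.5) → dense(1, sigmoid). Loss is binary cross-entropy; optimizer
Adam at 1e-3; batch size 64; up to 50 epochs with early stopping
(patience 10) on a 15% stratified validation split, restoring the best
weights. Histogram counts are log1p-compressed on input: corner cells can
hold hundreds of points while most cells hold a few, and raw counts at
that spread destabilize early training. A pair is called interacting iff
the predicted probability strictly exceeds 0.5; the threshold is fixed and
exposed only for downstream ranking. The network is implemented in numpy
(im2col convolutions, exact batch-norm backprop) and is deterministic for
a fixed seed; inference applies no dropout and uses running batch-norm
statistics.

## Negative sampling and cross-validation

Negatives are sampled once globally, before fold assignment: both id lists
are shuffled 10 times with the Knuth–Durstenfeld (Fisher–Yates) algorithm,
then pairs are drawn uniformly (one id from each list) and kept iff not
positive and not already drawn, until round(β × n_positives) are collected
(rejection cap 1e7 draws; infeasible β raises before sampling). Folds are
assigned at the pair level, stratified by label so each fold's positive
count is within one pair of the global fraction; stratification stabilizes
small-corpus evaluation and can be disabled. Pair-level splitting means an
RNA may appear in both training and test pairs — the sequences are shared
resources; only pair labels are split. A strict entity-disjoint mode
(folding by lncRNA) is available and off by default. Within each fold the
featurizer (doc2vec, LNS graph, role embedder) is fitted on the RNAs of
the training pairs only; test RNAs are encoded by doc2vec inference and
role lookup, so no test-pair information reaches the trainable encoders.

Metrics: SN = TP/(TP+FN), SP = TN/(TN+FP), ACC, F1 = 2TP/(2TP+FP+FN), and
the Matthews correlation coefficient in its standard form with the square
root in the denominator (a circulating variant omits the square root, but
that quantity is not the Matthews coefficient; MCC here is property-tested
to equal the Pearson correlation of the binary label vectors). Any metric
with a zero denominator is reported as undefined (None), never as 0. AUC
uses the Mann–Whitney rank formulation with midranks for ties and is
cross-checked against an independent implementation in the tests.

## Synthetic data

The generator emulates a curated interaction corpus at desk scale:
miRNAs 20–25 nt, lncRNAs 200–300 nt (the lower bound is the defining
lncRNA property; the range is kept narrow to keep desk-scale runs fast),
i.i.d. uniform base composition, and positive pairs drawn uniformly
without replacement from the lncRNA × miRNA universe. With the
`seed_complement` signal, each positive lncRNA receives the reverse
complement of its partner miRNA's seed (positions 2–8, the canonical
7-mer driving target recognition), substituted in place at a uniform
random offset so lengths stay in range. With `signal="none"`, labels are
independent of sequence — the null corpus used for leakage controls.

What the generator does **not** emulate: realistic GC skew or composition
bias, transcript-length distributions, paralog structure, hub miRNAs with
many targets (positive degrees are near-uniform), or thermodynamically
realistic binding (a single perfect 7-mer site stands in for it).

### What passing tests do and do not show

Every stage is verified against independent oracles (hand-enumerated
k-mer/CTD values, brute-force histogram binning, simplex grid search,
MCC–Pearson equivalence), the pipeline is leakage-controlled (shuffled
labels stay at chance), and the classifier demonstrably learns separable
tensor inputs. However, the end-to-end cross-validated AUC on the planted
corpus sits at chance, and the analysis shows why: the planted cue is a
*single* 7-mer site in a 200–300 nt lncRNA, which shifts composition-level
features (k-mer frequencies, CTD) by well under one standard deviation of
their sampling noise; direct motif matching on the raw sequences scores
AUC ≈ 0.97 on the same pairs, while a gradient-boosted tree on the
concatenated pre-fusion feature vectors scores ≈ 0.5 even at 10× corpus
scale. The histogram fusion further removes dimension identity (it is
permutation-invariant by design, which the tests require), so
cross-matching a specific lncRNA site to a specific miRNA seed is not
representable from the fused tensors. The pipeline's discriminative power
on real corpora therefore rests on corpus-level regularities (homology and
composition structure among interacting RNAs) that the i.i.d.-uniform
generator deliberately lacks — a desk-scale corpus with a single planted
site is a sound control for leakage and plumbing, but not a demonstration
of biological signal recovery, and results on real data should be read
with that in mind.

## Numerical choices and degenerate inputs

* LNS: stable argsort for neighbor ties; all-identical rows give objective
  0 and any simplex solution is accepted.
* Histogram: right edge of the last bin inclusive (maximal values are not
  dropped); constant categories map to the corner cell.
* Batch norm requires ≥ 2 samples; trailing odd single-sample batches are
  skipped during training.
* Early stopping is disabled automatically when the validation split would
  be smaller than 2 samples or single-class.
* Seeds: every stochastic component (generator, sampler, fold shuffle,
  embedder init, walks, dropout, batch order) flows through an explicit
  `numpy.random.Generator`; identical seeds give bit-identical runs on a
  single worker.

## Problem sizes used in the shipped checks

The bundled end-to-end checks run the default desk-scale corpus (50
lncRNAs, 20 miRNAs, 100 positives, β = 1) with 2-fold cross-validation,
10 seeds for the learnability check and 5 seeds for the shuffled-label
control and the ablation ordering; per-fold featurizer fitting takes
roughly 10 s and classifier training 10–15 s on one CPU.
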