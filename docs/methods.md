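# Methods

`hybriclass` implements an instance-based image classifier realized in
DNA sequence space.  Labeled images are encoded as 59-nt strands and
grouped into per-class "tubes"; a query image is encoded the same way,
its reverse complement acts as the probe, and the query is assigned to
the class whose tube gives the largest summed equilibrium hybridization
yield against the probe.  Specific hybridization (a strand meeting its
exact reverse complement) gives yield ≈ 1; non-specific hybridization
between partially complementary strands gives intermediate yields, and
it is this graded signal that carries the similarity structure.

This note records the model choices, the parameters that matter, and
the places where the design was genuinely open.

## Thermodynamic yield model

The default yield oracle is a transparent two-part model:

1. **Duplex free energy.**  The minimum ΔG° over all antiparallel
   ungapped registrations of the two strands.  Within a registration, a
   conformation chooses which Watson–Crick-pairable positions actually
   pair; adjacent paired positions contribute the tabulated
   nearest-neighbor stack ΔH − T·ΔS (unified parameter set, bundled as
   `data/nn_params.txt` with its citation), a gap of m unpaired interior
   positions costs min(m · 1.0, 3.0 + 0.5·(m−1)) kcal/mol (a fixed
   per-mismatch penalty or an affine loop, whichever is cheaper), and
   one initiation term is charged per duplex.  The optimum over
   conformations is found by a linear-time dynamic program per
   registration (prefix minima handle the two gap cost families); a
   brute-force enumeration over all registrations and all subsets of
   pairable positions serves as the test oracle at lengths ≤ 12.
2. **Two-state equilibrium.**  A + B ⇌ AB with both strands initially
   at c₀ and K = exp(−ΔG°/RT) (reference 1 M).  The duplex fraction
   ("yield") solves K·c₀·(1−y)² = y; the numerically stable root is
   y = 2x / (2x + 1 + √(4x+1)) with x = K·c₀, exact in both the x → 0
   and x → ∞ limits and verified against bisection to 1e-9.

Default reaction conditions: 25 °C, c₀ = 1 nM, complexes of at most two
strands.  R = 1.98720425864083e-3 kcal/(mol·K).

Deliberate omissions (the main fidelity gaps relative to a
partition-function calculation): intramolecular secondary structure,
complexes larger than two strands, salt correction, dangling ends, and
full mismatch-specific nearest-neighbor tables (a single constant per
internal mismatch instead).  A different oracle can be swapped in
through `thermo.register_adapter` and the `external_adapter` backend.

A consequence worth stating up front: with a *minimum*-energy duplex and
a two-state isotherm, the melting transition of a 59-nt duplex at 1 nM
is extremely sharp.  A random 59-mer against its reverse complement has
ΔG° ≈ −90 kcal/mol; the yield stays ≈ 1 until roughly 21 point
mutations and collapses to ≈ 0 by roughly 32.  Several design choices
below exist because of this cliff.

## Sequence-pair corpus

Predictor training pairs are 59-nt, homopolymer-free (no run of three
or more identical bases), labeled by the backend above, deduplicated as
unordered pairs, and balanced across ten equal-width yield bins (the
last bin right-closed, so a label of exactly 1.0 is in-range).  Two
independent random strands have yield ≈ 0 almost surely, so coverage of
the upper bins comes from a mutated-complement construction: a random
strand paired with a k-point-mutated copy of its reverse complement.
With k drawn uniformly on 0..59, intermediate yields are still rare
(≈ 0.4% of draws per middle bin) because of the melting cliff, so a
third mixture component confines k to the transition window
(0.32–0.56 of the length).  `generate_balanced_pairs` draws adaptively
— shifting to the transition component once the extreme bins are full —
until every bin holds its quota (20,000 pairs total at the default
2,000 per bin, typically ~120k draws, a few tens of seconds).
Mutations are applied constructively so that every intermediate string
stays homopolymer-free.

## Stage 1 — feature extractor

A LeNet-5-style CNN (conv 5×5/6 channels, 2×2 max-pool, conv 5×5/16,
pool, then fully connected 400→120→50→10, ReLU activations) trained
with Adam on cross-entropy.  The 50-wide second fully connected layer
(FC2) is the feature vector; all parameters are frozen afterwards.
Euclidean distance E between FC2 vectors, in raw activation units with
no normalization, is the image-similarity signal used downstream.

## Stage 2 — yield predictor

A two-layer CNN regressor over the stacked one-hot pair: channel 1 is
the first sequence, channel 2 the reverse complement of the second, so
a perfectly hybridizing pair presents as two identical 4×59 layers.
Layer 1 convolves all four base rows jointly (kernel 4×5, 32 channels),
layer 2 is 1×5 with 64 channels; features are averaged over positions
(duplex energy is approximately additive along the helix) and a sigmoid
head emits a yield in [0, 1].  Training minimizes MSE against the
labeled corpus (Adam, lr 3e-3, 20 epochs, 10% held out).

Measured fidelity on the balanced 20k corpus: held-out MSE ≈ 0.05,
Spearman ρ ≈ 0.65.  The limit is structural, not an optimization
artifact: the oracle's ΔG° is a minimum over registrations and
conformations — akin to a maximal-scoring-segment statistic — so
mid-transition yields depend on *where* the mismatches fall in a way no
small position-local model represents (an additive reconstruction of
ΔG° from the alignment at zero offset mispredicts with MSE ≈ 0.22).
Wider kernels, max-pooling paths, weight decay, longer schedules and a
3× corpus all plateaued at the same level, trading bias for variance.
On its training manifold the model is nonetheless well calibrated where
it matters: its yield-vs-mutation-count curve crosses 0.8 at ≈ 19
mutations, close to the true transition onset (≈ 21).

## Stage 3 — encoder

Two linear layers, 50 → 256 → 4×59, column-wise softmax; the decoded
sequence is the per-column argmax (ties broken in the fixed row order
A, T, C, G).  The objective has two parts:

* **Encoding loss**: any column whose maximum probability is below 0.5
  pays cross-entropy against the one-hot indicator of its own argmax
  (exactly −ln of the column maximum); confident columns pay nothing.
* **Sequence loss**: image pairs that are close in feature space
  (E < T1) with the same label should reach yield ≥ T2 = 0.8; pairs far
  apart (E ≥ T1) with different labels should reach a low yield.  Close
  pairs with different labels and far pairs with the same label are
  deliberately unconstrained.

T1 is calibrated per corpus as the 8th percentile of pairwise feature
distances on a 400-image sample.  On the synthetic glyph corpus this
lands between the intra-class distance mode (median ≈ 9) and the
inter-class mode (≈ 19+), covering ≈ 97% of same-class pairs while
leaving < 3% of different-class pairs unconstrained.  A higher
percentile that lands inside the inter-class distribution exempts the
most confusable class pairs from any separating force, and they
measurably collapse onto a single sequence.

### How the loss is descended

The 0/1 sequence loss has no useful gradient, so training uses hinge
surrogates — but three details, each forced by instrumented failures,
decide whether training produces genuine separation:

1. **The low-yield margin is 0.05, not T2.**  Because of the melting
   cliff, a different-class pair whose yield has just dropped below 0.8
   is typically ~20 mutations apart — still fully bound at equilibrium.
   Repulsion therefore runs until the yield falls below ``t_low`` = 0.05,
   which corresponds to genuine separation past the cliff.
2. **Branches are gated by the thermodynamic backend, not the neural
   predictor.**  If the frozen predictor's estimate decides when a pair
   is "done", gradient descent reliably parks cross-class pairs in the
   predictor's blind spots: layouts where the predictor reports ≈ 0.05
   while the true equilibrium yield is 1.0 (measured repeatedly, also
   on homopolymer-free sequences).  The backend's two-state yield of
   the *decoded* pair costs ~0.1 ms and cannot be gamed.
3. **The descent direction is the base-agreement gradient.**  The
   classification duplex pairs an instance strand with the reverse
   complement of the query's, so two images hybridize strongly exactly
   when their soft matrices agree column-wise.  Active pairs are pushed
   along (attraction) or against (repulsion) their partner's soft
   matrix — the gradient of the inner product Σⱼ⟨p1ⱼ, p2ⱼ⟩, the
   differentiable leading term of duplex stability.  Using the
   predictor's input gradient instead is adversarially exploitable (its
   level sets are wrinkled; runs ranged from accuracy 0.1 to 0.9 across
   sampling seeds), while the agreement direction moves the true yield
   monotonically (accuracy 1.0 across seeds under otherwise identical
   conditions).

The predictor remains frozen throughout stage 3, supplies the estimated
yield recorded in the loss values and training diagnostics, and is the
artifact whose fidelity stage 2 measures; it is not the transport of
the stage-3 gradient.

Two regularizers complete the objective.  A differentiable homopolymer
penalty (the sum over bases and 3-column windows of the product of the
base's three probabilities, weight 0.5) keeps outputs inside the
homopolymer-free space the predictor was calibrated on — also the space
synthesis prefers; outputs are never filtered, and the realized
homopolymer rate is reported (≈ 0 after training, ≈ 100% without the
penalty).  The encoding loss joins only for the last 30% of epochs:
it does not affect the decoded sequence (argmax), and switching it on
from the start saturates the softmax columns, freezing the layout
before the sequence forces have organized it.

Training: Adam, lr 1e-3, 35 epochs × 4096 sampled pairs (batch 64),
pair sampling uniform with a 50% same-label forcing rate.  Stage 3 only
updates encoder parameters; parameter checksums of the extractor and
predictor are asserted unchanged.

## Classification

Every training image is encoded and stored in its class tube
(duplicates kept — a tube is a multiset of strands).  A query is
encoded, its reverse complement becomes the probe, yields are computed
pairwise between probe and every instance at the stated conditions
(each pair in isolation at 1 nM; no one-pot competition), summed per
tube, and the argmax class is returned (ties → smallest label, with a
warning).  Evaluation reports overall and per-class accuracy, the
confusion matrix, and each misclassified query with its per-tube yield
sums; `top_k_neighbors` ranks all instances by yield for
neighbor-retrieval views.

## Synthetic corpus

Ten hand-designed stroke templates loosely shaped like the digits 0–9,
rendered at 4× resolution with per-image affine jitter (rotation ±15°,
translation ±2 px, scale 0.9–1.1), stroke width 1.5–2.5 px, bilinear
downsampling to 28×28 and clipped additive Gaussian noise (σ = 0.05).
Classes 4 and 9 share a closed-head-plus-tail layout so the corpus has
a genuinely confusable pair.  What the generator does *not* emulate:
handwriting stroke statistics, the long tail of malformed digits, or
MNIST's intra-class multimodality (e.g. crossed vs. open 7s) — so
passing results here demonstrate that the machinery works end to end
under controlled conditions, not that MNIST-level accuracy transfers.
Real MNIST IDX files are read by `synthetic_data.read_idx` and the
full-scale protocol is the same code with larger sizes and, optionally,
an external yield adapter.

## Scaled-down study conditions

The default experiment (tests and the acceptance script): 10 classes ×
200 training images, 100 queries (10 per class), 20,000 balanced
predictor pairs, surrogate loss, one global seed fanned out to
per-stage seeds via `SeedSequence`.  A full run takes ≈ 2.5 minutes on
one CPU.  Typical results: backbone validation accuracy 1.0, predictor
held-out MSE ≈ 0.05, classification accuracy 1.0 with mean same-class
yield ≈ 1.0 against mean different-class yield ≈ 0.01–0.04.

## Numerical and degenerate-input conventions

Argmax ties in decoding follow the fixed row order A < T < C < G.
Sequences shorter than 2 nt, or pairs with no complementary bases at
any registration, return the no-binding sentinel (+∞ ΔG°, yield 0).
Yields are clamped nowhere — the closed form is in [0, 1] by
construction.  All networks are float64 with He-uniform initialization
from seeded generators; training is single-threaded deterministic given
the seed.  Empty FASTA files parse to empty lists; lowercase or
non-ACGT characters are rejected with the offending position named.

## Known limitations

* The two-state oracle understates the softness of real (ensemble)
  hybridization; with a partition-function backend the predictor's task
  would be smoother and its fidelity numbers better than reported here.
* The neural predictor is a diagnostic-grade surrogate (MSE ≈ 0.05 on
  the balanced corpus), not a replacement for the backend; the
  classifier never uses it.
* Classification treats each probe–instance pair in isolation;
  competitive binding in a real one-pot tube is out of scope.
* The glyph corpus is easier than MNIST; headline accuracies here do
  not predict accuracy on handwritten digits.
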