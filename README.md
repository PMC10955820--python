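# hybriclass

Instance-based image classification carried out in DNA sequence space.

Non-specific hybridization — the partial binding of strands that are
similar but not perfectly complementary — is a natural molecular
measure of similarity.  `hybriclass` builds a classifier on top of it:
every labeled image is encoded as a 59-nt DNA strand by a trained
neural encoder and stored in the "tube" of its class; to classify a
query image, the reverse complement of its encoded strand is used as a
probe, the equilibrium hybridization yield of the probe against every
stored instance is computed, yields are summed per tube, and the class
with the largest sum wins:

```
label(q) = argmax_c  Σ_{s ∈ tube_c}  yield( s , revcomp(enc(q)) )
```

The yield of a strand pair is the equilibrium duplex fraction
[AB]/c₀ of the two-state reaction A + B ⇌ AB at 25 °C and 1 nM, with
the duplex free energy from a nearest-neighbor stacking model
(minimum over registrations and pairing conformations, computed by
dynamic programming).  A perfectly complementary 59-nt pair has yield
≈ 1; unrelated random strands ≈ 0; the graded region in between is
what encodes similarity.

Training proceeds in three stages, all on one CPU:

1. **feature extractor** — a LeNet-5-style CNN for 28×28 grayscale
   digits; the 50-D second fully connected layer is the image feature.
2. **yield predictor** — a two-layer CNN regressing the yield of a
   one-hot sequence pair, trained on a yield-balanced corpus of 20,000
   labeled random pairs.
3. **encoder** — two linear layers with column-wise softmax mapping the
   50-D feature to a 4×59 base matrix, trained (with stages 1–2 frozen)
   so that images that are close in feature space with the same label
   give high-yield pairs and distant different-label images give
   low-yield pairs.

A built-in synthetic glyph corpus (ten digit-like stroke templates with
affine jitter and noise) makes the whole pipeline runnable without any
download; real MNIST IDX files are read directly when available, and an
external yield oracle (e.g. a NUPACK installation) can be plugged in
via `thermo.register_adapter`.

## Worked example

```python
from hybriclass import pipeline

run = pipeline.run_full(pipeline.PipelineConfig(seed=7))
ev = run["evaluation"]
print(f"accuracy {ev.overall_accuracy:.2f}")
print(f"intra-class yield {run['yield_stats']['mean_intra_yield']:.3f} "
      f"vs inter-class {run['yield_stats']['mean_inter_yield']:.3f}")
print(ev.confusion_matrix)
```

prints (≈2.5 minutes on one CPU):

```
accuracy 1.00
intra-class yield 1.000 vs inter-class 0.014
predicted   0   1   2   3   4   5   6   7   8   9
true
0          10   0   0   0   0   0   0   0   0   0
1           0  10   0   0   0   0   0   0   0   0
2           0   0  10   0   0   0   0   0   0   0
3           0   0   0  10   0   0   0   0   0   0
4           0   0   0   0  10   0   0   0   0   0
5           0   0   0   0   0  10   0   0   0   0
6           0   0   0   0   0   0  10   0   0   0
7           0   0   0   0   0   0   0  10   0   0
8           0   0   0   0   0   0   0   0  10   0
9           0   0   0   0   0   0   0   0   0  10
```

All 100 held-out glyph queries are routed to the right tube: a query's
probe hybridizes essentially completely (yield ≈ 1) with the ~200
same-class instance strands and almost not at all (yield ≈ 0.01) with
other tubes, so the yield sums separate cleanly.  The same objects are
available stepwise (`make_corpus`, `stage1_backbone`,
`make_pair_corpus`, `stage2_predictor`, `stage3_encoder`) and from the
command line:

```
hybriclass make-data        --workdir run --seed 7
hybriclass generate-pairs   --workdir run --seed 7
hybriclass train-backbone   --workdir run --seed 7
hybriclass train-predictor  --workdir run --seed 7
hybriclass train-encoder    --workdir run --seed 7
hybriclass build-library    --workdir run --seed 7
hybriclass evaluate         --workdir run --seed 7
```

Artifacts are plain formats: the instance library as FASTA with
`classLabel|instanceIndex` headers, pair corpora as TSV, corpora as
MNIST-style IDX, results as TSV, plus a JSON manifest per stage.

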