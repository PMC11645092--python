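# Methods

## The pipeline

`gazeattr` implements an end-to-end gaze-based screening pipeline for
distinguishing ASD from typically-developing (TD) viewers from their
scanpaths on natural images, together with training-data attribution and
dataset distillation on top of the trained classifier.

The stages:

1. **Decomposition.** Aggregated scanpath files (four columns: within-
   participant fixation index, x, y, duration in ms; a new participant
   begins at every index-0 row) are split into per-participant scanpaths
   s_{i,j}.  The decomposition is unique: the number of scanpaths equals the
   number of index-0 rows, and concatenating them reproduces the file.
2. **Augmentation.**  Individual scanpaths are often very short (as few as
   two fixations).  Durations are rescaled per scanpath to integers in
   [1, 100]; each fixation is replicated according to its scaled duration;
   each replica receives an independent uniform integer shift
   Δx, Δy ∈ [−10, 10] and is clipped to the image.  Fixation maps are
   rendered from the original (pre-jitter) fixations as the union of
   radius-10 Euclidean disks.
3. **Classification.**  A three-branch network: a CNN over the stimulus
   image, an identically shaped CNN over the fixation map, and an LSTM over
   the (x, y) fixation sequence whose final hidden state h_T summarizes the
   scanpath.  Each branch feeds a linear head reducing it to one scalar
   (O_img, O_fix, O_scnpts); the concatenated 3-vector passes through a
   final linear layer and a sigmoid to give P(ASD).  Loss is binary
   cross-entropy; the optimizer is Adam; a parameter snapshot w(i) with its
   learning rate η_i is stored after every epoch.
4. **Attribution (TracIn).**  Training is replayed over the k stored
   checkpoints:

       self_influence(x)  = Σ_i η_i ⟨∇l(w(i), x), ∇l(w(i), x)⟩
       influence(x, x')   = Σ_i η_i ⟨∇l(w(i), x), ∇l(w(i), x')⟩

   High self-influence flags outliers and mislabeled samples; strongly
   positive (negative) influence on a test sample marks a proponent
   (opponent).
5. **Distillation.**  The samples with the highest self-influence are
   removed from the training set to a target usage tier (77%, 67%, 50% by
   default); the model retrained on the survivors is SIST, a random subset
   of identical size gives the RST control, and the full-data model is FT.
   The test split is fixed and shared by every variant.

## Network engine

The network, backprop, and Adam are implemented directly over NumPy float64
arrays (`gazeattr.nn`): 3×3 same-padding convolution via sliding windows,
2×2 max pooling, global-average-pool or flatten reductions, an LSTM with
variable-length masking (state is carried through padded steps, so
`h[:, -1]` is each sequence's true final state), inverted dropout, and a
numerically stable sigmoid/BCE pair.  Gradient correctness is enforced in
the test suite against central finite differences at 1e-4 relative error,
and the vectorized attribution path is checked against a naive per-sample,
per-checkpoint accumulation at 1e-10.

Per-sample gradients for attribution default to the final fusion layer
("last_layer", 4 parameters), the standard scalable TracIn practice; a
"full" mode differentiates every parameter and is used by the oracle tests
and the category-attribution analysis where gradient direction matters.

## Configurations

`GBACConfig` defaults mirror the reference architecture: conv filters
[32, 64, 128, 256] with 3×3 kernels in both CNN branches, a 2-layer LSTM of
hidden size 1024 with dropout 0.3 (input sizes 2 and 1024), sigmoid + BCE,
Adam, 16 epochs, r = 5 seeded runs.  Input image size (128×128), learning
rate (1e-4), and batch size (32) are not architectural constants and are
config fields.

`desk_config()` is the reduced preset used by every synthetic experiment in
the tests and the acceptance script: 32×32 inputs, conv filters (8, 16),
1 LSTM layer of hidden size 16, 8 epochs, batch 16, learning rate 1e-2,
original (non-replicated) scanpaths to the LSTM, and a **flatten** final
reduction in the conv branches instead of global average pooling.  The
flatten choice is load-bearing: GAP is translation invariant, and the
planted class signal (below) is *where* fixations land, which GAP provably
cannot see; on a perfectly separable toy corpus the flatten preset fits to
1.00 training accuracy within budget while GAP stalls.  At paper scale the
default remains GAP after the fourth conv block (`final_pool="gap"`).

Other numerical choices: duration rescaling rounds half away from zero (so
the midpoint of [1, 100] maps to 51); a degenerate duration range (all
equal) maps every fixation to 50; jitter offsets are integers; jittered
points are clipped to bounds rather than resampled, preserving the
replica-count invariant Σ replicas = Σ scaled durations; fixation maps are
binary by default with a count-map option; ranking ties break by sample id.

## Synthetic data

The generator (`gazeattr.synth`) emulates the structure of an aggregated
child eye-tracking corpus at desk scale: 30 stimuli × (5 ASD-like + 5 TD)
participants = 300 records by default, stimuli in three categories
(people / objects / landscapes) with seed-determined textures, fixation
counts uniform in [2, 20], log-normal millisecond durations
(μ = log 250, σ = 0.5), and optional label noise that flips exactly
round(rate·N) uniformly chosen records.  Everything is written to disk
(PNG stimuli, scanpath text files, manifest CSV) and read back through the
package's own parsers.

The planted class effect mirrors the clinical finding the real classifier
exploits — reduced attention to socially relevant image regions: each
"people" image carries a social region (a high-contrast disk placed near
the frame center, as faces tend to be in photographs), and a fixation lands
inside it with probability 0.7 for TD viewers vs 0.3 for the ASD-like
class, uniformly outside it otherwise.  Non-people images use the same
spatial law for both groups, so only people images carry signal — which
gives category-level attribution a recoverable ground truth.  Category
counts are a fixed largest-remainder apportionment of the mix (a curated
stimulus set), not an i.i.d. draw; an i.i.d. draw leaves the number of
signal-bearing images to chance and destabilizes every downstream
experiment at this scale.

What the generator does **not** model: saccade dynamics, center-bias and
saliency structure of real gaze, participant-specific styles, fixation
durations correlated with content, or any fitted distribution from real ASD
data.  Passing the synthetic experiments therefore shows the pipeline's
machinery recovers planted effects of realistic shape and size — not that
the classifier would reach any particular accuracy on clinical data.

## The synthetic experiments

Three experiments exercise the attribution/distillation claims end to end
(seeds fixed in the tests; derived from `--seed` in the acceptance script):

**Noisy-label recovery.**  Corpora of 300 records with 10% flipped labels;
per seed, the model trains on everything and samples are ranked by
self-influence.  Success means the flipped samples' mean percentile exceeds
the clean samples' in ≥ 4 of 5 seeds.  This experiment uses an all-people
corpus: label noise is only meaningful where the true label is predictable
from the data.  On signal-free images a flipped record is statistically
identical to a clean one, and worse, a flip creates an image-level label
majority that the image branch can fit, systematically *lowering* the
flip's self-influence — the experiment would measure memorization dynamics,
not label-noise detection.

**SIST vs RST.**  Same corpus design; one corpus, a fixed 60/10/30
train/val/test split, r = 5 training seeds; at the 77% tier the
self-influence-filtered subset (SIST) is compared against size-matched
random subsets (RST) on the shared test split.  The self-influence ranking
here uses the checkpoints from the first half of training
(`ranking_checkpoints="first_half"`): by the final epochs the reduced model
has begun to memorize the flipped samples, shrinking exactly the gradients
the filter needs (measured flip enrichment in the removed set roughly
doubles with early checkpoints).  The SIST−RST accuracy contrast at this
scale is small (a few points) relative to run-to-run noise; it was positive
in 5 of 6 probed corpora.  This fragility is a property of the desk-scale
regime (tiny test sets, weak planted signal), not of the method.

**Category attribution.**  Mixed corpus, clean labels; after training,
pairwise influence of every training sample on the correctly classified ASD
test samples is aggregated by stimulus category.  Categories are ranked by
the **signed** mean influence: attribution noise produces large entries of
both signs that cancel in the mean, while systematic support survives, so
the signed mean isolates the category the network actually learned from.
(A positive-part mean rewards high-variance noise from the signal-free
categories and inverts the ranking; both columns are reported.)  Success
means "people" ranks first in ≥ 4 of 5 seeds.

## Known limitations

- The engine is CPU-bound NumPy; paper-scale configurations (1024-unit
  LSTMs over replicated sequences) train slowly and are intended as
  documentation of the reference architecture, not as a performant path.
- Record-level splits share stimuli and participants between train and
  test; the participant-disjoint split mode exists precisely because the
  record-level number is optimistic about new-child generalization.
- Last-layer attribution compresses gradients to 4 dimensions; analyses
  that depend on gradient *direction* (category attribution) are more
  faithful in full-gradient mode.
- The SIST/RST contrast at desk scale is directional, not a calibrated
  effect size.
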