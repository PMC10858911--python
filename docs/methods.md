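# Methods

This note records the models, conventions and numerical choices behind
`fireflash`, and what the synthetic experiments do and do not demonstrate.

## Trajectorization

Flash detections are (frame, x, y, z) points at 30 fps. Streak linking is
greedy nearest-neighbour per frame step: each open streak is extended by at
most one detection of the next frame within the streak radius. The radius is
not pinned down by any published measurement; the default of 0.2 m per frame
step is a generous bound on inter-frame flight displacement (a firefly
cruising at ~1 m/s moves ~0.03 m per frame) and is exposed in the API.

Streak-to-trajectory linkage joins two streaks when the later one starts
within 1 s after the earlier one ends and the earlier streak's end position
is within 1 m of the later streak's start position; trajectories are the
connected components (transitive closure) of this relation, computed by
union-find. Endpoint-to-endpoint distance is the simplest reading of the
proximity rule; minimum pairwise distance between streaks would be a
configurable alternative but changes nothing for well-separated individuals.
Streaks overlapping in time are never linked: one firefly cannot flash in
two places at once. Frames are 0-based and each binarized sequence's time
axis starts at its first flash frame, so all sequences start and end with 1.

Cleaning fills interior zero-runs of 1-2 bits (< 0.07 s at 30 fps), which
are dropped-frame/occlusion artifacts, and is idempotent. Cleaning runs
*before* the single-flash threshold so that flashes reconnected by filling
count as one pattern. The bit-based rule is kept at other frame rates, where
the 0.07 s equivalence no longer holds.

## Reference templates

Literature references are entered as alternating on/off durations in
seconds (from published timing measurements; six of the seven study species
have one, *B. wickershamorum* has none and is represented by absence rather
than a zero template). Each segment is rendered as `round(duration * 30)`
bits with a one-bit floor. Population references average a species' training
sequences: sequences are left-aligned at their first flash — the only
alignment landmark every sequence shares — and zero-padded right to the
maximum length. The average is real-valued in [0, 1]; the same
intersection/dot-product formulas apply with real template values.

## Baseline classifiers

The Jaccard variant used here defines the union as the *summed* on-mass of
both sequences (not the set union), so identical binary sequences score 0.5;
the bound `score <= 0.5` is asserted as a property. The DTW distance is the
classic |a_i - b_j| local-cost dynamic program without a window constraint.
Score vectors are converted to probabilities by a temperature-1 softmax;
DTW distances are negated first so that closer references are more probable
— the literal "arg max of the softmax of the distances" would select the
most distant species. Ties break toward the lowest label-encoded (sorted
name order) species, deterministically. The SVM uses an RBF kernel (C = 1,
kernel width `1/(n_features * var)`, i.e. sklearn's `gamma="scale"`) on
standardized (flash count, mean duration, mean gap) features, with
Platt-scaled pairwise-coupled probabilities.

## GRU classifier

The recurrent core is the standard gated recurrent unit (reset gate, update
gate, tanh candidate state), two layers of 128 units, fed one sequence bit
per timestep. The readout head is deliberately minimal: a LeakyReLU with
negative slope 0.1 applied to the final hidden state of the top layer,
followed by a single affine map to species logits. The activation placement
(between the recurrent stack and the readout) is one of several defensible
readings of "activation layers" and is configurable.

Forward, backpropagation through time and the Adam optimizer are
implemented directly in NumPy; gradients are validated against central
finite differences in the test suite (agreement to ~1e-10). Variable-length
batches are right-padded with an explicit mask that freezes the hidden
state past each sequence's end, so the state at the last padded timestep
equals the state at the true end; batched and unbatched passes agree to
1e-5 by contract. Training uses cross-entropy, global-norm gradient
clipping at 0.1, early stopping on validation loss with patience 50, a
safety cap of 1000 epochs, and returns the parameters of the
best-validation-loss epoch. One master seed drives initialization and
shuffling. Default batch size 8 and learning rate 1e-5 follow the protocol
selected for the full field dataset from the grid {8, 16, 32} x
{1e-3, 1e-4, 1e-5}.

## Cross-validation, metrics and sympatry

The 60-fold stratified scheme is realized as 6 repeats of stratified
10-fold, which guarantees (rather than makes merely probable) that every
sequence is tested at least once and never appears in a fold's training and
test sides simultaneously. Within each fold the 90% training pool is
randomly undersampled without replacement to the minority-class count, a
stratified 10% validation split is carved from the equalized pool, and all
remaining sequences join the test side. Metrics are support-weighted
precision/recall and accuracy (checked against a brute-force per-class
tally), row-normalized confusion matrices, and one-vs-rest ROC curves.

The artificial-sympatry experiment mixes two species' held-out sequences at
a proportion p of a 400-sequence set (2/398 at p = 0.005 up to 200/200 at
p = 0.5) and reports each species' mean true-positive rate over 500 seeded
iterations; sampling is without replacement unless a held-out pool is
smaller than the request. Because every classifier here is deterministic at
inference, each held-out sequence is classified once and iterations
resample cached per-sequence outcomes — statistically identical to
reclassifying every sampled set, at a small fraction of the cost.

## Confidence filtering and characterization

The top-100 filter keeps, per population, the correctly classified
sequences with the highest maximum softmax probability (ties broken by
ascending dataset index; all of them if fewer than 100 qualify), verified
against an independent re-sort of the full prediction table. All gaps and
durations are pooled at the event level — each gap and each flash
contributes one observation, each sequence one flash count — because the
target distributions are event-level; per-sequence averaging converges to
the same means for i.i.d. data. Histogram bins default to 1 flash and one
frame (1/30 s). Both raw and filtered characterizations can be computed.

## Synthetic generator

The generator emulates the study conditions: per-population flash count,
inter-flash gap and flash duration are drawn from normal distributions with
the means and standard deviations measured for the twelve filmed
populations, then quantized to the frame grid (round half away from zero,
for cross-platform determinism). Floors — 2 flashes, 1 frame per flash,
3 frames per gap — keep every generated sequence a fixed point of the
cleaning rule and of the single-flash threshold. Normality is an emulation
choice; the field distributions are published only as mean +/- sd. The
rounded-normal quantization preserves means to well under a frame whenever
the sd exceeds ~0.3 frames, which holds for the statistics the recovery
experiments target; very short flashes (e.g. 0.04 s ~ 1.2 frames) pin at the
1-frame floor and would recover biased low, so no recovery target uses them.
Swarm mode embeds each firefly as a reflected Gaussian random walk in a box
arena and emits its on-frames as detections with optional positional noise
and frame drops, returning the planted firefly identity per event for
round-trip tests.

What passing synthetic tests shows: the pipeline's operations are correct
under the stated model (linkage recovers planted individuals that stay
separated by more than the linkage distance; statistics recover planted
means through quantization; classifiers separate species whose parameter
ranges are disjoint). What it does not show: performance on real recordings
with overlapping individuals, partial patterns, camera-sensitivity flash
trimming, or temperature-driven drift — the field-dataset results quoted in
the README require the deposited recordings.

## Experiment sizes and configurations

The separable two-species task used by the classification and sympatry
experiments pairs a short-pattern species (2-3 flashes, 0.30 s gaps, 0.10 s
flashes) with a long-pattern species (15-16 flashes, 0.80 s gaps, 0.20 s
flashes), 200 training / 50 validation / 50 test sequences per species.
Within-species sds are kept at 0.02 s (0.5 flashes) — comparable to the
tightest filmed populations — because template averaging decoheres under
larger length jitter, and the task is meant to be separable by *every*
classifier family. The GRU for this task trains with learning rate 1e-3 and
batch size 8 (from the protocol grid; the separable task converges in a few
epochs, so epochs are capped at 6). Parameter-recovery experiments use
10,000 sequences per preset. DTW's known sensitivity to averaged-template
blur at high within-class variance is a property of the method, mirrored in
its weak field-data recall.

## Known limitations

Single-flash species and patterns with >1 s dark periods cannot be
trajectorized under the 1 s linkage rule, so the pipeline never sees them
end to end. The streak radius and the endpoint-distance convention are
package choices where the acquisition protocol is silent. Checkpoints store
raw NumPy arrays and are not portable to other GRU implementations.
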