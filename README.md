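# fireflash

Automated classification and characterization of firefly flash patterns.

Many nocturnal fireflies advertise their species with precisely timed
bioluminescent flash patterns, which makes them both identifiable from video
and acutely vulnerable to light pollution. `fireflash` implements the full
analysis pipeline for stereoscopic swarm recordings made at 30 frames per
second: it links 3D flash detections into per-individual trajectories,
binarizes them into 0/1 flash sequences, classifies the emitting species, and
produces data-driven characterizations of flash-pattern variability. It is
aimed at computational ethologists and conservation researchers monitoring
firefly populations.

## What it does

**Trajectorization.** Flash detections at consecutive frames within a small
radius (default 0.2 m) are concatenated into *streaks* — one continuous flash
as the insect moves. Streaks within both 1 s and 1 m of each other are
assumed to come from the same individual and joined transitively into a
*trajectory*. Each trajectory becomes a binary sequence (1 = light detected,
30 bits per second) spanning its first to last flash. Interflash gaps of 1-2
bits (< 0.07 s) are tracking artifacts and filled in; single-flash
trajectories are discarded as noise; species with fewer than 100 trajectories
are dropped.

**Classification.** The primary classifier is a 2-layer GRU recurrent
network (128-dimensional hidden state) that reads one bit per timestep,

    h(t) = f(W_hh h(t-1) + W_xh x(t) + b)

with reset/update gating, a LeakyReLU(0.1) on the final hidden state, and an
affine softmax readout over species. Training uses Adam on cross-entropy,
gradient-norm clipping at 0.1, and early stopping on validation loss
(patience 50). Four baselines compare each sequence (a_m) against
per-species reference templates (b_n): the summed-mass Jaccard index
`sum_i a_i b_i / (sum a + sum b)`, the dot product, dynamic time warping
distance (softmaxed after negation), and an RBF-kernel SVM over the
3-vector (flash count, mean flash duration, mean inter-flash gap).
References are either *literature* patterns (published on/off timings,
bundled for six species) or *population* references (the elementwise average
of a species' training sequences).

**Evaluation & characterization.** Stratified cross-validation with random
undersampling to equal class counts; weighted precision/recall, row-
normalized confusion matrices, one-vs-rest ROC curves; artificial-sympatry
experiments mixing two species at proportions from 0.5% to 50% of a
400-sequence test set. Population characterization keeps only the 100
correctly classified sequences with the highest softmax confidence and pools
their flash counts, gaps and durations into normalized histograms.

**Synthetic data.** A seeded generator draws flash sequences from normal
distributions of count/gap/duration (quantized to the 30 fps grid) and can
embed simulated fireflies in a 3D arena as random walks, emitting flash
detections with positional noise plus the planted ground truth. Presets
carry the measured statistics of the twelve filmed populations of the seven
study species, so every pipeline stage is testable without field recordings.

## Worked example

```python
import numpy as np
from fireflash import generate_population, preset_table2, classify_by_reference
from fireflash.characterize import characterize_population
from fireflash.references import literature_references

preset = preset_table2()["P. carolinus, TN, Jun. 2020"]
ds = generate_population(preset, 1000, seed=42)

char = characterize_population(ds)
print(f"flash count     : {char.means['n_flashes']:.2f} +/- {char.sds['n_flashes']:.2f}")
print(f"inter-flash gap : {char.means['gap_s']:.3f} +/- {char.sds['gap_s']:.3f} s")
print(f"flash duration  : {char.means['duration_s']:.3f} +/- {char.sds['duration_s']:.3f} s")

out = classify_by_reference(ds.sequences[0], literature_references(), metric="dtw")
print("predicted:", out.predicted, " p =", round(out.probabilities[out.predicted], 3))
```

prints

```
flash count     : 7.23 +/- 1.91
inter-flash gap : 0.420 +/- 0.041 s
flash duration  : 0.140 +/- 0.032 s
predicted: P. carolinus  p = 0.665
```

The generated population reproduces the preset's measured statistics
(7.2 flashes, 0.42 s gaps, 0.14 s flashes for this population), and dynamic
time warping against the six published literature patterns identifies the
sampled sequence as *P. carolinus*.

A `fireflash` console script exposes the pipeline stages
(`trajectorize`, `simulate`, `classify`, `train`, `predict`, `evaluate`,
`characterize`); run `fireflash --help`.

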