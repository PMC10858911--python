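"""Confidence-based filtering and data-driven population characterization.

The raw trajectorization output is noisy, so characterization uses only the
sequences a trained classifier is most confident — and correct — about: for
each test sequence, take the maximum softmax probability; keep it only if
the arg max matches the true label; sort by probability and keep the top
100. The surviving sequences are pooled into empirical distributions of the
three trajectory-level statistics (flash count, inter-flash gap, flash
duration), each histogram normalized to unit mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fireflash.references import PatternSpec
from fireflash.sequences import SequenceDataset, sequence_stats


@dataclass
class PopulationCharacterization:
    """Per-population empirical distributions and moments of flash statistics.

    ``histograms`` maps statistic name ("n_flashes", "gap_s", "duration_s")
    to (bin_edges, mass) with masses summing to 1; ``means`` and ``sds`` map
    the same names to pooled moments.
    """

    population: str
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    means: dict[str, float]
    sds: dict[str, float]
    n_sequences: int
    filtered: bool = False

    def __post_init__(self):
        for name, (_, mass) in self.histograms.items():
            if mass.size and abs(mass.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} histogram mass must sum to 1")
        if not all(np.isfinite(v) for v in self.means.values()):
            raise ValueError("means must be finite")


def top_confident_subset(model, test: SequenceDataset,
                         n: int = 100) -> SequenceDataset:
    """The ``n`` correctly classified sequences with the highest confidence.

    Confidence is the maximum softmax probability of the model's prediction;
    only sequences whose predicted species equals the true label qualify. If
    fewer than ``n`` qualify, all of them are returned (with a warning when
    none do). Probability ties break by ascending dataset index.
    """
    if any(s.species is None for s in test.sequences):
        raise ValueError("test sequences must be labeled")
    preds = model.predict(test)
    qualified: list[tuple[float, int]] = []
    for i, (seq, out) in enumerate(zip(test.sequences, preds)):
        p = max(out.probabilities.values())
        if out.predicted == seq.species:
            qualified.append((p, i))
    if not qualified:
        import warnings

        warnings.warn("no correctly classified sequences; subset is empty")
        return SequenceDataset([], label_map=dict(test.label_map))
    qualified.sort(key=lambda t: (-t[0], t[1]))
    keep = [i for _, i in qualified[:n]]
    return test.subset(keep)


STAT_NAMES = ("n_flashes", "gap_s", "duration_s")


def characterize_population(ds: SequenceDataset,
                            bins: dict[str, float] | None = None,
                            population: str | None = None,
                            filtered: bool = False) -> PopulationCharacterization:
    """Pool flash statistics across a population's sequences.

    Every flash duration and every gap contributes one observation (event-
    level pooling); each sequence contributes one flash count. Histogram bin
    widths default to 1 flash for counts and one frame (1/30 s) for gaps and
    durations. Moments are the pooled mean and (population) sd.
    """
    if len(ds) == 0:
        raise ValueError("cannot characterize an empty population")
    widths = {"n_flashes": 1.0, "gap_s": 1.0 / 30.0, "duration_s": 1.0 / 30.0}
    if bins:
        widths.update(bins)
    counts: list[float] = []
    gaps: list[float] = []
    durations: list[float] = []
    for seq in ds.sequences:
        stats = sequence_stats(seq)
        counts.append(stats.n_flashes)
        gaps.extend(stats.gaps_s)
        durations.extend(stats.flash_durations_s)
    pools = {"n_flashes": np.asarray(counts, dtype=float),
             "gap_s": np.asarray(gaps, dtype=float),
             "duration_s": np.asarray(durations, dtype=float)}
    histograms = {}
    means = {}
    sds = {}
    for name, values in pools.items():
        if values.size == 0:
            histograms[name] = (np.array([]), np.array([]))
            means[name] = float("nan")
            sds[name] = float("nan")
            continue
        w = widths[name]
        lo = np.floor(values.min() / w) * w
        hi = np.ceil(values.max() / w + 0.5) * w
        edges = np.arange(lo, hi + w / 2, w)
        mass, edges = np.histogram(values, bins=edges)
        mass = mass / mass.sum()
        histograms[name] = (edges, mass)
        means[name] = float(values.mean())
        sds[name] = float(values.std())
    if np.isnan(means["gap_s"]):
        raise ValueError("population contains only single-flash sequences; gaps undefined")
    name = population or (ds.sequences[0].species or "population")
    return PopulationCharacterization(population=name, histograms=histograms,
                                      means=means, sds=sds,
                                      n_sequences=len(ds), filtered=filtered)


def compare_to_literature(char: PopulationCharacterization,
                          lit: PatternSpec | None) -> dict[str, float | None]:
    """Differences (data mean - literature value) per statistic; None where
    no literature value exists."""
    if lit is None:
        return {name: None for name in STAT_NAMES}
    lit_values = {
        "n_flashes": float(lit.n_flashes),
        "gap_s": lit.mean_gap_s(),
        "duration_s": lit.mean_flash_duration_s(),
    }
    out: dict[str, float | None] = {}
    for name in STAT_NAMES:
        ref = lit_values[name]
        out[name] = None if ref is None else char.means[name] - ref
    return out
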