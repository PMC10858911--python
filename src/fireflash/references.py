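"""Per-species ground-truth flash-pattern templates.

Two template families are supported:

* *literature references* — binary time series encoded from published
  characteristic flash patterns, entered as alternating on/off durations in
  seconds (six of the seven study species have one; Bicellonycha
  wickershamorum has no published pattern and is represented by absence);
* *population references* — real-valued templates obtained by averaging a
  species' training sequences, capturing intra-species variability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from fireflash.sequences import DEFAULT_FPS, FlashSequence

#: species with a published characteristic pattern bundled with the package
LITERATURE_PATTERN_FILE = "literature_patterns.csv"


@dataclass
class PatternSpec:
    """A flash pattern as an ordered list of (state, duration) segments.

    ``segments`` alternate between ``"on"`` (light) and ``"off"`` (dark),
    starting and ending with an on segment; durations are in seconds.
    """

    segments: list[tuple[str, float]]
    species: str | None = None

    def __post_init__(self):
        if not self.segments:
            raise ValueError("pattern must have at least one segment")
        for state, dur in self.segments:
            if state not in ("on", "off"):
                raise ValueError(f"segment state must be 'on' or 'off', got {state!r}")
            if dur <= 0:
                raise ValueError(f"segment durations must be positive, got {dur}")
        if self.segments[0][0] != "on" or self.segments[-1][0] != "on":
            raise ValueError("pattern must start and end with an 'on' segment")

    @classmethod
    def from_flash_train(cls, n_flashes: int, flash_s: float, gap_s: float,
                         species: str | None = None) -> "PatternSpec":
        """Regular train of ``n_flashes`` flashes of ``flash_s`` separated by ``gap_s``."""
        if n_flashes < 1:
            raise ValueError("n_flashes must be >= 1")
        segs: list[tuple[str, float]] = []
        for i in range(n_flashes):
            if i:
                segs.append(("off", gap_s))
            segs.append(("on", flash_s))
        return cls(segs, species=species)

    @property
    def n_flashes(self) -> int:
        return sum(1 for state, _ in self.segments if state == "on")

    def mean_flash_duration_s(self) -> float:
        durs = [d for state, d in self.segments if state == "on"]
        return float(np.mean(durs))

    def mean_gap_s(self) -> float | None:
        gaps = [d for state, d in self.segments if state == "off"]
        return float(np.mean(gaps)) if gaps else None


@dataclass
class ReferencePattern:
    """A per-species template series; binary for literature, [0,1] for population."""

    values: np.ndarray
    fps: float = DEFAULT_FPS
    species: str | None = None
    provenance: str = "literature"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if values.min() < 0 or values.max() > 1:
            raise ValueError("reference values must lie in [0, 1]")
        if self.provenance not in ("literature", "population"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "literature" and not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("literature references must be binary")
        self.values = values

    def __len__(self) -> int:
        return self.values.size


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def encode_literature_reference(spec: PatternSpec,
                                fps: float = DEFAULT_FPS) -> ReferencePattern:
    """Render a pattern spec as a binary time series at ``fps``.

    Each segment occupies ``round(duration_s * fps)`` bits of its state, with
    a floor of one bit so no segment vanishes under quantization.
    """
    chunks = []
    for state, dur in spec.segments:
        n = max(1, _round_half_away(dur * fps))
        chunks.append(np.full(n, 1.0 if state == "on" else 0.0))
    return ReferencePattern(np.concatenate(chunks), fps=fps, species=spec.species,
                            provenance="literature")


def build_population_reference(train: Sequence[FlashSequence]) -> ReferencePattern:
    """Average a species' training sequences into a real-valued template.

    Sequences all start with a flash, so they are left-aligned at onset,
    zero-padded on the right to the maximum length, and averaged elementwise.
    """
    train = list(train)
    if not train:
        raise ValueError("cannot build a population reference from no sequences")
    species = {s.species for s in train}
    if len(species) != 1:
        raise ValueError(f"training sequences must share one species, got {sorted(map(str, species))}")
    fps = {s.fps for s in train}
    if len(fps) != 1:
        raise ValueError("training sequences must share one fps")
    max_len = max(len(s) for s in train)
    acc = np.zeros(max_len)
    for s in train:
        acc[: len(s)] += s.bits
    return ReferencePattern(acc / len(train), fps=fps.pop(),
                            species=species.pop(), provenance="population")


def read_pattern_specs(path_or_file) -> dict[str, PatternSpec]:
    """Read `species,state,duration_s` rows (in segment order) into PatternSpecs."""
    segments: dict[str, list[tuple[str, float]]] = {}
    if hasattr(path_or_file, "read"):
        rows = list(csv.reader(path_or_file))
    else:
        with open(path_or_file, newline="") as fh:
            rows = list(csv.reader(fh))
    if not rows:
        return {}
    if [h.strip() for h in rows[0]] != ["species", "state", "duration_s"]:
        raise ValueError("expected header species,state,duration_s")
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            species, state, dur = row
            segments.setdefault(species, []).append((state, float(dur)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed row at line {lineno}: {row!r}") from exc
    return {sp: PatternSpec(segs, species=sp) for sp, segs in segments.items()}


def literature_patterns() -> dict[str, PatternSpec]:
    """The six bundled published flash patterns, keyed by species name.

    B. wickershamorum has no published pattern and is absent from the mapping.
    """
    ref = resources.files("fireflash").joinpath("data", LITERATURE_PATTERN_FILE)
    with ref.open(newline="") as fh:
        return read_pattern_specs(fh)


def literature_references(fps: float = DEFAULT_FPS) -> dict[str, ReferencePattern]:
    """Binary literature templates for the six species with published patterns."""
    return {sp: encode_literature_reference(spec, fps=fps)
            for sp, spec in literature_patterns().items()}


def population_references(sequences: Iterable[FlashSequence]) -> dict[str, ReferencePattern]:
    """Per-species population templates from a pool of labeled training sequences."""
    by_species: dict[str, list[FlashSequence]] = {}
    for s in sequences:
        if s.species is None:
            raise ValueError("all sequences must be labeled")
        by_species.setdefault(s.species, []).append(s)
    return {sp: build_population_reference(seqs) for sp, seqs in sorted(by_species.items())}
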