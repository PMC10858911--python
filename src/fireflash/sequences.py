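"""Core data model for flash sequences, trajectorization of 3D flash detections,
binarization, cleaning and thresholding.

A field recording yields per-frame 3D flash detections (:class:`FlashEvent`).
Detections at consecutive frames within a small radius are concatenated into
:class:`Streak` objects (one continuous flash as the insect moves); streaks
within 1 s and 1 m of each other are transitively linked into a
:class:`Trajectory`, attributed to one individual. Each trajectory is then
binarized into a 0/1 series at the recording frame rate (30 fps), 1 = light
detected, spanning the first to the last flash.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_FPS = 30.0
#: default spatial radius (meters) linking detections at consecutive frames
DEFAULT_STREAK_RADIUS_M = 0.2
#: streak-to-trajectory linkage thresholds: <= 1 s and <= 1 m
DEFAULT_MAX_GAP_S = 1.0
DEFAULT_MAX_DIST_M = 1.0


@dataclass(frozen=True)
class FlashEvent:
    """One detected flash point: frame index and 3D position in meters."""

    frame: int
    position: tuple[float, float, float]
    recording_id: str = ""

    def __post_init__(self):
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3 or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position}")
        object.__setattr__(self, "position", pos)


@dataclass
class Streak:
    """A run of flash detections at strictly consecutive frames."""

    events: list[FlashEvent]

    def __post_init__(self):
        if not self.events:
            raise ValueError("streak must contain at least one event")
        frames = [e.frame for e in self.events]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("streak frames must be strictly consecutive")

    @property
    def start_frame(self) -> int:
        return self.events[0].frame

    @property
    def end_frame(self) -> int:
        return self.events[-1].frame

    @property
    def start_position(self) -> np.ndarray:
        return np.asarray(self.events[0].position)

    @property
    def end_position(self) -> np.ndarray:
        return np.asarray(self.events[-1].position)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class Trajectory:
    """Transitively connected streaks attributed to one individual firefly."""

    streaks: list[Streak]
    recording_id: str = ""

    def __post_init__(self):
        if not self.streaks:
            raise ValueError("trajectory must contain at least one streak")
        self.streaks = sorted(self.streaks, key=lambda s: s.start_frame)

    @property
    def start_frame(self) -> int:
        return self.streaks[0].start_frame

    @property
    def end_frame(self) -> int:
        return max(s.end_frame for s in self.streaks)

    def flash_frames(self) -> np.ndarray:
        """Sorted unique frame indices at which this trajectory flashes."""
        return np.unique([e.frame for s in self.streaks for e in s.events])


@dataclass
class FlashSequence:
    """Binary flash sequence at a fixed frame rate, spanning first to last flash.

    ``bits[i] = 1`` means light was detected at frame ``start_frame + i``.
    Valid sequences start and end with a 1.
    """

    bits: np.ndarray
    fps: float = DEFAULT_FPS
    species: str | None = None
    recording_id: str | None = None
    start_frame: int | None = None

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or bits.size < 1:
            raise ValueError("bits must be a non-empty 1-D array")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0s and 1s")
        if bits[0] != 1 or bits[-1] != 1:
            raise ValueError("a flash sequence must start and end with a flash (1)")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        self.bits = bits

    def __len__(self) -> int:
        return self.bits.size

    @property
    def duration_s(self) -> float:
        return frames_to_seconds(self.bits.size, self.fps)

    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_string(cls, s: str, **kwargs) -> "FlashSequence":
        if not s or set(s) - {"0", "1"}:
            raise ValueError(f"bit string must be non-empty over {{0,1}}, got {s!r}")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"), **kwargs)


@dataclass
class SequenceDataset:
    """A list of flash sequences plus a species-name <-> integer label encoding.

    The label map is a bijection over all species present, assigning integer
    codes in sorted name order (deterministic label encoding).
    """

    sequences: list[FlashSequence]
    label_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        present = {s.species for s in self.sequences if s.species is not None}
        if not self.label_map:
            self.label_map = {sp: i for i, sp in enumerate(sorted(present))}
        else:
            missing = present - set(self.label_map)
            if missing:
                raise ValueError(f"label_map is missing species {sorted(missing)}")
            codes = list(self.label_map.values())
            if len(set(codes)) != len(codes):
                raise ValueError("label_map codes must be unique")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def species_names(self) -> list[str]:
        return sorted(self.label_map, key=self.label_map.get)

    def labels(self) -> np.ndarray:
        """Integer labels per sequence (all sequences must be labeled)."""
        return np.array([self.label_map[s.species] for s in self.sequences])

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sequences:
            if s.species is not None:
                out[s.species] = out.get(s.species, 0) + 1
        return out

    def subset(self, indices: Iterable[int]) -> "SequenceDataset":
        """New dataset with the given sequences; the label map is preserved."""
        return SequenceDataset([self.sequences[i] for i in indices],
                               label_map=dict(self.label_map))


@dataclass
class SequenceStats:
    """Trajectory-level flash statistics: count, per-flash durations, gaps."""

    n_flashes: int
    flash_durations_s: list[float]
    gaps_s: list[float]

    def __post_init__(self):
        if self.n_flashes != len(self.flash_durations_s):
            raise ValueError("n_flashes must equal the number of flash durations")
        if len(self.gaps_s) != max(self.n_flashes - 1, 0):
            raise ValueError("expected n_flashes - 1 gaps")


def frames_to_seconds(n_frames: int, fps: float = DEFAULT_FPS) -> float:
    """Convert a frame count to seconds; 30 frames = 1 s at the default rate."""
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    if n_frames < 0:
        raise ValueError(f"n_frames must be >= 0, got {n_frames}")
    return n_frames / fps


def link_streaks(events: Sequence[FlashEvent],
                 radius_m: float = DEFAULT_STREAK_RADIUS_M) -> list[Streak]:
    """Concatenate flash detections into streaks.

    Detections at consecutive frames within ``radius_m`` of each other belong
    to the same streak. Linking is greedy nearest-neighbour per frame step:
    each open streak is extended by at most one detection of the next frame.
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")
    if not events:
        return []
    events = sorted(events, key=lambda e: e.frame)
    done: list[list[FlashEvent]] = []
    open_streaks: list[list[FlashEvent]] = []
    i = 0
    n = len(events)
    while i < n:
        frame = events[i].frame
        batch = []
        while i < n and events[i].frame == frame:
            batch.append(events[i])
            i += 1
        # close streaks that did not reach this frame
        still_open = []
        for s in open_streaks:
            if s[-1].frame == frame - 1:
                still_open.append(s)
            else:
                done.append(s)
        open_streaks = still_open
        # greedy nearest-neighbour matching of this frame's detections to open streaks
        pairs = []
        for bi, ev in enumerate(batch):
            p = np.asarray(ev.position)
            for si, s in enumerate(open_streaks):
                d = float(np.linalg.norm(p - np.asarray(s[-1].position)))
                if d <= radius_m:
                    pairs.append((d, bi, si))
        pairs.sort(key=lambda t: t[0])
        used_b: set[int] = set()
        used_s: set[int] = set()
        for d, bi, si in pairs:
            if bi in used_b or si in used_s:
                continue
            open_streaks[si].append(batch[bi])
            used_b.add(bi)
            used_s.add(si)
        for bi, ev in enumerate(batch):
            if bi not in used_b:
                open_streaks.append([ev])
    done.extend(open_streaks)
    done.sort(key=lambda s: (s[0].frame, tuple(s[0].position)))
    return [Streak(s) for s in done]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def link_trajectories(streaks: Sequence[Streak],
                      max_gap_s: float = DEFAULT_MAX_GAP_S,
                      max_dist_m: float = DEFAULT_MAX_DIST_M,
                      fps: float = DEFAULT_FPS,
                      recording_id: str = "") -> list[Trajectory]:
    """Group streaks into trajectories under the 1 s / 1 m rule.

    Two streaks are linked when the later one starts within ``max_gap_s``
    after the earlier one ends AND the end position of the earlier streak is
    within ``max_dist_m`` of the start position of the later streak.
    Trajectories are the connected components of this relation (transitive
    closure); overlapping-in-time streaks are never linked, since one firefly
    cannot produce two simultaneous flashes.
    """
    if not streaks:
        return []
    streaks = list(streaks)
    n = len(streaks)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: streaks[i].end_frame)
    for ii, i in enumerate(order):
        a = streaks[i]
        for j in order[ii + 1:]:
            b = streaks[j]
            if b.start_frame <= a.end_frame:
                continue
            dt = (b.start_frame - a.end_frame) / fps
            if dt > max_gap_s:
                # later streaks are end-sorted, not start-sorted: skip, don't break
                continue
            dist = float(np.linalg.norm(a.end_position - b.start_position))
            if dist <= max_dist_m:
                uf.union(i, j)
    groups: dict[int, list[Streak]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(streaks[i])
    trajs = [Trajectory(g, recording_id=recording_id) for g in groups.values()]
    trajs.sort(key=lambda t: t.start_frame)
    return trajs


def trajectory_to_sequence(traj: Trajectory, fps: float = DEFAULT_FPS) -> FlashSequence:
    """Binarize a trajectory: bit i is 1 iff frame (first_frame + i) flashed."""
    frames = traj.flash_frames()
    first, last = int(frames[0]), int(frames[-1])
    bits = np.zeros(last - first + 1, dtype=np.int8)
    bits[frames - first] = 1
    return FlashSequence(bits, fps=fps, recording_id=traj.recording_id or None,
                         start_frame=first)


def clean_short_gaps(seq: FlashSequence) -> FlashSequence:
    """Fill interflash gaps of 1 or 2 bits (< 0.07 s at 30 fps) with ones.

    Such gaps are tracking artifacts (a dropped frame, brief occlusion by
    brush) rather than real dark periods; gaps of 3+ bits are kept. The
    operation is idempotent.
    """
    bits = seq.bits.copy()
    n = bits.size
    i = 0
    while i < n:
        if bits[i] == 0:
            j = i
            while j < n and bits[j] == 0:
                j += 1
            if j - i <= 2:  # interior by construction: bits[0] == bits[-1] == 1
                bits[i:j] = 1
            i = j
        else:
            i += 1
    return FlashSequence(bits, fps=seq.fps, species=seq.species,
                         recording_id=seq.recording_id, start_frame=seq.start_frame)


def _flash_run_count(bits: np.ndarray) -> int:
    padded = np.concatenate([[0], bits, [0]])
    return int(np.sum((padded[1:] == 1) & (padded[:-1] == 0)))


def filter_single_flash(ds: SequenceDataset) -> SequenceDataset:
    """Drop sequences containing only one flash (noise-threshold rule)."""
    kept = [s for s in ds.sequences if _flash_run_count(s.bits) >= 2]
    return SequenceDataset(kept)


def filter_rare_species(ds: SequenceDataset, min_count: int = 100) -> SequenceDataset:
    """Drop species with fewer than ``min_count`` sequences; rebuild labels."""
    counts = ds.counts()
    keep = {sp for sp, c in counts.items() if c >= min_count}
    kept = [s for s in ds.sequences if s.species in keep]
    return SequenceDataset(kept)


def sequence_stats(seq: FlashSequence) -> SequenceStats:
    """Run-length statistics of a (cleaned) sequence.

    Flash runs give per-flash durations; interior zero runs give inter-flash
    gaps (end of one flash to the start of the next), all in seconds.
    """
    bits = seq.bits
    # run-length encode
    change = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [bits.size]])
    durations = []
    gaps = []
    for s, e in zip(starts, ends):
        length_s = (e - s) / seq.fps
        if bits[s] == 1:
            durations.append(length_s)
        else:
            gaps.append(length_s)
    return SequenceStats(n_flashes=len(durations), flash_durations_s=durations,
                         gaps_s=gaps)


# ---------------------------------------------------------------------------
# File I/O
#
# Localization file: CSV `recording_id,frame,x,y,z` (meters, 0-based frames).
# Sequence file: CSV `species,recording_id,start_frame,bits`, bits a 0/1 string.

LOC_HEADER = ["recording_id", "frame", "x", "y", "z"]
SEQ_HEADER = ["species", "recording_id", "start_frame", "bits"]


def read_localizations(path) -> list[FlashEvent]:
    """Read flash detections from a `recording_id,frame,x,y,z` CSV."""
    events: list[FlashEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return events
        if [h.strip() for h in header] != LOC_HEADER:
            raise ValueError(f"{path}: expected header {','.join(LOC_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                rec, frame, x, y, z = row
                events.append(FlashEvent(frame=int(frame),
                                         position=(float(x), float(y), float(z)),
                                         recording_id=rec))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
    return events


def read_sequences(path) -> SequenceDataset:
    """Read a flash-sequence dataset from a `species,recording_id,start_frame,bits` CSV."""
    seqs: list[FlashSequence] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return SequenceDataset([])
        if [h.strip() for h in header] != SEQ_HEADER:
            raise ValueError(f"{path}: expected header {','.join(SEQ_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                species, rec, start, bits = row
                seqs.append(FlashSequence.from_string(
                    bits,
                    species=species or None,
                    recording_id=rec or None,
                    start_frame=int(start) if start else None,
                ))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
    return SequenceDataset(seqs)


def write_sequences(ds: SequenceDataset, path) -> None:
    """Write a dataset to CSV; `read_sequences` round-trips it losslessly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SEQ_HEADER)
        for s in ds.sequences:
            writer.writerow([
                s.species or "",
                s.recording_id or "",
                "" if s.start_frame is None else s.start_frame,
                s.bitstring(),
            ])
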