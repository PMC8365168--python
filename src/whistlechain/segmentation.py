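"""Segmentation of whistles into sounding segments and pitch-target detection.

A whistle alternates sounding stretches and silences.  Segments are maximal
runs of intensity above a silence threshold, after closing sub-perceptual
gaps and discarding spuriously short runs.  Within each segment, pitch
targets (the melodic anchors every downstream measure consumes) are the
zero-crossings of the derivative of the lightly smoothed pitch contour, with
the segment endpoints always included so contour classes such as ascending
vs. horizontal are decidable from target heights alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_tracks import Whistle, WhistleSet

logger = logging.getLogger(__name__)

TARGET_KINDS = ("start", "peak", "valley", "end")


@dataclass
class SegmentationConfig:
    """Tunables for segmentation and target detection.

    silence_threshold : absolute intensity cut; ``None`` means 10% of the
        whistle's maximum intensity (robust to recording level).
    min_gap : silences strictly shorter than this are closed (seconds).
    min_segment : sounding runs strictly shorter than this are dropped (s).
    max_pitch_gap : unvoiced runs of at most this many samples inside a
        segment are linearly interpolated; longer runs split the segment.
    smooth_window : centred moving-average window (samples) applied before
        derivative zero-crossing detection.
    min_prominence : interior extrema must differ from both flanking targets
        by at least this many semitones.
    """

    silence_threshold: float | None = None
    min_gap: float = 0.02
    min_segment: float = 0.05
    max_pitch_gap: int = 5
    smooth_window: int = 5
    min_prominence: float = 0.5


@dataclass
class Segment:
    """A sounding stretch of one whistle (half-open sample interval)."""

    whistle_id: str
    index: int
    start_sample: int
    end_sample: int
    sample_rate: float
    start_time: float
    pitch_values: np.ndarray  # semitones, NaN-free

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ValueError("segment must have start_sample < end_sample")
        self.pitch_values = np.asarray(self.pitch_values, dtype=float)
        if self.pitch_values.size != self.end_sample - self.start_sample:
            raise ValueError("pitch_values length must match sample span")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def onset_st(self) -> float:
        """Onset pitch of the segment: its first sample, in semitones."""
        return float(self.pitch_values[0])


@dataclass
class PitchTarget:
    sample_index: int  # within the segment
    value: float       # semitones
    kind: str          # start / peak / valley / end

    def __post_init__(self) -> None:
        if self.kind not in TARGET_KINDS:
            raise ValueError(f"unknown target kind {self.kind!r}")


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) index pairs of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def _interp_short_pitch_gaps(pitch: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill interior NaN runs of length <= max_gap by linear interpolation."""
    out = pitch.copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    valid_idx = np.flatnonzero(~isnan)
    if valid_idx.size == 0:
        return out
    for start, end in _runs_above(isnan):
        if end - start <= max_gap and start > 0 and end < out.size:
            if not (np.isnan(out[start - 1]) or np.isnan(out[end])):
                xs = np.arange(start, end)
                out[start:end] = np.interp(xs, [start - 1, end],
                                           [out[start - 1], out[end]])
    return out


def segment_whistle(whistle: Whistle,
                    config: SegmentationConfig | None = None) -> list[Segment]:
    """Split a whistle into sounding segments using its intensity track.

    Segments are maximal runs of intensity strictly above the silence
    threshold, after (a) closing inter-run gaps shorter than ``min_gap`` and
    (b) discarding runs shorter than ``min_segment``.  Unvoiced pitch runs
    longer than ``max_pitch_gap`` samples split a segment; shorter interior
    runs are interpolated.  A whistle with no sample above threshold yields
    an empty list.
    """
    cfg = config or SegmentationConfig()
    intensity = whistle.intensity.values
    rate = whistle.intensity.sample_rate
    thr = cfg.silence_threshold
    if thr is None:
        thr = 0.1 * float(np.max(intensity)) if intensity.size else 0.0
    mask = intensity > thr
    runs = _runs_above(mask)
    if not runs:
        return []

    # close gaps strictly shorter than min_gap
    min_gap_samples = cfg.min_gap * rate
    merged: list[list[int]] = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] < min_gap_samples:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    # drop runs strictly shorter than min_segment
    min_seg_samples = cfg.min_segment * rate
    kept = [(s, e) for s, e in merged if (e - s) >= min_seg_samples]

    # split on long unvoiced pitch runs; interpolate short ones
    pitch = whistle.pitch.values
    pieces: list[tuple[int, int, np.ndarray]] = []
    for s, e in kept:
        chunk = _interp_short_pitch_gaps(pitch[s:e], cfg.max_pitch_gap)
        voiced = ~np.isnan(chunk)
        for rs, re in _runs_above(voiced):
            if (re - rs) >= min_seg_samples:
                pieces.append((s + rs, s + re, chunk[rs:re]))

    segments = []
    for idx, (s, e, vals) in enumerate(pieces):
        segments.append(Segment(
            whistle_id=whistle.whistle_id, index=idx,
            start_sample=s, end_sample=e, sample_rate=rate,
            start_time=whistle.pitch.start_time + s / rate,
            pitch_values=vals))
    return segments


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with a window that shrinks at the edges."""
    if window <= 1 or values.size <= 2:
        return values.astype(float, copy=True)
    window = min(window, values.size)
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def _candidate_extrema(s: np.ndarray) -> list[tuple[int, float, str]]:
    """Interior extrema from sign changes of the first difference.

    Plateaus are handled by comparing consecutive runs of nonzero slope; the
    extremum is placed at the arg-extreme sample between the two runs.
    """
    d = np.diff(s)
    sign = np.sign(d)
    nz = np.flatnonzero(sign)
    cands: list[tuple[int, float, str]] = []
    if nz.size < 2:
        return cands
    prev = nz[0]
    for cur in nz[1:]:
        if sign[cur] != sign[prev]:
            lo, hi = prev + 1, cur + 1  # samples between the two slope runs
            if sign[prev] > 0:
                idx = lo + int(np.argmax(s[lo:hi]))
                cands.append((idx, float(s[idx]), "peak"))
            else:
                idx = lo + int(np.argmin(s[lo:hi]))
                cands.append((idx, float(s[idx]), "valley"))
        prev = cur
    return cands


def _prune_targets(targets: list[list], min_prominence: float) -> list[list]:
    """Drop interior extrema closer than min_prominence to a flanking target.

    Removal can leave two like-kind interior extrema adjacent; the less
    extreme one is dropped to restore peak/valley alternation.  Endpoints
    are never removed.
    """
    t = [list(x) for x in targets]

    def weakest() -> int | None:
        worst, worst_val = None, np.inf
        for i in range(1, len(t) - 1):
            depth = min(abs(t[i][1] - t[i - 1][1]), abs(t[i][1] - t[i + 1][1]))
            if depth < min_prominence and depth < worst_val:
                worst, worst_val = i, depth
        return worst

    while len(t) > 2:
        i = weakest()
        if i is None:
            break
        del t[i]
        # restore alternation among interior extrema
        changed = True
        while changed and len(t) > 2:
            changed = False
            for j in range(1, len(t) - 2):
                a, b = t[j], t[j + 1]
                if a[2] == b[2] and a[2] in ("peak", "valley"):
                    if a[2] == "peak":
                        drop = j if a[1] <= b[1] else j + 1
                    else:
                        drop = j if a[1] >= b[1] else j + 1
                    del t[drop]
                    changed = True
                    break
    return t


def detect_targets(segment: Segment,
                   smooth_window: int = 5,
                   min_prominence: float = 0.5) -> list[PitchTarget]:
    """Annotate a segment with pitch targets.

    The pitch contour is smoothed with a centred moving average, interior
    targets are the sign changes of its first difference whose extremum
    differs from both flanking targets by at least ``min_prominence``
    semitones, and both endpoints are always targets (kinds start/end).
    """
    vals = segment.pitch_values
    if vals.size < 2:
        raise ValueError("segment must have at least 2 pitch samples")
    if smooth_window > vals.size:
        logger.debug("segment %s/%d shorter than smooth_window; shrinking",
                     segment.whistle_id, segment.index)
    s = moving_average(vals, smooth_window)
    cands = _candidate_extrema(s)
    raw = ([[0, float(s[0]), "start"]]
           + [[i, v, k] for i, v, k in cands]
           + [[vals.size - 1, float(s[-1]), "end"]])
    pruned = _prune_targets(raw, min_prominence)
    return [PitchTarget(sample_index=i, value=v, kind=k) for i, v, k in pruned]


# ---------------------------------------------------------------------------
# Analyzed containers: the hand-off surface for every measure module
# ---------------------------------------------------------------------------

@dataclass
class AnalyzedWhistle:
    """A whistle with its segments and per-segment target lists."""

    whistle: Whistle
    segments: list[Segment]
    targets: list[list[PitchTarget]]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.targets):
            raise ValueError("one target list per segment required")

    @property
    def onsets_st(self) -> np.ndarray:
        return np.asarray([seg.onset_st for seg in self.segments])


@dataclass
class AnalyzedSet:
    """One (chain, generation) whistle set after segmentation + targets."""

    chain_id: str
    generation: int
    whistles: list[AnalyzedWhistle] = field(default_factory=list)

    def iter_segments(self) -> Iterable[tuple[Segment, list[PitchTarget]]]:
        for aw in self.whistles:
            yield from zip(aw.segments, aw.targets)

    @property
    def n_segments(self) -> int:
        return sum(len(aw.segments) for aw in self.whistles)


def analyze_whistle(whistle: Whistle,
                    config: SegmentationConfig | None = None) -> AnalyzedWhistle:
    cfg = config or SegmentationConfig()
    segments = segment_whistle(whistle, cfg)
    targets = [detect_targets(seg, cfg.smooth_window, cfg.min_prominence)
               for seg in segments]
    return AnalyzedWhistle(whistle=whistle, segments=segments, targets=targets)


def analyze_set(wset: WhistleSet,
                config: SegmentationConfig | None = None) -> AnalyzedSet:
    cfg = config or SegmentationConfig()
    return AnalyzedSet(chain_id=wset.chain_id, generation=wset.generation,
                       whistles=[analyze_whistle(w, cfg) for w in wset])


def targets_table(analyzed: AnalyzedSet):
    """Tidy per-target rows (for CSV export); imported lazily to avoid a hard
    pandas dependency at segmentation time."""
    import pandas as pd

    rows = []
    for aw in analyzed.whistles:
        for seg, targs in zip(aw.segments, aw.targets):
            for j, t in enumerate(targs):
                rows.append({
                    "chain_id": analyzed.chain_id,
                    "generation": analyzed.generation,
                    "whistle_id": seg.whistle_id,
                    "segment_index": seg.index,
                    "start_s": seg.start_time,
                    "end_s": seg.start_time + seg.duration,
                    "target_index": j,
                    "target_s": seg.start_time + t.sample_index / seg.sample_rate,
                    "target_st": t.value,
                    "kind": t.kind,
                })
    return pd.DataFrame(rows)
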