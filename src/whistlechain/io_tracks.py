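"""Data model and I/O for whistle pitch and intensity tracks.

Whistled signals are represented as uniformly sampled time series: a pitch
track in semitones (``st = 12 * log2(f / f_ref)``) paired with an intensity
track in arbitrary non-negative units where 0 means silence.  Twelve whistles
form a :class:`WhistleSet` (one generation of one transmission chain) and a
:class:`ChainDataset` holds the full chains-by-generations grid.

On disk a dataset is a directory of two-column track CSVs (``time_s,value``)
plus a manifest CSV listing one row per whistle.  Unvoiced pitch samples are
written as empty fields and carried in memory as NaN.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

#: Default semitone reference frequency (Hz).  Only pitch *differences* enter
#: any downstream measure, so this affects reported absolute values only.
DEFAULT_REF_HZ = 100.0

#: Default track sample rate (samples per second).
DEFAULT_SAMPLE_RATE = 500.0

#: Physical range of the slide whistle used to produce the signals (Hz).
INSTRUMENT_FLOOR_HZ = 450.0
INSTRUMENT_CEILING_HZ = 2500.0


class TrackFormatError(ValueError):
    """A track file violates the two-column uniformly sampled contract."""


class ManifestError(ValueError):
    """A dataset manifest is inconsistent (duplicates, missing files...)."""


def hz_to_semitones(freq_hz, ref_hz: float = DEFAULT_REF_HZ):
    """Convert frequency in Hz to semitones relative to ``ref_hz``.

    Accepts scalars or arrays.  NaN values pass through (unvoiced samples);
    non-positive finite frequencies raise ``ValueError``.
    """
    if ref_hz <= 0:
        raise ValueError(f"ref_hz must be positive, got {ref_hz}")
    arr = np.asarray(freq_hz, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = arr <= 0
    if np.any(bad):
        raise ValueError("frequencies must be positive")
    out = 12.0 * np.log2(arr / ref_hz)
    return float(out) if np.isscalar(freq_hz) else out


def semitones_to_hz(st, ref_hz: float = DEFAULT_REF_HZ):
    """Inverse of :func:`hz_to_semitones`."""
    if ref_hz <= 0:
        raise ValueError(f"ref_hz must be positive, got {ref_hz}")
    arr = np.asarray(st, dtype=float)
    out = ref_hz * np.exp2(arr / 12.0)
    return float(out) if np.isscalar(st) else out


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("track values must be one-dimensional")
    if arr.size < 1:
        raise ValueError("track must contain at least one sample")
    return arr


@dataclass
class PitchTrack:
    """Uniformly sampled pitch contour in semitones; NaN marks unvoiced."""

    values: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("present pitch values must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class IntensityTrack:
    """Uniformly sampled intensity; arbitrary non-negative units, 0 = silent."""

    values: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class Whistle:
    """One whistled signal: paired pitch and intensity tracks."""

    whistle_id: str
    chain_id: str
    generation: int
    pitch: PitchTrack
    intensity: IntensityTrack

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.pitch.n_samples != self.intensity.n_samples:
            raise ValueError(
                f"whistle {self.whistle_id}: pitch ({self.pitch.n_samples}) and "
                f"intensity ({self.intensity.n_samples}) sample counts differ"
            )
        if not math.isclose(self.pitch.sample_rate, self.intensity.sample_rate,
                            rel_tol=1e-6):
            raise ValueError(f"whistle {self.whistle_id}: track rates differ")


@dataclass
class WhistleSet:
    """All whistles of one (chain, generation) cell; canonically 12 of them."""

    chain_id: str
    generation: int
    whistles: list[Whistle]

    def __post_init__(self) -> None:
        for w in self.whistles:
            if w.chain_id != self.chain_id or w.generation != self.generation:
                raise ValueError(
                    f"whistle {w.whistle_id} does not belong to "
                    f"({self.chain_id}, gen {self.generation})"
                )
        ids = [w.whistle_id for w in self.whistles]
        if len(set(ids)) != len(ids):
            raise ManifestError(f"duplicate whistle_id within set {self.chain_id}/"
                                f"{self.generation}")

    def __len__(self) -> int:
        return len(self.whistles)

    def __iter__(self) -> Iterator[Whistle]:
        return iter(self.whistles)


@dataclass
class ChainDataset:
    """Mapping chain_id -> generation-ordered list of whistle sets."""

    chains: dict[str, list[WhistleSet]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain_id, sets in self.chains.items():
            gens = [s.generation for s in sets]
            if any(b <= a for a, b in zip(gens, gens[1:])):
                raise ValueError(f"chain {chain_id}: generations must be "
                                 f"strictly increasing, got {gens}")
            for s in sets:
                if s.chain_id != chain_id:
                    raise ValueError(f"set {s.chain_id} filed under {chain_id}")

    def sets(self) -> Iterator[WhistleSet]:
        for chain_id in sorted(self.chains):
            yield from self.chains[chain_id]

    @property
    def n_sets(self) -> int:
        return sum(len(v) for v in self.chains.values())


# ---------------------------------------------------------------------------
# Track CSV I/O
# ---------------------------------------------------------------------------

_TIME_TOL = 1e-6  # uniform-step tolerance, seconds


def _read_rows(path: Path) -> tuple[np.ndarray, np.ndarray]:
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise TrackFormatError(f"{path}: empty file")
        for row in reader:
            if not row:
                continue
            times.append(float(row[0]))
            raw = row[1].strip() if len(row) > 1 else ""
            values.append(float(raw) if raw else math.nan)
    if len(times) < 2:
        raise TrackFormatError(f"{path}: need at least 2 rows to infer the "
                               f"sample rate, got {len(times)}")
    return np.asarray(times), np.asarray(values)


def read_track_csv(path, kind: str = "pitch") -> PitchTrack | IntensityTrack:
    """Read a two-column ``time_s,value`` CSV into a track.

    The time column must be uniformly spaced within 1 microsecond; the first
    offending data row (1-based, header excluded) is named in the error.
    Empty value fields become NaN (only meaningful for pitch).
    """
    path = Path(path)
    times, values = _read_rows(path)
    step = times[1] - times[0]
    if step <= 0:
        raise TrackFormatError(f"{path}: non-increasing time at row 2")
    diffs = np.diff(times)
    bad = np.nonzero(np.abs(diffs - step) > _TIME_TOL)[0]
    if bad.size:
        row = int(bad[0]) + 2  # data-row number of the offending sample
        raise TrackFormatError(
            f"{path}: non-uniform sampling at row {row} "
            f"(step {diffs[bad[0]]:.6f}s, expected {step:.6f}s)")
    rate = 1.0 / step
    cls = PitchTrack if kind == "pitch" else IntensityTrack
    return cls(values=values, sample_rate=rate, start_time=float(times[0]))


def write_track_csv(track: PitchTrack | IntensityTrack, path) -> None:
    """Write a track as ``time_s,value`` CSV; NaN pitch as empty field.

    Finite values are written with ``repr`` so a write/read round trip is
    bit-identical.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("time_s,value\n")
        step = 1.0 / track.sample_rate
        for i, v in enumerate(track.values):
            t = track.start_time + i * step
            sval = "" if math.isnan(v) else repr(float(v))
            fh.write(f"{t:.6f},{sval}\n")


# ---------------------------------------------------------------------------
# Manifest / dataset I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("chain_id", "generation", "whistle_id",
                    "pitch_file", "intensity_file")


def read_manifest(path) -> ChainDataset:
    """Load a full dataset from a manifest CSV.

    The manifest has columns ``chain_id, generation, whistle_id, pitch_file,
    intensity_file``; file paths are relative to the manifest's directory.
    An empty manifest yields an empty dataset.
    """
    path = Path(path)
    base = path.parent
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return ChainDataset()
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ManifestError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)
    grouped: dict[tuple[str, int], list[Whistle]] = {}
    order: list[tuple[str, int]] = []
    for row in rows:
        chain_id = row["chain_id"]
        generation = int(row["generation"])
        wid = row["whistle_id"]
        pitch_path = base / row["pitch_file"]
        intensity_path = base / row["intensity_file"]
        for p in (pitch_path, intensity_path):
            if not p.exists():
                raise OSError(f"whistle {wid}: track file not found: {p}")
        pitch = read_track_csv(pitch_path, kind="pitch")
        intensity = read_track_csv(intensity_path, kind="intensity")
        key = (chain_id, generation)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        if any(w.whistle_id == wid for w in grouped[key]):
            raise ManifestError(f"duplicate whistle_id {wid!r} in set "
                                f"{chain_id}/{generation}")
        grouped[key].append(Whistle(whistle_id=wid, chain_id=chain_id,
                                    generation=generation, pitch=pitch,
                                    intensity=intensity))
    chains: dict[str, list[WhistleSet]] = {}
    for chain_id, generation in sorted(order):
        chains.setdefault(chain_id, []).append(
            WhistleSet(chain_id=chain_id, generation=generation,
                       whistles=grouped[(chain_id, generation)]))
    return ChainDataset(chains=chains)


def write_dataset(dataset: ChainDataset, out_dir) -> Path:
    """Write one CSV per track plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for wset in dataset.sets():
            for w in wset:
                pf = f"{w.whistle_id}_pitch.csv"
                inf = f"{w.whistle_id}_intensity.csv"
                write_track_csv(w.pitch, out_dir / pf)
                write_track_csv(w.intensity, out_dir / inf)
                writer.writerow([w.chain_id, w.generation, w.whistle_id, pf, inf])
    return manifest_path


# ---------------------------------------------------------------------------
# Praat PitchTier interoperability
# ---------------------------------------------------------------------------

def read_pitchtier(path, ref_hz: float = DEFAULT_REF_HZ) -> PitchTrack:
    """Read a Praat short-format PitchTier text file as a semitone PitchTrack.

    PitchTier values are in Hz and are converted with ``ref_hz``.  The points
    must be uniformly spaced in time (same contract as the CSV reader).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2 or "ooTextFile" not in lines[0] or "PitchTier" not in lines[1]:
        raise TrackFormatError(f"{path}: not a short-format PitchTier file")
    nums = []
    for ln in lines[2:]:
        # short format: bare numbers; long format lines like "value = 450" also accepted
        token = ln.split("=")[-1].strip()
        try:
            nums.append(float(token))
        except ValueError:
            continue
    if len(nums) < 3:
        raise TrackFormatError(f"{path}: no points found")
    n = int(nums[2])
    pairs = nums[3:3 + 2 * n]
    if len(pairs) != 2 * n:
        raise TrackFormatError(f"{path}: expected {n} points, file truncated")
    times = np.asarray(pairs[0::2])
    hz = np.asarray(pairs[1::2])
    if n < 2:
        raise TrackFormatError(f"{path}: need at least 2 points")
    step = times[1] - times[0]
    diffs = np.diff(times)
    bad = np.nonzero(np.abs(diffs - step) > _TIME_TOL)[0]
    if bad.size:
        raise TrackFormatError(f"{path}: non-uniform sampling at point {bad[0] + 2}")
    return PitchTrack(values=hz_to_semitones(hz, ref_hz),
                      sample_rate=1.0 / step, start_time=float(times[0]))
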