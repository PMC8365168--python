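from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from whistlechain.io_tracks import IntensityTrack, PitchTrack, Whistle
from whistlechain.segmentation import AnalyzedWhistle, PitchTarget, Segment

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

RATE = 500.0


def make_whistle(pitch, intensity=None, whistle_id="w0", chain_id="c0",
                 generation=1, rate=RATE) -> Whistle:
    pitch = np.asarray(pitch, dtype=float)
    if intensity is None:
        intensity = np.where(np.isnan(pitch), 0.0, 70.0)
    return Whistle(whistle_id=whistle_id, chain_id=chain_id,
                   generation=generation,
                   pitch=PitchTrack(values=pitch, sample_rate=rate),
                   intensity=IntensityTrack(values=np.asarray(intensity, float),
                                            sample_rate=rate))


def make_segment(values, whistle_id="w0", index=0, start=0, rate=RATE) -> Segment:
    values = np.asarray(values, dtype=float)
    return Segment(whistle_id=whistle_id, index=index, start_sample=start,
                   end_sample=start + values.size, sample_rate=rate,
                   start_time=start / rate, pitch_values=values)


def analyzed_from_onsets(onsets, seg_len=50, gap=25, whistle_id="w0",
                         rate=RATE) -> AnalyzedWhistle:
    """A whistle whose segments are flat holds at the given onset pitches."""
    segments, targets, pitch = [], [], []
    cursor = 0
    for i, onset in enumerate(onsets):
        if i > 0:
            pitch.extend([np.nan] * gap)
            cursor += gap
        vals = np.full(seg_len, float(onset))
        segments.append(Segment(whistle_id=whistle_id, index=i,
                                start_sample=cursor,
                                end_sample=cursor + seg_len, sample_rate=rate,
                                start_time=cursor / rate, pitch_values=vals))
        targets.append([PitchTarget(0, float(onset), "start"),
                        PitchTarget(seg_len - 1, float(onset), "end")])
        pitch.extend(vals.tolist())
        cursor += seg_len
    whistle = make_whistle(pitch, whistle_id=whistle_id, rate=rate)
    return AnalyzedWhistle(whistle=whistle, segments=segments, targets=targets)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
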