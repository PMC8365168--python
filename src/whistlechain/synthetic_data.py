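"""Synthetic whistle sets and transmission chains with planted structure.

The study conditions these defaults emulate: 4 parallel chains of 10
generations, each generation a set of 12 whistles produced on a slide
whistle confined to roughly 450-2500 Hz, whistles averaging about 2.5 s and
composed of sounding segments (mean about 0.5 s) separated by silences.

Every generated set carries a ground-truth record (planted scale levels,
per-segment building-block type and contour label, per-whistle block
sequences, empirical label entropy), so each downstream measure can be
verified by parameter recovery.  Chains drift linearly between a start and
an end parameterization, which makes slope recovery by the linear trend
models well-posed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tracks import (INSTRUMENT_CEILING_HZ, INSTRUMENT_FLOOR_HZ,
                        ChainDataset, IntensityTrack, PitchTrack, Whistle,
                        WhistleSet, hz_to_semitones)
from .motif_universals import shannon_entropy
from .pitch_universals import CONTOUR_LABELS


class ValidationError(ValueError):
    """Generator parameters are infeasible or inconsistent."""


def _default_mixture() -> dict[str, float]:
    return {"horizontal": 0.25, "ascending": 0.15, "descending": 0.25,
            "arched": 0.15, "u_shaped": 0.10, "undulating": 0.10}


@dataclass
class GeneratorParams:
    """Everything that shapes one generated whistle set.

    ``n_pitch_levels = 0`` means a continuous pitch space (no scale);
    ``>= 2`` plants that many equally spaced scale levels that anchor every
    pitch target.  ``block_reuse_concentration`` controls how unevenly the
    building-block types are drawn (0 = uniform use, larger = heavier reuse
    of the first blocks, hence lower label entropy and higher chunk
    strength).
    """

    n_whistles: int = 12
    pitch_floor_hz: float = INSTRUMENT_FLOOR_HZ
    pitch_ceiling_hz: float = INSTRUMENT_CEILING_HZ
    sample_rate: float = 500.0
    n_pitch_levels: int = 3
    level_jitter_sd: float = 0.5
    n_block_types: int = 5
    block_reuse_concentration: float = 1.0
    contour_mixture: dict[str, float] = field(default_factory=_default_mixture)
    mean_segment_duration_s: float = 0.5
    mean_gap_duration_s: float = 0.2
    segments_per_whistle_mean: float = 4.0
    onset_interval_scale_st: float = 4.0
    pitch_noise_sd: float = 0.2
    seed: int | None = None

    def validate(self) -> None:
        if self.n_whistles < 1:
            raise ValidationError("n_whistles must be >= 1")
        if not 0 < self.pitch_floor_hz < self.pitch_ceiling_hz:
            raise ValidationError("need 0 < pitch_floor_hz < pitch_ceiling_hz")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.n_pitch_levels < 0:
            raise ValidationError("n_pitch_levels must be >= 0")
        for name in ("level_jitter_sd", "pitch_noise_sd",
                     "block_reuse_concentration"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_block_types < 1:
            raise ValidationError("n_block_types must be >= 1")
        unknown = set(self.contour_mixture) - set(CONTOUR_LABELS)
        if unknown:
            raise ValidationError(f"unknown contour labels {sorted(unknown)}")
        total = sum(self.contour_mixture.values())
        if abs(total - 1.0) > 1e-6 or min(self.contour_mixture.values()) < 0:
            raise ValidationError("contour_mixture must be a probability vector")
        if min(self.mean_segment_duration_s, self.mean_gap_duration_s) <= 0:
            raise ValidationError("durations must be positive")
        if self.segments_per_whistle_mean < 1:
            raise ValidationError("segments_per_whistle_mean must be >= 1")
        lo, hi = self.semitone_bounds()
        if self.n_pitch_levels >= 2:
            spacing = (hi - lo) / (self.n_pitch_levels - 1)
            if spacing < 3 * self.level_jitter_sd:
                raise ValidationError(
                    f"scale spacing {spacing:.2f} st is below 3x the level "
                    f"jitter ({self.level_jitter_sd} st): levels would smear")

    def semitone_bounds(self) -> tuple[float, float]:
        """Usable semitone window: instrument range minus a safety margin so
        jitter and noise cannot push samples out of bounds."""
        margin = 1.0 + 3.0 * (self.level_jitter_sd + self.pitch_noise_sd)
        lo = hz_to_semitones(self.pitch_floor_hz) + margin
        hi = hz_to_semitones(self.pitch_ceiling_hz) - margin
        if hi <= lo:
            raise ValidationError("pitch bounds too narrow for jitter/noise margin")
        return lo, hi

    def scale_levels(self) -> np.ndarray | None:
        """Planted scale (semitones), or None for a continuous pitch space."""
        lo, hi = self.semitone_bounds()
        if self.n_pitch_levels == 0:
            return None
        if self.n_pitch_levels == 1:
            return np.array([(lo + hi) / 2.0])
        return np.linspace(lo, hi, self.n_pitch_levels)


# contour shapes as relative target offsets in units of one excursion
_SHAPES: dict[str, tuple[float, ...]] = {
    "horizontal": (0.0, 0.0),
    "ascending": (0.0, 1.0),
    "descending": (0.0, -1.0),
    "arched": (0.0, 1.0, 0.0),
    "u_shaped": (0.0, -1.0, 0.0),
    "undulating": (0.0, 1.0, 0.0, 1.0),
}


@dataclass
class BlockTemplate:
    block_id: int
    label: str
    rise_st: float

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(_SHAPES[self.label]) * self.rise_st

    @property
    def n_targets(self) -> int:
        return len(_SHAPES[self.label])


@dataclass
class SetGroundTruth:
    """Planted structure of one generated whistle set."""

    chain_id: str
    generation: int
    params: GeneratorParams
    scale_levels: np.ndarray | None
    templates: list[BlockTemplate]
    records: list[dict] = field(default_factory=list)
    block_sequences: list[list[int]] = field(default_factory=list)

    @property
    def label_entropy_bits(self) -> float:
        labels = [r["block_id"] for r in self.records]
        counts = np.bincount(labels, minlength=1)
        return shannon_entropy(counts[counts > 0])

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = dict(r)
            row["chain_id"] = self.chain_id
            row["generation"] = self.generation
            row["target_values_st"] = ";".join(f"{v:.4f}"
                                               for v in r["target_values_st"])
            rows.append(row)
        return pd.DataFrame(rows)


def _make_templates(params: GeneratorParams, rng: np.random.Generator,
                    ) -> list[BlockTemplate]:
    lo, hi = params.semitone_bounds()
    span = hi - lo
    labels = list(CONTOUR_LABELS)
    probs = np.array([params.contour_mixture.get(l, 0.0) for l in labels])
    support = int(np.count_nonzero(probs))
    n = params.n_block_types
    if n <= support:
        chosen = list(rng.choice(labels, size=n, replace=False, p=probs))
    else:
        chosen = list(rng.choice(labels, size=n, replace=True, p=probs))
    levels = params.scale_levels()
    templates: list[BlockTemplate] = []
    dup_count: dict[str, int] = {}
    for i, label in enumerate(chosen):
        dup = dup_count.get(label, 0)
        dup_count[label] = dup + 1
        if levels is not None and levels.size >= 2:
            spacing = levels[1] - levels[0]
            steps = max(1, int(round(10.0 / spacing))) + dup
            steps = min(steps, levels.size - 1)
            rise = steps * spacing
        else:
            rise = min(rng.uniform(8.0, 14.0) + 6.0 * dup, 0.9 * span)
        templates.append(BlockTemplate(block_id=i, label=label, rise_st=rise))
    return templates


def _reflect(x: float, a: float, b: float) -> float:
    if b <= a:
        return a
    span = b - a
    y = (x - a) % (2 * span)
    return a + (span - abs(y - span))


def _choose_onset(template: BlockTemplate, prev_onset: float | None,
                  params: GeneratorParams, levels: np.ndarray | None,
                  rng: np.random.Generator) -> float:
    lo, hi = params.semitone_bounds()
    off = template.offsets
    a, b = lo - float(off.min()), hi - float(off.max())
    if levels is not None:
        feasible = levels[(levels >= a - 1e-9) & (levels <= b + 1e-9)]
        if feasible.size == 0:
            feasible = np.array([min(max((a + b) / 2.0, a), b)])
        if prev_onset is None:
            return float(rng.choice(feasible))
        delta = rng.exponential(params.onset_interval_scale_st)
        proposal = _reflect(prev_onset + rng.choice([-1.0, 1.0]) * delta, a, b)
        return float(feasible[np.argmin(np.abs(feasible - proposal))])
    if prev_onset is None:
        return float(rng.uniform(a, b))
    delta = rng.exponential(params.onset_interval_scale_st)
    return _reflect(prev_onset + rng.choice([-1.0, 1.0]) * delta, a, b)


def _render_segment(template: BlockTemplate, onset: float, n_samples: int,
                    params: GeneratorParams, rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pitch samples for one segment plus the planted target values."""
    targets = onset + template.offsets \
        + rng.normal(0.0, params.level_jitter_sd, template.n_targets)
    breakpoints = np.linspace(0, n_samples - 1, template.n_targets)
    pitch = np.interp(np.arange(n_samples), breakpoints, targets)
    if params.pitch_noise_sd > 0:
        pitch = pitch + rng.normal(0.0, params.pitch_noise_sd, n_samples)
    abs_lo = hz_to_semitones(params.pitch_floor_hz)
    abs_hi = hz_to_semitones(params.pitch_ceiling_hz)
    return np.clip(pitch, abs_lo, abs_hi), targets


def generate_whistle_set(params: GeneratorParams, chain_id: str = "chain1",
                         generation: int = 1, seed=None,
                         ) -> tuple[WhistleSet, SetGroundTruth]:
    """Generate one whistle set with known planted structure.

    Deterministic given the seed (argument, falling back to ``params.seed``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    levels = params.scale_levels()
    templates = _make_templates(params, rng)
    c = params.block_reuse_concentration
    weights = np.exp(-c * np.arange(params.n_block_types))
    block_probs = weights / weights.sum()
    rate = params.sample_rate

    truth = SetGroundTruth(chain_id=chain_id, generation=generation,
                           params=params, scale_levels=levels,
                           templates=templates)
    whistles: list[Whistle] = []
    for w in range(params.n_whistles):
        wid = f"{chain_id}_g{generation:02d}_w{w:02d}"
        n_segments = 1 + rng.poisson(max(params.segments_per_whistle_mean - 1, 0.0))
        block_ids = rng.choice(params.n_block_types, size=n_segments,
                               p=block_probs)
        pitch_parts: list[np.ndarray] = []
        intensity_parts: list[np.ndarray] = []
        cursor = 0
        prev_onset: float | None = None
        seq: list[int] = []
        for s, bid in enumerate(block_ids):
            template = templates[int(bid)]
            if s > 0:
                gap = float(np.clip(rng.gamma(4.0, params.mean_gap_duration_s / 4.0),
                                    0.04, 4.0 * params.mean_gap_duration_s))
                gap_n = max(int(round(gap * rate)), int(0.04 * rate))
                pitch_parts.append(np.full(gap_n, np.nan))
                intensity_parts.append(np.zeros(gap_n))
                cursor += gap_n
            dur = float(np.clip(rng.gamma(4.0, params.mean_segment_duration_s / 4.0),
                                0.15, 4.0 * params.mean_segment_duration_s))
            n_samp = max(int(round(dur * rate)), int(0.15 * rate))
            onset = _choose_onset(template, prev_onset, params, levels, rng)
            pitch, target_vals = _render_segment(template, onset, n_samp,
                                                 params, rng)
            level = rng.uniform(60.0, 90.0)
            pitch_parts.append(pitch)
            intensity_parts.append(np.full(n_samp, level))
            truth.records.append({
                "whistle_id": wid, "segment_index": s,
                "block_id": int(bid), "contour_label": template.label,
                "onset_st": onset, "start_sample": cursor,
                "end_sample": cursor + n_samp,
                "target_values_st": target_vals.tolist(),
            })
            cursor += n_samp
            prev_onset = onset
            seq.append(int(bid))
        truth.block_sequences.append(seq)
        pitch_track = PitchTrack(values=np.concatenate(pitch_parts),
                                 sample_rate=rate)
        intensity_track = IntensityTrack(values=np.concatenate(intensity_parts),
                                         sample_rate=rate)
        whistles.append(Whistle(whistle_id=wid, chain_id=chain_id,
                                generation=generation, pitch=pitch_track,
                                intensity=intensity_track))
    wset = WhistleSet(chain_id=chain_id, generation=generation,
                      whistles=whistles)
    return wset, truth


# ---------------------------------------------------------------------------
# Chains: linear drift between a start and an end parameterization
# ---------------------------------------------------------------------------

@dataclass
class ChainPlan:
    start_params: GeneratorParams
    end_params: GeneratorParams
    n_generations: int = 10
    n_chains: int = 4

    def validate(self) -> None:
        if self.n_generations < 2:
            raise ValidationError("n_generations must be >= 2")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        self.start_params.validate()
        self.end_params.validate()


_INT_FIELDS = {"n_whistles", "n_pitch_levels", "n_block_types"}


def interpolate_params(start: GeneratorParams, end: GeneratorParams,
                       frac: float) -> GeneratorParams:
    """Per-field linear interpolation between two parameterizations.

    Integer fields are rounded; the contour mixture is blended elementwise
    and renormalized; seeds are dropped (chain generation assigns its own).
    """
    kwargs = {}
    for f in dataclasses.fields(GeneratorParams):
        a, b = getattr(start, f.name), getattr(end, f.name)
        if f.name == "seed":
            kwargs[f.name] = None
        elif f.name == "contour_mixture":
            keys = sorted(set(a) | set(b))
            mix = {k: (1 - frac) * a.get(k, 0.0) + frac * b.get(k, 0.0)
                   for k in keys}
            total = sum(mix.values())
            kwargs[f.name] = {k: v / total for k, v in mix.items()}
        elif f.name in _INT_FIELDS:
            kwargs[f.name] = int(round((1 - frac) * a + frac * b))
        else:
            kwargs[f.name] = (1 - frac) * a + frac * b
    return GeneratorParams(**kwargs)


def generate_chain_dataset(plan: ChainPlan, seed: int | None = None,
                           ) -> tuple[ChainDataset,
                                      dict[tuple[str, int], SetGroundTruth]]:
    """Generate every (chain, generation) set of a transmission-chain plan.

    Generation g (1-based) uses parameters interpolated at
    ``(g - 1) / (n_generations - 1)``; each set gets an independent child
    seed derived from the master seed, so chains share the drift schedule
    but not their noise.
    """
    plan.validate()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(plan.n_chains * plan.n_generations)
    chains: dict[str, list[WhistleSet]] = {}
    truths: dict[tuple[str, int], SetGroundTruth] = {}
    k = 0
    for c in range(plan.n_chains):
        chain_id = f"chain{c + 1}"
        sets: list[WhistleSet] = []
        for g in range(1, plan.n_generations + 1):
            frac = (g - 1) / (plan.n_generations - 1)
            params = interpolate_params(plan.start_params, plan.end_params,
                                        frac)
            wset, truth = generate_whistle_set(params, chain_id=chain_id,
                                               generation=g, seed=children[k])
            k += 1
            sets.append(wset)
            truths[(chain_id, g)] = truth
        chains[chain_id] = sets
    return ChainDataset(chains=chains), truths


def ground_truth_frame(truths: dict[tuple[str, int], SetGroundTruth],
                       ) -> pd.DataFrame:
    frames = [truths[k].frame() for k in sorted(truths)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def initial_set_params(seed: int | None = None) -> GeneratorParams:
    """Analogue of the deliberately unstructured seed material given to the
    first participants: continuous pitch (no scale), essentially no block
    reuse, and a descending-heavy contour mixture."""
    return GeneratorParams(
        n_pitch_levels=0,
        n_block_types=12,
        block_reuse_concentration=0.0,
        contour_mixture={"horizontal": 0.12, "ascending": 0.12,
                         "descending": 0.32, "arched": 0.0,
                         "u_shaped": 0.14, "undulating": 0.30},
        seed=seed,
    )


def drifting_plan(n_generations: int = 10, n_chains: int = 4) -> ChainPlan:
    """Default drifting plan: discreteness and block reuse increase over
    generations while contour complexity decreases — the qualitative pattern
    the measures are built to detect."""
    start = GeneratorParams(
        n_pitch_levels=2,
        block_reuse_concentration=0.3,
        contour_mixture={"horizontal": 0.10, "ascending": 0.10,
                         "descending": 0.10, "arched": 0.25,
                         "u_shaped": 0.15, "undulating": 0.30},
    )
    end = GeneratorParams(
        n_pitch_levels=5,
        block_reuse_concentration=2.2,
        contour_mixture={"horizontal": 0.35, "ascending": 0.15,
                         "descending": 0.30, "arched": 0.10,
                         "u_shaped": 0.05, "undulating": 0.05},
    )
    return ChainPlan(start_params=start, end_params=end,
                     n_generations=n_generations, n_chains=n_chains)


def constant_plan(params: GeneratorParams | None = None,
                  n_generations: int = 10, n_chains: int = 4) -> ChainPlan:
    """Null plan: every generation exchangeable (no drift)."""
    p = params or GeneratorParams()
    return ChainPlan(start_params=p, end_params=dataclasses.replace(p),
                     n_generations=n_generations, n_chains=n_chains)
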