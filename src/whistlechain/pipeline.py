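"""Orchestration: dataset -> tidy measure table -> trend report.

The measure table is long-format with one row per (set, measure) for
set-level measures and one row per whistle / segment / interval observation
for the lower-level ones.  Columns: chain_id, generation, whistle_id (empty
for set-level rows), item (observation index within whistle, empty
otherwise), dataset ('actual'/'shuffled' for the interval pair, empty
otherwise), measure, unit, value, degenerate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import motif_universals as motif
from . import pitch_universals as pu
from .config import MeasureConfig, PipelineConfig
from .io_tracks import ChainDataset
from .segmentation import SegmentationConfig, analyze_set
from .trends import fit_all_trends

#: Measures fitted with the generation x dataset interaction model.
INTERACTION_MEASURES = ("mean_onset_interval",)

MEASURE_COLUMNS = ("chain_id", "generation", "whistle_id", "item", "dataset",
                   "measure", "unit", "value", "degenerate")


def _row(analyzed, measure, unit, value, whistle_id="", item="", dataset="",
         degenerate=False) -> dict:
    return {"chain_id": analyzed.chain_id, "generation": analyzed.generation,
            "whistle_id": whistle_id, "item": item, "dataset": dataset,
            "measure": measure, "unit": unit, "value": value,
            "degenerate": degenerate}


def measure_set(analyzed, cfg: MeasureConfig, rng: np.random.Generator,
                ) -> list[dict]:
    """All measure rows of one analyzed whistle set."""
    rows: list[dict] = []
    targets = pu.collect_tone_targets(analyzed)

    if targets.size >= 2:
        disc = pu.gmm_component_count(targets, k_max=cfg.k_max,
                                      n_runs=cfg.n_runs,
                                      seed=int(rng.integers(2**31 - 1)))
        ok, _ = pu.few_elements_check(disc)
        rows.append(_row(analyzed, "chi2_uniform", "stat", disc.chi2,
                         degenerate=disc.degenerate))
        rows.append(_row(analyzed, "chi2_p", "p", disc.p_value,
                         degenerate=disc.degenerate))
        rows.append(_row(analyzed, "gmm_components", "count",
                         disc.mean_components))
        rows.append(_row(analyzed, "few_elements_ok", "bool", float(ok)))

    if analyzed.n_segments > 0:
        props = pu.contour_proportions(analyzed, cfg.slide_threshold)
        for label in pu.CONTOUR_LABELS:
            rows.append(_row(analyzed, f"contour_prop_{label}", "proportion",
                             props[label]))
        segments = [seg for seg, _ in analyzed.iter_segments()]
        result, _labeling = motif.motif_measures(
            segments, threshold=cfg.block_threshold,
            resample_len=cfg.resample_len,
            smooth_window=cfg.ddtw_smooth_window,
            entropy_base=cfg.entropy_base)
        rows.append(_row(analyzed, "entropy", "bits", result.entropy))
        rows.append(_row(analyzed, "n_blocks", "count", result.n_blocks))
        rows.append(_row(analyzed, "chunk_strength", "count",
                         result.chunk_strength,
                         degenerate=bool(np.isnan(result.chunk_strength))))

    all_intervals: list[float] = []
    for aw in analyzed.whistles:
        wid = aw.whistle.whistle_id
        phrase = pu.phrase_measures(aw)
        rows.append(_row(analyzed, "n_segments", "count", phrase.n_segments,
                         whistle_id=wid, degenerate=phrase.degenerate))
        rows.append(_row(analyzed, "whistle_duration_s", "s",
                         phrase.whistle_duration_s, whistle_id=wid,
                         degenerate=phrase.degenerate))
        rows.append(_row(analyzed, "mean_segment_duration_s", "s",
                         phrase.mean_segment_duration_s, whistle_id=wid,
                         degenerate=phrase.degenerate))
        for seg, targs in zip(aw.segments, aw.targets):
            rows.append(_row(analyzed, "targets_per_segment", "count",
                             len(targs), whistle_id=wid, item=str(seg.index)))
        intervals = pu.onset_intervals(aw)
        for i, v in enumerate(intervals):
            rows.append(_row(analyzed, "onset_interval_st", "st", float(v),
                             whistle_id=wid, item=str(i)))
        all_intervals.extend(intervals.tolist())
        icr = pu.compression_ratio(aw, n_shuffles=cfg.n_shuffles,
                                   seed=int(rng.integers(2**31 - 1)))
        rows.append(_row(analyzed, "compression_ratio", "ratio",
                         icr.compression_ratio, whistle_id=wid,
                         degenerate=icr.degenerate))
        if not icr.degenerate:
            rows.append(_row(analyzed, "mean_onset_interval", "st",
                             icr.mean_actual, whistle_id=wid,
                             dataset="actual"))
            rows.append(_row(analyzed, "mean_onset_interval", "st",
                             icr.mean_shuffled, whistle_id=wid,
                             dataset="shuffled"))

    if all_intervals:
        frac = float(np.mean(np.asarray(all_intervals) <= pu.SMALL_INTERVAL_ST))
        rows.append(_row(analyzed, "prop_intervals_leq_750c", "proportion",
                         frac))
    return rows


def measure_dataset(dataset: ChainDataset,
                    seg_config: SegmentationConfig | None = None,
                    measure_config: MeasureConfig | None = None,
                    seed: int | None = 0) -> pd.DataFrame:
    """Measure every set of a dataset; deterministic given the seed."""
    seg_cfg = seg_config or SegmentationConfig()
    cfg = measure_config or MeasureConfig()
    ss = np.random.SeedSequence(seed)
    sets = list(dataset.sets())
    children = ss.spawn(len(sets))
    rows: list[dict] = []
    for wset, child in zip(sets, children):
        analyzed = analyze_set(wset, seg_cfg)
        rows.extend(measure_set(analyzed, cfg, np.random.default_rng(child)))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def write_measures(table: pd.DataFrame, path, config: PipelineConfig | None = None,
                   seed: int | None = None) -> None:
    """Write the measure table with run metadata as header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__
    with open(path, "w", newline="") as fh:
        fh.write(f"# whistlechain {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config.hash()}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        table.to_csv(fh, index=False)


def read_measures(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#",
                     dtype={"whistle_id": str, "item": str, "dataset": str},
                     keep_default_na=False, na_values=[""])
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def trend_report(table: pd.DataFrame, min_generations: int = 3) -> pd.DataFrame:
    """Fit generation trends for every fit-worthy measure in a table."""
    fit_table = table[~table["degenerate"].astype(bool)].copy()
    skip = {"chi2_p", "few_elements_ok"}  # derived / non-trend measures
    fit_table = fit_table[~fit_table["measure"].isin(skip)]
    return fit_all_trends(fit_table, min_generations=min_generations,
                          interaction_measures=INTERACTION_MEASURES)


def format_report(trends: pd.DataFrame) -> str:
    """Human-readable trend lines: measure, b +- SEM, df, P."""
    lines = []
    for _, r in trends.iterrows():
        term = "" if r["term"] == "generation" else f" [{r['term']}]"
        lines.append(f"{r['measure']}{term}: b = {r['b']:.4f} ± {r['sem']:.4f} "
                     f"SEM, df = {r['df']:.1f}, P = {r['p']:.4g}")
    return "\n".join(lines)
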