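"""Per-set measures for the pitch-domain melodic universals.

Covers discreteness of pitch targets (chi-square against uniform plus
BIC-selected Gaussian-mixture component counts), the few-elements scale
constraint, melodic contour classification into six categories, onset-to-
onset interval sizes with the shuffle-null interval compression ratio, and
phrase-length measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .segmentation import AnalyzedSet, AnalyzedWhistle, PitchTarget

CONTOUR_LABELS = ("horizontal", "ascending", "descending",
                  "arched", "u_shaped", "undulating")

#: Reporting constant: the "small interval" reference, 750 cents = 7.5 st.
SMALL_INTERVAL_ST = 7.5

#: Reporting constant: the "short phrase" reference duration, seconds.
SHORT_PHRASE_S = 9.0


# ---------------------------------------------------------------------------
# MU1 / MU2: discreteness of tone targets
# ---------------------------------------------------------------------------

@dataclass
class Chi2Result:
    chi2: float
    df: int
    p_value: float
    n_bins: int
    degenerate: bool = False


@dataclass
class DiscretenessResult:
    """Joint discreteness summary of one whistle set's tone targets."""

    chi2: float
    df: int
    p_value: float
    n_targets: int
    mean_components: float
    per_run_components: list[int] = field(default_factory=list)
    degenerate: bool = False


def collect_tone_targets(analyzed: AnalyzedSet) -> np.ndarray:
    """All target semitone values (start/peak/valley/end) of a set, in
    whistle order then segment order then target order."""
    vals = [t.value for _, targs in analyzed.iter_segments() for t in targs]
    return np.asarray(vals, dtype=float)


def chi2_uniform(targets, bin_width: float = 1.0,
                 range_override: tuple[float, float] | None = None) -> Chi2Result:
    """Goodness-of-fit of target values against a uniform distribution.

    Bins are consecutive ``bin_width``-wide intervals covering
    ``[floor(min), ceil(max))`` (or the explicit range override); expected
    counts are n/k per bin, and the statistic is the usual sum of
    (observed - expected)^2 / expected with k - 1 degrees of freedom.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.size < 2:
        raise ValueError("need at least 2 targets")
    if range_override is not None:
        lo, hi = map(float, range_override)
    else:
        lo, hi = float(np.floor(targets.min())), float(np.ceil(targets.max()))
    k = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    observed, _ = np.histogram(targets, bins=k, range=(lo, lo + k * bin_width))
    if k == 1:
        return Chi2Result(chi2=0.0, df=0, p_value=1.0, n_bins=1, degenerate=True)
    chi2, p = stats.chisquare(observed)
    return Chi2Result(chi2=float(chi2), df=k - 1, p_value=float(p), n_bins=k)


def gmm_component_count(targets, k_max: int = 10, n_runs: int = 100,
                        seed=None) -> DiscretenessResult:
    """Average BIC-selected Gaussian-mixture component count over restarts.

    Each run fits one-dimensional mixtures with free means and variances for
    k = 1..k_max from a fresh random initialization and keeps the k with the
    lowest BIC; restart-to-restart variability is averaged away over
    ``n_runs`` runs.  Deterministic given ``seed``.
    """
    x = np.asarray(targets, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if n < k_max + 1:
        warnings.warn(f"only {n} targets; lowering k_max from {k_max} to {n - 1}")
        k_max = max(1, n - 1)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    per_run: list[int] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in run_seeds:
            best_k, best_bic = 1, np.inf
            for k in range(1, k_max + 1):
                # k-means++ seeding: the restart is still random, but a bad
                # draw cannot strand EM in a degenerate optimum that would
                # make an overfitted k win the BIC comparison
                gm = GaussianMixture(n_components=k, covariance_type="full",
                                     n_init=1, init_params="k-means++",
                                     max_iter=200, reg_covar=1e-6,
                                     random_state=int(s) % (2**31 - 1))
                gm.fit(x)
                bic = gm.bic(x)
                if bic < best_bic - 1e-12:
                    best_k, best_bic = k, bic
            per_run.append(best_k)
    chi2 = chi2_uniform(targets) if n >= 2 else Chi2Result(0.0, 0, 1.0, 1, True)
    return DiscretenessResult(chi2=chi2.chi2, df=chi2.df, p_value=chi2.p_value,
                              n_targets=n,
                              mean_components=float(np.mean(per_run)),
                              per_run_components=per_run,
                              degenerate=chi2.degenerate)


def few_elements_check(result: DiscretenessResult | float,
                       limit: int = 7) -> tuple[bool, int]:
    """Scale-size constraint: rounded mean component count at most ``limit``.

    Returns (satisfied, rounded count).  Accepts a DiscretenessResult or a
    bare mean.  Rounding is half-up for stability across platforms.
    """
    mean = result.mean_components if isinstance(result, DiscretenessResult) \
        else float(result)
    rounded = int(np.floor(mean + 0.5))
    return rounded <= limit, rounded


# ---------------------------------------------------------------------------
# MU3: contour classification
# ---------------------------------------------------------------------------

def classify_contour(targets, slide_threshold: float = 1.0) -> str:
    """Classify a segment's target sequence into one of six contour types.

    Successive target differences smaller in magnitude than
    ``slide_threshold`` are level and dropped.  No remaining differences:
    horizontal; all positive: ascending; all negative: descending; a single
    +/- sign change: arched; a single -/+ change: u_shaped; two or more
    changes: undulating.
    """
    vals = np.asarray([t.value if isinstance(t, PitchTarget) else float(t)
                       for t in targets])
    if vals.size == 1:
        return "horizontal"  # degenerate
    if vals.size < 1:
        raise ValueError("need at least 1 target")
    diffs = np.diff(vals)
    moves = diffs[np.abs(diffs) >= slide_threshold]
    if moves.size == 0:
        return "horizontal"
    signs = np.sign(moves)
    if np.all(signs > 0):
        return "ascending"
    if np.all(signs < 0):
        return "descending"
    changes = np.flatnonzero(np.diff(signs) != 0)
    if changes.size == 1:
        return "arched" if signs[0] > 0 else "u_shaped"
    return "undulating"


def contour_proportions(analyzed: AnalyzedSet,
                        slide_threshold: float = 1.0) -> dict[str, float]:
    """Proportion of each contour type over all segments of a set."""
    labels = [classify_contour(targs, slide_threshold)
              for _, targs in analyzed.iter_segments()]
    if not labels:
        raise ValueError(f"set {analyzed.chain_id}/{analyzed.generation} "
                         f"has no segments")
    n = len(labels)
    return {lab: labels.count(lab) / n for lab in CONTOUR_LABELS}


# ---------------------------------------------------------------------------
# MU4: onset-to-onset intervals and the interval compression ratio
# ---------------------------------------------------------------------------

@dataclass
class IntervalResult:
    actual_intervals: np.ndarray
    mean_actual: float
    mean_shuffled: float
    compression_ratio: float
    shuffled_means: np.ndarray
    degenerate: bool = False


def onset_intervals(analyzed: AnalyzedWhistle) -> np.ndarray:
    """Absolute semitone differences between consecutive segment onsets."""
    onsets = analyzed.onsets_st
    if onsets.size < 2:
        return np.empty(0)
    return np.abs(np.diff(onsets))


def compression_ratio(analyzed: AnalyzedWhistle, n_shuffles: int = 100,
                      seed=None) -> IntervalResult:
    """Shuffle-null interval compression ratio of one whistle.

    The mean absolute onset-to-onset interval under random reordering of the
    segments, divided by the actual mean interval.  Values above 1 mean the
    produced order uses smaller pitch jumps than chance.  Undefined (marked
    degenerate, NaN ratio) for fewer than 2 segments or a zero actual mean.
    """
    onsets = analyzed.onsets_st
    actual = np.abs(np.diff(onsets)) if onsets.size >= 2 else np.empty(0)
    if onsets.size < 2 or float(actual.mean()) == 0.0:
        return IntervalResult(actual_intervals=actual,
                              mean_actual=float(actual.mean()) if actual.size else np.nan,
                              mean_shuffled=np.nan, compression_ratio=np.nan,
                              shuffled_means=np.empty(0), degenerate=True)
    rng = np.random.default_rng(seed)
    means = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(onsets)
        means[i] = np.abs(np.diff(perm)).mean()
    mean_actual = float(actual.mean())
    mean_shuffled = float(means.mean())
    return IntervalResult(actual_intervals=actual, mean_actual=mean_actual,
                          mean_shuffled=mean_shuffled,
                          compression_ratio=mean_shuffled / mean_actual,
                          shuffled_means=means)


# ---------------------------------------------------------------------------
# MU7: phrase measures
# ---------------------------------------------------------------------------

@dataclass
class PhraseResult:
    n_segments: int
    whistle_duration_s: float
    mean_segment_duration_s: float
    degenerate: bool = False


def phrase_measures(analyzed: AnalyzedWhistle) -> PhraseResult:
    """Segment count, whistle span (first onset to last offset) and mean
    segment duration, in seconds."""
    segs = analyzed.segments
    if not segs:
        return PhraseResult(0, 0.0, 0.0, degenerate=True)
    rate = segs[0].sample_rate
    duration = (segs[-1].end_sample - segs[0].start_sample) / rate
    mean_seg = float(np.mean([s.duration for s in segs]))
    return PhraseResult(n_segments=len(segs), whistle_duration_s=duration,
                        mean_segment_duration_s=mean_seg)


def targets_per_segment(analyzed: AnalyzedSet) -> list[int]:
    """Number of pitch targets of each segment (contour-complexity proxy)."""
    return [len(targs) for _, targs in analyzed.iter_segments()]
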