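"""Building-block discovery and motif/repetition measures.

Whistle segments are compared by Derivative Dynamic Time Warping (DTW on
locally estimated derivatives, so similarity reflects movement *shape*
through pitch space rather than absolute pitch), clustered with
average-linkage agglomerative clustering under a merge threshold, and the
resulting building-block inventory feeds Shannon entropy (compressibility /
reuse of elements) and associative chunk strength (recurring bigram/trigram
sequences of blocks).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .segmentation import Segment, moving_average

#: Merge threshold below which two segments count as the same building block.
#: Scale depends on the distance normalization documented in ddtw_distance.
DEFAULT_BLOCK_THRESHOLD = 0.08

#: Length every segment is resampled to before derivative estimation.
DEFAULT_RESAMPLE_LEN = 25

#: Moving-average window (samples of the raw 500 Hz track) applied to segment
#: pitch before DDTW when clustering, to keep sample noise out of derivatives.
DEFAULT_DDTW_SMOOTH = 25


def _resample(values: np.ndarray, length: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size == length:
        return x.copy()
    return np.interp(np.linspace(0.0, x.size - 1.0, length),
                     np.arange(x.size), x)


def derivative_estimate(q: np.ndarray) -> np.ndarray:
    """Keogh-Pazzani local derivative.

    Interior points: d_i = ((q_i - q_{i-1}) + (q_{i+1} - q_{i-1}) / 2) / 2;
    boundary points copy their neighbour's estimate.
    """
    q = np.asarray(q, dtype=float)
    if q.size < 3:
        raise ValueError("need at least 3 samples for a derivative estimate")
    d = np.empty_like(q)
    d[1:-1] = ((q[1:-1] - q[:-2]) + (q[2:] - q[:-2]) / 2.0) / 2.0
    d[0] = d[1]
    d[-1] = d[-2]
    return d


@njit(cache=True)
def _dtw_normalized(da: np.ndarray, db: np.ndarray) -> float:  # pragma: no cover
    """DTW on derivative sequences: squared local cost, accumulated cost
    divided by the optimal warping path's length.  Ties prefer the diagonal,
    then the vertical, then the horizontal predecessor."""
    n, m = da.shape[0], db.shape[0]
    acc = np.empty((n, m))
    plen = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            c = (da[i] - db[j]) ** 2
            if i == 0 and j == 0:
                acc[i, j] = c
                plen[i, j] = 1
            elif i == 0:
                acc[i, j] = acc[i, j - 1] + c
                plen[i, j] = plen[i, j - 1] + 1
            elif j == 0:
                acc[i, j] = acc[i - 1, j] + c
                plen[i, j] = plen[i - 1, j] + 1
            else:
                diag = acc[i - 1, j - 1]
                up = acc[i - 1, j]
                left = acc[i, j - 1]
                if diag <= up and diag <= left:
                    acc[i, j] = diag + c
                    plen[i, j] = plen[i - 1, j - 1] + 1
                elif up <= left:
                    acc[i, j] = up + c
                    plen[i, j] = plen[i - 1, j] + 1
                else:
                    acc[i, j] = left + c
                    plen[i, j] = plen[i, j - 1] + 1
    return acc[n - 1, m - 1] / plen[n - 1, m - 1]


def ddtw_distance(a, b, resample_len: int = DEFAULT_RESAMPLE_LEN) -> float:
    """Derivative Dynamic Time Warping distance between two pitch sequences.

    Both sequences are linearly resampled to ``resample_len`` points, local
    derivatives are estimated (Keogh-Pazzani), and DTW with squared
    derivative differences as local cost is run over the full alignment; the
    accumulated cost is normalized by the optimal path length.  Symmetric,
    zero for identical sequences, and invariant to constant pitch offsets.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("sequences must have at least 3 samples")
    if resample_len < 3:
        raise ValueError("resample_len must be >= 3")
    da = derivative_estimate(_resample(a, resample_len))
    db = derivative_estimate(_resample(b, resample_len))
    return float(_dtw_normalized(da, db))


def pairwise_ddtw(sequences: Sequence[np.ndarray],
                  resample_len: int = DEFAULT_RESAMPLE_LEN,
                  smooth_window: int | None = None) -> np.ndarray:
    """Square matrix of pairwise DDTW distances, optionally pre-smoothing
    each sequence with a centred moving average."""
    prepped = []
    for s in sequences:
        s = np.asarray(s, dtype=float)
        if smooth_window and smooth_window > 1:
            s = moving_average(s, smooth_window)
        prepped.append(derivative_estimate(_resample(s, resample_len)))
    n = len(prepped)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(_dtw_normalized(prepped[i], prepped[j]))
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass
class BlockLabeling:
    """Assignment of every segment of a set to a building-block type."""

    segment_keys: list[tuple[str, int]]  # (whistle_id, segment_index)
    labels: list[int]
    n_blocks: int
    block_frequencies: dict[int, int]

    def __post_init__(self) -> None:
        if len(self.segment_keys) != len(self.labels):
            raise ValueError("one label per segment required")
        if sum(self.block_frequencies.values()) != len(self.labels):
            raise ValueError("frequencies must sum to the number of segments")

    def sequences(self) -> list[list[int]]:
        """Per-whistle ordered block-label sequences (whistle order as given)."""
        seqs: dict[str, list[int]] = {}
        order: list[str] = []
        for (wid, _), lab in zip(self.segment_keys, self.labels):
            if wid not in seqs:
                seqs[wid] = []
                order.append(wid)
            seqs[wid].append(lab)
        return [seqs[w] for w in order]


def _canonical_labels(raw: np.ndarray) -> list[int]:
    """Relabel cluster ids by order of first occurrence (deterministic)."""
    mapping: dict[int, int] = {}
    out = []
    for r in raw:
        if r not in mapping:
            mapping[r] = len(mapping)
        out.append(mapping[r])
    return out


def cluster_building_blocks(segments: Sequence[Segment],
                            threshold: float = DEFAULT_BLOCK_THRESHOLD,
                            resample_len: int = DEFAULT_RESAMPLE_LEN,
                            smooth_window: int | None = DEFAULT_DDTW_SMOOTH,
                            ) -> BlockLabeling:
    """Group a set's segments into building blocks.

    Average-linkage agglomerative clustering on the pairwise DDTW matrix;
    merging continues while the smallest inter-cluster distance is strictly
    below ``threshold``.  A threshold of 0 therefore leaves every segment
    its own block, even exact duplicates.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("need at least 1 segment")
    keys = [(s.whistle_id, s.index) for s in segments]
    n = len(segments)
    if n == 1:
        return BlockLabeling(segment_keys=keys, labels=[0], n_blocks=1,
                             block_frequencies={0: 1})
    dist = pairwise_ddtw([s.pitch_values for s in segments],
                         resample_len=resample_len,
                         smooth_window=smooth_window)
    Z = linkage(squareform(dist, checks=False), method="average")
    heights = Z[:, 2]
    below = heights[heights < threshold]
    if below.size == 0:
        labels = list(range(n))
    else:
        raw = fcluster(Z, t=float(below.max()), criterion="distance")
        labels = _canonical_labels(raw)
    freqs = dict(sorted(Counter(labels).items()))
    return BlockLabeling(segment_keys=keys, labels=labels,
                         n_blocks=len(freqs), block_frequencies=freqs)


def shannon_entropy(labeling, base: float = 2.0) -> float:
    """Entropy H = -sum p_i log p_i of building-block relative frequencies.

    Accepts a :class:`BlockLabeling` or an iterable of counts.  Zero for a
    single block, ``log(k)`` for k equiprobable blocks (log base 2 by
    default, so the unit is bits).
    """
    if isinstance(labeling, BlockLabeling):
        counts = np.asarray(list(labeling.block_frequencies.values()), dtype=float)
    else:
        counts = np.asarray(list(labeling), dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("need at least one occupied block")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chunk_strength(sequences: Sequence[Sequence[int]],
                   pooled: bool = True) -> float:
    """Associative chunk strength of a whistle set.

    Every bigram and trigram token inside each whistle's block sequence
    (tokens never cross whistle boundaries) is collected, type frequencies
    are counted across the whole set, and the mean over all tokens of their
    type's frequency is returned.  ``pooled=False`` instead averages the
    bigram-token mean and trigram-token mean separately and then averages
    the two.  Returns NaN when no whistle has at least 2 blocks.
    """
    bigrams: list[tuple] = []
    trigrams: list[tuple] = []
    for seq in sequences:
        seq = tuple(seq)
        bigrams.extend(seq[i:i + 2] for i in range(len(seq) - 1))
        trigrams.extend(seq[i:i + 3] for i in range(len(seq) - 2))
    tokens = bigrams + trigrams
    if not tokens:
        return float("nan")
    counts = Counter(tokens)

    def mean_token_freq(toks: list[tuple]) -> float:
        return float(np.mean([counts[t] for t in toks]))

    if pooled:
        return mean_token_freq(tokens)
    parts = [mean_token_freq(t) for t in (bigrams, trigrams) if t]
    return float(np.mean(parts))


@dataclass
class MotifResult:
    entropy: float
    chunk_strength: float
    n_blocks: int


def motif_measures(segments: Sequence[Segment],
                   threshold: float = DEFAULT_BLOCK_THRESHOLD,
                   resample_len: int = DEFAULT_RESAMPLE_LEN,
                   smooth_window: int | None = DEFAULT_DDTW_SMOOTH,
                   entropy_base: float = 2.0) -> tuple[MotifResult, BlockLabeling]:
    """Cluster a set's segments and compute both motif measures."""
    labeling = cluster_building_blocks(segments, threshold=threshold,
                                       resample_len=resample_len,
                                       smooth_window=smooth_window)
    return MotifResult(entropy=shannon_entropy(labeling, base=entropy_base),
                       chunk_strength=chunk_strength(labeling.sequences()),
                       n_blocks=labeling.n_blocks), labeling
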