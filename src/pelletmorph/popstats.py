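"""Population statistics for pellet diameter distributions.

A pellet population is summarised by the median area-equivalent diameter
(robust against extreme values) and the interquartile range as the
intra-flask heterogeneity measure. Flask-to-flask variation is quantified
by a distribution-free overlap coefficient (OVL) of number-density (q0)
histograms over a fixed grid of 80 diameter classes (0–4000 µm, 50 µm
bins):

    OVL(A, B) = Σ_i min(f_A(d_i), f_B(d_i)),   i = 1..80

where f_A, f_B are the bin densities normalised to the total pellet count.
OVL ranges from 0 (disjoint) to 1 (the smaller set lies entirely within
the larger). Populations with fewer than 30 analysed pellets are treated
as poorly grown: they are flagged as excluded and any OVL pair involving
them is set to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: fixed q0 grid: 0–4000 µm in 50 µm bins = 80 diameter classes
BIN_EDGES = np.arange(0.0, 4000.0 + 50.0, 50.0)
N_CLASSES = len(BIN_EDGES) - 1

#: populations below this count are excluded from population statistics
MIN_PELLETS = 30


@dataclass
class Q0Distribution:
    """Number-density histogram over the fixed 80-class diameter grid."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("density length must match bin count")


@dataclass
class PopulationSummary:
    median_ed: float
    iqr: float
    n: int
    excluded: bool
    modality_flag: str  # "unimodal", "multimodal" or "undefined"


@dataclass
class ReplicateOVL:
    pairwise: np.ndarray
    mean_ovl: float


def q0_histogram(diameters) -> Q0Distribution:
    """Counts per half-open diameter class [edge, edge+50), normalised.

    Diameters at or above 4000 µm cannot be binned on the fixed grid and
    are rejected with a logged count (they cannot arise downstream of the
    3000 µm post-filter, but manual records might exceed it).
    """
    d = np.asarray(diameters, dtype=float)
    over = int(np.sum(d >= BIN_EDGES[-1]))
    if over:
        logger.warning("rejecting %d diameters >= %g µm from the q0 grid",
                       over, BIN_EDGES[-1])
    d = d[(d >= 0) & (d < BIN_EDGES[-1])]
    counts, _ = np.histogram(d, bins=BIN_EDGES)
    n_total = int(counts.sum())
    density = counts / n_total if n_total > 0 else counts.astype(float)
    return Q0Distribution(bin_edges=BIN_EDGES.copy(), density=density, n_total=n_total)


def detect_modality(
    q0: Q0Distribution, window: int = 3, prominence_fraction: float = 0.10
) -> str:
    """Unimodal/multimodal call from smoothed peak counting.

    The density is smoothed with a centred moving average (``window`` bins)
    and local maxima with prominence above ``prominence_fraction`` of the
    smoothed maximum are counted; two or more peaks flag a multimodal
    population. This operationalises a visual judgement and is reported as
    a flag, never silently enforced.
    """
    if q0.n_total < MIN_PELLETS:
        return "undefined"
    kernel = np.ones(window) / window
    smooth = np.convolve(q0.density, kernel, mode="same")
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_fraction * padded.max())
    return "multimodal" if len(peaks) >= 2 else "unimodal"


def summarize(diameters) -> PopulationSummary:
    """Median/IQR summary with the <30-pellet exclusion rule.

    Percentiles use linear interpolation between order statistics. An
    empty population yields NaN statistics and an excluded flag.
    """
    d = np.asarray(diameters, dtype=float)
    n = int(d.size)
    if n == 0:
        return PopulationSummary(float("nan"), float("nan"), 0, True, "undefined")
    median = float(np.median(d))
    q25, q75 = np.percentile(d, [25.0, 75.0])
    excluded = n < MIN_PELLETS
    modality = detect_modality(q0_histogram(d)) if not excluded else "undefined"
    return PopulationSummary(median, float(q75 - q25), n, excluded, modality)


def ovl_pair(a: Q0Distribution, b: Q0Distribution) -> float:
    """Overlap coefficient of two q0 distributions on the same grid.

    Zero rule: any pair involving a population with fewer than 30 pellets
    is scored 0, matching the population validity threshold.
    """
    if not np.array_equal(a.bin_edges, b.bin_edges):
        raise ValueError("q0 distributions are on different bin grids")
    if a.n_total < MIN_PELLETS or b.n_total < MIN_PELLETS:
        return 0.0
    return float(np.minimum(a.density, b.density).sum())


def ovl_replicates(populations) -> ReplicateOVL:
    """Pairwise OVL matrix over replicate populations and its mean.

    ``populations`` is a sequence of diameter lists (one per replicate
    flask). The mean is taken over the off-diagonal unordered pairs.
    """
    if len(populations) < 2:
        raise ValueError("at least two replicate populations are required")
    q0s = [q0_histogram(p) for p in populations]
    k = len(q0s)
    mat = np.ones((k, k))
    off = []
    for i in range(k):
        mat[i, i] = ovl_pair(q0s[i], q0s[i])
        for j in range(i + 1, k):
            v = ovl_pair(q0s[i], q0s[j])
            mat[i, j] = mat[j, i] = v
            off.append(v)
    return ReplicateOVL(pairwise=mat, mean_ovl=float(np.mean(off)))
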