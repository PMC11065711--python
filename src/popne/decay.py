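"""LD decay with distance: distance-binned r-squared summaries, the
useful-LD crossing distance, and equidistant SNP-panel sizing.

Bins are half-open intervals (lo, hi] over pair distance.  The default
edges 0/10/25/50/100/200/500 kb are the bins conventional in livestock LD
surveys.  The crossing distance where mean r2 first falls below a threshold
(0.2 by default, the level associated with ~0.85 genomic-selection accuracy)
is located by linear interpolation between bin summary points, with a
companion value snapped to 10 kb granularity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ld import LDPair

logger = logging.getLogger(__name__)

DEFAULT_EDGES_BP = (0, 10_000, 25_000, 50_000, 100_000, 200_000, 500_000)
DEFAULT_R2_THRESHOLD = 0.2


@dataclass(frozen=True)
class DistanceBin:
    """Summary of pairwise r2 within one (lo_bp, hi_bp] distance interval."""

    lo_bp: int
    hi_bp: int
    n_pairs: int
    mean_r2: float
    sd_r2: float
    mean_dist_bp: float
    label: str = ""

    def __post_init__(self):
        if self.lo_bp >= self.hi_bp:
            raise ValueError(f"bin bounds ({self.lo_bp}, {self.hi_bp}] are empty")


@dataclass(frozen=True)
class PanelDesign:
    genome_len_kb: float
    spacing_kb: float
    n_markers: int
    r2_threshold: float


@dataclass(frozen=True)
class DecayCrossing:
    """Where mean r2 first drops below the threshold.

    ``status`` is "ok", "not_reached_below_min" (even the shortest-distance
    bin is below threshold) or "not_reached_within_window" (no bin falls
    below it).  ``crossing_bp`` interpolates between bin (mean_dist, mean_r2)
    points; ``crossing_coarse_bp`` is the largest 10 kb multiple still at or
    above threshold.
    """

    status: str
    threshold: float
    crossing_bp: Optional[float] = None
    crossing_coarse_bp: Optional[int] = None


def _summarize(dist: np.ndarray, r2: np.ndarray, lo: int, hi: int, label: str) -> DistanceBin:
    n = dist.size
    return DistanceBin(
        lo_bp=int(lo), hi_bp=int(hi), n_pairs=int(n),
        mean_r2=float(r2.mean()) if n else float("nan"),
        sd_r2=float(r2.std(ddof=1)) if n > 1 else (0.0 if n == 1 else float("nan")),
        mean_dist_bp=float(dist.mean()) if n else float("nan"),
        label=label,
    )


def bin_ld(pairs: Iterable[LDPair],
           edges_bp: Sequence[int] = DEFAULT_EDGES_BP) -> list[DistanceBin]:
    """Aggregate a pair stream into distance bins plus a final "overall" row.

    Every pair with distance in (edges[0], edges[-1]] lands in exactly one
    half-open bin; pairs outside the window are ignored.
    """
    edges = np.asarray(edges_bp, dtype=np.int64)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 values")
    dist = []
    r2 = []
    for p in pairs:
        dist.append(p.dist_bp)
        r2.append(p.r2)
    dist = np.asarray(dist, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.float64)
    inside = (dist > edges[0]) & (dist <= edges[-1])
    dist, r2 = dist[inside], r2[inside]
    # (lo, hi]: right-closed bins
    which = np.searchsorted(edges, dist, side="left") - 1
    bins = []
    for b in range(edges.size - 1):
        sel = which == b
        label = f"{edges[b] // 1000}-{edges[b + 1] // 1000} kb"
        bins.append(_summarize(dist[sel], r2[sel], edges[b], edges[b + 1], label))
    bins.append(_summarize(dist, r2, edges[0], edges[-1], "overall"))
    return bins


def bins_frame(bins: list[DistanceBin]) -> pd.DataFrame:
    return pd.DataFrame({
        "BIN": [b.label for b in bins],
        "LO_BP": [b.lo_bp for b in bins],
        "HI_BP": [b.hi_bp for b in bins],
        "N_PAIRS": [b.n_pairs for b in bins],
        "MEAN_R2": [b.mean_r2 for b in bins],
        "SD_R2": [b.sd_r2 for b in bins],
        "MEAN_DIST_BP": [b.mean_dist_bp for b in bins],
    })


def decay_crossing(bins: list[DistanceBin],
                   r2_threshold: float = DEFAULT_R2_THRESHOLD) -> DecayCrossing:
    """Interpolated distance where bin-mean r2 first falls below threshold."""
    pts = [(b.mean_dist_bp, b.mean_r2) for b in bins
           if b.label != "overall" and b.n_pairs > 0]
    pts.sort()
    if not pts:
        return DecayCrossing(status="not_reached_within_window", threshold=r2_threshold)
    means = [m for _, m in pts]
    if any(means[i] < means[i + 1] for i in range(len(means) - 1)):
        logger.warning("bin-mean r2 is not monotonically decreasing with distance")
    if means[0] < r2_threshold:
        return DecayCrossing(status="not_reached_below_min", threshold=r2_threshold)
    for (d0, m0), (d1, m1) in zip(pts, pts[1:]):
        if m0 >= r2_threshold > m1:
            frac = (m0 - r2_threshold) / (m0 - m1)
            x = d0 + frac * (d1 - d0)
            return DecayCrossing(status="ok", threshold=r2_threshold,
                                 crossing_bp=float(x),
                                 crossing_coarse_bp=int(math.floor(x / 10_000) * 10_000))
    return DecayCrossing(status="not_reached_within_window", threshold=r2_threshold)


def panel_size(genome_len_kb: float, spacing_kb: float) -> int:
    """Markers needed to cover ``genome_len_kb`` at equidistant spacing:
    floor(genome length / spacing).  A fractional marker is meaningless."""
    if genome_len_kb <= 0 or spacing_kb <= 0:
        raise ValueError("genome length and spacing must be positive")
    return int(math.floor(genome_len_kb / spacing_kb))
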