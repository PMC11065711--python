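"""Historical effective population size from distance-binned LD.

The estimator inverts the drift-recombination expectation of r2 (Sved 1971;
Corbin et al. 2012): pairs are binned by physical distance; each bin's mean
distance maps to genetic distance d = k * delta (k Morgans per bp, default
1e-8) and to a recombination fraction via the Sved-Feldman modifier
c = d (1 - d/2); the bin mean r2, corrected for finite sample size
(r2_adj = r2 - 1/(beta * n), beta = 1 unphased / 2 phased), then yields

    Ne(t) = (1 / (4 f(c))) * (1 / r2_adj - alpha),   t = 1 / (2 c)

with f the identity unless configured and alpha a mutation correction
(default 1).  Short-distance pairs inform ancient sizes, long-distance pairs
recent ones.  Bins whose corrected r2 leaves (0, 1/alpha) are dropped with a
reason, never clamped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedResult
from .ld import LDPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeLdConfig:
    """Tuning for the LD-based Ne trajectory.

    ``n_bins`` equal-width distance bins between ``min_dist_bp`` and
    ``max_dist_bp``; a wide window pushed to several Mb reaches the most
    recent generations, short distances the ancient ones.
    """

    k_morgan_per_bp: float = 1e-8
    alpha: float = 1.0
    beta: int = 1
    n_bins: int = 30
    min_dist_bp: int = 10_000
    max_dist_bp: int = 4_000_000
    mapping_f: Optional[Callable[[float], float]] = None  # identity if None

    def __post_init__(self):
        if self.k_morgan_per_bp <= 0:
            raise ConfigError("k must be positive")
        if self.alpha < 1:
            raise ConfigError("alpha must be >= 1")
        if self.beta not in (1, 2):
            raise ConfigError("beta must be 1 (unphased) or 2 (phased)")
        if self.min_dist_bp >= self.max_dist_bp:
            raise ConfigError("min_dist_bp must be < max_dist_bp")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")

    def f(self, c: float) -> float:
        return c if self.mapping_f is None else self.mapping_f(c)


@dataclass(frozen=True)
class NeEstimate:
    """One (t generations ago, Ne) point on the demographic trajectory."""

    t_generations: float
    ne: float
    c: float
    r2_adj: float
    n_pairs: int


def physical_to_genetic(delta_bp: float, k: float = 1e-8) -> float:
    """Map physical distance (bp) to genetic distance d = k * delta (Morgans)."""
    if delta_bp < 0:
        raise ValueError("distance must be non-negative")
    return k * delta_bp


def sved_feldman_c(d: float) -> float:
    """Recombination fraction from map distance: c = d (1 - d/2).

    Monotone on [0, 1] with c(1) = 0.5, the free-recombination ceiling.
    """
    if d < 0:
        raise ValueError("map distance must be non-negative")
    if d > 1:
        warnings.warn(f"Sved-Feldman modifier applied beyond its intended range (d={d})")
    return d * (1.0 - d / 2.0)


def adjust_r2(mean_r2: float, n: int, beta: int = 1) -> float:
    """Finite-sample correction r2_adj = r2 - 1/(beta*n); may go <= 0."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    return mean_r2 - 1.0 / (beta * n)


def ne_at_bin(r2_adj: float, c: float, alpha: float = 1.0,
              mapping_f: Optional[Callable[[float], float]] = None
              ) -> tuple[float, float]:
    """(t, Ne) for one bin: Ne = (1/(4 f(c))) (1/r2_adj - alpha), t = 1/(2c)."""
    if c <= 0:
        raise ValueError("recombination rate must be positive")
    if r2_adj <= 0:
        raise UndefinedResult("over-corrected: adjusted r2 <= 0")
    if r2_adj >= 1.0 / alpha:
        raise UndefinedResult("saturated: adjusted r2 >= 1/alpha gives Ne <= 0")
    fc = c if mapping_f is None else mapping_f(c)
    ne = (1.0 / (4.0 * fc)) * (1.0 / r2_adj - alpha)
    return 1.0 / (2.0 * c), ne


@dataclass
class NeTrajectory:
    estimates: list[NeEstimate]
    dropped: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T_GEN": [e.t_generations for e in self.estimates],
            "NE": [e.ne for e in self.estimates],
            "C": [e.c for e in self.estimates],
            "R2_ADJ": [e.r2_adj for e in self.estimates],
            "N_PAIRS": [e.n_pairs for e in self.estimates],
        })


def ne_trajectory(pairs: Iterable[LDPair], n: int,
                  config: NeLdConfig = NeLdConfig()) -> NeTrajectory:
    """Ne(t) trajectory from a pair stream, sorted by t ascending.

    Pairs are partitioned into ``config.n_bins`` equal-width distance bins on
    [min_dist_bp, max_dist_bp]; per bin the arithmetic mean pair distance
    drives d -> c -> t and the mean r2 drives r2_adj -> Ne.  ``n`` is the
    number of genotyped individuals (a single panel-wide value).
    """
    if n < 2:
        raise ConfigError("sample size must be >= 2")
    dist = []
    r2 = []
    for p in pairs:
        if config.min_dist_bp <= p.dist_bp <= config.max_dist_bp:
            dist.append(p.dist_bp)
            r2.append(p.r2)
    dist = np.asarray(dist, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    edges = np.linspace(config.min_dist_bp, config.max_dist_bp, config.n_bins + 1)
    which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, config.n_bins - 1)
    estimates = []
    dropped = []
    for b in range(config.n_bins):
        sel = which == b
        npairs = int(sel.sum())
        if npairs == 0:
            dropped.append({"bin": b, "reason": "empty", "n_pairs": 0})
            continue
        mean_d = float(dist[sel].mean())
        mean_r2 = float(r2[sel].mean())
        c = sved_feldman_c(physical_to_genetic(mean_d, config.k_morgan_per_bp))
        r2a = adjust_r2(mean_r2, n, config.beta)
        try:
            t, ne = ne_at_bin(r2a, c, config.alpha, config.mapping_f)
        except UndefinedResult as exc:
            dropped.append({"bin": b, "reason": str(exc), "n_pairs": npairs})
            continue
        estimates.append(NeEstimate(t, ne, c, r2a, npairs))
    estimates.sort(key=lambda e: e.t_generations)
    if not estimates:
        logger.warning("all %d distance bins dropped; empty Ne trajectory", config.n_bins)
    return NeTrajectory(estimates=estimates, dropped=dropped)
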