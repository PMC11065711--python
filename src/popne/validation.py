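"""Parameter-recovery experiments: run the full pipeline on simulated data of
known truth and summarize how well each estimator recovers it.

These are the package's own end-to-end checks (used by the test suite and
the reproduction script), kept in the library so their study conditions are
versioned alongside the estimators they validate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ne_ld import NeLdConfig, ne_trajectory
from .ld import pairwise_ld_scan
from .pedigree import coancestry_analysis
from .qc import QCThresholds, apply_qc
from .simulate import (PedigreeTruth, SimulationTruth, simulate_pedigree,
                       simulate_wright_fisher)


@dataclass
class LdNeRecovery:
    true_ne: int
    median_ne: float
    estimates: list[float]
    n_pairs_total: int
    n_replicates: int


def ld_ne_recovery(seed: int, true_ne: int = 50, n_replicates: int = 20,
                   n_sampled: int = 50, n_loci: int = 1200,
                   chrom_length_bp: int = 10_000_000, n_chromosomes: int = 3,
                   n_generations: int = 200,
                   t_window: tuple[float, float] = (10.0, 100.0)) -> LdNeRecovery:
    """Recover a constant Ne from LD in replicated Wright-Fisher panels.

    Each replicate simulates a constant-size population long enough for LD at
    the probed recombination fractions to equilibrate (3 independent 10 Mb
    chromosomes, so bin means average over several genealogies), applies
    marker QC, scans pairwise r2 over 0.4-5.5 Mb (t roughly 9-120 generations
    at 1e-8 Morgans/bp) and inverts the drift-recombination expectation per
    distance bin.  Returns the pooled bin estimates restricted to
    ``t_window`` and their median.
    """
    rng = np.random.default_rng(seed)
    cfg = NeLdConfig(n_bins=20, min_dist_bp=400_000, max_dist_bp=5_500_000)
    estimates: list[float] = []
    n_pairs_total = 0
    for _ in range(n_replicates):
        truth = SimulationTruth(ne_schedule=[(n_generations, true_ne)],
                                n_sampled=n_sampled, n_loci=n_loci,
                                chrom_length_bp=chrom_length_bp,
                                n_chromosomes=n_chromosomes,
                                seed=int(rng.integers(2**31 - 1)))
        panel = simulate_wright_fisher(truth)
        filtered, _ = apply_qc(panel, QCThresholds())
        pairs = list(pairwise_ld_scan(filtered, max_dist_bp=cfg.max_dist_bp))
        n_pairs_total += len(pairs)
        traj = ne_trajectory(pairs, filtered.n_samples, cfg)
        estimates.extend(e.ne for e in traj.estimates
                         if t_window[0] <= e.t_generations <= t_window[1])
    return LdNeRecovery(true_ne=true_ne,
                        median_ne=float(np.median(estimates)) if estimates else float("nan"),
                        estimates=estimates, n_pairs_total=n_pairs_total,
                        n_replicates=n_replicates)


@dataclass
class PedigreeNeRecovery:
    theoretical_ne: float
    ne_fi_median: float
    ne_ci_median: float
    ne_fi: list[float]
    ne_ci: list[float]
    n_replicates: int


def pedigree_ne_recovery(seed: int, n_sires: int = 25, n_dams: int = 25,
                         offspring_per_generation: int = 100,
                         n_generations: int = 10,
                         n_replicates: int = 10) -> PedigreeNeRecovery:
    """Recover 4 Nm Nf / (Nm + Nf) from simulated hierarchical pedigrees.

    Per replicate: grow the pedigree and run the coancestry analysis with the
    last-born generation as the reference cohort (pairwise coancestry between
    contemporaries is what the per-generation drift increment describes;
    mixing cohorts of different depths inflates NeC).
    """
    rng = np.random.default_rng(seed)
    fi: list[float] = []
    ci: list[float] = []
    theo = PedigreeTruth(n_sires, n_dams, offspring_per_generation,
                         n_generations, 0).theoretical_ne
    for _ in range(n_replicates):
        ped, _truth = simulate_pedigree(n_sires, n_dams, offspring_per_generation,
                                        n_generations, int(rng.integers(2**31 - 1)))
        cohort = [i for i, y in zip(ped.ids, ped.birth_years)
                  if y == n_generations]
        res = coancestry_analysis(ped, cohort)
        if res.ne_fi.defined:
            fi.append(res.ne_fi.value)
        if res.ne_ci.defined:
            ci.append(res.ne_ci.value)
    return PedigreeNeRecovery(theoretical_ne=theo,
                              ne_fi_median=float(np.median(fi)) if fi else float("nan"),
                              ne_ci_median=float(np.median(ci)) if ci else float("nan"),
                              ne_fi=fi, ne_ci=ci, n_replicates=n_replicates)
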