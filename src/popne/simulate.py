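"""Forward simulators with recorded ground truth, for parameter-recovery
validation of every estimator in the pipeline.

``simulate_wright_fisher`` runs a discrete-generation diploid Wright-Fisher
population (random parents with selfing, Poisson crossovers at a per-bp
rate, no mutation after initialization) and samples unphased genotypes, so
LD at a recombination fraction c reaches the drift-recombination balance the
LD-based Ne estimator inverts.  ``simulate_pedigree`` grows a two-sex
hierarchical-mating pedigree with known sire/dam counts, whose theoretical
effective size 4 Nm Nf / (Nm + Nf) is the recovery target for the
pedigree-based estimators.  Both are fully reproducible from their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .errors import ConfigError
from .io import GenotypeDataset, PedigreeTable, VariantRecord, normalize_coding


@dataclass
class SimulationTruth:
    """Everything needed to regenerate a simulated panel and to score
    estimates against it.

    ``ne_schedule`` is a list of (n_generations, N diploids) segments applied
    oldest first; a single segment gives a constant-size population.
    """

    ne_schedule: list[tuple[int, int]]
    n_sampled: int
    n_loci: int
    chrom_length_bp: int
    seed: int
    recomb_rate_per_bp: float = 1e-8
    init_maf_law: tuple = ("uniform", 0.05, 0.5)
    mating: Optional[tuple[int, int]] = None
    n_chromosomes: int = 1  # extra chromosomes = independent replicates

    def __post_init__(self):
        if self.n_sampled <= 0 or self.n_loci <= 0 or self.chrom_length_bp <= 0 \
                or self.n_chromosomes <= 0:
            raise ConfigError("all counts must be positive")
        if not self.ne_schedule or any(g <= 0 or n <= 0 for g, n in self.ne_schedule):
            raise ConfigError("ne_schedule segments must have positive spans and sizes")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _gamete(rng: np.random.Generator, h0: np.ndarray, h1: np.ndarray,
            pos: np.ndarray, rate: float, length: int) -> np.ndarray:
    """One recombinant gamete: crossovers as a Poisson process along the
    chromosome, alternating between the two parental haplotypes."""
    n_x = rng.poisson(rate * length)
    start = rng.integers(2)
    if n_x == 0:
        return (h0 if start == 0 else h1).copy()
    breaks = np.sort(rng.uniform(0, length, size=n_x))
    seg = np.searchsorted(breaks, pos)
    use = (seg + start) % 2
    return np.where(use == 0, h0, h1)


def simulate_wright_fisher(truth: SimulationTruth) -> GenotypeDataset:
    """Forward-in-time diploid Wright-Fisher genotype panel.

    Loci start in linkage equilibrium at frequencies drawn from
    ``init_maf_law``; each offspring draws two parents uniformly with
    replacement (selfing allowed); the final ``n_sampled`` individuals are
    drawn without replacement.  Monomorphic loci are retained (QC removes
    them downstream).  With ``n_chromosomes > 1`` each chromosome is an
    independent replicate population (same truth, distinct drift history)
    carrying ``n_loci`` markers, concatenated under labels "1", "2", ...
    """
    if truth.n_chromosomes > 1:
        chroms = []
        child = np.random.default_rng(truth.seed).integers(2**31 - 1,
                                                           size=truth.n_chromosomes)
        for k in range(truth.n_chromosomes):
            sub = SimulationTruth(
                ne_schedule=list(truth.ne_schedule), n_sampled=truth.n_sampled,
                n_loci=truth.n_loci, chrom_length_bp=truth.chrom_length_bp,
                seed=int(child[k]), recomb_rate_per_bp=truth.recomb_rate_per_bp,
                init_maf_law=truth.init_maf_law)
            ds = simulate_wright_fisher(sub)
            chroms.append(ds)
        variants = []
        calls = np.concatenate([d.calls for d in chroms], axis=1)
        for k, d in enumerate(chroms, 1):
            variants.extend(VariantRecord(str(k), f"chr{k}_{v.id}", v.pos_bp,
                                          v.alleles) for v in d.variants)
        return GenotypeDataset(variants=variants, samples=chroms[0].samples,
                               calls=calls)
    rng = np.random.default_rng(truth.seed)
    L = truth.n_loci
    length = truth.chrom_length_bp
    if L > length:
        raise ConfigError("more loci than base pairs on the chromosome")
    cand = np.unique(rng.integers(1, length + 1, size=4 * L + 16))
    while cand.size < L:  # vanishingly rare unless L ~ length
        cand = np.unique(np.concatenate([cand, rng.integers(1, length + 1, size=4 * L)]))
    pos = np.sort(rng.permutation(cand)[:L])
    law, lo, hi = truth.init_maf_law
    if law != "uniform":
        raise ConfigError(f"unknown initial-frequency law {law!r}")
    p0 = rng.uniform(lo, hi, size=L)
    n0 = truth.ne_schedule[0][1]
    haps = (rng.random((2 * n0, L)) < p0).astype(np.int8)
    n_prev = n0
    for gens, n_cur in truth.ne_schedule:
        for _ in range(gens):
            new = np.empty((2 * n_cur, L), dtype=np.int8)
            parents = rng.integers(n_prev, size=2 * n_cur)
            for k, par in enumerate(parents):
                new[k] = _gamete(rng, haps[2 * par], haps[2 * par + 1],
                                 pos, truth.recomb_rate_per_bp, length)
            haps = new
            n_prev = n_cur
    if truth.n_sampled > n_prev:
        raise ConfigError(
            f"cannot sample {truth.n_sampled} individuals from a final "
            f"population of {n_prev}")
    picked = rng.choice(n_prev, size=truth.n_sampled, replace=False)
    calls = (haps[2 * picked] + haps[2 * picked + 1]).astype(np.int8)
    variants = [VariantRecord("1", f"snp{j + 1}", int(pos[j]), ("A", "G"))
                for j in range(L)]
    samples = [f"ind{i + 1}" for i in range(truth.n_sampled)]
    ds = GenotypeDataset(variants=variants, samples=samples, calls=calls)
    return normalize_coding(ds)


@dataclass
class PedigreeTruth:
    n_sires: int
    n_dams: int
    offspring_per_generation: int
    n_generations: int
    seed: int

    @property
    def theoretical_ne(self) -> float:
        """Unequal-sex-ratio effective size 4 Nm Nf / (Nm + Nf)."""
        return 4.0 * self.n_sires * self.n_dams / (self.n_sires + self.n_dams)

    def to_json(self) -> str:
        d = asdict(self)
        d["theoretical_ne"] = self.theoretical_ne
        return json.dumps(d, indent=2, sort_keys=True)


def simulate_pedigree(n_sires: int, n_dams: int, offspring_per_generation: int,
                      n_generations: int, seed: int
                      ) -> tuple[PedigreeTable, PedigreeTruth]:
    """Multi-generation hierarchical random-mating pedigree.

    Generation 0 holds ``n_sires`` unknown-parent males and ``n_dams``
    unknown-parent females.  Each later generation has
    ``offspring_per_generation`` individuals with alternating sexes; every
    offspring's sire is drawn uniformly from ``n_sires`` breeding males and
    its dam from ``n_dams`` breeding females of the previous generation.
    Birth year is the generation index.
    """
    if min(n_sires, n_dams, offspring_per_generation, n_generations) <= 0:
        raise ConfigError("all pedigree simulation counts must be positive")
    half = offspring_per_generation // 2
    if half < n_sires or offspring_per_generation - half < n_dams:
        raise ConfigError(
            "offspring_per_generation too small to supply "
            f"{n_sires} sires and {n_dams} dams per generation")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    sires: list[Optional[str]] = []
    dams: list[Optional[str]] = []
    years: list[Optional[int]] = []
    males = [f"G0_M{i + 1}" for i in range(n_sires)]
    females = [f"G0_F{i + 1}" for i in range(n_dams)]
    for x in males + females:
        ids.append(x)
        sires.append(None)
        dams.append(None)
        years.append(0)
    for g in range(1, n_generations + 1):
        breed_s = rng.choice(males, size=n_sires, replace=False)
        breed_d = rng.choice(females, size=n_dams, replace=False)
        new_m, new_f = [], []
        for k in range(offspring_per_generation):
            sex = "M" if k < half else "F"
            name = f"G{g}_{sex}{k + 1 if sex == 'M' else k - half + 1}"
            ids.append(name)
            sires.append(str(rng.choice(breed_s)))
            dams.append(str(rng.choice(breed_d)))
            years.append(g)
            (new_m if sex == "M" else new_f).append(name)
        males, females = new_m, new_f
    ped = PedigreeTable(ids, sires, dams, years)
    return ped, PedigreeTruth(n_sires, n_dams, offspring_per_generation,
                              n_generations, seed)


def expected_r2_sved(N: float, c: float, n: float = math.inf,
                     beta: int = 1, alpha: float = 1.0) -> float:
    """Drift-recombination equilibrium expectation of r2 (Sved 1971) plus the
    finite-sample term: 1/(alpha + 4 N c) + 1/(beta n)."""
    if N < 1 or not 0 < c <= 0.5:
        raise ValueError("need N >= 1 and 0 < c <= 0.5")
    sampling = 0.0 if math.isinf(n) else 1.0 / (beta * n)
    return 1.0 / (alpha + 4.0 * N * c) + sampling
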