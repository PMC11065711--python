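"""Pairwise linkage disequilibrium within a physical-distance window.

The primary r-squared is the squared Pearson correlation of genotype dosages
over pairwise-complete samples (PLINK's default for unphased data).  Gamete
frequencies for D and D-prime come from an EM fit that resolves the
double-heterozygote phase ambiguity.  Pairs where either locus is
monomorphic after pairwise deletion are skipped, not zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .errors import DataError, UndefinedResult
from .io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST_BP = 500_000


@dataclass(frozen=True)
class LDPair:
    """LD record for one same-chromosome SNP pair (``idx_a < idx_b``)."""

    chrom: str
    idx_a: int
    idx_b: int
    dist_bp: int
    r2: float
    n_obs: int
    d_raw: Optional[float] = None
    d_prime: Optional[float] = None


def haplotype_ld(pAB: float, pA: float, pB: float) -> tuple[float, float, float]:
    """D, |D'| and r-squared from gamete and allele frequencies.

    D = pAB - pA*pB; D' scales |D| by its maximum attainable value given the
    allele frequencies; r2 = D^2 / (pA(1-pA) pB(1-pB)).
    """
    if not (0.0 < pA < 1.0 and 0.0 < pB < 1.0):
        raise UndefinedResult("LD undefined at a monomorphic locus")
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    if not (lo - 1e-12 <= pAB <= hi + 1e-12):
        raise ValueError(f"pAB={pAB} incompatible with pA={pA}, pB={pB}")
    d = pAB - pA * pB
    if d > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    return d, min(d_prime, 1.0), min(r2, 1.0)


def dosage_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Invariant to which allele is counted at either locus.  Raises
    :class:`UndefinedResult` if fewer than 2 complete pairs remain or either
    locus is monomorphic in the complete-pairs subset.
    """
    a = np.asarray(dosages_a, dtype=np.float64)
    b = np.asarray(dosages_b, dtype=np.float64)
    ok = (np.asarray(dosages_a) != MISSING) & (np.asarray(dosages_b) != MISSING)
    n = int(ok.sum())
    if n < 2:
        raise UndefinedResult(f"only {n} pairwise-complete observations")
    x, y = a[ok], b[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise UndefinedResult("locus monomorphic in the complete-pairs subset")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy)), n


@dataclass
class HaplotypeFreqs:
    """EM-estimated gamete frequencies for two counted alleles A and B."""

    pAB: float
    pAb: float
    paB: float
    pab: float
    converged: bool
    n_iter: int

    def __iter__(self):
        return iter((self.pAB, self.pAb, self.paB, self.pab))


def em_haplotype_freqs(dosages_a, dosages_b, tol: float = 1e-10,
                       max_iter: int = 1000) -> HaplotypeFreqs:
    """EM over the double-heterozygote ambiguity on unphased dosage pairs.

    Only the AB/ab vs Ab/aB split of double heterozygotes is latent; all
    other genotype combinations resolve to gametes directly.
    """
    a = np.asarray(dosages_a)
    b = np.asarray(dosages_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise UndefinedResult("fewer than 2 pairwise-complete observations")
    # 3x3 genotype table, indices = dosage of the counted allele
    tab = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            tab[i, j] = np.count_nonzero((a == i) & (b == j))
    n_gam = 2 * a.size
    ndh = tab[1, 1]
    # fixed gamete counts from unambiguous genotypes
    nAB = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    nAb = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    naB = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    nab = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    pA = (2 * tab[2, :].sum() + tab[1, :].sum()) / n_gam
    pB = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / n_gam
    # start from linkage equilibrium
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = f[0] * f[3] + f[1] * f[2]
        w = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = np.array([
            nAB + ndh * w,
            nAb + ndh * (1 - w),
            naB + ndh * (1 - w),
            nab + ndh * w,
        ]) / n_gam
        delta = np.abs(new - f).max()
        f = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM haplotype frequencies did not converge in %d iterations", max_iter)
    return HaplotypeFreqs(f[0], f[1], f[2], f[3], converged, it)


def pairwise_ld_scan(dataset: GenotypeDataset,
                     max_dist_bp: int = DEFAULT_MAX_DIST_BP,
                     want_dprime: bool = False) -> Iterator[LDPair]:
    """Yield every same-chromosome SNP pair with 0 < dist <= ``max_dist_bp``.

    Emits pairs ordered by (chrom block, idx_a, idx_b) so output is
    reproducible byte-for-byte.  Pairs with too few complete observations or
    a monomorphic locus are counted and skipped (see the log).
    """
    pos = dataset.positions()
    chroms = dataset.chromosomes()
    for j in range(1, dataset.n_variants):
        if chroms[j] == chroms[j - 1] and pos[j] < pos[j - 1]:
            raise DataError("variants are not sorted by position; sort the dataset first")
    X = dataset.calls.astype(np.float64)
    valid = dataset.calls != MISSING
    Xz = np.where(valid, X, 0.0)
    skipped = {"too_few_obs": 0, "monomorphic": 0}
    for chrom in sorted(set(chroms), key=lambda c: (0, int(c)) if c.isdigit() else (1, c)):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        for ii, i in enumerate(idx):
            hi = ii + np.searchsorted(cpos[ii:], cpos[ii] + max_dist_bp, side="right")
            targets = idx[ii + 1:hi]
            if targets.size == 0:
                continue
            w = valid[:, i:i + 1] & valid[:, targets]
            n = w.sum(axis=0)
            xa = Xz[:, i:i + 1]
            Y = Xz[:, targets]
            sa = (xa * w).sum(axis=0)
            sy = (Y * w).sum(axis=0)
            saa = (xa * xa * w).sum(axis=0)
            syy = (Y * Y * w).sum(axis=0)
            say = (xa * Y * w).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = say - sa * sy / n
                va = saa - sa * sa / n
                vy = syy - sy * sy / n
                r2 = cov * cov / (va * vy)
            for t, jv in enumerate(targets):
                if n[t] < 2:
                    skipped["too_few_obs"] += 1
                    continue
                if va[t] <= 1e-12 or vy[t] <= 1e-12:
                    skipped["monomorphic"] += 1
                    continue
                d_raw = d_prime = None
                if want_dprime:
                    try:
                        fr = em_haplotype_freqs(dataset.calls[:, i], dataset.calls[:, jv])
                        pA = fr.pAB + fr.pAb
                        pB = fr.pAB + fr.paB
                        d_raw, d_prime, _ = haplotype_ld(fr.pAB, pA, pB)
                    except UndefinedResult:
                        pass
                yield LDPair(chrom=str(chrom), idx_a=int(i), idx_b=int(jv),
                             dist_bp=int(pos[jv] - pos[i]),
                             r2=float(min(r2[t], 1.0)), n_obs=int(n[t]),
                             d_raw=d_raw, d_prime=d_prime)
    if skipped["too_few_obs"] or skipped["monomorphic"]:
        logger.info("LD scan skipped pairs: %s", skipped)


def ld_pairs_frame(pairs, dataset: Optional[GenotypeDataset] = None):
    """Materialize a pair stream as a DataFrame (TSV-ready columns)."""
    import pandas as pd

    rows = list(pairs)
    df = pd.DataFrame({
        "CHR": [p.chrom for p in rows],
        "IDX_A": [p.idx_a for p in rows],
        "IDX_B": [p.idx_b for p in rows],
        "DIST_BP": [p.dist_bp for p in rows],
        "N_OBS": [p.n_obs for p in rows],
        "R2": [p.r2 for p in rows],
    })
    if dataset is not None and len(df):
        df.insert(1, "SNP_A", [dataset.variants[p.idx_a].id for p in rows])
        df.insert(2, "BP_A", [dataset.variants[p.idx_a].pos_bp for p in rows])
        df.insert(3, "SNP_B", [dataset.variants[p.idx_b].id for p in rows])
        df.insert(4, "BP_B", [dataset.variants[p.idx_b].pos_bp for p in rows])
    if rows and rows[0].d_prime is not None:
        df["D"] = [p.d_raw for p in rows]
        df["DPRIME"] = [p.d_prime for p in rows]
    return df
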