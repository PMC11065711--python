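"""Pedigree-based effective population size from coancestry and inbreeding.

Kinship (coancestry) C is built by the standard tabular method; inbreeding
F_i is the coancestry of an individual's parents.  Pedigree depth per
individual is measured as equivalent complete generations,
t_i = sum over known ancestors of (1/2)^g.  Per-generation increases

    dC_ij = 1 - (1 - C_ij)^(2 / (t_i + t_j))        (Cervantes et al. 2011)
    dF_i  = 1 - (1 - F_i)^(1 / (t_i - 1))           (Gutierrez et al. 2009)

are averaged over a reference set (default: all non-founders) and inverted
into effective sizes NeC = 1/(2 mean dC) and NeF = 1/(2 mean dF).  Their
ratio S = NeC/NeF gauges subdivision: both measure the same accumulated
drift, so S near 1 signals panmixia and S < 1 structured matings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .io import PedigreeTable


@dataclass
class NeResult:
    """An effective-size estimate or a reasoned 'undefined'."""

    value: Optional[float]
    mean_delta: float
    se: Optional[float]
    n_used: int
    n_excluded: int
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class CoancestryResult:
    kinship: np.ndarray            # aligned with ``ids``
    ids: list[str]
    inbreeding: np.ndarray
    ecg: np.ndarray                # equivalent complete generations
    ne_ci: NeResult
    ne_fi: NeResult
    s_ratio: Optional[float]
    reference_set: list[str]


def kinship_matrix(pedigree: PedigreeTable) -> np.ndarray:
    """Coancestry matrix by the tabular method, aligned with ``pedigree.ids``.

    C(x,x) = (1 + C(sire_x, dam_x)) / 2 and C(x,y) = (C(sire_x,y) +
    C(dam_x,y)) / 2 over earlier individuals; an unknown parent contributes 0.
    """
    ids = pedigree.ids
    topo = pedigree.topological_order()
    parents = pedigree.parents()
    n = len(ids)
    # work in topological coordinates, then map back
    tpos = {i: k for k, i in enumerate(topo)}
    C = np.zeros((n, n))
    for x in topo:
        xi = tpos[x]
        s, d = parents[x]
        si = tpos[s] if s is not None else None
        di = tpos[d] if d is not None else None
        if xi > 0:
            row = np.zeros(xi)
            if si is not None:
                row += C[si, :xi]
            if di is not None:
                row += C[di, :xi]
            row *= 0.5
            C[xi, :xi] = row
            C[:xi, xi] = row
        f_par = C[si, di] if (si is not None and di is not None) else 0.0
        C[xi, xi] = 0.5 * (1.0 + f_par)
    # permute back to file order
    perm = np.array([tpos[i] for i in ids])
    return C[np.ix_(perm, perm)]


def inbreeding_coefficients(pedigree: PedigreeTable,
                            kinship: Optional[np.ndarray] = None) -> np.ndarray:
    """F_i = coancestry of i's parents (0 when either parent is unknown)."""
    C = kinship if kinship is not None else kinship_matrix(pedigree)
    index = {i: k for k, i in enumerate(pedigree.ids)}
    F = np.zeros(len(pedigree))
    for k, (s, d) in enumerate(zip(pedigree.sires, pedigree.dams)):
        if s is not None and d is not None:
            F[k] = C[index[s], index[d]]
    return F


def equivalent_complete_generations(pedigree: PedigreeTable) -> np.ndarray:
    """t_i = sum over known ancestors of (1/2)^g; founders have t = 0.

    Computed by the recursion t_i = sum over known parents of (1 + t_p)/2.
    """
    parents = pedigree.parents()
    t: dict[str, float] = {}
    for x in pedigree.topological_order():
        s, d = parents[x]
        t[x] = sum((1.0 + t[p]) / 2.0 for p in (s, d) if p is not None)
    return np.array([t[i] for i in pedigree.ids])


def delta_coancestry(c_ij: float, t_i: float, t_j: float) -> float:
    """Per-generation increase in coancestry for one pair."""
    if not 0.0 <= c_ij < 1.0:
        raise ValueError(f"coancestry {c_ij} outside [0, 1)")
    if t_i + t_j <= 0:
        raise DataError("founder pair: t_i + t_j = 0, delta-C undefined")
    return 1.0 - (1.0 - c_ij) ** (2.0 / (t_i + t_j))


def delta_inbreeding(f_i: float, t_i: float) -> float:
    """Per-generation increase in inbreeding, defined only for t_i > 1."""
    if t_i <= 1.0:
        raise DataError("delta-F requires pedigree depth t > 1")
    return 1.0 - (1.0 - f_i) ** (1.0 / (t_i - 1.0))


def _resolve_reference(pedigree: PedigreeTable,
                       reference_set: Optional[Sequence[str]]) -> list[str]:
    if reference_set is not None:
        missing = [r for r in reference_set if r not in set(pedigree.ids)]
        if missing:
            raise DataError(f"reference individuals not in pedigree: {missing[:3]}")
        return list(reference_set)
    return [i for i, s, d in zip(pedigree.ids, pedigree.sires, pedigree.dams)
            if s is not None or d is not None]


def ne_coancestry(pedigree: PedigreeTable,
                  reference_set: Optional[Sequence[str]] = None,
                  kinship: Optional[np.ndarray] = None,
                  ecg: Optional[np.ndarray] = None) -> NeResult:
    """NeC = 1/(2 mean dC_ij) over unordered pairs in the reference set.

    Pairs with t_i + t_j = 0 are excluded and counted; the standard error of
    the pair mean is reported alongside.
    """
    ref = _resolve_reference(pedigree, reference_set)
    C = kinship if kinship is not None else kinship_matrix(pedigree)
    t = ecg if ecg is not None else equivalent_complete_generations(pedigree)
    index = {i: k for k, i in enumerate(pedigree.ids)}
    ridx = np.array([index[r] for r in ref])
    if ridx.size < 2:
        return NeResult(None, float("nan"), None, 0, 0,
                        reason="need >= 2 reference individuals")
    Cr = C[np.ix_(ridx, ridx)]
    tr = t[ridx]
    iu, ju = np.triu_indices(ridx.size, k=1)
    tsum = tr[iu] + tr[ju]
    ok = tsum > 0
    n_excl = int((~ok).sum())
    if not np.any(ok):
        return NeResult(None, float("nan"), None, 0, n_excl,
                        reason="all pairs are founder pairs (t_i + t_j = 0)")
    dc = 1.0 - (1.0 - Cr[iu[ok], ju[ok]]) ** (2.0 / tsum[ok])
    mean_dc = float(dc.mean())
    se = float(dc.std(ddof=1) / math.sqrt(dc.size)) if dc.size > 1 else None
    if mean_dc <= 0:
        return NeResult(None, mean_dc, se, int(dc.size), n_excl,
                        reason="mean delta-C = 0: no coancestry accumulation")
    return NeResult(1.0 / (2.0 * mean_dc), mean_dc, se, int(dc.size), n_excl)


def ne_inbreeding(pedigree: PedigreeTable,
                  reference_set: Optional[Sequence[str]] = None,
                  kinship: Optional[np.ndarray] = None,
                  ecg: Optional[np.ndarray] = None) -> NeResult:
    """NeF = 1/(2 mean dF_i) over reference individuals with t_i > 1."""
    ref = _resolve_reference(pedigree, reference_set)
    t = ecg if ecg is not None else equivalent_complete_generations(pedigree)
    F = inbreeding_coefficients(pedigree, kinship)
    index = {i: k for k, i in enumerate(pedigree.ids)}
    ridx = np.array([index[r] for r in ref], dtype=int)
    eligible = ridx[t[ridx] > 1.0]
    n_excl = int(ridx.size - eligible.size)
    if eligible.size == 0:
        return NeResult(None, float("nan"), None, 0, n_excl,
                        reason="no individuals with pedigree depth t > 1")
    df = 1.0 - (1.0 - F[eligible]) ** (1.0 / (t[eligible] - 1.0))
    mean_df = float(df.mean())
    se = float(df.std(ddof=1) / math.sqrt(df.size)) if df.size > 1 else None
    if mean_df <= 0:
        return NeResult(None, mean_df, se, int(df.size), n_excl,
                        reason="mean delta-F = 0: no inbreeding accumulation")
    return NeResult(1.0 / (2.0 * mean_df), mean_df, se, int(df.size), n_excl)


def equivalent_subpopulations(ne_ci: NeResult, ne_fi: NeResult) -> Optional[float]:
    """S = NeC / NeF; None when either estimate is undefined."""
    if not (ne_ci.defined and ne_fi.defined):
        return None
    return ne_ci.value / ne_fi.value


def coancestry_analysis(pedigree: PedigreeTable,
                        reference_set: Optional[Sequence[str]] = None
                        ) -> CoancestryResult:
    """Full pedigree analysis: kinship, F, ECG, NeC, NeF and the S ratio."""
    C = kinship_matrix(pedigree)
    t = equivalent_complete_generations(pedigree)
    F = inbreeding_coefficients(pedigree, C)
    ref = _resolve_reference(pedigree, reference_set)
    nc = ne_coancestry(pedigree, ref, kinship=C, ecg=t)
    nf = ne_inbreeding(pedigree, ref, kinship=C, ecg=t)
    return CoancestryResult(kinship=C, ids=list(pedigree.ids), inbreeding=F,
                            ecg=t, ne_ci=nc, ne_fi=nf,
                            s_ratio=equivalent_subpopulations(nc, nf),
                            reference_set=ref)
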