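"""Independent brute-force oracles used to validate the package's fast paths.

Each oracle is written from the defining formula (exact rational arithmetic
or naive enumeration) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def pearson_r2_brute(a, b, missing=-1) -> tuple[float, int]:
    """Squared Pearson correlation by the textbook sums, loop-based."""
    xs, ys = [], []
    for x, y in zip(a, b):
        if x != missing and y != missing:
            xs.append(float(x))
            ys.append(float(y))
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return (sxy * sxy) / (sxx * syy), n


def hwe_enumeration_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE p by full enumeration of heterozygote counts, conditioning
    on the allele counts, in exact rational arithmetic."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # copies of allele 1
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_maj < 0:
            continue
        weights[h] = Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(hom_min) * math.factorial(hom_maj))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def kinship_path_counting(pedigree) -> np.ndarray:
    """Kinship by Wright's path counting: for i != j sum over common
    ancestors A and pairs of ancestral paths sharing no individual but A of
    (1/2)^(len_i + len_j + 1) (1 + F_A)."""
    parents = pedigree.parents()
    path_cache: dict[str, list[tuple]] = {}

    def paths_up(i):
        if i not in path_cache:
            out = [(i,)]
            for p in parents[i]:
                if p is not None:
                    out += [(i,) + q for q in paths_up(p)]
            path_cache[i] = out
        return path_cache[i]

    phi_cache: dict[tuple, float] = {}

    def inbreeding(i):
        s, d = parents[i]
        return phi(s, d) if (s is not None and d is not None) else 0.0

    def phi(i, j):
        key = (i, j) if i <= j else (j, i)
        if key in phi_cache:
            return phi_cache[key]
        if i == j:
            val = 0.5 * (1.0 + inbreeding(i))
        else:
            val = 0.0
            for P in paths_up(i):
                inner_p = set(P[:-1])
                for Q in paths_up(j):
                    if P[-1] == Q[-1] and not (inner_p & set(Q[:-1])):
                        val += 0.5 ** (len(P) + len(Q) - 1) * (1.0 + inbreeding(P[-1]))
        phi_cache[key] = val
        return val

    ids = pedigree.ids
    n = len(ids)
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            C[a, b] = C[b, a] = phi(ids[a], ids[b])
    return C


def pair_loglik(table: np.ndarray, pAB: float, pA: float, pB: float) -> float:
    """Multinomial log-likelihood of a 3x3 dosage table under random union of
    gametes with haplotype frequencies derived from (pAB, pA, pB)."""
    f = {"AB": pAB, "Ab": pA - pAB, "aB": pB - pAB, "ab": 1 - pA - pB + pAB}
    dose = {"AB": (1, 1), "Ab": (1, 0), "aB": (0, 1), "ab": (0, 0)}
    geno = np.zeros((3, 3))
    for h1, f1 in f.items():
        for h2, f2 in f.items():
            i = dose[h1][0] + dose[h2][0]
            j = dose[h1][1] + dose[h2][1]
            geno[i, j] += f1 * f2
    ll = 0.0
    for i in range(3):
        for j in range(3):
            if table[i, j]:
                if geno[i, j] <= 0:
                    return -math.inf
                ll += table[i, j] * math.log(geno[i, j])
    return ll


def random_pedigree(rng: np.random.Generator, n: int):
    """Random acyclic pedigree on <= n individuals (parents precede children)."""
    from popne.io import PedigreeTable

    ids = [f"I{k}" for k in range(n)]
    sires, dams = [], []
    for k in range(n):
        if k < 2 or rng.random() < 0.3:
            sires.append(None)
            dams.append(None)
        else:
            s = int(rng.integers(k))
            d = int(rng.integers(k))
            sires.append(ids[s])
            dams.append(ids[d] if d != s else None)  # no selfed matings
    return PedigreeTable(ids, sires, dams)
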