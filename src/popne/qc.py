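"""Marker quality control: autosome restriction, call rate, MAF and an exact
Hardy-Weinberg test, applied in that order with first-failing-rule attribution.

Defaults follow common practice for dense bovine SNP panels: retain markers
with call rate >= 0.90, minor allele frequency >= 0.05 and exact HWE p-value
>= 1e-5, restricted to the 29 cattle autosomes.  Thresholds are inclusive.
No sample-level QC is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import UndefinedResult
from .io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

CATTLE_AUTOSOMES = frozenset(str(i) for i in range(1, 30))

RULES = ("autosome_or_unmapped", "call_rate", "maf", "hwe")


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-5
    autosome_labels: frozenset = CATTLE_AUTOSOMES

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_pass: int
    n_fail_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def pass_proportion(self) -> float:
        return self.n_pass / self.n_input if self.n_input else float("nan")


def snp_call_rate(dataset: GenotypeDataset, j: int) -> float:
    """Fraction of samples with a non-missing call at variant ``j``."""
    if dataset.n_samples == 0:
        raise UndefinedResult("call rate undefined with zero samples")
    col = dataset.calls[:, j]
    return float(np.count_nonzero(col != MISSING) / dataset.n_samples)


def minor_allele_frequency(dataset: GenotypeDataset, j: int) -> float:
    """min(p, 1-p) of the counted allele over non-missing dosages."""
    col = dataset.calls[:, j]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise UndefinedResult("MAF undefined for an all-missing variant")
    p = float(obs.sum()) / (2 * obs.size)
    return min(p, 1.0 - p)


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one (the Wigginton/Cutler/Abecasis convention, no mid-p).
    """
    if min(n_hom1, n_het, n_hom2) < 0 or n_hom1 + n_het + n_hom2 < 1:
        raise ValueError("genotype counts must be non-negative and sum to >= 1")
    n = n_hom1 + n_het + n_hom2
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_minor == 0:
        return 1.0
    # P(het = h | allele counts) over all h with the parity of n_minor
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1) - gammaln(hs + 1) - gammaln(hom_minor + 1) - gammaln(hom_major + 1)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hs == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _hwe_p_for_variant(col: np.ndarray) -> float:
    obs = col[col != MISSING]
    n_hom1 = int(np.count_nonzero(obs == 2))
    n_het = int(np.count_nonzero(obs == 1))
    n_hom2 = int(np.count_nonzero(obs == 0))
    return hwe_exact_p(n_hom1, n_het, n_hom2)


def apply_qc(dataset: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
             ) -> tuple[GenotypeDataset, QCReport]:
    """Filter variants; each failure is attributed to the first failing rule
    (autosome/position -> call rate -> MAF -> HWE)."""
    fails = {r: 0 for r in RULES}
    keep: list[int] = []
    for j, v in enumerate(dataset.variants):
        if v.chrom not in thresholds.autosome_labels or v.pos_bp < 1:
            fails["autosome_or_unmapped"] += 1
            continue
        if snp_call_rate(dataset, j) < thresholds.min_call_rate:
            fails["call_rate"] += 1
            continue
        col = dataset.calls[:, j]
        if not np.any(col != MISSING):
            fails["call_rate"] += 1  # all-missing cannot reach the MAF rule
            continue
        if minor_allele_frequency(dataset, j) < thresholds.min_maf:
            fails["maf"] += 1
            continue
        if _hwe_p_for_variant(col) < thresholds.hwe_p_floor:
            fails["hwe"] += 1
            continue
        keep.append(j)
    report = QCReport(n_input=dataset.n_variants, n_pass=len(keep), n_fail_by_rule=fails)
    if not keep:
        logger.warning("QC removed every variant (%d input)", dataset.n_variants)
    return dataset.subset_variants(keep), report
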