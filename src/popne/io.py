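"""Genotype and pedigree containers plus PLINK text PED/MAP readers/writers.

Genotypes travel as counted-allele dosages (0/1/2, -1 = missing) in a
samples x variants ``numpy`` matrix.  The counted allele at each variant is
the first non-missing allele encountered in file order (lexicographically
smaller allele on ties of first appearance), so re-reading a file is
bit-deterministic.  r-squared is invariant to this coding; the sign of D is
reproducible because the coding is.

Positions are 1-based base pairs per the MAP convention; ``pos_bp == 0``
marks an unmapped marker (removed by QC downstream).  Pairwise distances are
``pos_b - pos_a`` with no half-open adjustment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import networkx as nx

from .errors import DataError, FormatError

MISSING = -1  # dosage sentinel


def _chrom_sort_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP.  ``alleles[0]`` is the counted (dosage) allele."""

    chrom: str
    id: str
    pos_bp: int
    alleles: tuple[str, str]

    def __post_init__(self):
        if not self.chrom:
            raise DataError(f"variant {self.id}: empty chromosome label")
        if self.pos_bp < 0:
            raise DataError(f"variant {self.id}: negative position {self.pos_bp}")
        if self.alleles[0] == self.alleles[1]:
            raise DataError(f"variant {self.id}: alleles must be distinct")


@dataclass
class GenotypeDataset:
    """An unphased diploid SNP panel: variants, sample ids and a dosage matrix.

    ``calls`` has shape (n_samples, n_variants) with entries in {0, 1, 2} or
    ``MISSING`` (-1).  Variants are kept sorted by (chrom, pos_bp).
    """

    variants: list[VariantRecord]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        keys = [(_chrom_sort_key(v.chrom), v.pos_bp) for v in self.variants]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            order = sorted(range(len(keys)), key=keys.__getitem__)
            self.variants = [self.variants[i] for i in order]
            self.calls = self.calls[:, order]
        seen = set()
        for v in self.variants:
            key = (v.chrom, v.pos_bp, v.id)
            if key in seen:
                raise DataError(f"duplicate variant (chrom={v.chrom}, pos={v.pos_bp}, id={v.id})")
            seen.add(key)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeDataset":
        keep = list(keep)
        return GenotypeDataset(
            variants=[self.variants[i] for i in keep],
            samples=list(self.samples),
            calls=self.calls[:, keep].copy(),
        )


def normalize_coding(dataset: GenotypeDataset) -> GenotypeDataset:
    """Re-code dosages so the counted allele matches what ``read_ped_map``
    would pick for the file ``write_ped_map`` produces (first-seen rule,
    lexicographic tie-break on heterozygotes).  Makes write->read an identity.
    """
    calls = dataset.calls.copy()
    variants = list(dataset.variants)
    for j, v in enumerate(variants):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        first = int(obs[0])
        flip = False
        if first == 0:
            flip = True
        elif first == 1 and v.alleles[0] > v.alleles[1]:
            flip = True
        if flip:
            nz = col != MISSING
            col[nz] = 2 - col[nz]
            variants[j] = VariantRecord(v.chrom, v.id, v.pos_bp, (v.alleles[1], v.alleles[0]))
    return GenotypeDataset(variants=variants, samples=list(dataset.samples), calls=calls)


# ---------------------------------------------------------------------------
# PED / MAP

def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    MAP: 4 whitespace columns (chrom, id, cM, bp).  PED: 6 leading columns
    then two allele tokens per variant; "0" is a missing allele and a
    half-missing genotype ("0 A") counts as missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, vid, _cm, bp = parts
            map_rows.append((chrom, vid, int(bp)))
    m = len(map_rows)

    samples: list[str] = []
    geno_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} PED columns "
                    f"for {m} variants, got {len(parts)}"
                )
            samples.append(parts[1])
            geno_rows.append(parts[6:])

    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (chrom, vid, bp) in enumerate(map_rows):
        counted: Optional[str] = None
        other: Optional[str] = None
        col = np.full(n, MISSING, dtype=np.int8)
        pairs = [(geno_rows[i][2 * j], geno_rows[i][2 * j + 1]) for i in range(n)]
        for a1, a2 in pairs:
            if a1 == "0" or a2 == "0":
                continue
            for al in sorted({a1, a2}):  # lexicographic tie-break on first appearance
                if counted is None:
                    counted = al
                elif other is None and al != counted:
                    other = al
                elif al not in (counted, other):
                    raise DataError(f"variant {vid}: more than two alleles observed")
        if counted is None:
            counted, other = "A", "B"  # all-missing column: placeholder alleles
        if other is None:
            other = "B" if counted != "B" else "A"  # monomorphic in file
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            col[i] = (a1 == counted) + (a2 == counted)
        calls[:, j] = col
        variants.append(VariantRecord(chrom, vid, bp, (counted, other)))

    return GenotypeDataset(variants=variants, samples=samples, calls=calls)


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP so that :func:`read_ped_map` reproduces ``calls`` exactly
    (the dataset is coding-normalized first)."""
    ds = normalize_coding(dataset)
    with open(map_path, "w") as fh:
        for v in ds.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, v in enumerate(ds.variants):
                d = ds.calls[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [v.alleles[0], v.alleles[0]]
                elif d == 1:
                    fields += [v.alleles[0], v.alleles[1]]
                else:
                    fields += [v.alleles[1], v.alleles[1]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Pedigrees

UNKNOWN_PARENT = ("0", "", "NA", "na", "-")


@dataclass
class PedigreeTable:
    """A pedigree: per individual its sire, dam (``None`` = unknown) and an
    optional birth year.  Guaranteed acyclic on construction."""

    ids: list[str]
    sires: list[Optional[str]]
    dams: list[Optional[str]]
    birth_years: Optional[list[Optional[int]]] = None

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            dupes = [i for i in self.ids if self.ids.count(i) > 1]
            raise DataError(f"duplicate individual id: {dupes[0]}")
        known = set(self.ids)
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        for child, s, d in zip(self.ids, self.sires, self.dams):
            for p in (s, d):
                if p is not None:
                    if p not in known:
                        raise DataError(f"individual {child}: parent {p} not in pedigree")
                    g.add_edge(p, child)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise DataError(f"pedigree contains a cycle: {path}")
        self._graph = g

    def __len__(self) -> int:
        return len(self.ids)

    def topological_order(self) -> list[str]:
        """Ancestors before descendants; deterministic (ties by file order)."""
        pos = {i: k for k, i in enumerate(self.ids)}
        return list(nx.lexicographical_topological_sort(self._graph, key=pos.get))

    def founders(self) -> list[str]:
        return [i for i, s, d in zip(self.ids, self.sires, self.dams)
                if s is None and d is None]

    def parents(self) -> dict[str, tuple[Optional[str], Optional[str]]]:
        return {i: (s, d) for i, s, d in zip(self.ids, self.sires, self.dams)}


def _parse_parent(token: str) -> Optional[str]:
    return None if token.strip() in UNKNOWN_PARENT else token.strip()


def read_pedigree(path) -> PedigreeTable:
    """Read a delimited pedigree table (id, sire, dam[, birth_year]).

    Delimiter (comma, tab or whitespace) is auto-detected; "0" or an empty
    field marks an unknown parent; a header row is skipped if its first field
    looks like a column name.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty pedigree file")
    delim = None
    for cand in (",", "\t"):
        if cand in lines[0]:
            delim = cand
            break
    rows = []
    for lineno, ln in enumerate(lines, 1):
        parts = [p.strip() for p in (ln.split(delim) if delim else ln.split())]
        if len(parts) not in (3, 4):
            raise FormatError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
        rows.append((lineno, parts))
    first = [p.lower() for p in rows[0][1]]
    if first[0] in ("id", "individual", "animal", "indiv", "ind"):
        rows = rows[1:]
    ids, sires, dams, years = [], [], [], []
    has_year = False
    for lineno, parts in rows:
        ids.append(parts[0])
        sires.append(_parse_parent(parts[1]))
        dams.append(_parse_parent(parts[2]))
        if len(parts) == 4 and parts[3] not in ("", "NA"):
            try:
                years.append(int(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad birth year {parts[3]!r}") from exc
            has_year = True
        else:
            years.append(None)
    return PedigreeTable(ids, sires, dams, years if has_year else None)


def write_pedigree(ped: PedigreeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tbirth_year\n")
        years = ped.birth_years or [None] * len(ped)
        for i, s, d, y in zip(ped.ids, ped.sires, ped.dams, years):
            fh.write(f"{i}\t{s or 0}\t{d or 0}\t{'' if y is None else y}\n")


def write_tsv(df, path) -> None:
    """All tabular outputs leave the package as tab-separated text."""
    df.to_csv(path, sep="\t", index=False)
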