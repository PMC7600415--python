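"""Casein-complex haplotype data model, allele frequencies, LD and grouping.

The goat casein complex on chromosome 6 clusters four loci: CSN1S1
(alpha-S1), CSN1S2 (alpha-S2), CSN2 (beta) and CSN3 (kappa casein).  Each
animal carries two phased haplotypes, an ordered sequence of allele tokens
per locus block.  Tokens are single bases, the deletion token ``.-`` or
multi-base insertions such as ``AATC``; input files must delimit tokens
(concatenated display strings are ambiguous with indels and are not
parsed).

Summary statistics: per-SNP minor allele frequency (variants with
MAF < 0.05 flagged rare), observed heterozygosity, and pairwise linkage
disequilibrium D' and r^2 computed directly from phased haplotypes.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, FormatError, ValidationError

#: MAF threshold separating common from rare variants.
RARE_MAF = 0.05

_TOKEN_RE = re.compile(r"^([ACGT]+|\.-)$")
#: Delimiter between allele tokens inside one CSV field.
TOKEN_SEP = " "


@dataclass(frozen=True)
class LocusBlock:
    """One casein locus: ordered SNP positions within the block."""

    name: str
    snp_ids: tuple[str, ...]

    @property
    def n_positions(self) -> int:
        return len(self.snp_ids)


def _block(name: str, n: int) -> LocusBlock:
    return LocusBlock(name, tuple(f"{name}_{i:02d}" for i in range(1, n + 1)))


#: Default casein-complex block layout: 48 SNPs over the four loci.
CASEIN_BLOCKS = (
    _block("CSN1S1", 18),
    _block("CSN1S2", 18),
    _block("CSN2", 8),
    _block("CSN3", 4),
)


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Two phased per-block allele-token sequences for one animal."""

    animal_id: str
    hap1: dict[str, tuple[str, ...]]
    hap2: dict[str, tuple[str, ...]]

    def phases(self):
        return (self.hap1, self.hap2)


def haplotype_key(hap: dict[str, tuple[str, ...]], blocks=CASEIN_BLOCKS) -> str:
    """Canonical label of a full-complex haplotype (token-delimited)."""
    return "/".join("-".join(hap[b.name]) for b in blocks)


def _validate_assignment(a: HaplotypeAssignment, blocks) -> None:
    for phase_no, hap in enumerate(a.phases(), start=1):
        for b in blocks:
            if b.name not in hap:
                raise ValidationError(
                    f"animal {a.animal_id}: missing block {b.name} (phase {phase_no})"
                )
            toks = hap[b.name]
            if len(toks) != b.n_positions:
                raise ValidationError(
                    f"animal {a.animal_id}, block {b.name}: {len(toks)} tokens, "
                    f"expected {b.n_positions}"
                )
            bad = [t for t in toks if not _TOKEN_RE.match(t)]
            if bad:
                raise ValidationError(
                    f"animal {a.animal_id}, block {b.name}: invalid token(s) {bad}"
                )


def parse_haplotypes(path, blocks=CASEIN_BLOCKS) -> list[HaplotypeAssignment]:
    """Read per-animal phased haplotypes from a token-delimited CSV.

    Columns: ``animal_id`` plus ``<BLOCK>_1`` and ``<BLOCK>_2`` per block,
    each field holding space-delimited allele tokens.
    """
    needed = ["animal_id"] + [f"{b.name}_{p}" for b in blocks for p in (1, 2)]
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in needed if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            hap1 = {
                b.name: tuple(row[f"{b.name}_1"].split(TOKEN_SEP)) for b in blocks
            }
            hap2 = {
                b.name: tuple(row[f"{b.name}_2"].split(TOKEN_SEP)) for b in blocks
            }
            a = HaplotypeAssignment(row["animal_id"].strip(), hap1, hap2)
            _validate_assignment(a, blocks)
            out.append(a)
    return out


def write_haplotypes(assignments, path, blocks=CASEIN_BLOCKS) -> None:
    cols = ["animal_id"] + [f"{b.name}_{p}" for b in blocks for p in (1, 2)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for a in assignments:
            row = [a.animal_id]
            for b in blocks:
                row.append(TOKEN_SEP.join(a.hap1[b.name]))
                row.append(TOKEN_SEP.join(a.hap2[b.name]))
            writer.writerow(row)


class MafResult(NamedTuple):
    maf: float
    minor_allele: str | None
    rare: bool
    monomorphic: bool


def maf(calls) -> MafResult:
    """Minor allele frequency of one biallelic SNP column.

    ``calls`` are allele tokens pooled over both phases of all animals.
    Monomorphic columns return MAF 0 with the flag set; more than two
    distinct alleles raise :class:`ValidationError`.
    """
    calls = list(calls)
    if not calls:
        raise ValidationError("maf needs at least one allele call")
    counts = Counter(calls)
    if len(counts) > 2:
        raise ValidationError(f"more than two alleles observed: {sorted(counts)}")
    if len(counts) == 1:
        return MafResult(0.0, None, False, True)
    (minor, n_minor) = min(counts.items(), key=lambda kv: (kv[1], kv[0]))
    freq = n_minor / len(calls)
    return MafResult(freq, minor, freq < RARE_MAF, False)


def snp_calls(assignments, block_name: str, pos: int):
    """Pooled phased allele calls (2 per animal) at one SNP position."""
    out = []
    for a in assignments:
        out.append(a.hap1[block_name][pos])
        out.append(a.hap2[block_name][pos])
    return out


def heterozygosity(assignments, block_name: str, pos: int) -> float:
    """Fraction of animals whose two phases differ at the SNP."""
    if not assignments:
        raise ValidationError("heterozygosity needs at least one animal")
    het = [
        a.hap1[block_name][pos] != a.hap2[block_name][pos] for a in assignments
    ]
    return float(np.mean(het))


def ld_pair(calls_i, calls_j) -> tuple[float, float]:
    """Pairwise LD (|D'|, r^2) from aligned phased calls at two SNPs.

    D = p_AB - p_A p_B; D' = D / D_max with
    D_max = min(p_A p_b, p_a p_B) when D > 0 else min(p_A p_B, p_a p_b);
    r^2 = D^2 / (p_A p_a p_B p_b).
    """
    calls_i = list(calls_i)
    calls_j = list(calls_j)
    if len(calls_i) != len(calls_j):
        raise ValidationError("phased call vectors must be aligned")
    ai = sorted(set(calls_i))
    aj = sorted(set(calls_j))
    if len(ai) != 2 or len(aj) != 2:
        raise DegenerateDataError("LD undefined unless both SNPs are biallelic")
    n = len(calls_i)
    x = np.array([c == ai[0] for c in calls_i], dtype=float)
    y = np.array([c == aj[0] for c in calls_j], dtype=float)
    p_a, p_b = x.mean(), y.mean()
    p_ab = float(np.mean(x * y))
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(d / d_max) if d_max > 0 else 0.0
    r2 = d**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(dprime), float(r2)


@dataclass(frozen=True)
class SnpMatrix:
    """Phased allele calls: two token rows per animal, SNPs in block order."""

    animal_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    phase1: np.ndarray  # (n_animals, n_snps) object array of tokens
    phase2: np.ndarray

    @classmethod
    def from_assignments(cls, assignments, blocks=CASEIN_BLOCKS) -> "SnpMatrix":
        snp_ids = tuple(s for b in blocks for s in b.snp_ids)
        p1 = np.array(
            [[t for b in blocks for t in a.hap1[b.name]] for a in assignments],
            dtype=object,
        )
        p2 = np.array(
            [[t for b in blocks for t in a.hap2[b.name]] for a in assignments],
            dtype=object,
        )
        return cls(
            animal_ids=tuple(a.animal_id for a in assignments),
            snp_ids=snp_ids,
            phase1=p1,
            phase2=p2,
        )

    def calls(self, snp_index: int) -> list[str]:
        """Pooled phased calls at one SNP (both phases, all animals)."""
        return list(self.phase1[:, snp_index]) + list(self.phase2[:, snp_index])


def ld_table(assignments, blocks=CASEIN_BLOCKS) -> pd.DataFrame:
    """Long-format pairwise LD over all polymorphic biallelic SNPs."""
    matrix = SnpMatrix.from_assignments(assignments, blocks)
    cols = []
    for idx, snp_id in enumerate(matrix.snp_ids):
        calls = matrix.calls(idx)
        if len(set(calls)) == 2:
            cols.append((snp_id, calls))
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            dprime, r2 = ld_pair(cols[i][1], cols[j][1])
            rows.append(
                {
                    "snp_i": cols[i][0],
                    "snp_j": cols[j][0],
                    "dprime": dprime,
                    "r2": r2,
                }
            )
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "dprime", "r2"])


@dataclass(frozen=True)
class HaplotypeGrouping:
    """Animals grouped by full-complex haplotype variant."""

    groups: dict[str, tuple[str, ...]]
    n_animals: int
    n_haplotypes: int

    @property
    def animals_per_haplotype(self) -> float:
        return self.n_animals / self.n_haplotypes


def group_by_haplotype(
    assignments,
    blocks=CASEIN_BLOCKS,
    *,
    homozygous_only: bool = False,
) -> HaplotypeGrouping:
    """Enumerate haplotype variants and map animals onto variant groups.

    By default an animal contributes to the group of every distinct variant
    it carries (heterozygotes appear in two groups).  With
    ``homozygous_only=True`` only animals whose two haplotypes are identical
    are grouped, giving disjoint groups; the variant inventory still counts
    every haplotype observed in the sample.
    """
    variants: set[str] = set()
    groups: dict[str, list[str]] = {}
    for a in assignments:
        k1 = haplotype_key(a.hap1, blocks)
        k2 = haplotype_key(a.hap2, blocks)
        variants.update((k1, k2))
        if homozygous_only:
            if k1 == k2:
                groups.setdefault(k1, []).append(a.animal_id)
        else:
            for k in {k1, k2}:
                groups.setdefault(k, []).append(a.animal_id)
    return HaplotypeGrouping(
        groups={k: tuple(v) for k, v in sorted(groups.items())},
        n_animals=len(assignments),
        n_haplotypes=len(variants),
    )
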