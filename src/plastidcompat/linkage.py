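"""Minimal linkage toolkit for selfed recombinant inbred lines (RILs).

An F6 RIL population from a biparental cross is effectively homozygous, so
each line is scored A (first parent's allele) or B (second parent's) at
every locus.  The observed recombinant fraction R between two loci
overestimates nothing but accumulates recombination over the selfing
generations; the per-meiosis recombination fraction r follows the
Haldane-Waddington relation for selfing RILs,

    R = 2r / (1 + 2r)    <=>    r = R / (2 - 2R),

and map distance uses Haldane's function d = -50 ln(1 - 2r) centimorgans.

Three-point ordering is by parsimony: the middle locus is the one whose
discordances are explained by single crossovers, i.e. the order minimizing
apparent double recombinants.  Ties are flagged ambiguous, never broken
silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "-"


@dataclass
class RILTable:
    """lines x loci genotype matrix over {A, B, missing}."""

    genotypes: pd.DataFrame  # index: line ids; columns: loci; values A/B/NaN

    def __post_init__(self):
        bad = set(self.genotypes.stack().unique()) - {"A", "B"}
        if bad:
            raise ValueError(f"genotype values other than A/B/missing: {sorted(bad)}")

    @property
    def lines(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def loci(self) -> list[str]:
        return list(self.genotypes.columns)

    def column(self, locus: str) -> pd.Series:
        return self.genotypes[locus]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RILTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df.replace(MISSING, np.nan))

    def write_tsv(self, path: str | Path) -> None:
        self.genotypes.fillna(MISSING).to_csv(path, sep="\t", index_label="line")


def haldane_waddington_r(R: float) -> float:
    """Per-meiosis recombination fraction from the RIL-observable fraction."""
    if not 0 <= R < 1:
        raise ValueError(f"recombinant fraction {R} outside [0, 1)")
    return R / (2 - 2 * R)


def haldane_cm(r: float) -> float:
    """Haldane map distance (cM) for per-meiosis recombination fraction r."""
    if r >= 0.5:
        return math.inf
    return -50.0 * math.log(1 - 2 * r)


@dataclass(frozen=True)
class RecombinantCount:
    n_recombinant: int
    n_scored: int
    R: float
    r: float
    cM: float


def recombinant_count(table: RILTable, locus_a: str, locus_b: str) -> RecombinantCount:
    """Count lines with discordant genotypes at two loci and convert to
    per-meiosis recombination and Haldane map distance."""
    a = table.column(locus_a)
    b = table.column(locus_b)
    both = a.notna() & b.notna()
    n_scored = int(both.sum())
    if n_scored == 0:
        raise ValueError(
            f"loci {locus_a!r} and {locus_b!r} share no commonly scored lines"
        )
    n_rec = int((a[both] != b[both]).sum())
    R = n_rec / n_scored
    r = haldane_waddington_r(R)
    return RecombinantCount(n_rec, n_scored, R, r, haldane_cm(r))


@dataclass(frozen=True)
class ThreePointOrder:
    order: tuple[str, str, str]
    double_recombinants: int
    ambiguous: bool
    counts: dict[str, int]  # candidate middle -> apparent double recombinants


def order_three(
    table: RILTable, locus_a: str, locus_m: str, locus_b: str
) -> ThreePointOrder:
    """Parsimony ordering of three loci.

    For each candidate middle locus, a line is an apparent double
    recombinant when the two flanking genotypes agree and the middle
    disagrees; the order minimizing that count wins.  Equal minima are
    reported as ambiguous with the input order retained.
    """
    loci = (locus_a, locus_m, locus_b)
    if len(set(loci)) != 3:
        raise ValueError("three distinct loci required")
    cols = {l: table.column(l) for l in loci}
    counts = {}
    for mid in loci:
        flank = [l for l in loci if l != mid]
        f1, f2, m = cols[flank[0]], cols[flank[1]], cols[mid]
        scored = f1.notna() & f2.notna() & m.notna()
        counts[mid] = int(((f1 == f2) & (m != f1) & scored).sum())
    best = min(counts.values())
    winners = [l for l in loci if counts[l] == best]
    ambiguous = len(winners) > 1
    mid = locus_m if (ambiguous and locus_m in winners) else winners[0]
    flank = [l for l in loci if l != mid]
    return ThreePointOrder(
        order=(flank[0], mid, flank[1]),
        double_recombinants=best,
        ambiguous=ambiguous,
        counts=counts,
    )


def cosegregation(
    table: RILTable, locus: str, phenotype_genotypes: pd.Series
) -> tuple[int, int]:
    """(n_match, n_scored) between a marker column and a per-line A/B
    assignment obtained from phenotyping (e.g. progeny testing)."""
    a = table.column(locus)
    b = phenotype_genotypes.reindex(a.index)
    both = a.notna() & b.notna()
    n_scored = int(both.sum())
    if n_scored == 0:
        raise ValueError(
            f"no lines scored for both {locus!r} and the phenotype assignment"
        )
    return int((a[both] == b[both]).sum()), n_scored
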