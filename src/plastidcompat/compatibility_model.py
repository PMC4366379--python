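"""Primary/secondary determinant model of plastid-nuclear compatibility.

The model abstracts two independent molecular features ("determinants") of
the plastid-encoded accD product, each of which must be matched by a fitted
"binding site" on a nuclear-encoded partner in the acetyl-CoA carboxylase
complex.  Each accession carries four boolean flags:

* ``cyt_primary``   - the accD product carries the primary determinant
  (the feature set exclusive to the incompatible cytoplasms);
* ``cyt_secondary`` - the accD product carries the secondary determinant
  (tandem duplication of the ISDTND hexapeptide; equivalently a short
  poly-E run);
* ``nuc_bind_primary`` / ``nuc_bind_secondary`` - the nuclear genome
  encodes a binding site fitted to the respective determinant.

A cross "cytoplasm donor x nuclear donor" is scored by a strict rule order:
the primary determinant, when present, decides alone (it masks the
secondary); otherwise the secondary determinant decides; a cytoplasm with
neither determinant is compatible with everything, except that a *vacant*
secondary binding site in the nuclear partner gives partial compatibility
(reduced pollen fertility rather than lethality).

Besides forward prediction, the module infers determinant states from
observed cross outcomes by complete constraint search over the 16 flag
combinations per accession, reporting which flags are identifiable (fixed
across all consistent assignments) and which are free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

OUTCOMES = ("compatible", "partial", "incompatible")
FLAGS = ("cyt_primary", "cyt_secondary", "nuc_bind_primary", "nuc_bind_secondary")


@dataclass(frozen=True)
class DeterminantGenotype:
    accession: str
    cyt_primary: bool | None
    cyt_secondary: bool | None
    nuc_bind_primary: bool | None
    nuc_bind_secondary: bool | None

    @property
    def flags(self) -> tuple[bool | None, ...]:
        return (self.cyt_primary, self.cyt_secondary,
                self.nuc_bind_primary, self.nuc_bind_secondary)

    @property
    def resolved(self) -> bool:
        return all(f is not None for f in self.flags)


@dataclass(frozen=True)
class CrossOutcome:
    """A directed cross: the cytoplasm donor is the maternal parent,
    written first in 'A x B'."""

    cytoplasm_donor: str
    nuclear_donor: str
    outcome: str

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def predict_cross(cyt: DeterminantGenotype, nuc: DeterminantGenotype) -> str:
    """Outcome of cytoplasm-of-``cyt`` x nucleus-of-``nuc``.

    Rule order: (1) primary determinant present -> compatible iff the
    nuclear partner has the primary binding site; (2) else secondary
    determinant present -> compatible iff the secondary binding site is
    there; (3) else no determinant -> partial if the nuclear partner
    carries a vacant secondary binding site, compatible otherwise.
    """
    if not cyt.resolved or not nuc.resolved:
        unknown = [f for g in (cyt, nuc) for f in FLAGS
                   if getattr(g, f) is None]
        raise ValueError(
            f"predict_cross requires resolved flags; unknown: {unknown}"
        )
    if cyt.cyt_primary:
        return "compatible" if nuc.nuc_bind_primary else "incompatible"
    if cyt.cyt_secondary:
        return "compatible" if nuc.nuc_bind_secondary else "incompatible"
    return "partial" if nuc.nuc_bind_secondary else "compatible"


def forward_panel(genotypes: Sequence[DeterminantGenotype]) -> list[CrossOutcome]:
    """Deterministic closure of predict_cross over all ordered pairs,
    including selfs (which are always compatible)."""
    byacc = {g.accession: g for g in genotypes}
    return [
        CrossOutcome(a, b, predict_cross(byacc[a], byacc[b]))
        for a in byacc for b in byacc
    ]


# ---------------------------------------------------------------------------
# deriving cytoplasm flags from protein features


def cytoplasm_genotype_from_features(
    table,  # VariablePositionTable for the accD alignment
    accession: str,
    primary_rows=None,
    secondary_predicate: str = "isdtnd_duplication",
    protein_seq: str | None = None,
    duplication_region: tuple[int, int] = (124, 135),
    max_poly_e: int = 3,
) -> tuple[bool, bool]:
    """(cyt_primary, cyt_secondary) from an accession's accD profile.

    ``cyt_primary`` is true iff the accession carries *all* curated
    primary-marker rows (by default the rows exclusive to the incompatible
    cytoplasms, i.e. the boldfaced set).  ``cyt_secondary`` is true iff the
    ISDTND hexapeptide is tandemly duplicated over ``duplication_region``
    of the alignment — operationally, the accession does not carry a
    deletion covering the second copy.  The alternative predicate
    ``"poly_e"`` instead requires the poly-E run of the protein to be at
    most ``max_poly_e`` residues (the short-stretch state).
    """
    from .protein_analysis import poly_run

    lo, hi = duplication_region
    if table.alignment_length < hi:
        raise ValueError(
            f"profile does not cover alignment region {lo}-{hi} "
            f"(length {table.alignment_length})"
        )
    if primary_rows is None:
        primary_rows = [r for r in table.rows
                        if set(r.occurrence) == {"VIR320", "L100"}]
    carried = {(r.start, r.end, r.kind, r.alt_residues)
               for r in table.rows if accession in r.occurrence}
    primary = all(
        (r.start, r.end, r.kind, r.alt_residues) in carried for r in primary_rows
    ) and bool(primary_rows)

    if secondary_predicate == "isdtnd_duplication":
        secondary = not any(
            r.kind in ("deletion", "absence")
            and accession in r.occurrence
            and r.start >= lo and r.end <= hi
            for r in table.rows
        )
    elif secondary_predicate == "poly_e":
        if protein_seq is None:
            raise ValueError("poly_e predicate requires the protein sequence")
        secondary = poly_run(protein_seq, "E").length <= max_poly_e
    else:
        raise ValueError(f"unknown secondary predicate {secondary_predicate!r}")
    return primary, secondary


# ---------------------------------------------------------------------------
# inference


@dataclass
class InferenceResult:
    accessions: list[str]
    solutions: list[dict[str, tuple[bool, bool, bool, bool]]]
    consistent: bool
    conflict_core: list[CrossOutcome] | None = None

    def identifiable(self) -> dict[str, dict[str, bool | None]]:
        """Per accession, per flag: the fixed value if identical across all
        solutions, else None (free)."""
        out: dict[str, dict[str, bool | None]] = {}
        for acc in self.accessions:
            out[acc] = {}
            for i, f in enumerate(FLAGS):
                vals = {sol[acc][i] for sol in self.solutions}
                out[acc][f] = vals.pop() if len(vals) == 1 else None
        return out

    def contains(self, assignment: dict[str, tuple[bool, bool, bool, bool]]) -> bool:
        return any(sol == assignment for sol in self.solutions)


_STATES = list(product([False, True], repeat=4))


def infer_states(
    outcomes: Iterable[CrossOutcome],
    accessions: Sequence[str] | None = None,
    find_core: bool = True,
) -> InferenceResult:
    """All determinant-state assignments consistent with observed crosses.

    Complete backtracking search over the 16 flag combinations per
    accession; a partial assignment is pruned as soon as any outcome among
    already-assigned accessions is contradicted, so the search visits
    exactly the consistent subtree plus its frontier.  With no outcomes the
    (empty) assignment is vacuously consistent.
    """
    outcomes = list(outcomes)
    if accessions is None:
        seen: list[str] = []
        for o in outcomes:
            for acc in (o.cytoplasm_donor, o.nuclear_donor):
                if acc not in seen:
                    seen.append(acc)
        accessions = seen
    accessions = list(accessions)
    by_pair: dict[tuple[str, str], str] = {}
    conflict = False
    for o in outcomes:
        key = (o.cytoplasm_donor, o.nuclear_donor)
        if by_pair.get(key, o.outcome) != o.outcome:
            conflict = True
        by_pair[key] = o.outcome
    if conflict:
        core = _conflict_core(outcomes, accessions) if find_core else None
        return InferenceResult(accessions, [], False, conflict_core=core)

    solutions: list[dict] = []
    assignment: dict[str, tuple] = {}

    def geno(acc):
        return DeterminantGenotype(acc, *assignment[acc])

    def consistent_with(acc) -> bool:
        for (c, n), obs in by_pair.items():
            if acc in (c, n) and c in assignment and n in assignment:
                if predict_cross(geno(c), geno(n)) != obs:
                    return False
        return True

    def backtrack(i: int) -> None:
        if i == len(accessions):
            solutions.append(dict(assignment))
            return
        acc = accessions[i]
        for state in _STATES:
            assignment[acc] = state
            if consistent_with(acc):
                backtrack(i + 1)
        del assignment[acc]

    backtrack(0)
    if solutions:
        return InferenceResult(accessions, solutions, True)
    core = _conflict_core(outcomes, accessions) if find_core else None
    return InferenceResult(accessions, [], False, conflict_core=core)


def _has_solution(outcomes: list[CrossOutcome], accessions: list[str]) -> bool:
    return infer_states(outcomes, accessions, find_core=False).consistent


def _conflict_core(outcomes: list[CrossOutcome],
                   accessions: list[str]) -> list[CrossOutcome]:
    """A minimal subset of outcomes that is still unsatisfiable
    (greedy deletion; minimal, not necessarily minimum)."""
    core = list(outcomes)
    i = 0
    while i < len(core):
        trial = core[:i] + core[i + 1:]
        if not _has_solution(trial, accessions):
            core = trial
        else:
            i += 1
    return core


# ---------------------------------------------------------------------------
# TSV interchange


def read_genotype_tsv(path: str | Path) -> list[DeterminantGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        vals = [None if r[f] == "?" else bool(int(r[f])) for f in FLAGS]
        out.append(DeterminantGenotype(r["accession"], *vals))
    return out


def write_genotype_tsv(genotypes: Sequence[DeterminantGenotype],
                       path: str | Path) -> None:
    rows = []
    for g in genotypes:
        row = {"accession": g.accession}
        for f in FLAGS:
            v = getattr(g, f)
            row[f] = "?" if v is None else str(int(v))
        rows.append(row)
    pd.DataFrame(rows, columns=["accession", *FLAGS]).to_csv(
        path, sep="\t", index=False)


def read_cross_tsv(path: str | Path) -> list[CrossOutcome]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [CrossOutcome(r["cytoplasm_donor"], r["nuclear_donor"], r["outcome"])
            for _, r in df.iterrows()]


def write_cross_tsv(outcomes: Sequence[CrossOutcome], path: str | Path) -> None:
    pd.DataFrame(
        [{"cytoplasm_donor": o.cytoplasm_donor, "nuclear_donor": o.nuclear_donor,
          "outcome": o.outcome} for o in outcomes],
        columns=["cytoplasm_donor", "nuclear_donor", "outcome"],
    ).to_csv(path, sep="\t", index=False)
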