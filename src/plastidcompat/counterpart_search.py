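"""Nuclear counterparts of plastid candidate loci via complex membership.

A plastid-encoded candidate subunit is only a plausible incompatibility
gene if a nuclear-encoded partner from the same multi-subunit complex maps
to the chromosome region genetically implicated in the conflict.  This
module provides (a) a curated lookup of the complexes and nuclear partner
subunits for each plastid candidate locus, and (b) a filter over an
annotated gene-interval table (the syntenic Medicago truncatula region)
that counts genes, counts "hypothetical protein" entries, and pulls out the
genes whose product description matches the partner keywords.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml


@dataclass(frozen=True)
class PartnerEntry:
    locus: str
    complex_name: str
    partners: tuple[str, ...]
    keywords: tuple[str, ...]


def load_partner_table(path: str | Path | None = None) -> dict[str, PartnerEntry]:
    """The curated plastid-locus -> nuclear-partner lookup.

    Shipped as a static YAML asset; an empty partner list is a valid entry
    (a locus whose nuclear counterparts are unknown).
    """
    if path is None:
        ref = resources.files("plastidcompat") / "data" / "complex_partners.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {}
    for locus, entry in raw.items():
        table[locus] = PartnerEntry(
            locus=locus,
            complex_name=entry.get("complex", ""),
            partners=tuple(entry.get("partners", []) or []),
            keywords=tuple(entry.get("keywords", []) or []),
        )
    return table


def complex_partners(
    locus: str, table: dict[str, PartnerEntry] | None = None
) -> PartnerEntry:
    """Curated partner descriptors for one plastid locus (verbatim lookup)."""
    if table is None:
        table = load_partner_table()
    if locus not in table:
        raise KeyError(f"no complex-partner entry for locus {locus!r}")
    return table[locus]


# ---------------------------------------------------------------------------
# gene-interval table

GENE_COLUMNS = ["gene_id", "description", "chrom", "start", "end"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.sort_values("start").reset_index(drop=True)


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class IntervalResult:
    hits: pd.DataFrame
    n_genes: int
    n_hypothetical: int


def interval_filter(
    table: pd.DataFrame,
    interval: tuple[int, int],
    keywords: list[str],
) -> IntervalResult:
    """Filter a gene-interval table for candidate nuclear counterparts.

    ``n_genes`` counts records whose span lies within the interval,
    ``n_hypothetical`` those whose description contains the literal
    substring "hypothetical protein", and ``hits`` the records matching any
    keyword (case-insensitive substring), re-sorted by start.
    """
    lo, hi = interval
    if hi < lo:
        raise ValueError(f"inverted interval ({lo}, {hi})")
    sub = table[(table["start"] >= lo) & (table["end"] <= hi)]
    sub = sub.sort_values("start").reset_index(drop=True)
    desc = sub["description"].str.lower()
    n_hyp = int(desc.str.contains("hypothetical protein", regex=False).sum())
    if keywords:
        mask = pd.Series(False, index=sub.index)
        for kw in keywords:
            mask |= desc.str.contains(kw.lower(), regex=False)
        hits = sub[mask].reset_index(drop=True)
    else:
        hits = sub.iloc[0:0]
    return IntervalResult(hits=hits, n_genes=len(sub), n_hypothetical=n_hyp)
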