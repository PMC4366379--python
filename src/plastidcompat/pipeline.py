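"""End-to-end orchestration: screen -> proteins -> counterparts -> linkage
-> compatibility, with per-stage TSV outputs and a Markdown summary.

Every stage is a thin wrapper over the corresponding analysis module; the
pipeline exists so a whole run is reproducible from one config + seed
(outputs are byte-identical across reruns).  Stages can be toggled off
individually.  Inputs default to the shipped study fixtures and the
seeded synthetic genome panel, and can be overridden with file paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, fixtures
from .compatibility_model import (
    cytoplasm_genotype_from_features,
    forward_panel,
    infer_states,
    predict_cross,
)
from .counterpart_search import complex_partners, interval_filter, load_partner_table
from .linkage import RILTable, cosegregation, order_three, recombinant_count
from .protein_analysis import (
    column_to_residue,
    deletion_sizes,
    exclusive_differences,
    n_replaced_residues,
    poly_run,
    scan_zinc_finger,
    span_contains,
    ungap,
    variable_position_table,
    write_variable_table,
)
from .synthetic_data import default_screen_config, gen_genome_panel
from .variant_screen import (
    PresenceMatrix,
    align_and_call,
    funnel_counts,
    nominate_loci,
    pattern_filter,
    read_variant_tsv,
    write_variant_tsv,
)


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    out_dir: str = "plastidcompat_run"
    seed: int = 0
    screen: bool = True
    proteins: bool = True
    counterparts: bool = True
    linkage: bool = True
    compat: bool = True
    variants_tsv: str | None = None  # pre-computed difference list (skips calling)
    ril_tsv: str | None = None
    scs1_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the target directory is not analysis input
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Key numbers computed by a pipeline run, stage by stage."""

    funnel: dict = field(default_factory=dict)
    candidates: pd.DataFrame | None = None
    proteins: dict = field(default_factory=dict)
    counterparts: dict = field(default_factory=dict)
    linkage: dict = field(default_factory=dict)
    compat: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    log: list[str] = [
        f"plastidcompat {__version__}",
        f"seed {config.seed}",
        f"config {config.digest()}",
    ]
    sections: list[str] = ["# plastidcompat run summary\n"]

    if config.screen:
        _stage_screen(config, out, report, sections)
        log.append("stage screen: ok")
    if config.proteins:
        _stage_proteins(out, report, sections)
        log.append("stage proteins: ok")
    if config.counterparts:
        _stage_counterparts(out, report, sections)
        log.append("stage counterparts: ok")
    if config.linkage:
        _stage_linkage(config, out, report, sections)
        log.append("stage linkage: ok")
    if config.compat:
        _stage_compat(out, report, sections)
        log.append("stage compat: ok")

    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / "summary.md").write_text("\n".join(sections) + "\n")
    return report


# ---------------------------------------------------------------------------


def screen_matrix(config: RunConfig) -> PresenceMatrix:
    """The presence/absence matrix for the screen stage: read from a
    provided difference list, or generated+called from the synthetic panel."""
    phenos = {
        "WL1238": "reference",
        "JI1794": "compatible_cytoplasm",
        "721": "compatible_cytoplasm",
        "L100": "incompatible_cytoplasm",
        "VIR320": "incompatible_cytoplasm",
    }
    if config.variants_tsv:
        return read_variant_tsv(config.variants_tsv, phenos)
    panel = gen_genome_panel(default_screen_config(), seed=config.seed)
    calls = {acc: align_and_call(panel.reference, q)
             for acc, q in panel.queries.items()}
    return PresenceMatrix.from_calls(calls, panel.truth.phenotype)


def _stage_screen(config, out, report, sections):
    matrix = screen_matrix(config)
    write_variant_tsv(matrix, out / "variants.tsv")
    filtered = pattern_filter(matrix)
    counts = funnel_counts(filtered)
    candidates = nominate_loci(filtered)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    report.funnel = counts
    report.candidates = candidates
    sections.append("## Variant screen\n")
    sections.append(
        f"{counts['n_pattern_variants']} pattern variants -> "
        f"{counts['n_pattern_variants'] - counts['n_noncoding']} coding -> "
        f"{counts['n_nonsynonymous_substitutions']} non-synonymous + "
        f"{counts['n_indels']} indels -> {len(candidates)} candidate loci\n"
    )
    sections.append("```\n" + candidates.to_string(index=False) + "\n```\n")


def _stage_proteins(out, report, sections):
    results = {}
    for name, aln, exclusive_target in [
        ("accD", fixtures.accd_alignment(), set(fixtures.INCOMPATIBLE)),
        ("Bccp3", fixtures.bccp3_alignment(), set(fixtures.INCOMPATIBLE)),
    ]:
        table = variable_position_table(aln, fixtures.REFERENCE)
        write_variable_table(table, out / f"{name}_variable_positions.tsv",
                             exclusive_target=exclusive_target)
        others = set(aln.ids) - {fixtures.REFERENCE} - exclusive_target
        excl = exclusive_differences(table, exclusive_target, others)
        results[name] = {
            "alignment_length": table.alignment_length,
            "n_variable_positions": table.n_variable_positions,
            "n_indel_columns": table.n_indel_columns,
            "n_exclusive_replaced_residues": n_replaced_residues(excl),
            "exclusive_deletion_sizes": deletion_sizes(excl),
        }
    accd = fixtures.accd_alignment()
    results["isdtnd_copies"] = {
        acc: fixtures.isdtnd_copies(accd, acc) for acc in accd.ids
    }
    results["poly_e"] = {
        acc: poly_run(ungap(accd.row(acc)), "E").length for acc in accd.ids
    }
    wl_row = accd.row(fixtures.REFERENCE)
    wl = ungap(wl_row)
    zf = scan_zinc_finger(wl)
    results["zinc_finger_spans"] = zf
    residue_240 = column_to_residue(wl_row, 240)  # the E>R column
    results["zinc_finger_contains_240"] = any(
        span_contains(s, residue_240 - 1) for s in zf
    )
    report.proteins = results
    sections.append("## Protein analysis\n")
    for name in ("accD", "Bccp3"):
        r = results[name]
        sections.append(
            f"{name}: {r['n_variable_positions']} variable positions, "
            f"{r['n_indel_columns']} indel columns over "
            f"{r['alignment_length']} alignment columns; exclusive to "
            f"incompatible cytoplasms: {r['n_exclusive_replaced_residues']} "
            f"replaced residues, deletions {r['exclusive_deletion_sizes']}\n"
        )


def _stage_counterparts(out, report, sections):
    table = fixtures.medicago_interval_table()
    table.to_csv(out / "medicago_interval_synthetic.tsv", sep="\t", index=False)
    partners = load_partner_table()
    accd_entry = complex_partners("accD", partners)
    res = interval_filter(table, fixtures.MEDICAGO_INTERVAL,
                          list(accd_entry.keywords))
    res.hits.to_csv(out / "counterpart_hits.tsv", sep="\t", index=False)
    report.counterparts = {
        "n_genes": res.n_genes,
        "n_hypothetical": res.n_hypothetical,
        "n_hits": len(res.hits),
        "bccp3_hit": fixtures.BCCP3_GENE_ID in set(res.hits["gene_id"]),
        "partners": {k: list(v.partners) for k, v in partners.items()},
    }
    sections.append("## Nuclear counterparts\n")
    sections.append(
        f"Syntenic interval: {res.n_genes} genes, {res.n_hypothetical} "
        f"hypothetical proteins, {len(res.hits)} ACCase-partner hits\n"
    )


def _stage_linkage(config, out, report, sections):
    if config.ril_tsv:
        table = RILTable.read_tsv(config.ril_tsv)
        scs1 = (pd.read_csv(config.scs1_tsv, sep="\t", index_col=0, dtype=str)
                .iloc[:, 0] if config.scs1_tsv else None)
    else:
        table, scs1 = fixtures.paper_ril_table()
    a, m, b = table.loci[:3]
    pairs = {
        f"{a}-{b}": recombinant_count(table, a, b),
        f"{m}-{a}": recombinant_count(table, m, a),
        f"{m}-{b}": recombinant_count(table, m, b),
    }
    order = order_three(table, a, m, b)
    res = {
        "n_lines": len(table.lines),
        "recombinants": {k: v.n_recombinant for k, v in pairs.items()},
        "cM": {k: round(v.cM, 2) for k, v in pairs.items()},
        "order": order.order,
        "order_ambiguous": order.ambiguous,
        "double_recombinants": order.double_recombinants,
    }
    if scs1 is not None:
        res["cosegregation"] = cosegregation(table, m, scs1)
    report.linkage = res
    pd.DataFrame(
        [{"pair": k, "n_recombinant": v.n_recombinant, "n_scored": v.n_scored,
          "R": v.R, "r": v.r, "cM": v.cM} for k, v in pairs.items()]
    ).to_csv(out / "linkage.tsv", sep="\t", index=False)
    sections.append("## Linkage\n")
    sections.append(
        f"Order {' - '.join(order.order)} with {order.double_recombinants} "
        f"double recombinants; recombinant counts {res['recombinants']}"
        + (f"; cosegregation {res['cosegregation'][0]}/"
           f"{res['cosegregation'][1]}" if scs1 is not None else "")
        + "\n"
    )


def _stage_compat(out, report, sections):
    table1 = fixtures.load_table1()
    cyt_flags = {
        acc: cytoplasm_genotype_from_features(table1, acc)
        for acc in fixtures.ACCESSIONS
    }
    observed = fixtures.paper_example_crosses(include_selfs=True)
    inference = infer_states(observed)
    panel = {g.accession: g for g in fixtures.paper_determinant_panel()}
    predictions = forward_panel(list(panel.values()))
    obs_map = {(o.cytoplasm_donor, o.nuclear_donor): o.outcome for o in observed}
    n_checked = n_correct = 0
    for p in predictions:
        key = (p.cytoplasm_donor, p.nuclear_donor)
        if key in obs_map:
            n_checked += 1
            n_correct += p.outcome == obs_map[key]
    from .compatibility_model import write_cross_tsv, write_genotype_tsv

    write_genotype_tsv(list(panel.values()), out / "determinant_genotypes.tsv")
    write_cross_tsv(predictions, out / "predicted_crosses.tsv")
    report.compat = {
        "cytoplasm_flags": cyt_flags,
        "n_observed": n_checked,
        "n_correct": n_correct,
        "n_solutions": len(inference.solutions),
        "identifiable": inference.identifiable(),
    }
    sections.append("## Compatibility model\n")
    sections.append(
        f"Rule engine reproduces {n_correct}/{n_checked} observed crosses; "
        f"{len(inference.solutions)} determinant-state assignments are "
        f"consistent with the observations\n"
    )
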