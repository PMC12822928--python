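"""Per-individual and per-site summaries of validated dietary PSMs.

Produces the per-individual table (identified proteins, PSM count, unique
peptides, taxa), per-site totals, and tidy per-individual / per-taxon-group
PSM counts suitable for stacked-bar and pie-chart rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .psm_io import PsmRecord, ReferenceSets
from .taxonomy import TaxonAssignment


@dataclass
class IndividualSummary:
    individual_id: str
    site: str
    subsite: str
    proteins: list[str] = field(default_factory=list)
    psm_count: int = 0
    unique_peptides: int = 0
    taxa: list[str] = field(default_factory=list)


@dataclass
class SiteSummary:
    site: str
    total_psms: int = 0
    per_individual: dict[str, dict[str, int]] = field(default_factory=dict)
    per_taxon_group: dict[str, int] = field(default_factory=dict)


def _stable_dedup(items: list[str]) -> list[str]:
    return list(dict.fromkeys(items))


def summarize_individual(
    individual_id: str,
    psms: list[PsmRecord],
    assignments: dict[str, TaxonAssignment],
    refsets: ReferenceSets,
    site: str = "",
    subsite: str = "",
) -> IndividualSummary:
    """Aggregate one individual's validated dietary PSMs.

    Unique peptides are distinct (sequence, modification set) pairs;
    proteins and taxa are deduplicated order-stably. Every PSM must carry a
    taxonomic assignment for its peptide.
    """
    if psms:
        site = site or psms[0].site
        subsite = subsite or psms[0].subsite
    missing = [p.peptide for p in psms if p.peptide not in assignments]
    if missing:
        raise ValueError(f"PSMs without taxonomic assignment: {sorted(set(missing))}")
    return IndividualSummary(
        individual_id=individual_id,
        site=site,
        subsite=subsite,
        proteins=_stable_dedup([refsets.protein_name(p.primary_accession) for p in psms]),
        psm_count=len(psms),
        unique_peptides=len({p.peptidoform for p in psms}),
        taxa=_stable_dedup([assignments[p.peptide].label for p in psms]),
    )


def summarize_site(
    site: str,
    psms: list[PsmRecord],
    assignments: dict[str, TaxonAssignment],
    refsets: ReferenceSets,
    merge_map: dict[str, str] | None = None,
) -> SiteSummary:
    """Site-level totals, per-individual protein counts, per-taxon-group counts.

    Each PSM is counted exactly once in per_taxon_group, under its
    assignment label collapsed through merge_map when provided.
    """
    summary = SiteSummary(site=site)
    for p in psms:
        if p.site != site:
            continue
        summary.total_psms += 1
        per_protein = summary.per_individual.setdefault(p.individual_id, {})
        name = refsets.protein_name(p.primary_accession)
        per_protein[name] = per_protein.get(name, 0) + 1
        label = assignments[p.peptide].label
        if merge_map:
            label = merge_map.get(label, label)
        summary.per_taxon_group[label] = summary.per_taxon_group.get(label, 0) + 1
    return summary


def write_individual_table(
    summaries: list[IndividualSummary], path: str | Path
) -> None:
    """Write the per-individual table; empty cells render as an en dash."""
    lines = ["\t".join([
        "individual_id", "site", "subsite", "identified_proteins",
        "psm_count", "unique_peptides", "taxa_identified",
    ])]
    for s in summaries:
        lines.append("\t".join([
            s.individual_id, s.site, s.subsite,
            ", ".join(s.proteins) if s.proteins else "–",
            str(s.psm_count), str(s.unique_peptides),
            ", ".join(s.taxa) if s.taxa else "–",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_site_summary(summaries: list[SiteSummary], path: str | Path) -> None:
    payload = {
        s.site: {
            "total_psms": s.total_psms,
            "per_individual": s.per_individual,
            "per_taxon_group": s.per_taxon_group,
        }
        for s in summaries
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_tidy_counts(
    summaries: list[SiteSummary], per_individual_path: str | Path,
    per_taxon_path: str | Path,
) -> None:
    """Tidy TSVs backing the stacked-bar (per individual) and pie (per taxon) views."""
    lines = ["site\tindividual_id\tprotein\tpsm_count"]
    for s in summaries:
        for individual, per_protein in sorted(s.per_individual.items()):
            for protein, n in sorted(per_protein.items()):
                lines.append(f"{s.site}\t{individual}\t{protein}\t{n}")
    Path(per_individual_path).write_text("\n".join(lines) + "\n")

    lines = ["site\ttaxon_group\tpsm_count"]
    for s in summaries:
        for label, n in sorted(s.per_taxon_group.items()):
            lines.append(f"{s.site}\t{label}\t{n}")
    Path(per_taxon_path).write_text("\n".join(lines) + "\n")
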