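"""Deamidation-aware taxonomic assignment of dietary milk peptides.

Peptides are matched as exact substrings of the dietary protein database
under I/L equivalence (the two residues are mass-identical in MS). In
deamidation-aware mode an observed D may additionally align to a database
N, and an observed E to a database Q — never the reverse — with every such
position recorded. This captures the classic ambiguity of the BLG peptide
TPEVDDEALEK, which reads either as an unmodified bovine sequence or as a
deamidated sheep sequence (N at position 6), and is reported as the
alternation label "Bovinae/Ovis".

Match sets are collapsed to a reported label: a single taxon (rolled up to
its reporting rank), an alternation when the split hinges on deamidation
assumptions, the lowest common ancestor otherwise, or "unspecific" when the
LCA sits at or above the ceiling rank (Mammalia). Bacterial homolog hits
are dropped (exclusion list) or counted as the mapped milk protein without
contributing taxon evidence (reassignment rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .psm_io import ConfigurationError, ReferenceSets, TaxonomyTree


@dataclass(frozen=True)
class PeptideMatch:
    peptide: str
    accession: str
    taxon: str | None
    start: int  # 1-based offset in the protein sequence
    deamidation_positions: frozenset[int] = frozenset()
    il_positions: frozenset[int] = frozenset()
    reassigned_to: str | None = None


@dataclass
class TaxonAssignment:
    peptide: str
    matches: list[PeptideMatch]
    label: str
    deamidation_dependent: bool


@dataclass
class ReportingConfig:
    """How matched taxa collapse into reported labels."""

    ceiling_rank_node: str = "Mammalia"
    rollup: dict[str, str] = field(default_factory=lambda: {"Bos": "Bovinae"})
    display_groups: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ReportingConfig":
        raw = yaml.safe_load(
            resources.files("calcproteo.data").joinpath("rules.yaml").read_text()
        )
        return cls(
            ceiling_rank_node=raw.get("ceiling_rank_node", "Mammalia"),
            rollup=dict(raw.get("rollup", {}) or {}),
            display_groups=dict(raw.get("display_groups", {}) or {}),
        )


def _positions_match(
    observed: str, database: str, deamidation_aware: bool
) -> tuple[bool, frozenset[int], frozenset[int]]:
    deam: set[int] = set()
    il: set[int] = set()
    for k, (o, d) in enumerate(zip(observed, database), start=1):
        if o == d:
            continue
        if {o, d} == {"I", "L"}:
            il.add(k)
            continue
        if deamidation_aware and ((o == "D" and d == "N") or (o == "E" and d == "Q")):
            deam.add(k)
            continue
        return False, frozenset(), frozenset()
    return True, frozenset(deam), frozenset(il)


def match_peptide(
    peptide: str, refsets: ReferenceSets, mode: str = "deamidation_aware"
) -> list[PeptideMatch]:
    """All occurrences of the peptide across the dietary database.

    strict: exact substring with I/L equivalence only; deamidation_aware
    additionally aligns observed D to database N and observed E to database
    Q, recording those positions.
    """
    if mode not in ("strict", "deamidation_aware"):
        raise ValueError(f"unknown mode {mode!r}")
    aware = mode == "deamidation_aware"
    matches: list[PeptideMatch] = []
    n = len(peptide)
    for acc, (_, seq, lineage) in sorted(refsets.dietary.items()):
        for start in range(len(seq) - n + 1):
            ok, deam, il = _positions_match(peptide, seq[start:start + n], aware)
            if ok:
                matches.append(PeptideMatch(
                    peptide=peptide, accession=acc, taxon=lineage[-1],
                    start=start + 1, deamidation_positions=deam, il_positions=il,
                ))
    return matches


def apply_reassignment_rules(
    matches: list[PeptideMatch], refsets: ReferenceSets
) -> list[PeptideMatch]:
    """Drop excluded-homolog hits; relabel reassigned hits, voiding their taxon."""
    out: list[PeptideMatch] = []
    dietary_names = {entry[0] for entry in refsets.dietary.values()}
    for m in matches:
        if m.accession in refsets.exclusion_accessions:
            continue
        if m.accession in refsets.reassignment_rules:
            target = refsets.reassignment_rules[m.accession]
            if target not in dietary_names:
                raise ConfigurationError(
                    f"reassignment target {target!r} absent from dietary database"
                )
            out.append(PeptideMatch(
                peptide=m.peptide, accession=m.accession, taxon=None,
                start=m.start, deamidation_positions=m.deamidation_positions,
                il_positions=m.il_positions, reassigned_to=target,
            ))
            continue
        out.append(m)
    return out


def _label_for_taxa(
    taxa: set[str], tree: TaxonomyTree, reporting: ReportingConfig
) -> str:
    if not taxa:
        return "unmatched"
    if len(taxa) == 1:
        taxon = next(iter(taxa))
        return reporting.rollup.get(taxon, taxon)
    lca = tree.lca(taxa)
    if tree.is_at_or_above(lca, reporting.ceiling_rank_node):
        return "unspecific"
    return reporting.rollup.get(lca, lca)


def assign_group(
    matches: list[PeptideMatch],
    tree: TaxonomyTree,
    reporting: ReportingConfig | None = None,
    merge_map: dict[str, str] | None = None,
) -> TaxonAssignment:
    """Collapse a peptide's matches into one reported taxon label.

    When dropping deamidation-assumed matches would change the label, the
    assignment is flagged deamidation-dependent and reported as an
    alternation "strict-side/deamidated-side" over the maximally specific
    alternatives. An optional merge_map collapses the final label into a
    display group.
    """
    reporting = reporting or ReportingConfig.default()
    peptide = matches[0].peptide if matches else ""
    taxa = {m.taxon for m in matches if m.taxon is not None}
    for t in taxa:
        if t not in tree.nodes:
            raise ValueError(f"taxon {t!r} absent from tree")
    strict_taxa = {
        m.taxon for m in matches
        if m.taxon is not None and not m.deamidation_positions
    }
    deam_only_taxa = taxa - strict_taxa

    label_all = _label_for_taxa(taxa, tree, reporting)
    label_strict = _label_for_taxa(strict_taxa, tree, reporting)
    if not taxa:
        label, dependent = "unmatched", False
    elif not deam_only_taxa:
        label, dependent = label_all, False
    elif not strict_taxa:
        # every match assumes deamidation: the identification itself depends on it
        label, dependent = label_all, True
    elif label_all == label_strict:
        label, dependent = label_all, False
    else:
        label_deam = _label_for_taxa(deam_only_taxa, tree, reporting)
        label, dependent = f"{label_strict}/{label_deam}", True

    if merge_map:
        label = merge_map.get(label, label)
    return TaxonAssignment(
        peptide=peptide, matches=matches, label=label, deamidation_dependent=dependent
    )


def assign_peptides(
    peptides: list[str],
    refsets: ReferenceSets,
    tree: TaxonomyTree,
    reporting: ReportingConfig | None = None,
    mode: str = "deamidation_aware",
) -> dict[str, TaxonAssignment]:
    """Match, apply homolog rules and group every distinct peptide."""
    reporting = reporting or ReportingConfig.default()
    out: dict[str, TaxonAssignment] = {}
    for peptide in dict.fromkeys(peptides):
        matches = apply_reassignment_rules(
            match_peptide(peptide, refsets, mode=mode), refsets
        )
        assignment = assign_group(matches, tree, reporting)
        if not assignment.peptide:
            assignment.peptide = peptide
        out[peptide] = assignment
    return out
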