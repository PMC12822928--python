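"""PSM/protein filtering and the target-decoy FDR quality gate.

Mirrors the post-search pre-processing applied to each calculus proteome:
an e-value cut-off, a minimum-PSM-per-protein support rule, and exclusion of
whole samples whose protein / peptide false discovery rates exceed the gate.

FDR is estimated as 100 * D / T over distinct units (primary accessions at
protein level, peptidoforms at peptide level); the min-PSM rule is applied
once, after the e-value rule, with no fixpoint iteration.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .psm_io import PipelineConfig, PsmRecord


@dataclass
class FilterReport:
    sample_id: str
    n_psm_in: int = 0
    n_psm_out: int = 0
    protein_fdr_pct: float = 0.0
    peptide_fdr_pct: float = 0.0
    passed_gate: bool = True
    removal_log: list[tuple[int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_psm_in": self.n_psm_in,
            "n_psm_out": self.n_psm_out,
            "protein_fdr_pct": self.protein_fdr_pct,
            "peptide_fdr_pct": self.peptide_fdr_pct,
            "passed_gate": self.passed_gate,
            "removal_log": [{"psm_index": i, "reason": r} for i, r in self.removal_log],
        }


def _distinct_units(psms: list[PsmRecord], level: str) -> tuple[int, int]:
    """(targets, decoys) counted over distinct units at the given level."""
    targets: set = set()
    decoys: set = set()
    for p in psms:
        key = p.primary_accession if level == "protein" else p.peptidoform
        (decoys if p.is_decoy else targets).add(key)
    return len(targets), len(decoys)


def compute_fdr(psms: list[PsmRecord], level: str) -> float:
    """Target-decoy FDR percentage, 100 * D / T over distinct units.

    Raises ValueError on empty input or when no target units exist.
    """
    if level not in ("protein", "peptide"):
        raise ValueError(f"level must be 'protein' or 'peptide', got {level!r}")
    if not psms:
        raise ValueError("cannot compute FDR of an empty PSM list")
    n_t, n_d = _distinct_units(psms, level)
    if n_t == 0:
        raise ValueError("no target units; FDR undefined")
    return 100.0 * n_d / n_t


def apply_filters(
    psms: list[PsmRecord], config: PipelineConfig
) -> tuple[list[PsmRecord], FilterReport]:
    """E-value filter, then single-pass min-PSM-per-protein support rule.

    Decoy PSMs survive both rules for FDR bookkeeping but are removed from
    the kept list. A surviving set with decoys and no targets gets infinite
    FDR so the quality gate fails it.
    """
    config.validate()
    sample_id = psms[0].sample_id if psms else ""
    report = FilterReport(sample_id=sample_id, n_psm_in=len(psms))
    if not psms:
        return [], report

    surviving: list[tuple[int, PsmRecord]] = []
    for i, p in enumerate(psms):
        if p.e_value <= config.e_value_max:
            surviving.append((i, p))
        else:
            report.removal_log.append((i, "e_value"))

    support = Counter(p.primary_accession for _, p in surviving)
    passing: list[tuple[int, PsmRecord]] = []
    for i, p in surviving:
        if support[p.primary_accession] >= config.min_psm_per_protein:
            passing.append((i, p))
        else:
            report.removal_log.append((i, "min_psm_per_protein"))

    fdr_set = [p for _, p in passing]
    if fdr_set:
        n_t_prot, n_d_prot = _distinct_units(fdr_set, "protein")
        n_t_pep, n_d_pep = _distinct_units(fdr_set, "peptide")
        report.protein_fdr_pct = 100.0 * n_d_prot / n_t_prot if n_t_prot else (
            math.inf if n_d_prot else 0.0
        )
        report.peptide_fdr_pct = 100.0 * n_d_pep / n_t_pep if n_t_pep else (
            math.inf if n_d_pep else 0.0
        )

    kept: list[PsmRecord] = []
    for i, p in passing:
        if p.is_decoy:
            report.removal_log.append((i, "decoy"))
        else:
            kept.append(p)
    report.n_psm_out = len(kept)
    report.passed_gate = qc_gate(report, config)
    return kept, report


def qc_gate(report: FilterReport, config: PipelineConfig) -> bool:
    """True iff both FDR percentages sit at or below their bounds (inclusive)."""
    return (
        report.protein_fdr_pct <= config.protein_fdr_max_pct
        and report.peptide_fdr_pct <= config.peptide_fdr_max_pct
    )
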