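"""Bulk deamidation analysis.

Spontaneous deamidation converts asparagine to aspartate (N2D, +0.984 Da)
and glutamine to glutamate (Q2E) and accumulates with protein age, so
ancient endogenous proteins should carry markedly higher deamidation rates
than modern laboratory or environmental contaminants. Rates are estimated
per unit (protein accession by default) by pooling residue instances over
all of its PSMs, and the contaminant group is compared with the
oral-plus-dietary group by a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .oral_auth import classify_psm
from .psm_io import PsmRecord, ReferenceSets

logger = logging.getLogger(__name__)

GROUP_OF_CATEGORY = {
    "common_contaminant": "contaminant",
    "lab_contaminant": "contaminant",
    "oral_microbiome": "oral_plus_dietary",
    "salivary": "oral_plus_dietary",
    "dietary": "oral_plus_dietary",
    # "other" is excluded from grouping
}


@dataclass
class DeamidationSummary:
    unit_id: str
    group: str
    n_sites_N: int = 0
    n_deam_N: int = 0
    n_sites_Q: int = 0
    n_deam_Q: int = 0

    @property
    def rate_N(self) -> float:
        return self.n_deam_N / self.n_sites_N if self.n_sites_N else 0.0

    @property
    def rate_Q(self) -> float:
        return self.n_deam_Q / self.n_sites_Q if self.n_sites_Q else 0.0

    @property
    def rate_total(self) -> float:
        sites = self.n_sites_N + self.n_sites_Q
        return (self.n_deam_N + self.n_deam_Q) / sites if sites else 0.0


def residue_observations(psm: PsmRecord) -> tuple[int, int, int, int]:
    """(N sites, deamidated N, Q sites, deamidated Q) in one PSM."""
    deam_positions = {pos for pos, name in psm.modifications if name == "Deamidated"}
    n_N = deam_N = n_Q = deam_Q = 0
    for i, residue in enumerate(psm.peptide, start=1):
        if residue == "N":
            n_N += 1
            deam_N += i in deam_positions
        elif residue == "Q":
            n_Q += 1
            deam_Q += i in deam_positions
    return n_N, deam_N, n_Q, deam_Q


def bulk_rates(
    psms: list[PsmRecord],
    refsets: ReferenceSets,
    unit: str = "protein",
) -> list[DeamidationSummary]:
    """Pool residue observations per unit; each PSM contributes once.

    unit="protein" keys on the primary accession; unit="sample" keys on
    (sample_id, group). Units with no N or Q sites are omitted (logged);
    PSMs whose accession matches no reference compilation are excluded.
    """
    if unit not in ("protein", "sample"):
        raise ValueError(f"unit must be 'protein' or 'sample', got {unit!r}")
    summaries: dict[tuple[str, str], DeamidationSummary] = {}
    for p in psms:
        category = classify_psm(p, refsets)
        group = GROUP_OF_CATEGORY.get(category)
        if group is None:
            continue
        unit_id = p.primary_accession if unit == "protein" else p.sample_id
        key = (unit_id, group)
        summary = summaries.setdefault(key, DeamidationSummary(unit_id, group))
        n_N, deam_N, n_Q, deam_Q = residue_observations(p)
        summary.n_sites_N += n_N
        summary.n_deam_N += deam_N
        summary.n_sites_Q += n_Q
        summary.n_deam_Q += deam_Q

    out: list[DeamidationSummary] = []
    for summary in summaries.values():
        if summary.n_sites_N + summary.n_sites_Q == 0:
            logger.info("unit %s has no N/Q sites; omitted", summary.unit_id)
            continue
        out.append(summary)
    return out


def compare_groups(
    summaries: list[DeamidationSummary],
) -> tuple[float, float, int, int]:
    """Two-sided Wilcoxon rank-sum on per-unit total deamidation rates.

    Returns (U statistic, p value, n contaminant, n oral_plus_dietary).
    Exact null when both groups have n <= 12 and the pooled rates carry no
    ties; normal approximation with tie correction otherwise.
    """
    contaminant = [s.rate_total for s in summaries if s.group == "contaminant"]
    endogenous = [s.rate_total for s in summaries if s.group == "oral_plus_dietary"]
    if not contaminant:
        raise ValueError("contaminant group is empty")
    if not endogenous:
        raise ValueError("oral_plus_dietary group is empty")
    pooled = contaminant + endogenous
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (len(contaminant) <= 12 and len(endogenous) <= 12 and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(
        contaminant, endogenous, alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue), len(contaminant), len(endogenous)
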