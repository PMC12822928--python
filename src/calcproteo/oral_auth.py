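"""Oral-signature authentication of calculus proteomes.

Each PSM is classified by its primary accession against the reference
compilations (oral microbiome, salivary, common contaminants, laboratory
contaminants, dietary). A sample's raw authenticity score is

    raw = oral PSMs / (oral + contaminant PSMs)

with oral = oral_microbiome + salivary and contaminant = common + lab;
dietary and unmatched PSMs enter neither side. Raw scores are min-max
normalized across the batch and a sample passes when its normalized score
reaches the (inclusive) threshold. When two proteomes of the same
individual both pass, their PSM sets are merged under a hyphenated sample
id and the whole batch is re-assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

from .psm_io import CATEGORY_PRECEDENCE, PipelineConfig, PsmRecord, ReferenceSets

logger = logging.getLogger(__name__)

CATEGORIES = [
    "oral_microbiome", "salivary", "common_contaminant", "lab_contaminant",
    "dietary", "other",
]

ORAL = ("oral_microbiome", "salivary")
CONTAMINANT = ("common_contaminant", "lab_contaminant")


@dataclass
class AuthResult:
    sample_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    raw_score: float = 0.0
    norm_score: float | None = None
    passed: bool | None = None


def classify_psm(psm: PsmRecord, refsets: ReferenceSets) -> str:
    """Category of a PSM by primary-accession membership, with precedence."""
    acc = psm.primary_accession
    for category in CATEGORY_PRECEDENCE:
        if category == "lab_contaminant" and acc in refsets.lab_contaminants:
            return "lab_contaminant"
        if category == "common_contaminant" and acc in refsets.common_contaminants:
            return "common_contaminant"
        if category == "oral_microbiome" and acc in refsets.oral_microbiome:
            return "oral_microbiome"
        if category == "salivary" and acc in refsets.salivary:
            return "salivary"
        if category == "dietary" and acc in refsets.dietary:
            return "dietary"
    return "other"


def score_sample(psms: list[PsmRecord], refsets: ReferenceSets) -> AuthResult:
    """Count categories and fill the raw oral-signature score for one sample."""
    sample_ids = {p.sample_id for p in psms}
    if len(sample_ids) > 1:
        raise ValueError(f"score_sample got mixed sample_ids: {sorted(sample_ids)}")
    result = AuthResult(sample_id=next(iter(sample_ids)) if sample_ids else "")
    for p in psms:
        result.counts[classify_psm(p, refsets)] += 1
    oral = sum(result.counts[c] for c in ORAL)
    contaminant = sum(result.counts[c] for c in CONTAMINANT)
    if oral + contaminant == 0:
        logger.warning(
            "sample %s: no oral or contaminant PSMs; raw score set to 0",
            result.sample_id,
        )
        result.raw_score = 0.0
    else:
        result.raw_score = oral / (oral + contaminant)
    return result


def normalize_batch(results: list[AuthResult]) -> list[AuthResult]:
    """Min-max normalize raw scores across the batch (degenerate batch -> 0.5)."""
    if not results:
        raise ValueError("cannot normalize an empty batch")
    raws = [r.raw_score for r in results]
    lo, hi = min(raws), max(raws)
    if hi == lo:
        logger.warning(
            "all %d raw scores equal (%.4f); normalized scores set to 0.5",
            len(results), lo,
        )
        for r in results:
            r.norm_score = 0.5
    else:
        for r in results:
            r.norm_score = (r.raw_score - lo) / (hi - lo)
    return results


def authenticate(results: list[AuthResult], config: PipelineConfig) -> list[AuthResult]:
    """Fill the pass flag: normalized score at or above the threshold passes."""
    for r in results:
        if r.norm_score is None:
            raise ValueError(f"sample {r.sample_id}: norm_score not set")
        r.passed = r.norm_score >= config.auth_threshold
    return results


def _merged_id(sample_ids: list[str]) -> str:
    if all(s.isdigit() for s in sample_ids):
        ordered = sorted(sample_ids, key=int)
    else:
        ordered = sorted(sample_ids)
    return "-".join(ordered)


def merge_replicates(
    psms_by_sample: dict[str, list[PsmRecord]],
    pass_map: dict[str, bool],
    individual_map: dict[str, str],
) -> dict[str, list[PsmRecord]]:
    """Merge the PSM sets of individuals with two or more passing proteomes.

    The merged sample id joins the constituent ids with "-"; constituents
    are replaced by the merge. Non-passing samples are left untouched.
    Downstream the batch is re-filtered, re-scored, re-normalized and
    re-thresholded.
    """
    by_individual: dict[str, list[str]] = {}
    for sid in psms_by_sample:
        if pass_map.get(sid):
            by_individual.setdefault(individual_map.get(sid, sid), []).append(sid)

    merged = dict(psms_by_sample)
    for individual, sids in by_individual.items():
        if len(sids) < 2:
            continue
        new_id = _merged_id(sids)
        combined: list[PsmRecord] = []
        for sid in sorted(sids, key=lambda s: (int(s) if s.isdigit() else 0, s)):
            combined.extend(
                _dc_replace(p, sample_id=new_id) for p in merged.pop(sid)
            )
        merged[new_id] = combined
        logger.info("merged samples %s of individual %s into %s", sids, individual, new_id)
    return merged
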