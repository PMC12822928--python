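"""End-to-end orchestration of the post-search inference chain.

Stage order: read -> per-sample filtering -> FDR quality gate ->
oral-signature authentication (score, min-max normalize, threshold) ->
replicate merging with re-filtering and re-authentication -> bulk
deamidation analysis with contaminant-vs-endogenous rank-sum tests ->
spectral validation of low-scoring dietary PSMs -> deamidation-aware
taxonomic assignment -> per-individual and per-site summaries.

Every input PSM ends a run as exactly one of kept or excluded-with-reason;
the manifest records config, input digests, per-stage counts and the seed,
and contains no timestamps so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .deamidation import bulk_rates, compare_groups
from .filtering import apply_filters
from .oral_auth import (
    AuthResult, authenticate, classify_psm, merge_replicates,
    normalize_batch, score_sample,
)
from .psm_io import (
    PipelineConfig, PsmRecord, ReferenceSets, Spectrum, TaxonomyTree,
    file_digest, load_reference_sets, read_mgf, read_psm_table,
    write_psm_table, format_modifications,
)
from .report import (
    summarize_individual, summarize_site, write_individual_table,
    write_site_summary, write_tidy_counts,
)
from .spectral import validate_dietary
from .taxonomy import ReportingConfig, assign_peptides

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    kept_psms: list[PsmRecord]
    auth_results: list[AuthResult]
    filter_reports: dict
    deamidation_summaries: list
    deamidation_tests: dict
    validation_results: list
    assignments: dict
    individual_summaries: list
    site_summaries: list
    manifest: dict


def _group_by_sample(psms: list[PsmRecord]) -> dict[str, list[PsmRecord]]:
    out: dict[str, list[PsmRecord]] = defaultdict(list)
    for p in psms:
        out[p.sample_id].append(p)
    return dict(out)


def run_pipeline_data(
    psms: list[PsmRecord],
    spectra: dict[str, Spectrum],
    refsets: ReferenceSets,
    tree: TaxonomyTree,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    input_digests: dict[str, str] | None = None,
    reporting: ReportingConfig | None = None,
    individuals_meta: list[tuple[str, str, str]] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write the output set."""
    config.validate()
    reporting = reporting or ReportingConfig.default()
    manifest: dict = {
        "version": __version__,
        "config": dict(config.__dict__),
        "inputs": input_digests or {},
        "seed": config.random_seed,
        "stages": {},
    }
    manifest["stages"]["input_psms"] = len(psms)

    # ---- per-sample filtering + FDR gate --------------------------------
    def filter_batch(by_sample):
        kept, reports, excluded = {}, {}, []
        for sid in sorted(by_sample):
            sample_kept, report = apply_filters(by_sample[sid], config)
            reports[sid] = report
            if report.passed_gate:
                kept[sid] = sample_kept
            else:
                excluded.append(sid)
                logger.info("sample %s excluded: FDR gate (protein %.2f%%, peptide %.2f%%)",
                            sid, report.protein_fdr_pct, report.peptide_fdr_pct)
        return kept, reports, excluded

    by_sample = _group_by_sample(psms)
    individual_map = {p.sample_id: p.individual_id for p in psms}
    kept_by_sample, reports, gate_excluded = filter_batch(by_sample)
    manifest["stages"]["samples_in"] = len(by_sample)
    manifest["stages"]["samples_failed_fdr_gate"] = sorted(gate_excluded)

    # ---- authentication -------------------------------------------------
    def authenticate_batch(kept):
        results = []
        for sid in sorted(kept):
            r = score_sample(kept[sid], refsets)
            if not r.sample_id:
                r.sample_id = sid
            results.append(r)
        if results:
            normalize_batch(results)
            authenticate(results, config)
        return results

    auth_results = authenticate_batch(kept_by_sample)
    pass_map = {r.sample_id: bool(r.passed) for r in auth_results}

    # ---- replicate merging + repeat -------------------------------------
    merged_raw = merge_replicates(
        {sid: by_sample[sid] for sid in kept_by_sample}, pass_map, individual_map
    )
    if set(merged_raw) != set(kept_by_sample):
        kept_by_sample, merged_reports, merged_excluded = filter_batch(merged_raw)
        reports.update(merged_reports)
        gate_excluded += merged_excluded
        auth_results = authenticate_batch(kept_by_sample)
        pass_map = {r.sample_id: bool(r.passed) for r in auth_results}
        individual_map.update({
            sid: merged_raw[sid][0].individual_id for sid in merged_raw if merged_raw[sid]
        })
    manifest["stages"]["samples_passed_auth"] = sorted(s for s, ok in pass_map.items() if ok)

    passed_psms = [p for sid, ok in pass_map.items() if ok for p in kept_by_sample[sid]]
    failed_psms = [p for sid, ok in pass_map.items() if not ok for p in kept_by_sample[sid]]
    manifest["stages"]["psms_after_filtering"] = sum(len(v) for v in kept_by_sample.values())
    manifest["stages"]["psms_in_passed_samples"] = len(passed_psms)

    # ---- deamidation ----------------------------------------------------
    deam_summaries = bulk_rates(passed_psms, refsets, unit="protein")
    deam_tests: dict = {}
    for subset, subset_psms in (("passed", passed_psms), ("failed", failed_psms)):
        summaries = bulk_rates(subset_psms, refsets, unit="protein")
        try:
            stat, p, n_c, n_e = compare_groups(summaries)
            deam_tests[subset] = {
                "statistic": stat, "p_value": p,
                "n_contaminant": n_c, "n_oral_dietary": n_e,
            }
        except ValueError as exc:
            deam_tests[subset] = {"skipped": str(exc)}

    # ---- spectral validation of dietary PSMs ----------------------------
    kept_dietary, validation_results = validate_dietary(
        passed_psms, spectra, refsets, config
    )
    non_dietary = [p for p in passed_psms if classify_psm(p, refsets) != "dietary"]
    kept_psms = non_dietary + kept_dietary
    manifest["stages"]["dietary_psms_validated"] = len(kept_dietary)
    manifest["stages"]["dietary_psms_excluded"] = (
        len(passed_psms) - len(non_dietary) - len(kept_dietary)
    )

    # ---- taxonomy -------------------------------------------------------
    assignments = assign_peptides(
        [p.peptide for p in kept_dietary], refsets, tree, reporting
    )

    # ---- summaries ------------------------------------------------------
    by_individual: dict[str, list[PsmRecord]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    for ind, site, subsite in individuals_meta or []:
        meta[ind] = (site, subsite)
    for p in psms:
        meta.setdefault(p.individual_id, (p.site, p.subsite))
    for p in kept_dietary:
        by_individual[p.individual_id].append(p)
    individual_summaries = [
        summarize_individual(
            ind, by_individual.get(ind, []), assignments, refsets,
            site=site, subsite=subsite,
        )
        for ind, (site, subsite) in sorted(meta.items())
    ]
    sites = sorted({p.site for p in kept_dietary})
    site_summaries = [
        summarize_site(site, kept_dietary, assignments, refsets,
                       merge_map=reporting.display_groups)
        for site in sites
    ]
    manifest["stages"]["individuals"] = len(individual_summaries)

    result = PipelineResult(
        kept_psms=kept_psms,
        auth_results=auth_results,
        filter_reports={sid: r.to_dict() for sid, r in sorted(reports.items())},
        deamidation_summaries=deam_summaries,
        deamidation_tests=deam_tests,
        validation_results=validation_results,
        assignments=assignments,
        individual_summaries=individual_summaries,
        site_summaries=site_summaries,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_psm_table(result.kept_psms, out / "kept_psms.tsv")

    lines = ["sample_id\toral_microbiome\tsalivary\tcommon_contaminant\t"
             "lab_contaminant\tdietary\tother\traw_score\tnorm_score\tpassed"]
    for r in result.auth_results:
        lines.append("\t".join([
            r.sample_id,
            *[str(r.counts[c]) for c in (
                "oral_microbiome", "salivary", "common_contaminant",
                "lab_contaminant", "dietary", "other")],
            f"{r.raw_score:.6f}",
            "" if r.norm_score is None else f"{r.norm_score:.6f}",
            str(r.passed),
        ]))
    (out / "authentication.tsv").write_text("\n".join(lines) + "\n")

    (out / "filter_reports.json").write_text(
        json.dumps(result.filter_reports, indent=2, sort_keys=True) + "\n")

    lines = ["unit_id\tgroup\tn_sites_N\tn_deam_N\tn_sites_Q\tn_deam_Q\t"
             "rate_N\trate_Q\trate_total"]
    for s in sorted(result.deamidation_summaries, key=lambda s: (s.group, s.unit_id)):
        lines.append(f"{s.unit_id}\t{s.group}\t{s.n_sites_N}\t{s.n_deam_N}\t"
                     f"{s.n_sites_Q}\t{s.n_deam_Q}\t{s.rate_N:.6f}\t"
                     f"{s.rate_Q:.6f}\t{s.rate_total:.6f}")
    (out / "deamidation.tsv").write_text("\n".join(lines) + "\n")
    (out / "deamidation_tests.json").write_text(
        json.dumps(result.deamidation_tests, indent=2, sort_keys=True) + "\n")

    lines = ["spectrum_ref\tpeptide\tion_score\tpearson\tcontrast_angle\t"
             "threshold_used\tvalidated\tn_matched\treason"]
    for v in result.validation_results:
        lines.append("\t".join([
            v.spectrum_ref, v.peptide, f"{v.ion_score:.2f}",
            "" if v.pearson is None else f"{v.pearson:.4f}",
            "" if v.contrast_angle is None else f"{v.contrast_angle:.4f}",
            f"{v.threshold_used:.2f}", str(v.validated), str(v.n_matched), v.reason,
        ]))
    (out / "validation.tsv").write_text("\n".join(lines) + "\n")

    lines = ["peptide\tlabel\tdeamidation_dependent\tmatched_accessions"]
    for peptide in sorted(result.assignments):
        a = result.assignments[peptide]
        accs = ";".join(sorted({m.accession for m in a.matches}))
        lines.append(f"{peptide}\t{a.label}\t{a.deamidation_dependent}\t{accs}")
    (out / "assignments.tsv").write_text("\n".join(lines) + "\n")

    write_individual_table(result.individual_summaries, out / "table1.tsv")
    write_site_summary(result.site_summaries, out / "site_summary.json")
    write_tidy_counts(result.site_summaries,
                      out / "psms_per_individual.tsv", out / "psms_per_taxon_group.tsv")
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    config_path: str | Path,
    psms_path: str | Path,
    out_dir: str | Path,
    mgf_path: str | Path | None = None,
    refs_dir: str | Path | None = None,
    dialect: str = "generic_tsv",
) -> PipelineResult:
    """File-based entry point; see run_pipeline_data for the stage order."""
    config = PipelineConfig.from_yaml(config_path)
    psms = read_psm_table(psms_path, dialect=dialect)
    spectra = read_mgf(mgf_path) if mgf_path else {}
    digests = {"psms": file_digest(psms_path), "config": file_digest(config_path)}
    if mgf_path:
        digests["mgf"] = file_digest(mgf_path)

    if refs_dir is not None:
        refs_dir = Path(refs_dir)
        refsets, tree = load_reference_sets(
            refs_dir / "dietary.fasta", refs_dir / "lists.yaml",
            refs_dir / "taxonomy.tsv",
        )
    else:
        from .synth import load_packaged_references
        refsets, tree = load_packaged_references()

    return run_pipeline_data(
        psms, spectra, refsets, tree, config,
        out_dir=out_dir, input_digests=digests,
    )
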