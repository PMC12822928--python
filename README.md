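# calcproteo

Post-search inference for ancient dental-calculus proteomics. Given the
PSM-level export of a database search over calculus proteomes (plus the MS2
spectra and reference accession compilations), the package answers the
questions a paleoproteomics study asks after the search engine has run:

1. **Filtering / quality gate** — e-value cut-off, minimum-PSM-per-protein
   support, and a target-decoy FDR gate per sample
   (FDR% = 100·D/T over distinct primary accessions or peptidoforms;
   samples with protein FDR > 5% or peptide FDR > 2% are excluded).
2. **Oral-signature authentication** — is a proteome endogenous calculus or
   burial/laboratory contamination? Each sample is scored
   `raw = oral / (oral + contaminant)` PSM counts, scores are min-max
   normalized across the batch, and a sample passes at ≥ 0.5. Replicate
   proteomes of one individual that both pass are merged (`220` + `221` →
   `220-221`) and the batch re-assessed.
3. **Deamidation damage assessment** — ancient proteins accumulate N→D
   (+0.984 Da) and Q→E deamidation; per-protein rates are compared between
   contaminants and oral+dietary proteins with a two-sided Wilcoxon
   rank-sum test, separately within passing and failing samples.
4. **Spectral validation** — dietary PSMs with ion score < 40 are checked by
   the Pearson correlation between observed and predicted b/y fragment
   intensities (threshold 0.70, relaxed to 0.60 for oxidized peptides),
   with the min-PSM support rule re-applied afterwards.
5. **Taxonomic assignment of milk peptides** — exact substring matching
   against a dietary protein database under I/L equivalence, optionally
   allowing observed D↔database N and E↔Q (deamidation-aware). Ambiguities
   that hinge on a deamidation assumption are reported as alternations:
   the BLG peptide `TPEVDDEALEK` reads as unmodified bovine *or*
   position-6-deamidated sheep sequence → label `Bovinae/Ovis`.
6. **Reporting** — per-individual tables (proteins, PSMs, unique peptides,
   taxa) and per-site totals / taxon-group breakdowns.

A synthetic-study generator (`calcproteo.synth`) produces complete studies
with known ground truth — category compositions, group-specific deamidation,
decoys, noisy spectra — plus a deterministic worked-example fixture.

## Worked example

The packaged fixture emulates the dietary component of a two-site Iron Age
calculus study (Bilsk and Mamai-Gora, Ukraine):

```python
from calcproteo.synth import make_worked_example, load_packaged_references, FIXTURE_INDIVIDUALS
from calcproteo.psm_io import PipelineConfig
from calcproteo.pipeline import run_pipeline_data

refs, tree = load_packaged_references()
res = run_pipeline_data(make_worked_example(), {}, refs, tree, PipelineConfig(),
                        individuals_meta=FIXTURE_INDIVIDUALS)
for s in res.individual_summaries:
    if s.psm_count:
        print(s.individual_id, s.site, s.psm_count, s.unique_peptides, s.taxa)
```

prints

```
143 Bilsk 18 11 ['Bovinae/Ovis', 'Bovinae', 'Bovidae', 'Ovis', 'Caprinae', 'Equus', 'unspecific']
151-152 Bilsk 2 2 ['Bovidae', 'Bovinae']
181-182 Bilsk 7 6 ['Bovinae/Ovis', 'Bovidae', 'Bovinae']
192 Mamai-Gora 2 2 ['Bovinae/Ovis', 'Bovinae']
203 Mamai-Gora 11 9 ['Bovinae/Ovis', 'Bovidae', 'unspecific', 'Bovinae']
220-221 Mamai-Gora 10 7 ['Bovinae/Ovis', 'Bovidae', 'Bovinae', 'Capra']
```

i.e. per-individual milk-protein PSM counts (18/2/7/2/11/10), unique
peptides, and taxon labels; the site totals are 27 (Bilsk) and 23
(Mamai-Gora), 50 milk PSMs in all. Horse milk (`Equus`, BLG-1) appears in
individual 143 only; the milk-fat-globule protein BTN1A1 only in 203.

## Command line

```bash
calcproteo simulate --seed 1 --out study/         # synthetic study
calcproteo run --config study/config.yaml --psms study/psms.tsv \
    --mgf study/spectra.mgf --refs study/refs --out out/
calcproteo fixture --out fx/                      # the worked example
```

Subcommands `filter`, `auth`, `deamidate`, `validate`, `assign`, `report`
expose the individual stages.

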