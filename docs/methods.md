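# Methods

This note records the models, defaults and design choices behind each stage,
and what the synthetic generator does and does not emulate.

## Filtering and FDR

A PSM survives when its e-value is at most `e_value_max` (default 0.01) and
its primary accession (the first listed; no protein inference is attempted)
is supported by at least `min_psm_per_protein` (default 2) PSMs that also
passed the e-value rule. The support rule is applied once, after the
e-value rule, with no fixpoint iteration: a protein that drops to one PSM
because its sibling was removed by the support rule itself is not revisited.
Single-pass application is deterministic and easy to reason about; iterating
to a fixpoint would only ever remove more PSMs.

FDR is estimated as 100·D/T over *distinct units* — primary accessions at
protein level, (peptide, modification set) pairs at peptide level — rather
than the 2D/(T+D) variant; the estimator is a documented choice since only
the thresholds themselves (5% protein, 2% peptide) are fixed by the
workflow being reproduced. Decoy PSMs survive both filter rules for FDR
bookkeeping and are then removed from the kept set. Gate bounds are
inclusive (≤), matching exclusion of samples *strictly above* threshold.
Degenerate cases: an empty sample yields an all-zero report that passes the
gate vacuously; a non-empty post-filter set with decoys but no targets gets
infinite FDR and fails.

## Oral-signature authentication

`raw = (oral_microbiome + salivary) / (oral + common_contaminant +
lab_contaminant)` PSM counts; dietary and unmatched PSMs sit in neither
numerator nor denominator (the score asks "of the proteins that indicate
provenance, how many point to the mouth?"). A zero denominator scores 0
with a warning. Raw scores are min-max normalized over the batch — defined
as all samples of one pipeline invocation, recomputed after replicate
merging — and the pass threshold (0.5) is inclusive. When every raw score
is equal, normalized scores are set to the midpoint 0.5 (passing, loudly
warned): a batch with no contrast carries no evidence against any sample,
and the choice keeps single-sample and fixture runs usable.

When an accession appears in several reference compilations the category
precedence is lab > common contaminant > oral microbiome > salivary >
dietary — contamination wins ties, which is the conservative direction for
authentication.

Replicate merging concatenates the already-extracted PSM lists of an
individual's passing proteomes under the hyphen-joined id and re-runs
filtering, scoring, normalization and thresholding on the updated batch.
(The original workflow re-ran the database search on merged raw data; no
search engine is in scope here, so merging operates on search output.)

## Deamidation

Rates are per residue *instance*: each PSM contributes every N and Q of its
peptide once, deamidated iff a `Deamidated` modification sits at that
position. The comparison unit is the protein (primary accession); pooled
N+Q rates (`rate_total`) feed a two-sided Wilcoxon rank-sum test of
contaminant vs oral+dietary proteins, run separately within passing and
failing samples. The exact null distribution is used when both groups have
n ≤ 12 and the pooled rates are tie-free; otherwise the normal
approximation with tie correction (scipy's `mannwhitneyu`). Sidedness is a
choice; two-sided is the conservative default.

## Spectral validation

Dietary PSMs with ion score ≥ 40 pass without spectral scoring. Below the
cutoff, the observed spectrum is stripped of peaks within ±1.0 m/z of the
precursor (configurable; 1.0 covers the isotope envelope at charge ≥ 2)
and compared with a predicted fragment spectrum. For each predicted ion the
observed intensity is the most intense peak within ±0.01 Da (the fragment
tolerance of the upstream search); the statistic thresholded is the Pearson
correlation over all predicted ions, on raw intensities. Predicted ions
falling inside the stripped precursor window are excluded from the
comparison — they cannot have a surviving observed partner, and for 2+
precursors the high-index doubly charged b/y ions land exactly there. The
normalized spectral contrast angle (1 − 2θ/π) is reported alongside but not
thresholded. Zero variance in either vector makes the score undefined and
the PSM fails. The threshold is 0.70, or 0.60 when the PSM carries any
`Oxidation` (Unimod 35, M or P): intensity predictors are unreliable for
modified peptides. After spectral removals the min-PSM support rule is
re-applied once to the dietary proteins.

The predictor is pluggable (any callable with the `FragmentSpectrum`
shape). The built-in model emits singly charged b/y ions — plus doubly
charged at 0.3 relative weight when the precursor charge is ≥ 2 — at
monoisotopic m/z (proton 1.00728, water 18.01056; modification deltas
+57.02146 carbamidomethyl, +15.99491 oxidation, +0.98402 deamidation), with
intensities `(1 + min(i, n−i))`, a triangular profile peaking at
mid-sequence, and y ions weighted 1.5× over b. It is a deterministic
structural stand-in, not a learned model: it reproduces the *geometry* of
fragment matching (m/z alignment, rank structure), which is what the
Pearson statistic tests, but not instrument- or collision-energy-specific
intensity patterns.

## Taxonomic assignment

Matching is exact substring search over the dietary database with I/L
equivalence (mass-identical residues). Deamidation-aware mode additionally
allows observed D over database N and observed E over database Q — never
the reverse — recording the positions. This replaces a BLAST-vs-nr step:
for short tryptic milk peptides, substitution scoring and gaps add nothing
over exact matching against a curated database, and the packaged database
is the documented contract.

Labels: a single matched taxon reports as itself, rolled up to its
reporting rank (`Bos` → `Bovinae`, since the database does not distinguish
bovine congeners); several taxa collapse to their LCA; an LCA at or above
the ceiling node (class Mammalia) reports `unspecific`. When removing the
deamidation-assumed matches would change the label, the assignment is
flagged `deamidation_dependent` and reported as the alternation of the
strict-side and deamidated-side labels (`Bovinae/Ovis`). Bacterial homolog
hits are dropped (exclusion list, genome-contamination artefacts) or
counted as the mapped milk protein with no taxon evidence of their own
(reassignment, e.g. the *S. aureus* lipocalin homolog → BLG). Display
grouping for site summaries merges `Pecora`+`Bovidae`,
`Bovinae`/`Ovis`/`Bovinae/Ovis`, and `Caprinae`+`Capra`.

The packaged dietary database contains synthetic stand-in sequences
(concatenated tryptic peptides) for BLG (Bos, Ovis, Capra), equine BLG-1/
BLG-2, Alpha-S1-casein (Bos, Ovis, Capra) and bovine BTN1A1, plus two
bacterial homolog entries; only the `TPEVDDEALEK`/`TPEVDNEALEK` locus is
taken from the literature. Because the database holds no non-bovid pecoran,
an LCA of exactly Pecora is unreachable; such peptides report `Bovidae`,
and the display group "Pecora and Bovidae" covers both.

## Synthetic generator

`simulate_study` draws, per sample, PSM categories from a fixed composition
(defaults: oral 0.55, contaminant 0.25, dietary 0.10, other 0.10 for
authentic samples; failing samples swap the oral and contaminant shares and
carry no dietary PSMs), deamidation per residue instance by group-specific
Bernoulli draws (endogenous N 0.5 / Q 0.15; contaminant N 0.05 / Q 0.02 —
in failing samples every protein uses contaminant rates, since an
unauthentic proteome contains no preserved ancient protein), decoy PSMs
with per-sample shared decoy accessions, ion scores from per-class normal
distributions (dietary splits into a sub-40 and an above-40 component), and
MS2 spectra for the low-scoring dietary PSMs from the built-in intensity
model with multiplicative log-normal noise (σ = 0.05). All randomness flows
from one `numpy` generator seeded by `SimulationParams.seed`.

What it does *not* emulate: chromatography, isotope envelopes, charge-state
ambiguity, co-isolation/chimeric spectra, homologous near-miss peptides in
the non-dietary categories, or realistic protein abundance distributions.
Passing tests therefore demonstrate the correctness of the inference chain
under its own model assumptions, not performance on real instrument data.

`make_worked_example` is fully deterministic: per-individual, per-protein
PSM counts are fixed to the published worked example (50 milk PSMs; Bilsk
27, Mamai-Gora 23), with peptides chosen once from the database's tryptic
peptides so that unique-peptide counts are reproducible; ion scores are ≥ 40
so the fixture needs no spectra.

## Problem sizes

Tests and the acceptance script run synthetic studies of 4–8 samples at
150–800 PSMs per sample, 100-trial spectral simulations, and 40 random
instances of ≤ 50 PSMs for the FDR oracle; the whole suite completes in a
few seconds.

## Known limitations

- No protein inference or grouping; the primary accession carries all
  protein-level bookkeeping.
- The FDR estimator assumes one decoy per target database entry upstream.
- Substring taxonomy cannot detect novel variants that differ by non-N/Q
  substitutions; that is intentional scope.
- The built-in intensity model makes no claim of instrument realism; plug
  in an external predictor for real-data use.
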