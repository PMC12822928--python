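"""Spectral validation of low-scoring dietary PSMs.

Dietary identifications whose search-engine ion score falls below the
validation cutoff are re-examined by comparing the observed MS2 spectrum
(after precursor-peak removal) with a predicted fragment spectrum. The
similarity statistic thresholded is the Pearson correlation between
predicted and observed fragment intensities; the normalized spectral
contrast angle is reported alongside for transparency. PSMs carrying an
oxidation (on M or P) use a relaxed threshold because intensity predictors
handle modified peptides poorly.

The fragment predictor is pluggable: any callable mapping
(peptide, modifications, charge) to a FragmentSpectrum will do. The
built-in stand-in emits singly (and, for multiply charged precursors,
doubly) charged b/y ions at monoisotopic m/z with a deterministic intensity
model: y ions weighted 1.5x over b ions, modulated by a triangular profile
peaking at mid-sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .psm_io import PipelineConfig, PsmRecord, ReferenceSets, Spectrum
from .oral_auth import classify_psm

PROTON = 1.00728
WATER = 18.01056

#: standard monoisotopic residue masses
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

MOD_DELTA = {
    "Carbamidomethyl": 57.02146,
    "Oxidation": 15.99491,
    "Deamidated": 0.98402,
}

#: relative weight of doubly charged fragment ions in the built-in model
DOUBLY_CHARGED_WEIGHT = 0.3


@dataclass(frozen=True)
class FragmentIon:
    series: str      # "b" or "y"
    index: int       # 1 .. len(peptide) - 1
    ion_charge: int  # 1 or 2
    mz: float
    predicted_intensity: float


@dataclass
class FragmentSpectrum:
    peptide: str
    charge: int
    ions: list[FragmentIon]


@dataclass
class ValidationResult:
    spectrum_ref: str
    peptide: str
    ion_score: float
    pearson: float | None
    contrast_angle: float | None
    threshold_used: float
    validated: bool
    n_matched: int
    reason: str


Predictor = Callable[[str, Sequence[tuple[int, str]], int], FragmentSpectrum]


def strip_precursor(spectrum: Spectrum, precursor_mz: float, halfwidth: float) -> Spectrum:
    """Remove peaks within +-halfwidth of the precursor m/z."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    peaks = tuple(
        p for p in spectrum.peaks if abs(p[0] - precursor_mz) > halfwidth
    )
    return Spectrum(spectrum.spectrum_ref, spectrum.precursor_mz, spectrum.charge, peaks)


def _residue_masses(peptide: str, modifications: Sequence[tuple[int, str]]) -> list[float]:
    masses = [RESIDUE_MASS[a] for a in peptide]
    for pos, name in modifications:
        if not 1 <= pos <= len(peptide):
            raise ValueError(
                f"modification position {pos} outside peptide of length {len(peptide)}"
            )
        masses[pos - 1] += MOD_DELTA[name]
    return masses


def predict_fragments(
    peptide: str,
    modifications: Sequence[tuple[int, str]],
    charge: int,
    predictor: Predictor | None = None,
) -> FragmentSpectrum:
    """Predict b/y fragment ions; external predictors share the same shape."""
    if len(peptide) < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    if predictor is not None:
        return predictor(peptide, modifications, charge)

    masses = _residue_masses(peptide, modifications)
    n = len(peptide)
    prefix = np.cumsum(masses)            # b fragment residue sums
    total = prefix[-1]
    ion_charges = (1, 2) if charge >= 2 else (1,)

    ions: list[FragmentIon] = []
    for i in range(1, n):
        # triangular profile peaking at mid-sequence, never zero
        profile = 1.0 + min(i, n - i)
        for q in ion_charges:
            q_weight = 1.0 if q == 1 else DOUBLY_CHARGED_WEIGHT
            b_mz = (prefix[i - 1] + q * PROTON) / q
            ions.append(FragmentIon("b", i, q, float(b_mz), profile * q_weight))
            y_mz = (total - prefix[n - i - 1] + WATER + q * PROTON) / q
            ions.append(FragmentIon("y", i, q, float(y_mz), 1.5 * profile * q_weight))
    return FragmentSpectrum(peptide=peptide, charge=charge, ions=ions)


def contrast_angle(a: np.ndarray, b: np.ndarray) -> float | None:
    """Normalized spectral contrast angle, 1 - 2*theta/pi, in [0, 1]."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return 1.0 - 2.0 * math.acos(cos) / math.pi


def score_psm(
    observed: Spectrum, predicted: FragmentSpectrum, tol_da: float
) -> tuple[float | None, int]:
    """Pearson correlation between predicted and matched observed intensities.

    For each predicted ion the observed intensity is the most intense peak
    within +-tol_da of its m/z (0 when none). Returns (pearson, n_matched);
    pearson is None when either intensity vector has zero variance.
    """
    if not predicted.ions:
        raise ValueError("predicted ion list is empty")
    mzs = np.array([p[0] for p in observed.peaks])
    intensities = np.array([p[1] for p in observed.peaks])
    pred = np.array([ion.predicted_intensity for ion in predicted.ions])
    obs = np.zeros(len(predicted.ions))
    n_matched = 0
    for k, ion in enumerate(predicted.ions):
        if len(mzs) == 0:
            continue
        lo = np.searchsorted(mzs, ion.mz - tol_da, side="left")
        hi = np.searchsorted(mzs, ion.mz + tol_da, side="right")
        if hi > lo:
            obs[k] = intensities[lo:hi].max()
            n_matched += 1
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return None, n_matched
    pearson = float(np.corrcoef(pred, obs)[0, 1])
    return pearson, n_matched


def _has_oxidation(psm: PsmRecord) -> bool:
    return any(name == "Oxidation" for _, name in psm.modifications)


def validate_dietary(
    psms: list[PsmRecord],
    spectra: dict[str, Spectrum],
    refsets: ReferenceSets,
    config: PipelineConfig,
    predictor: Predictor | None = None,
) -> tuple[list[PsmRecord], list[ValidationResult]]:
    """Spectral validation of dietary PSMs below the ion-score cutoff.

    High-scoring dietary PSMs pass without spectral scoring. Low-scoring
    ones are scored against the predicted fragment spectrum of their own
    peptide; the Pearson threshold relaxes from 0.70 to 0.60 when the PSM
    carries an Oxidation. After spectral removals the min-PSM-per-protein
    support rule is re-applied (single pass) to the dietary proteins.
    """
    dietary = [p for p in psms if classify_psm(p, refsets) == "dietary"]

    missing = [
        p.spectrum_ref for p in dietary
        if p.ion_score < config.ion_score_validation_cutoff
        and p.spectrum_ref not in spectra
    ]
    if missing:
        raise KeyError(f"spectra missing for PSMs requiring validation: {missing}")

    results: list[ValidationResult] = []
    surviving: list[PsmRecord] = []
    for p in dietary:
        threshold = (
            config.pearson_threshold_oxidized if _has_oxidation(p)
            else config.pearson_threshold_unmodified
        )
        if p.ion_score >= config.ion_score_validation_cutoff:
            results.append(ValidationResult(
                p.spectrum_ref, p.peptide, p.ion_score, None, None,
                threshold, True, 0, "ion_score_above_cutoff",
            ))
            surviving.append(p)
            continue
        spectrum = strip_precursor(
            spectra[p.spectrum_ref], p.precursor_mz, config.precursor_strip_halfwidth_mz
        )
        predicted = predict_fragments(p.peptide, p.modifications, p.charge, predictor)
        # predicted ions inside the stripped precursor window can never match
        # an observed peak; drop them from the comparison
        predicted.ions = [
            ion for ion in predicted.ions
            if abs(ion.mz - p.precursor_mz) > config.precursor_strip_halfwidth_mz
        ]
        pearson, n_matched = score_psm(spectrum, predicted, config.fragment_match_tol_da)
        angle = contrast_angle(
            np.array([i.predicted_intensity for i in predicted.ions]),
            _matched_vector(spectrum, predicted, config.fragment_match_tol_da),
        )
        ok = pearson is not None and pearson >= threshold
        results.append(ValidationResult(
            p.spectrum_ref, p.peptide, p.ion_score, pearson, angle,
            threshold, ok, n_matched,
            "pearson" if pearson is not None else "undefined_pearson",
        ))
        if ok:
            surviving.append(p)

    # re-apply the min-PSM support rule to dietary proteins after removals
    from collections import Counter
    support = Counter(p.primary_accession for p in surviving)
    kept: list[PsmRecord] = []
    for p in surviving:
        if support[p.primary_accession] >= config.min_psm_per_protein:
            kept.append(p)
        else:
            results.append(ValidationResult(
                p.spectrum_ref, p.peptide, p.ion_score, None, None,
                config.pearson_threshold_unmodified, False, 0,
                "min_psm_per_protein_after_validation",
            ))
    return kept, results


def _matched_vector(
    observed: Spectrum, predicted: FragmentSpectrum, tol_da: float
) -> np.ndarray:
    mzs = np.array([p[0] for p in observed.peaks])
    intensities = np.array([p[1] for p in observed.peaks])
    obs = np.zeros(len(predicted.ions))
    for k, ion in enumerate(predicted.ions):
        if len(mzs) == 0:
            break
        lo = np.searchsorted(mzs, ion.mz - tol_da, side="left")
        hi = np.searchsorted(mzs, ion.mz + tol_da, side="right")
        if hi > lo:
            obs[k] = intensities[lo:hi].max()
    return obs
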