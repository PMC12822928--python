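"""Fragment prediction, spectral similarity scoring and dietary validation."""

import numpy as np
import pytest
from pyteomics import mass as pt_mass

from calcproteo.psm_io import PipelineConfig, ReferenceSets, Spectrum
from calcproteo.spectral import (
    MOD_DELTA, predict_fragments, score_psm, strip_precursor, validate_dietary,
)
from calcproteo.synth import peptide_precursor_mz

from conftest import make_psm


def spectrum_from_prediction(predicted, ref="t", precursor_mz=1000.0, charge=2,
                             noise=None, rng=None):
    peaks: dict = {}
    for ion in predicted.ions:
        inten = ion.predicted_intensity
        if noise:
            inten *= float(np.exp(rng.normal(0.0, noise)))
        key = round(ion.mz, 6)
        peaks[key] = max(peaks.get(key, 0.0), inten)
    return Spectrum(ref, precursor_mz, charge, tuple(sorted(peaks.items())))


class TestStripPrecursor:
    def test_window_removed(self):
        spec = Spectrum("t", 500.3, 2, ((500.0, 1.0), (500.5, 2.0), (900.0, 3.0)))
        stripped = strip_precursor(spec, 500.3, 1.0)
        assert stripped.peaks == ((900.0, 3.0),)

    def test_no_peak_in_window_unchanged(self):
        spec = Spectrum("t", 500.3, 2, ((100.0, 1.0), (900.0, 3.0)))
        assert strip_precursor(spec, 500.3, 1.0).peaks == spec.peaks

    def test_all_peaks_in_window_empties_spectrum(self):
        spec = Spectrum("t", 500.3, 2, ((500.0, 1.0), (500.9, 2.0)))
        assert strip_precursor(spec, 500.3, 1.0).peaks == ()


class TestPredictFragments:
    def test_dipeptide_b1_y1_mz(self):
        predicted = predict_fragments("AG", (), 1)
        by_key = {(i.series, i.index, i.ion_charge): i.mz for i in predicted.ions}
        assert by_key[("b", 1, 1)] == pytest.approx(72.04439, abs=1e-4)
        assert by_key[("y", 1, 1)] == pytest.approx(76.03930, abs=1e-4)

    @pytest.mark.parametrize("peptide", ["TPEVDDEALEK", "IDALNENK", "AVLHPLEVR"])
    @pytest.mark.parametrize("series", ["b", "y"])
    def test_mz_matches_independent_mass_oracle(self, peptide, series):
        predicted = predict_fragments(peptide, (), 2)
        for ion in predicted.ions:
            if ion.series != series:
                continue
            frag = peptide[: ion.index] if series == "b" else peptide[-ion.index:]
            expected = pt_mass.fast_mass(frag, ion_type=series, charge=ion.ion_charge)
            assert ion.mz == pytest.approx(expected, abs=1e-3)

    def test_carbamidomethyl_shifts_cysteine_ions(self):
        plain = predict_fragments("ACK", (), 1)
        modified = predict_fragments("ACK", ((2, "Carbamidomethyl"),), 1)
        for p, m in zip(plain.ions, modified.ions):
            contains_c = (p.series == "b" and p.index >= 2) or \
                         (p.series == "y" and p.index >= 2)
            delta = (m.mz - p.mz) * p.ion_charge
            if contains_c:
                assert delta == pytest.approx(MOD_DELTA["Carbamidomethyl"], abs=1e-6)
            else:
                assert delta == pytest.approx(0.0, abs=1e-9)

    def test_single_residue_peptide_rejected(self):
        with pytest.raises(ValueError):
            predict_fragments("K", (), 2)

    def test_doubly_charged_ions_only_for_multiply_charged_precursor(self):
        assert {i.ion_charge for i in predict_fragments("PEPTIDEK", (), 1).ions} == {1}
        assert {i.ion_charge for i in predict_fragments("PEPTIDEK", (), 2).ions} == {1, 2}

    def test_y_ions_weighted_over_b(self):
        predicted = predict_fragments("PEPTIDEK", (), 1)
        b = {i.index: i.predicted_intensity for i in predicted.ions if i.series == "b"}
        y = {i.index: i.predicted_intensity for i in predicted.ions if i.series == "y"}
        for idx in b:
            assert y[idx] == pytest.approx(1.5 * b[idx])


class TestScorePsm:
    def test_noise_free_self_match_is_unity(self):
        predicted = predict_fragments("TPEVDDEALEK", (), 1)
        observed = spectrum_from_prediction(predicted)
        pearson, n = score_psm(observed, predicted, 0.01)
        assert pearson == pytest.approx(1.0, abs=1e-9)
        assert n == len(predicted.ions)

    def test_empty_observed_gives_undefined(self):
        predicted = predict_fragments("TPEVDDEALEK", (), 1)
        pearson, n = score_psm(Spectrum("t", 500.0, 2, ()), predicted, 0.01)
        assert pearson is None
        assert n == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        predicted = predict_fragments("IDALNENK", (), 2)
        observed = spectrum_from_prediction(predicted, noise=0.1, rng=rng)
        scaled = Spectrum("t", observed.precursor_mz, observed.charge,
                          tuple((mz, 37.5 * i) for mz, i in observed.peaks))
        p1, _ = score_psm(observed, predicted, 0.01)
        p2, _ = score_psm(scaled, predicted, 0.01)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_widening_tolerance_never_loses_matches(self):
        rng = np.random.default_rng(4)
        predicted = predict_fragments("AVLHPLEVR", (), 2)
        jittered = Spectrum("t", 500.0, 2, tuple(
            (ion.mz + rng.normal(0, 0.004), ion.predicted_intensity)
            for ion in sorted(predicted.ions, key=lambda i: i.mz)
        ))
        counts = [score_psm(jittered, predicted, tol)[1] for tol in (0.002, 0.01, 0.05)]
        assert counts == sorted(counts)

    def test_empty_prediction_is_error(self):
        from calcproteo.spectral import FragmentSpectrum
        with pytest.raises(ValueError):
            score_psm(Spectrum("t", 1.0, 1, ()), FragmentSpectrum("AK", 1, []), 0.01)

    def test_correct_peptide_beats_shuffled_decoy(self):
        """Self-match with 5% noise scores >= 0.95 and beats a decoy in >= 95/100 trials."""
        rng = np.random.default_rng(9)
        peptide = "TPEVDDEALEK"
        wins = 0
        for _ in range(100):
            predicted = predict_fragments(peptide, (), 2)
            observed = spectrum_from_prediction(predicted, noise=0.05, rng=rng)
            p_true, _ = score_psm(observed, predicted, 0.01)
            assert p_true >= 0.95
            shuffled = "".join(rng.permutation(list(peptide[:-1]))) + peptide[-1]
            p_decoy, _ = score_psm(
                observed, predict_fragments(shuffled, (), 2), 0.01)
            wins += p_decoy is None or p_decoy < p_true
        assert wins >= 95


@pytest.fixture
def dietary_refs():
    return ReferenceSets(dietary={
        "BLG_BOS": ("BLG", "TPEVDDEALEKIPAVFK", ("Root",)),
    })


class TestValidateDietary:
    def _psm(self, peptide, ion_score, ref, mods=(), charge=2):
        return make_psm(peptide=peptide, accession="BLG_BOS", ion_score=ion_score,
                        spectrum_ref=ref, mods=mods, charge=charge,
                        precursor_mz=peptide_precursor_mz(peptide, tuple(mods), charge))

    def test_high_score_psm_passes_without_spectrum(self, dietary_refs, config):
        psms = [self._psm("TPEVDDEALEK", 55.0, f"r{i}") for i in range(2)]
        kept, results = validate_dietary(psms, {}, dietary_refs, config)
        assert len(kept) == 2
        assert all(r.reason == "ion_score_above_cutoff" for r in results)

    def test_missing_spectrum_for_low_score_psm_is_error(self, dietary_refs, config):
        psms = [self._psm("TPEVDDEALEK", 30.0, "absent"),
                self._psm("TPEVDDEALEK", 55.0, "r1")]
        with pytest.raises(KeyError, match="absent"):
            validate_dietary(psms, {}, dietary_refs, config)

    def test_oxidized_psm_uses_relaxed_threshold(self, dietary_refs, config):
        peptide = "IPAVFK"
        mods = ((2, "Oxidation"),)  # hydroxyproline-style Unimod:35 on P
        psm = self._psm(peptide, 30.0, "r1", mods=mods)
        predicted = predict_fragments(peptide, mods, 2)
        # degrade the spectrum until pearson lands between 0.60 and 0.70
        rng = np.random.default_rng(31)
        pearson = None
        for noise in np.linspace(0.15, 1.2, 40):
            observed = spectrum_from_prediction(
                predicted, ref="r1", precursor_mz=psm.precursor_mz,
                noise=float(noise), rng=rng)
            p, _ = score_psm(observed, predicted, config.fragment_match_tol_da)
            if p is not None and 0.60 <= p < 0.70:
                pearson = p
                break
        assert pearson is not None, "could not construct an intermediate-quality spectrum"
        companion = self._psm(peptide, 55.0, "r2", mods=mods)
        kept, results = validate_dietary(
            [psm, companion], {"r1": observed}, dietary_refs, config)
        scored = next(r for r in results if r.spectrum_ref == "r1")
        assert scored.threshold_used == pytest.approx(0.60)
        assert scored.validated
        assert len(kept) == 2

    def test_min_psm_rule_reapplied_after_spectral_exclusion(self, dietary_refs, config):
        good = self._psm("TPEVDDEALEK", 55.0, "r1")
        bad = self._psm("IPAVFK", 30.0, "r2")
        # empty observed spectrum -> undefined pearson -> excluded; the protein
        # then has a single surviving PSM, which the support rule removes too
        spectra = {"r2": Spectrum("r2", bad.precursor_mz, 2, ())}
        kept, results = validate_dietary([good, bad], spectra, dietary_refs, config)
        assert kept == []
        reasons = {r.reason for r in results}
        assert "undefined_pearson" in reasons
        assert "min_psm_per_protein_after_validation" in reasons
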