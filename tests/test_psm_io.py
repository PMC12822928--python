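"""PSM table, MGF and reference-set I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from calcproteo import psm_io
from calcproteo.psm_io import (
    ConfigurationError, PipelineConfig, PsmRecord, RowError, Spectrum,
    read_mgf, read_psm_table, write_mgf, write_psm_table,
)
from calcproteo.synth import generate_reference_db, write_reference_dir

from conftest import make_psm

HEADER = "\t".join(psm_io.PSM_COLUMNS)


def _row(peptide="TPEVDDEALEK", mods="", accessions="BLG_BOS", decoy="False"):
    return "\t".join([
        "s1", "i1", "Bilsk", "Tsarina", "scan1", peptide, mods, accessions,
        "55.2", "0.001", decoy, "623.3", "2",
    ])


class TestReadPsmTable:
    def test_unmodified_row_parses_with_empty_mod_list(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(HEADER + "\n" + _row() + "\n")
        (rec,) = read_psm_table(path)
        assert rec.peptide == "TPEVDDEALEK"
        assert rec.modifications == ()
        assert rec.primary_accession == "BLG_BOS"
        assert not rec.is_decoy

    def test_modification_on_wrong_residue_is_row_error(self, tmp_path):
        # Deamidated:4 on ANQK sits on K, violating the placement invariant
        path = tmp_path / "psms.tsv"
        path.write_text(HEADER + "\n" + _row(peptide="ANQK", mods="Deamidated:4") + "\n")
        with pytest.raises(RowError, match="row 2"):
            read_psm_table(path)

    def test_header_only_file_yields_empty_list(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(HEADER + "\n")
        assert read_psm_table(path) == []

    def test_missing_column_is_configuration_error_naming_it(self, tmp_path):
        path = tmp_path / "psms.tsv"
        cols = [c for c in psm_io.PSM_COLUMNS if c != "e_value"]
        path.write_text("\t".join(cols) + "\n")
        with pytest.raises(ConfigurationError, match="e_value"):
            read_psm_table(path)

    def test_malformed_modification_token_reports_row(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(HEADER + "\n" + _row(mods="Deamidated@3") + "\n")
        with pytest.raises(RowError, match="row 2"):
            read_psm_table(path)

    def test_mascot_dialect_maps_columns_and_decoy_prefix(self, tmp_path):
        path = tmp_path / "mascot.csv"
        cols = ("sample_id,individual_id,site,subsite,pep_scan_title,pep_seq,"
                "modifications,prot_acc,pep_score,pep_expect,pep_exp_mz,pep_exp_z")
        path.write_text(
            cols + "\n"
            + "s1,i1,Bilsk,,t1,ANQK,Deamidated:2,DECOY_X1,30.0,0.2,250.1,2\n"
        )
        (rec,) = read_psm_table(path, dialect="mascot_csv")
        assert rec.is_decoy
        assert rec.modifications == ((2, "Deamidated"),)


def test_generic_table_round_trip_preserves_all_fields(tmp_path):
    psms = [
        make_psm(peptide="ANQK", mods=[(2, "Deamidated")], e_value=0.004),
        make_psm(peptide="MCK", mods=[(1, "Oxidation"), (2, "Carbamidomethyl")],
                 accession=("A", "B"), is_decoy=True, spectrum_ref="scan2"),
    ]
    path = tmp_path / "rt.tsv"
    write_psm_table(psms, path)
    assert read_psm_table(path) == psms


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_parsed_records_satisfy_modification_invariants(data):
    peptide = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12))
    mods = []
    for i, aa in enumerate(peptide, start=1):
        for name, targets in psm_io.MOD_TARGETS.items():
            if aa in targets and data.draw(st.booleans()):
                mods.append((i, name))
    rec = make_psm(peptide=peptide, mods=mods)
    for pos, name in rec.modifications:
        assert rec.peptide[pos - 1] in psm_io.MOD_TARGETS[name]


class TestMgf:
    def test_round_trip_within_tolerance_and_sorted(self, tmp_path):
        spec = Spectrum("t1", 500.25, 2, ((100.5, 3.0), (200.25, 1.0), (350.125, 7.5)))
        path = tmp_path / "s.mgf"
        write_mgf([spec], path)
        back = read_mgf(path)["t1"]
        assert back.precursor_mz == pytest.approx(500.25, abs=1e-6)
        for (mz_a, i_a), (mz_b, i_b) in zip(spec.peaks, back.peaks):
            assert mz_a == pytest.approx(mz_b, abs=1e-6)
            assert i_a == pytest.approx(i_b, abs=1e-6)

    def test_unsorted_peaks_returned_ascending(self, tmp_path):
        path = tmp_path / "s.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=t1\nPEPMASS=400.2\nCHARGE=2+\n"
            "300.1 5.0\n100.2 1.0\n200.3 2.0\nEND IONS\n"
        )
        peaks = read_mgf(path)["t1"].peaks
        assert [p[0] for p in peaks] == sorted(p[0] for p in peaks)

    def test_duplicate_title_is_error(self, tmp_path):
        block = "BEGIN IONS\nTITLE=t1\nPEPMASS=400.2\nCHARGE=2+\n100.0 1.0\nEND IONS\n"
        path = tmp_path / "s.mgf"
        path.write_text(block + block)
        with pytest.raises(ConfigurationError, match="duplicate"):
            read_mgf(path)

    def test_missing_pepmass_is_parse_error(self, tmp_path):
        path = tmp_path / "s.mgf"
        path.write_text("BEGIN IONS\nTITLE=t1\nCHARGE=2+\n100.0 1.0\nEND IONS\n")
        with pytest.raises(ConfigurationError, match="PEPMASS"):
            read_mgf(path)


class TestReferenceSets:
    def test_written_reference_dir_loads_back(self, tmp_path):
        refs, _ = generate_reference_db(seed=3)
        write_reference_dir(refs, tmp_path)
        loaded, tree = psm_io.load_reference_sets(
            tmp_path / "dietary.fasta", tmp_path / "lists.yaml", tmp_path / "taxonomy.tsv"
        )
        assert loaded.oral_microbiome == refs.oral_microbiome
        assert loaded.lab_contaminants == refs.lab_contaminants
        assert set(loaded.dietary) == set(refs.dietary)
        assert loaded.reassignment_rules == refs.reassignment_rules
        assert tree.root == "Root"

    def test_category_precedence_prefers_lab_contaminant(self, tmp_path, caplog):
        refs, _ = generate_reference_db(seed=3)
        shared = next(iter(refs.oral_microbiome))
        refs.lab_contaminants.add(shared)
        write_reference_dir(refs, tmp_path)
        loaded, _ = psm_io.load_reference_sets(
            tmp_path / "dietary.fasta", tmp_path / "lists.yaml", tmp_path / "taxonomy.tsv"
        )
        assert shared in loaded.lab_contaminants
        assert shared not in loaded.oral_microbiome

    def test_lineage_node_absent_from_tree_is_error(self, tmp_path):
        refs, _ = generate_reference_db(seed=3)
        write_reference_dir(refs, tmp_path)
        lineage_file = tmp_path / "dietary.lineages.tsv"
        lineage_file.write_text(
            lineage_file.read_text().replace("Bovinae>Bos", "Bovinae>Wisent")
        )
        with pytest.raises(ConfigurationError, match="Wisent"):
            psm_io.load_reference_sets(
                tmp_path / "dietary.fasta", tmp_path / "lists.yaml",
                tmp_path / "taxonomy.tsv",
            )

    def test_empty_dietary_fasta_is_valid(self, tmp_path):
        refs, _ = generate_reference_db(seed=3)
        refs.dietary = {}
        refs.reassignment_rules = {}
        write_reference_dir(refs, tmp_path)
        loaded, _ = psm_io.load_reference_sets(
            tmp_path / "dietary.fasta", tmp_path / "lists.yaml", tmp_path / "taxonomy.tsv"
        )
        assert loaded.dietary == {}


def test_config_yaml_round_trip_and_validation(tmp_path):
    cfg = PipelineConfig(e_value_max=0.05, random_seed=7)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert PipelineConfig.from_yaml(path) == cfg
    (tmp_path / "bad.yaml").write_text("pearson_threshold_unmodified: 1.5\n")
    with pytest.raises(ConfigurationError):
        PipelineConfig.from_yaml(tmp_path / "bad.yaml")
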