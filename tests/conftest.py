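import logging

import pytest

from calcproteo.psm_io import PipelineConfig, PsmRecord
from calcproteo.synth import load_packaged_references

logging.getLogger("calcproteo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def refsets_and_tree():
    return load_packaged_references()


@pytest.fixture(scope="session")
def refsets(refsets_and_tree):
    return refsets_and_tree[0]


@pytest.fixture(scope="session")
def tree(refsets_and_tree):
    return refsets_and_tree[1]


@pytest.fixture
def config():
    return PipelineConfig()


def make_psm(
    peptide="PEPTIDEK",
    accession="ACC1",
    sample_id="S1",
    individual_id="I1",
    site="SiteA",
    mods=(),
    ion_score=50.0,
    e_value=1e-4,
    is_decoy=False,
    spectrum_ref="scan1",
    charge=2,
    precursor_mz=500.0,
    subsite="",
):
    psm = PsmRecord(
        sample_id=sample_id, individual_id=individual_id, site=site,
        subsite=subsite, spectrum_ref=spectrum_ref, peptide=peptide,
        modifications=tuple(mods), accessions=(accession,) if isinstance(accession, str)
        else tuple(accession),
        ion_score=ion_score, e_value=e_value, is_decoy=is_decoy,
        precursor_mz=precursor_mz, charge=charge,
    )
    psm.validate()
    return psm
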