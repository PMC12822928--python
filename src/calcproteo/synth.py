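"""Synthetic study generation.

Two generators live here. ``simulate_study`` draws a complete multi-sample
calculus study with the statistical structure the analysis assumes:
category composition per sample (authentic samples dominated by oral
signature, failing samples by contaminants), group-specific Bernoulli
deamidation per N/Q residue instance, injected decoy hits, and MS2 spectra
for low-scoring dietary PSMs built from the deterministic fragment
intensity model with multiplicative log-normal noise. A truth record keeps
every latent label so each pipeline stage can be scored against it.

``make_worked_example`` deterministically emits the worked example: a
dietary PSM table whose per-individual, per-protein PSM counts equal the
published counts for the six dairy-positive individuals of the two
Ukrainian sites, with peptides drawn from the packaged milk-protein
database. Peptide identities are fixture-defined (chosen from the
database's tryptic peptides), except the diagnostic TPEVDDEALEK.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .psm_io import (
    PsmRecord, ReferenceSets, Spectrum, TaxonomyTree,
    read_lineage_table, read_taxonomy,
)
from .spectral import PROTON, WATER, predict_fragments, _residue_masses

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# packaged reference database
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("calcproteo.data").joinpath(name).read_text()


def load_packaged_references() -> tuple[ReferenceSets, TaxonomyTree]:
    """The packaged dietary database, homolog rules and taxonomy tree."""
    import io
    from Bio import SeqIO

    tree_path = resources.files("calcproteo.data").joinpath("taxonomy.tsv")
    tree = read_taxonomy(str(tree_path))

    lineages: dict = {}
    for line in _data_text("dietary_lineages.tsv").splitlines()[1:]:
        if line.strip():
            acc, name, lineage = line.split("\t")
            lineages[acc] = (name, tuple(lineage.split(">")))

    refs = ReferenceSets()
    for record in SeqIO.parse(io.StringIO(_data_text("dietary_synthetic.fasta")), "fasta"):
        name, lineage = lineages[record.id]
        refs.dietary[record.id] = (name, str(record.seq).upper(), lineage)

    rules = yaml.safe_load(_data_text("rules.yaml"))
    refs.exclusion_accessions = set(rules.get("exclusions", []))
    refs.reassignment_rules = dict(rules.get("reassignments", {}))
    return refs, tree


def generate_reference_db(
    seed: int,
    n_oral: int = 40,
    n_salivary: int = 15,
    n_common: int = 25,
    n_lab: int = 10,
) -> tuple[ReferenceSets, TaxonomyTree]:
    """Packaged dietary DB plus seeded random accession compilations."""
    rng = np.random.default_rng(seed)
    refs, tree = load_packaged_references()

    def draw(prefix: str, n: int) -> set[str]:
        return {
            f"{prefix}_{''.join(rng.choice(list(string.ascii_uppercase), 2))}{rng.integers(0, 10**6):06d}"
            for _ in range(n)
        }

    refs.oral_microbiome = draw("ORALMICRO", n_oral)
    refs.salivary = draw("SALIV", n_salivary)
    refs.common_contaminants = draw("COMCONT", n_common)
    refs.lab_contaminants = draw("LABCONT", n_lab)
    return refs, tree


def write_reference_dir(refs: ReferenceSets, outdir: str | Path) -> None:
    """Write a reference directory readable by psm_io.load_reference_sets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_lines, lineage_lines = [], ["accession\tprotein_name\tlineage"]
    for acc, (name, seq, lineage) in refs.dietary.items():
        fasta_lines.append(f">{acc}\n{seq}")
        lineage_lines.append(f"{acc}\t{name}\t{'>'.join(lineage)}")
    (outdir / "dietary.fasta").write_text(
        "\n".join(fasta_lines) + "\n" if fasta_lines else "")
    (outdir / "dietary.lineages.tsv").write_text("\n".join(lineage_lines) + "\n")
    (outdir / "lists.yaml").write_text(yaml.safe_dump({
        "oral_microbiome": sorted(refs.oral_microbiome),
        "salivary": sorted(refs.salivary),
        "common_contaminants": sorted(refs.common_contaminants),
        "lab_contaminants": sorted(refs.lab_contaminants),
        "exclusions": sorted(refs.exclusion_accessions),
        "reassignments": dict(sorted(refs.reassignment_rules.items())),
    }, sort_keys=False))
    (outdir / "taxonomy.tsv").write_text(_data_text("taxonomy.tsv"))


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Study-level knobs; defaults describe a well-separated two-group study."""

    n_samples: int = 8
    psms_per_sample: int = 200
    #: authentic-sample category composition (failing samples swap oral and
    #: contaminant shares); remainder to 1.0 is unmatched "other"
    oral_fraction: float = 0.55
    contaminant_fraction: float = 0.25
    dietary_fraction: float = 0.10
    #: fraction of failing samples in the batch
    bad_sample_fraction: float = 0.5
    #: per-residue-instance deamidation probabilities
    deam_n_endogenous: float = 0.5
    deam_q_endogenous: float = 0.15
    deam_n_contaminant: float = 0.05
    deam_q_contaminant: float = 0.02
    #: decoy PSMs added on top of psms_per_sample
    decoy_fraction: float = 0.02
    #: fraction of dietary PSMs drawn from the low ion-score component
    dietary_low_score_fraction: float = 0.5
    #: sigma of multiplicative log-normal intensity noise on spectra
    spectral_noise: float = 0.05
    #: pairs of passing samples sharing an individual (replicate merging)
    replicate_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        total = self.oral_fraction + self.contaminant_fraction + self.dietary_fraction
        if total > 1.0 + 1e-9:
            raise ValueError(f"category fractions sum to {total} > 1")
        for name, value in self.__dict__.items():
            if "fraction" in name or name.startswith("deam_"):
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{name}={value} outside [0, 1]")


#: (observed peptide, primary accession) pool the dietary simulator draws from
DIETARY_PEPTIDE_POOL = [
    ("TPEVDDEALEK", "BLG_BOS"), ("IPAVFK", "BLG_BOS"), ("VLVLDTDYK", "BLG_BOS"),
    ("GLDIQK", "BLG_BOS"), ("LIVTQTMK", "BLG_BOS"),
    ("IDALNENK", "BLG_OVIS"), ("ALPMHIR", "BLG_OVIS"),
    ("FNPTQLEGQCHVK", "BLG_CAPRA"),
    ("LVSDLTEK", "BLG1_EQUUS"), ("ANIPQTMR", "BLG1_EQUUS"), ("FTDSLAVR", "BLG1_EQUUS"),
    ("YLGYLEQLLR", "CASA1_BOS"), ("EDVPSER", "CASA1_BOS"),
    ("HQGLPQEVLNENLLR", "CASA1_BOS"), ("AYFYPELFR", "CASA1_OVIS"),
    ("AVLHPLEVR", "BTN1A1_BOS"), ("TLEPQSALK", "BTN1A1_BOS"),
]


def peptide_precursor_mz(
    peptide: str, modifications: tuple[tuple[int, str], ...], charge: int
) -> float:
    mass = sum(_residue_masses(peptide, modifications)) + WATER
    return (mass + charge * PROTON) / charge


def _random_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 16) -> str:
    """Random tryptic-looking peptide with at least one N and one Q."""
    n = int(rng.integers(min_len, max_len + 1))
    body = list(rng.choice(list(AA.replace("K", "").replace("R", "")), n - 1))
    body[int(rng.integers(0, n - 1))] = "N"
    pos = int(rng.integers(0, n - 1))
    while body[pos] == "N":
        pos = int(rng.integers(0, n - 1))
    body[pos] = "Q"
    return "".join(body) + str(rng.choice(["K", "R"]))


def _deamidate(
    rng: np.random.Generator, peptide: str, p_n: float, p_q: float
) -> tuple[tuple[int, str], ...]:
    mods = []
    for i, aa in enumerate(peptide, start=1):
        if aa == "N" and rng.random() < p_n:
            mods.append((i, "Deamidated"))
        elif aa == "Q" and rng.random() < p_q:
            mods.append((i, "Deamidated"))
    return tuple(mods)


def simulate_study(
    params: SimulationParams,
    refs: ReferenceSets | None = None,
) -> tuple[list[PsmRecord], dict[str, Spectrum], dict]:
    """Draw a complete synthetic study; see the module docstring."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    if refs is None:
        refs, _ = generate_reference_db(params.seed)

    # per-category accession pools with small per-protein peptide repertoires
    # so the min-PSM-per-protein rule leaves most proteins supported
    pools = {
        "oral_microbiome": sorted(refs.oral_microbiome),
        "salivary": sorted(refs.salivary),
        "common_contaminant": sorted(refs.common_contaminants),
        "lab_contaminant": sorted(refs.lab_contaminants),
        "other": [f"UNK_{i:04d}" for i in range(20)],
    }
    repertoire: dict[str, list[str]] = {
        acc: [_random_peptide(rng) for _ in range(4)]
        for accs in pools.values() for acc in accs
    }

    n_bad = int(round(params.n_samples * params.bad_sample_fraction))
    n_good = params.n_samples - n_bad
    samples = []
    for k in range(params.n_samples):
        good = k < n_good
        sid = f"{200 + k}"
        if params.replicate_pairs and good and k < 2 * params.replicate_pairs:
            individual = f"I{k // 2:02d}"
        else:
            individual = f"I{50 + k:02d}"
        samples.append((sid, individual, good))

    psms: list[PsmRecord] = []
    spectra: dict[str, Spectrum] = {}
    truth: dict = {
        "samples": {}, "psm_categories": {}, "decoy_refs": [],
        "params": dict(params.__dict__),
    }

    for sid, individual, good in samples:
        site = "SiteA" if good else "SiteB"
        truth["samples"][sid] = {"individual": individual, "authentic": good}
        oral_f = params.oral_fraction if good else params.contaminant_fraction
        cont_f = params.contaminant_fraction if good else params.oral_fraction
        category_p = {
            "oral_microbiome": 0.7 * oral_f,
            "salivary": 0.3 * oral_f,
            "common_contaminant": 0.6 * cont_f,
            "lab_contaminant": 0.4 * cont_f,
            "dietary": params.dietary_fraction if good else 0.0,
        }
        category_p["other"] = max(0.0, 1.0 - sum(category_p.values()))
        names = list(category_p)
        probs = np.array([category_p[c] for c in names])
        probs = probs / probs.sum()

        for j in range(params.psms_per_sample):
            category = str(rng.choice(names, p=probs))
            ref = f"{sid}.scan{j:05d}"
            charge = int(rng.choice([2, 2, 3]))
            if category == "dietary":
                idx = int(rng.integers(0, len(DIETARY_PEPTIDE_POOL)))
                peptide, acc = DIETARY_PEPTIDE_POOL[idx]
                low = rng.random() < params.dietary_low_score_fraction
                ion_score = float(rng.normal(32, 4) if low else rng.normal(55, 8))
                ion_score = min(ion_score, 39.0) if low else max(ion_score, 41.0)
                mods = _deamidate(
                    rng, peptide, params.deam_n_endogenous, params.deam_q_endogenous
                )
            else:
                acc = str(rng.choice(pools[category]))
                peptide = repertoire[acc][int(rng.integers(0, 4))]
                ion_score = float(max(rng.normal(60, 10), 20))
                # only authentic samples carry preserved ancient protein, so
                # endogenous deamidation rates apply in those samples alone
                endo = good and category in ("oral_microbiome", "salivary")
                mods = _deamidate(
                    rng, peptide,
                    params.deam_n_endogenous if endo else params.deam_n_contaminant,
                    params.deam_q_endogenous if endo else params.deam_q_contaminant,
                )
            # ~8% of target PSMs fail the e-value rule
            if rng.random() < 0.08:
                e_value = float(10 ** rng.uniform(-1.7, -0.3))
            else:
                e_value = float(10 ** rng.uniform(-6, -2.4))
            precursor_mz = peptide_precursor_mz(peptide, mods, charge)
            psm = PsmRecord(
                sample_id=sid, individual_id=individual, site=site,
                spectrum_ref=ref, peptide=peptide, modifications=mods,
                accessions=(acc,), ion_score=ion_score, e_value=e_value,
                is_decoy=False, precursor_mz=precursor_mz, charge=charge,
            )
            psm.validate()
            psms.append(psm)
            truth["psm_categories"][ref] = category

            if category == "dietary" and ion_score < 40:
                predicted = predict_fragments(peptide, mods, charge)
                noisy = [
                    (ion.mz, ion.predicted_intensity
                     * float(np.exp(rng.normal(0.0, params.spectral_noise))))
                    for ion in predicted.ions
                ]
                peaks: dict[float, float] = {}
                for mz, inten in noisy:
                    peaks[round(mz, 5)] = max(peaks.get(round(mz, 5), 0.0), inten)
                spec = Spectrum(
                    spectrum_ref=ref, precursor_mz=precursor_mz, charge=charge,
                    peaks=tuple(sorted(peaks.items())),
                )
                spec.validate()
                spectra[ref] = spec

        n_decoys = int(round(params.decoy_fraction * params.psms_per_sample))
        for j in range(n_decoys):
            peptide = _random_peptide(rng)
            ref = f"{sid}.decoy{j:04d}"
            charge = 2
            psm = PsmRecord(
                sample_id=sid, individual_id=individual, site=site,
                spectrum_ref=ref, peptide=peptide, modifications=(),
                # two shared decoy accessions per sample so decoys can pass
                # the min-PSM support rule and exercise the FDR gate
                accessions=(f"DECOY_{sid}_{j % 2}",),
                ion_score=float(max(rng.normal(30, 8), 10)),
                e_value=float(10 ** rng.uniform(-2.6, -0.3)),
                is_decoy=True,
                precursor_mz=peptide_precursor_mz(peptide, (), charge),
                charge=charge,
            )
            psms.append(psm)
            truth["psm_categories"][ref] = "decoy"
            truth["decoy_refs"].append(ref)

    return psms, spectra, truth


# ---------------------------------------------------------------------------
# the worked example
# ---------------------------------------------------------------------------

#: individual -> (site, subsite); subsets of the published cohort table
FIXTURE_INDIVIDUALS: list[tuple[str, str, str]] = [
    ("135", "Bilsk", "Cemetery B"),
    ("143", "Bilsk", "Tsarina"),
    ("147", "Bilsk", "Cemetery B"),
    ("151-152", "Bilsk", "Marchenki 8th Field"),
    ("158", "Bilsk", "Tsarina"),
    ("181-182", "Bilsk", "Marchenki 9th Field"),
    ("185-186", "Mamai-Gora", ""),
    ("192", "Mamai-Gora", ""),
    ("200", "Mamai-Gora", ""),
    ("203", "Mamai-Gora", ""),
    ("220-221", "Mamai-Gora", ""),
]

#: individual -> [(peptide, primary accession, PSM copies)]
#: copies sum to the published per-protein PSM counts per individual
FIXTURE_PSM_SPEC: dict[str, list[tuple[str, str, int]]] = {
    "143": [
        ("TPEVDDEALEK", "BLG_BOS", 2), ("IPAVFK", "BLG_BOS", 2),
        ("VLVLDTDYK", "BLG_BOS", 2), ("IDALNENK", "BLG_OVIS", 1),
        ("ALPMHIR", "BLG_OVIS", 2),                      # BLG: 9
        ("LVSDLTEK", "BLG1_EQUUS", 2), ("ANIPQTMR", "BLG1_EQUUS", 2),
        ("ENSAEPEQSLVCQCLVR", "BLG1_EQUUS", 2), ("FTDSLAVR", "BLG1_EQUUS", 1),  # BLG-1: 7
        ("YLGYLEQLLR", "CASA1_BOS", 1), ("HQGLPQEVLNENLLR", "CASA1_BOS", 1),    # casein: 2
    ],
    "151-152": [
        ("YLGYLEQLLR", "CASA1_BOS", 1), ("HQGLPQEVLNENLLR", "CASA1_BOS", 1),    # casein: 2
    ],
    "181-182": [
        ("TPEVDDEALEK", "BLG_BOS", 2), ("VLVLDTDYK", "BLG_BOS", 1),
        ("IPAVFK", "BLG_BOS", 1),                        # BLG: 4
        ("YLGYLEQLLR", "CASA1_BOS", 1), ("EDVPSER", "CASA1_BOS", 1),
        ("HQGLPQEVLNENLLR", "CASA1_BOS", 1),             # casein: 3
    ],
    "192": [
        ("TPEVDDEALEK", "BLG_BOS", 1), ("IPAVFK", "BLG_BOS", 1),                # BLG: 2
    ],
    "203": [
        ("TPEVDDEALEK", "BLG_BOS", 2), ("VLVLDTDYK", "BLG_BOS", 1),
        ("GLDIQK", "BLG_BOS", 1), ("ENSAEPEQSLVCQCLVR", "BLG_BOS", 1),          # BLG: 5
        ("YLGYLEQLLR", "CASA1_BOS", 2), ("EDVPSER", "CASA1_BOS", 1),
        ("HQGLPQEVLNENLLR", "CASA1_BOS", 1),             # casein: 4
        ("AVLHPLEVR", "BTN1A1_BOS", 1), ("TLEPQSALK", "BTN1A1_BOS", 1),         # BTN1A1: 2
    ],
    "220-221": [
        ("TPEVDDEALEK", "BLG_BOS", 2), ("VLVLDTDYK", "BLG_BOS", 2),
        ("IPAVFK", "BLG_BOS", 1), ("GLDIQK", "BLG_BOS", 1),
        ("FNPTQLEGQCHVK", "BLG_CAPRA", 2),               # BLG: 8
        ("YLGYLEQLLR", "CASA1_BOS", 1), ("EDVPSER", "CASA1_BOS", 1),            # casein: 2
    ],
}


def make_worked_example() -> list[PsmRecord]:
    """Deterministic dietary PSM table matching the published per-protein counts."""
    site_of = {ind: (site, subsite) for ind, site, subsite in FIXTURE_INDIVIDUALS}
    psms: list[PsmRecord] = []
    for individual, rows in FIXTURE_PSM_SPEC.items():
        site, subsite = site_of[individual]
        k = 0
        for peptide, acc, copies in rows:
            for _ in range(copies):
                charge = 2
                psm = PsmRecord(
                    sample_id=individual, individual_id=individual,
                    site=site, subsite=subsite,
                    spectrum_ref=f"fx_{individual}_{k:03d}",
                    peptide=peptide, modifications=(), accessions=(acc,),
                    ion_score=float(48 + (k % 5) * 7), e_value=5e-4,
                    is_decoy=False,
                    precursor_mz=peptide_precursor_mz(peptide, (), charge),
                    charge=charge,
                )
                psm.validate()
                psms.append(psm)
                k += 1
    return psms
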