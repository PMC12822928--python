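"""Domain types and file I/O for the calculus-proteome pipeline.

The canonical exchange format is a tab-separated PSM table (one row per
peptide-spectrum match) carrying sample/individual/site provenance, the
peptide, its variable modifications, the matched protein accessions, the
search-engine ion score and e-value, a decoy flag and precursor information.
MS2 spectra travel as MGF; reference accession lists and homolog rules as
YAML; the dietary protein database as FASTA with a lineage sidecar TSV.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

MOD_NAMES = ("Carbamidomethyl", "Oxidation", "Deamidated")

#: residues each variable modification may sit on
MOD_TARGETS = {
    "Carbamidomethyl": {"C"},
    "Oxidation": {"M", "P"},
    "Deamidated": {"N", "Q"},
}

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class ConfigurationError(ValueError):
    """Input file or configuration is structurally unusable."""


class RowError(ValueError):
    """A single table row violates the record contract."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with provenance labels."""

    sample_id: str
    individual_id: str
    site: str
    spectrum_ref: str
    peptide: str
    modifications: tuple[tuple[int, str], ...]
    accessions: tuple[str, ...]
    ion_score: float
    e_value: float
    is_decoy: bool
    precursor_mz: float
    charge: int
    subsite: str = ""

    @property
    def primary_accession(self) -> str:
        return self.accessions[0]

    @property
    def peptidoform(self) -> tuple[str, tuple[tuple[int, str], ...]]:
        """Distinct-peptide key: sequence plus sorted modification set."""
        return self.peptide, tuple(sorted(self.modifications))

    def validate(self) -> None:
        if not self.peptide or set(self.peptide) - AMINO_ACIDS:
            raise ValueError(f"peptide {self.peptide!r} is not an uppercase amino-acid string")
        if not self.accessions:
            raise ValueError("accessions must be non-empty")
        if self.e_value <= 0:
            raise ValueError(f"e_value must be > 0, got {self.e_value}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for pos, name in self.modifications:
            if name not in MOD_TARGETS:
                raise ValueError(f"unknown modification {name!r}")
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"modification position {pos} outside peptide of length {len(self.peptide)}"
                )
            residue = self.peptide[pos - 1]
            if residue not in MOD_TARGETS[name]:
                raise ValueError(
                    f"{name} at position {pos} sits on {residue}, "
                    f"allowed residues: {sorted(MOD_TARGETS[name])}"
                )


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 spectrum; peaks sorted by ascending m/z."""

    spectrum_ref: str
    precursor_mz: float
    charge: int
    peaks: tuple[tuple[float, float], ...]

    def validate(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak m/z values must be strictly increasing")
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("peak intensities must be non-negative")


@dataclass
class ReferenceSets:
    """Accession compilations driving classification, plus the dietary DB."""

    oral_microbiome: set[str] = field(default_factory=set)
    salivary: set[str] = field(default_factory=set)
    common_contaminants: set[str] = field(default_factory=set)
    lab_contaminants: set[str] = field(default_factory=set)
    #: accession -> (protein_name, sequence, lineage as tuple of node names)
    dietary: dict[str, tuple[str, str, tuple[str, ...]]] = field(default_factory=dict)
    exclusion_accessions: set[str] = field(default_factory=set)
    reassignment_rules: dict[str, str] = field(default_factory=dict)

    def protein_name(self, accession: str) -> str:
        entry = self.dietary.get(accession)
        return entry[0] if entry else accession


@dataclass
class TaxonomyTree:
    """Rooted taxonomy; nodes map name -> (rank, parent or None)."""

    nodes: dict[str, tuple[str, str | None]]

    def validate(self) -> None:
        roots = [n for n, (_, parent) in self.nodes.items() if parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for name in self.nodes:
            self.path_to_root(name)  # raises on cycles / missing parents

    @property
    def root(self) -> str:
        return next(n for n, (_, p) in self.nodes.items() if p is None)

    def rank(self, name: str) -> str:
        return self.nodes[name][0]

    def path_to_root(self, name: str) -> list[str]:
        """Node names from ``name`` up to and including the root."""
        path: list[str] = []
        seen: set[str] = set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in taxonomy at {cur!r}")
            if cur not in self.nodes:
                raise ValueError(f"taxon {cur!r} absent from tree")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur][1]
        return path

    def lca(self, names: Iterable[str]) -> str:
        """Lowest common ancestor by root-path intersection."""
        names = list(names)
        if not names:
            raise ValueError("lca of empty taxon set")
        common: list[str] | None = None
        for name in names:
            path = self.path_to_root(name)[::-1]  # root first
            if common is None:
                common = path
            else:
                keep = 0
                for a, b in zip(common, path):
                    if a != b:
                        break
                    keep += 1
                common = common[:keep]
        assert common
        return common[-1]

    def is_at_or_above(self, node: str, ceiling: str) -> bool:
        """True when ``node`` equals ``ceiling`` or is one of its ancestors."""
        return node in self.path_to_root(ceiling)


@dataclass
class PipelineConfig:
    """Thresholds for every pipeline stage (all bounds inclusive)."""

    e_value_max: float = 0.01
    min_psm_per_protein: int = 2
    protein_fdr_max_pct: float = 5.0
    peptide_fdr_max_pct: float = 2.0
    auth_threshold: float = 0.5
    ion_score_validation_cutoff: float = 40.0
    pearson_threshold_unmodified: float = 0.70
    pearson_threshold_oxidized: float = 0.60
    fragment_match_tol_da: float = 0.01
    precursor_strip_halfwidth_mz: float = 1.0
    random_seed: int = 0

    def validate(self) -> None:
        for name in (
            "e_value_max", "min_psm_per_protein", "protein_fdr_max_pct",
            "peptide_fdr_max_pct", "auth_threshold", "ion_score_validation_cutoff",
            "fragment_match_tol_da", "precursor_strip_halfwidth_mz",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("pearson_threshold_unmodified", "pearson_threshold_oxidized"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [-1, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------

PSM_COLUMNS = [
    "sample_id", "individual_id", "site", "subsite", "spectrum_ref", "peptide",
    "modifications", "accessions", "ion_score", "e_value", "is_decoy",
    "precursor_mz", "charge",
]

#: Mascot CSV export column names mapped onto the canonical schema.
MASCOT_COLUMN_MAP = {
    "pep_seq": "peptide",
    "pep_var_mod": "modifications",
    "prot_acc": "accessions",
    "pep_score": "ion_score",
    "pep_expect": "e_value",
    "pep_scan_title": "spectrum_ref",
    "pep_exp_mz": "precursor_mz",
    "pep_exp_z": "charge",
}


def _parse_modifications(token: str, row: int) -> tuple[tuple[int, str], ...]:
    token = token.strip()
    if not token:
        return ()
    mods = []
    for part in token.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            name, pos = part.split(":")
            mods.append((int(pos), name.strip()))
        except ValueError as exc:
            raise RowError(row, f"malformed modification token {part!r}") from exc
    return tuple(mods)


def format_modifications(mods: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{name}:{pos}" for pos, name in mods)


def read_psm_table(path: str | Path, dialect: str = "generic_tsv") -> list[PsmRecord]:
    """Read a PSM table; rows violating the record contract raise RowError."""
    import pandas as pd

    path = Path(path)
    if dialect == "generic_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif dialect == "mascot_csv":
        df = pd.read_csv(path, sep=",", dtype=str, keep_default_na=False)
        df = df.rename(columns=MASCOT_COLUMN_MAP)
        if "is_decoy" not in df.columns and "accessions" in df.columns:
            df["is_decoy"] = [
                str(acc.split(";")[0].startswith("DECOY_")) for acc in df["accessions"]
            ]
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"PSM table {path} missing columns: {missing}")

    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = row._asdict()
        try:
            rec = PsmRecord(
                sample_id=row["sample_id"],
                individual_id=row["individual_id"],
                site=row["site"],
                subsite=row["subsite"],
                spectrum_ref=row["spectrum_ref"],
                peptide=row["peptide"].strip().upper(),
                modifications=_parse_modifications(row["modifications"], i),
                accessions=tuple(a for a in row["accessions"].split(";") if a),
                ion_score=float(row["ion_score"]),
                e_value=float(row["e_value"]),
                is_decoy=str(row["is_decoy"]).strip().lower() in ("true", "1", "yes"),
                precursor_mz=float(row["precursor_mz"]),
                charge=int(row["charge"]),
            )
            rec.validate()
        except RowError:
            raise
        except (ValueError, KeyError) as exc:
            raise RowError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    lines = ["\t".join(PSM_COLUMNS)]
    for p in psms:
        lines.append("\t".join([
            p.sample_id, p.individual_id, p.site, p.subsite, p.spectrum_ref,
            p.peptide, format_modifications(p.modifications),
            ";".join(p.accessions), repr(p.ion_score), repr(p.e_value),
            str(p.is_decoy), repr(p.precursor_mz), str(p.charge),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> dict[str, Spectrum]:
    """Read an MGF file into a mapping spectrum title -> Spectrum."""
    spectra: dict[str, Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = params.get("title")
            if title is None:
                raise ConfigurationError(f"MGF block {i}: missing TITLE")
            if "pepmass" not in params:
                raise ConfigurationError(f"MGF block {i} ({title!r}): missing PEPMASS")
            if title in spectra:
                raise ConfigurationError(f"duplicate MGF TITLE {title!r}")
            charge = int(params["charge"][0]) if params.get("charge") else 0
            peaks = sorted(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spec = Spectrum(
                spectrum_ref=title,
                precursor_mz=float(params["pepmass"][0]),
                charge=charge,
                peaks=tuple(peaks),
            )
            spec.validate()
            spectra[title] = spec
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        import numpy as np
        entries.append({
            "m/z array": np.array([p[0] for p in s.peaks]),
            "intensity array": np.array([p[1] for p in s.peaks]),
            "params": {
                "title": s.spectrum_ref,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# reference sets
# ---------------------------------------------------------------------------

#: precedence when an accession appears in several compilations
#: (contamination wins ties — conservative authentication)
CATEGORY_PRECEDENCE = [
    "lab_contaminant", "common_contaminant", "oral_microbiome", "salivary", "dietary",
]

_LIST_KEYS = {
    "oral_microbiome": "oral_microbiome",
    "salivary": "salivary",
    "common_contaminants": "common_contaminant",
    "lab_contaminants": "lab_contaminant",
}


def load_reference_sets(
    fasta: str | Path,
    lists: str | Path,
    taxonomy: str | Path,
    lineages: str | Path | None = None,
) -> tuple[ReferenceSets, TaxonomyTree]:
    """Load accession lists (YAML), dietary FASTA + lineage sidecar, taxonomy TSV.

    When an accession appears in more than one category list the highest
    precedence category wins and a warning is logged.
    """
    fasta = Path(fasta)
    if lineages is None:
        lineages = fasta.with_suffix(".lineages.tsv")

    tree = read_taxonomy(taxonomy)

    raw = yaml.safe_load(Path(lists).read_text()) or {}
    refs = ReferenceSets()
    assigned: dict[str, str] = {}
    by_precedence = sorted(
        _LIST_KEYS.items(), key=lambda kv: CATEGORY_PRECEDENCE.index(kv[1])
    )
    for key, category in by_precedence:
        for acc in raw.get(key, []) or []:
            if acc in assigned:
                logger.warning(
                    "accession %s listed as %s and %s; keeping %s (precedence)",
                    acc, assigned[acc], category, assigned[acc],
                )
                continue
            assigned[acc] = category
            getattr(refs, key).add(acc)

    refs.exclusion_accessions = set(raw.get("exclusions", []) or [])
    refs.reassignment_rules = dict(raw.get("reassignments", {}) or {})

    lineage_map: dict[str, tuple[str, tuple[str, ...]]] = {}
    lineage_path = Path(lineages)
    if lineage_path.exists():
        lineage_map = read_lineage_table(lineage_path)

    for record in SeqIO.parse(str(fasta), "fasta"):
        acc = record.id
        seq = str(record.seq).upper()
        if set(seq) - AMINO_ACIDS:
            raise ConfigurationError(f"dietary sequence {acc} is not an amino-acid string")
        if acc not in lineage_map:
            raise ConfigurationError(f"dietary accession {acc} missing from lineage table")
        name, lineage = lineage_map[acc]
        for node in lineage:
            if node not in tree.nodes:
                raise ConfigurationError(
                    f"lineage node {node!r} of {acc} absent from taxonomy tree"
                )
        root_path = tree.path_to_root(lineage[-1])[::-1]
        if list(lineage) != root_path:
            raise ConfigurationError(
                f"lineage of {acc} is not the root-to-node path of {lineage[-1]!r}"
            )
        if acc in assigned:
            logger.warning(
                "dietary accession %s already categorized as %s; keeping %s",
                acc, assigned[acc], assigned[acc],
            )
            continue
        refs.dietary[acc] = (name, seq, lineage)

    for acc, target in refs.reassignment_rules.items():
        names = {entry[0] for entry in refs.dietary.values()}
        if target not in names:
            raise ConfigurationError(
                f"reassignment target {target!r} for {acc} absent from dietary database"
            )
    return refs, tree


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    nodes: dict[str, tuple[str, str | None]] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[:2] != ["name", "rank"]:
        raise ConfigurationError("taxonomy TSV must have columns name, rank, parent")
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        name, rank = parts[0], parts[1]
        parent = parts[2] if len(parts) > 2 and parts[2] else None
        nodes[name] = (rank, parent)
    tree = TaxonomyTree(nodes)
    tree.validate()
    return tree


def read_lineage_table(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        acc, name, lineage = line.split("\t")
        out[acc] = (name, tuple(lineage.split(">")))
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
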