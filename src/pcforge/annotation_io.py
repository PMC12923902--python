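"""Input layer: genome annotation, kcat and complex-stoichiometry tables.

Reads the four tabular/sequence inputs a proteome-constrained model build
needs — a genome-scale metabolic model (SBML, via cobrapy), a gene
annotation (flat TSV, or GFF3 + genome FASTA), a turnover-number table and
a complex-stoichiometry table — and derives the quantities reconstruction
consumes: nucleotide/peptide sequences, molecular weights, per-enzyme
turnover numbers after the default/floor policy.

Conventions
-----------
* Genomic coordinates are 1-based inclusive; strand ``-`` means the reverse
  complement of the top strand.
* Molecular weights are average (not monoisotopic) masses in g/mmol
  (numerically Da). The residue tables are versioned module constants so
  tests and the analytic oracle share one source of truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import pandas as pd

__all__ = [
    "GeneRecord",
    "KcatEntry",
    "ComplexDefinition",
    "extract_gene_sequence",
    "reverse_complement",
    "apply_kcat_policy",
    "peptide_mw",
    "rna_mw",
    "read_gem",
    "read_annotation_tsv",
    "read_annotation_gff",
    "read_kcat_tsv",
    "read_complex_tsv",
    "DEFAULT_KCAT_PER_S",
    "KCAT_FLOOR_PER_S",
    "RESIDUE_TABLE_VERSION",
    "AA_RESIDUE_MASS",
    "WATER_MASS",
    "NMP_MASS",
]

# ---------------------------------------------------------------------------
# Residue-mass tables (average masses, g/mmol). Version bumps whenever a
# value changes so downstream oracles can assert consistency.
# ---------------------------------------------------------------------------

RESIDUE_TABLE_VERSION = "avg-2024.1"

WATER_MASS = 18.0153

#: Average residue (amino acid minus water) masses.
AA_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Average nucleoside-5'-monophosphate masses (T is read as U).
NMP_MASS = {"A": 347.2212, "C": 323.1965, "G": 363.2206, "U": 324.1813}

DEFAULT_KCAT_PER_S = 5.0   # median of curated turnover numbers
KCAT_FLOOR_PER_S = 0.75    # floor applied to curated values below it

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class InputError(ValueError):
    """Fatal problem in one of the user-supplied input files."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """One annotated genomic feature (CDS, tRNA or rRNA gene).

    ``start``/``end`` are 1-based inclusive. ``peptide_seq`` is non-empty
    exactly for CDS features. ``is_up`` marks the unspecific-protein
    pseudo-gene, which behaves like a CDS but is excluded from enzyme
    complexes.
    """

    locus_tag: str
    feature_type: str  # CDS | tRNA | rRNA
    start: int
    end: int
    strand: str  # + | -
    nucleotide_seq: str = ""
    peptide_seq: str = ""
    is_up: bool = False
    #: amino-acid class served (tRNA features only); one charging reaction
    #: is built per class.
    aa_class: str = ""

    def __post_init__(self) -> None:
        if self.feature_type not in ("CDS", "tRNA", "rRNA"):
            raise InputError(
                f"{self.locus_tag}: unknown feature type {self.feature_type!r}"
            )
        if self.start > self.end or self.start < 1:
            raise InputError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.locus_tag}: strand must be '+' or '-'")
        if (self.feature_type == "CDS") != bool(self.peptide_seq):
            raise InputError(
                f"{self.locus_tag}: peptide sequence must be present exactly "
                "for CDS features"
            )


@dataclass
class KcatEntry:
    """One curated turnover number for (reaction, enzyme complex)."""

    reaction_id: str
    enzyme_id: str
    kcat: float  # s^-1
    tier: str = "default"
    keep_raw: bool = False


@dataclass
class ComplexDefinition:
    """Subunit composition of one enzyme complex; ``mw`` in g/mmol."""

    complex_id: str
    subunits: list[tuple[str, int]] = field(default_factory=list)
    mw: float = 0.0

    def compute_mw(self, peptide_mws: dict[str, float]) -> float:
        """Set ``mw`` = sum of copies x subunit peptide MW."""
        try:
            self.mw = sum(n * peptide_mws[tag] for tag, n in self.subunits)
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(
                f"complex {self.complex_id}: unknown subunit {exc.args[0]}"
            ) from exc
        return self.mw


# ---------------------------------------------------------------------------
# Sequences and masses
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene_sequence(genome: str, record: GeneRecord) -> str:
    """Slice a feature's nucleotide sequence out of the genome.

    Returns the top-strand slice for ``+`` features and its reverse
    complement for ``-`` features (1-based inclusive coordinates).
    """
    if not (1 <= record.start <= record.end <= len(genome)):
        raise InputError(
            f"{record.locus_tag}: coordinates {record.start}..{record.end} "
            f"outside genome of length {len(genome)}"
        )
    seq = genome[record.start - 1 : record.end]
    return reverse_complement(seq) if record.strand == "-" else seq


def peptide_mw(peptide_seq: str) -> float:
    """Average molecular weight of a peptide in g/mmol (residues + one water)."""
    if not peptide_seq:
        raise InputError("empty peptide sequence")
    try:
        return sum(AA_RESIDUE_MASS[a] for a in peptide_seq) + WATER_MASS
    except KeyError as exc:
        raise InputError(f"unknown amino acid {exc.args[0]!r}") from exc


def rna_mw(nucleotide_seq: str) -> float:
    """Average molecular weight of an RNA in g/mmol.

    5'-monophosphate convention: sum of NMP masses minus one condensation
    water per phosphodiester bond. ``T`` in the input is read as ``U``.
    """
    if not nucleotide_seq:
        raise InputError("empty nucleotide sequence")
    seq = nucleotide_seq.upper().replace("T", "U")
    try:
        total = sum(NMP_MASS[n] for n in seq)
    except KeyError as exc:
        raise InputError(f"unknown nucleotide {exc.args[0]!r}") from exc
    return total - (len(seq) - 1) * WATER_MASS


# ---------------------------------------------------------------------------
# kcat policy
# ---------------------------------------------------------------------------

def apply_kcat_policy(
    raw: list[KcatEntry],
    all_enzymes: list[str],
    default: float = DEFAULT_KCAT_PER_S,
    floor: float = KCAT_FLOOR_PER_S,
) -> dict[str, float]:
    """Resolve a complete enzyme -> kcat (s^-1) mapping.

    Enzymes with no curated entry get ``default`` (5 s^-1, the median of the
    curated values); curated values below ``floor`` (0.75 s^-1) are raised to
    the floor unless the entry is flagged ``keep_raw`` (used for genuinely
    slow enzymes such as CODH at 0.002 s^-1). Non-positive raw values are
    rejected with a warning and treated as absent. Idempotent.
    """
    resolved: dict[str, float] = {}
    for entry in raw:
        if entry.kcat <= 0:
            warnings.warn(
                f"non-positive kcat for {entry.enzyme_id} "
                f"({entry.kcat} /s); treating as absent",
                stacklevel=2,
            )
            continue
        kcat = entry.kcat
        if kcat < floor and not entry.keep_raw:
            kcat = floor
        resolved[entry.enzyme_id] = kcat
    for enzyme in all_enzymes:
        resolved.setdefault(enzyme, default)
    return resolved


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def read_gem(path: str | Path) -> cobra.Model:
    """Read a genome-scale model from SBML (Level 3 + fbc)."""
    return cobra.io.read_sbml_model(str(path))


_ANNOTATION_COLUMNS = {"locus_tag", "type", "start", "end", "strand", "seq"}


def read_annotation_tsv(path: str | Path) -> list[GeneRecord]:
    """Read the flat gene-annotation table.

    Columns: ``locus_tag, type, start, end, strand, seq`` plus optional
    ``peptide_seq`` and ``is_up``. ``seq`` is the already strand-corrected
    nucleotide sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = _ANNOTATION_COLUMNS - set(df.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                locus_tag=row.locus_tag,
                feature_type=row.type,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                nucleotide_seq=row.seq or "",
                peptide_seq=(getattr(row, "peptide_seq", "") or "")
                if row.type == "CDS"
                else "",
                is_up=str(getattr(row, "is_up", "")).lower()
                in ("1", "true", "yes"),
                aa_class=(getattr(row, "aa_class", "") or "")
                if row.type == "tRNA"
                else "",
            )
        )
    return records


_GENETIC_CODE: dict[str, str] = {}


def _translate(cds: str) -> str:
    """Standard-code translation, dropping the terminal stop if present."""
    from Bio.Seq import Seq

    pep = str(Seq(cds).translate(table=1))
    return pep[:-1] if pep.endswith("*") else pep


def read_annotation_gff(
    gff_path: str | Path, fasta_path: str | Path
) -> list[GeneRecord]:
    """Read annotation from GFF3 + genome FASTA.

    Keeps CDS/tRNA/rRNA features only; sequences are extracted from the
    genome (strand-corrected) and CDS features are translated with the
    standard code.
    """
    from Bio import SeqIO

    genomes = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records: list[GeneRecord] = []
    with open(gff_path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise InputError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("CDS", "tRNA", "rRNA"):
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            tag = attr_map.get("locus_tag") or attr_map.get("ID")
            if tag is None:
                raise InputError(f"GFF3 feature without locus_tag/ID: {line!r}")
            if seqid not in genomes:
                raise InputError(f"{tag}: sequence {seqid!r} not in FASTA")
            rec = GeneRecord(
                locus_tag=tag,
                feature_type=ftype,
                start=int(start),
                end=int(end),
                strand=strand,
                nucleotide_seq="",
                peptide_seq="M" if ftype == "CDS" else "",  # placeholder
            )
            rec.nucleotide_seq = extract_gene_sequence(genomes[seqid], rec)
            rec.peptide_seq = (
                _translate(rec.nucleotide_seq) if ftype == "CDS" else ""
            )
            records.append(rec)
    return records


def read_kcat_tsv(path: str | Path) -> list[KcatEntry]:
    """Read the turnover-number table (reaction_id, enzyme_id, kcat_per_s,
    tier, keep_raw)."""
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "enzyme_id", "kcat_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"kcat table missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            KcatEntry(
                reaction_id=str(row.reaction_id),
                enzyme_id=str(row.enzyme_id),
                kcat=float(row.kcat_per_s),
                tier=str(getattr(row, "tier", "default")),
                keep_raw=bool(getattr(row, "keep_raw", False)),
            )
        )
    return entries


def read_complex_tsv(path: str | Path) -> list[ComplexDefinition]:
    """Read the complex-stoichiometry table (complex_id, locus_tag, copies)."""
    df = pd.read_csv(path, sep="\t")
    required = {"complex_id", "locus_tag", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"complex table missing columns: {sorted(missing)}")
    out: dict[str, ComplexDefinition] = {}
    for row in df.itertuples(index=False):
        copies = int(row.copies)
        if copies < 1:
            raise InputError(
                f"complex {row.complex_id}: copies must be >= 1, got {copies}"
            )
        cdef = out.setdefault(
            str(row.complex_id), ComplexDefinition(str(row.complex_id))
        )
        cdef.subunits.append((str(row.locus_tag), copies))
    return list(out.values())
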