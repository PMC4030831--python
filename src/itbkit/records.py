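"""Domain records and file/fixture I/O.

The central objects are :class:`ProteinRecord` (one accessioned amino-acid
sequence with a species and family label), :class:`GeneModel` (a gene locus
with 1-based inclusive coordinates), and :class:`DomainAnnotation` (a labelled
residue interval on a protein).  Family labels (ITB1..ITB8 or OUTGROUP) always
come from metadata, never from the sequence itself: they are curated
assignments, not predictions.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

FAMILIES = ("ITB1", "ITB2", "ITB3", "ITB4", "ITB5", "ITB6", "ITB7", "ITB8", "OUTGROUP")

# 20 standard residues plus X for ambiguity.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

DOMAIN_CLASSES = (
    "signal_peptide",
    "integrin_beta",
    "cysteine_rich",
    "beta_tail",
    "transmembrane",
    "cytoplasmic",
    "FN3",
    "calx_beta",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its accession, species and family label."""

    id: str
    sequence: str
    species: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        if self.family is not None and self.family not in FAMILIES:
            raise ValueError(f"record {self.id!r}: unknown family {self.family!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with 1-based inclusive genomic coordinates."""

    gene_symbol: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    coding_exons: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_symbol}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_symbol}: strand must be '+' or '-'")
        if self.coding_exons < 1:
            raise ValueError(f"{self.gene_symbol}: coding_exons must be >= 1")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainAnnotation:
    """A labelled residue interval (1-based inclusive) on a protein record."""

    record_id: str
    domain_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.record_id}/{self.domain_class}: bad interval "
                f"[{self.start}, {self.end}]"
            )


def read_fasta(path: str | Path, metadata: dict[str, dict] | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated ProteinRecords.

    The first whitespace-delimited header token is the record id.  Sequences
    are uppercased and trailing '*' terminators stripped.  ``metadata`` maps
    id -> {"species": ..., "family": ...} (typically from
    :func:`read_metadata_tsv`); ids absent from the map get empty species and
    no family.

    Raises ``ValueError`` on an empty file or on residues outside the 20
    standard letters plus X, naming the offending position.
    """
    metadata = metadata or {}
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        meta = metadata.get(entry.id, {})
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=seq,
                species=meta.get("species", ""),
                family=meta.get("family"),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_metadata_tsv(path: str | Path) -> dict[str, dict]:
    """Read an id/species/family(/gene_symbol) metadata table keyed by id."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for row in csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        ):
            out[row["id"]] = {
                "species": row.get("species", ""),
                "family": row.get("family") or None,
                "gene_symbol": row.get("gene_symbol", ""),
            }
    return out


_COORD_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<a>[\d,]+)-(?P<b>[\d,]+)$")


@dataclass(frozen=True)
class GeneTableRow:
    """One row of the packaged gene-summary fixture.

    ``printed_kb`` is the gene size as printed in the source table;
    ``self_consistent`` records whether that size agrees with the row's own
    coordinates (a handful of printed rows do not).  Rows printed with
    descending coordinates (minus-strand convention) are normalised so that
    ``gene.start <= gene.end``.
    """

    animal: str
    gene: str
    family: str
    printed_kb: float | None
    subunit_mw: int
    amino_acids: int
    ncbi_id: str
    uniprot_id: str | None
    gene_model: GeneModel | None

    @property
    def self_consistent(self) -> bool:
        if self.gene_model is None or self.printed_kb is None:
            return False
        from .metrics import gene_span_kb

        return gene_span_kb(self.gene_model) == self.printed_kb


def parse_coordinates(text: str) -> tuple[str, int, int]:
    """Parse a printed ``chromosome:start-end`` string (commas allowed).

    Descending start/end are swapped so the returned interval is ascending.
    """
    m = _COORD_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unparseable coordinate string: {text!r}")
    a = int(m.group("a").replace(",", ""))
    b = int(m.group("b").replace(",", ""))
    return m.group("chrom"), min(a, b), max(a, b)


def load_gene_table(path: str | Path | None = None) -> list[GeneTableRow]:
    """Load the packaged vertebrate beta-integrin gene summary fixture."""
    if path is None:
        source = resources.files("itbkit.data").joinpath("table1_genes.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = []
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for raw in csv.DictReader(lines, delimiter="\t"):
        model = None
        if raw["coordinates"] != "na":
            chrom, start, end = parse_coordinates(raw["coordinates"])
            model = GeneModel(
                gene_symbol=raw["gene_symbol"],
                species=raw["species"],
                chromosome=chrom,
                start=start,
                end=end,
                strand=raw["strand"],
                coding_exons=int(raw["coding_exons"]),
            )
        rows.append(
            GeneTableRow(
                animal=raw["animal"],
                gene=raw["gene"],
                family=raw["family"],
                printed_kb=None if raw["printed_kb"] == "na" else float(raw["printed_kb"]),
                subunit_mw=int(raw["subunit_mw"]),
                amino_acids=int(raw["amino_acids"]),
                ncbi_id=raw["ncbi_id"],
                uniprot_id=None if raw["uniprot_id"] == "na" else raw["uniprot_id"],
                gene_model=model,
            )
        )
    return rows
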