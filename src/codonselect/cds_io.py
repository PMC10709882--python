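"""Reading, admission filtering and translation of coding sequences.

A CDS is admitted to the analysis only if it exceeds a minimum length
(default 300 bp, strict), starts with ATG, ends with a stop codon
(TGA/TAG/TAA), has length divisible by 3, contains no in-frame internal stop
and no ambiguous base.  Rejection is a recorded outcome, not an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STOP_CODONS, codons_of

__all__ = [
    "CdsRecord",
    "FilterReport",
    "read_fasta",
    "write_fasta",
    "filter_cds",
    "translate",
    "DuplicateIdError",
    "InternalStopError",
]

#: rejection reason codes, in the order they are checked
REASON_CODES = (
    "TOO_SHORT",
    "NO_ATG_START",
    "NO_VALID_STOP",
    "LEN_NOT_MULTIPLE_OF_3",
    "INTERNAL_STOP",
    "AMBIGUOUS_BASE",
)

_NON_ACGTN = re.compile(r"[^ACGTN]")


class DuplicateIdError(ValueError):
    """Two records within one species share a gene_id."""


class InternalStopError(ValueError):
    """An in-frame stop codon occurs before the terminal codon."""


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence: identity, species scope and uppercase DNA."""

    gene_id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.gene_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FilterReport:
    """Outcome of CDS admission: kept records plus (gene_id, reason) rejects."""

    kept: list[CdsRecord] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstatus\treason\n")
            for rec in self.kept:
                fh.write(f"{rec.gene_id}\tkept\t.\n")
            for gene_id, reason in self.rejected:
                fh.write(f"{gene_id}\trejected\t{reason}\n")


def _normalize(seq: str) -> str:
    """Uppercase, U->T, any other ambiguity code -> N."""
    s = seq.upper().replace("U", "T")
    return _NON_ACGTN.sub("N", s)


def read_fasta(path: str | Path, species: str = "") -> list[CdsRecord]:
    """Read a nucleotide multi-FASTA into CdsRecords.

    The header token before the first whitespace becomes the gene_id.
    Sequences are uppercased with U mapped to T and non-ACGTN codes mapped
    to N.  Duplicate ids within the file raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[CdsRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise DuplicateIdError(f"DUPLICATE_ID: {gene_id!r} in {path}")
        seen.add(gene_id)
        records.append(CdsRecord(gene_id, species, _normalize(str(entry.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[CdsRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.gene_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _rejection_reason(seq: str, min_len_bp: int) -> str | None:
    if len(seq) <= min_len_bp:  # "exceeding" read strictly
        return "TOO_SHORT"
    if not seq.startswith("ATG"):
        return "NO_ATG_START"
    if seq[-3:] not in STOP_CODONS:  # literal 3'-terminal triplet
        return "NO_VALID_STOP"
    if len(seq) % 3 != 0:
        return "LEN_NOT_MULTIPLE_OF_3"
    codons = codons_of(seq)
    if any(c in STOP_CODONS for c in codons[:-1] if "N" not in c):
        return "INTERNAL_STOP"
    if "N" in seq:
        return "AMBIGUOUS_BASE"
    return None


def filter_cds(records: list[CdsRecord], min_len_bp: int = 300) -> FilterReport:
    """Apply the six CDS admission rules; first failing rule is recorded."""
    report = FilterReport()
    for rec in records:
        reason = _rejection_reason(rec.seq, min_len_bp)
        if reason is None:
            report.kept.append(rec)
        else:
            report.rejected.append((rec.gene_id, reason))
    return report


def translate(record: CdsRecord | str) -> str:
    """Translate a filtered CDS with the standard code; terminal stop dropped."""
    seq = record.seq if isinstance(record, CdsRecord) else record
    if len(seq) % 3:
        raise ValueError("length not divisible by 3")
    coding = seq[:-3] if seq[-3:] in STOP_CODONS else seq
    protein = str(Seq(coding).translate(table=1))
    if "*" in protein:
        gene = record.gene_id if isinstance(record, CdsRecord) else "<seq>"
        raise InternalStopError(f"INTERNAL_STOP in {gene}")
    return protein
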