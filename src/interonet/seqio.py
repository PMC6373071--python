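"""Protein lists and sequences: the identifier space the whole pipeline keys on.

Inputs are plain-text accession lists (one accession per line) and FASTA
files whose headers carry the accession either as the whole ID token or as
the second pipe-delimited field of a UniProt-style header
(``sp|P12345|NAME``).  Accessions are matched case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino acids.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes accepted on input (B, Z, X) plus selenocysteine (U).
AMBIGUOUS = "BZXU"
VALID_RESIDUES = frozenset(AA20 + AMBIGUOUS)


class SequenceError(ValueError):
    """Raised for sequences outside the accepted amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: species label, accession, and amino-acid sequence."""

    species_id: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise SequenceError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise SequenceError(
                f"{self.accession}: invalid residue(s) {sorted(bad)!r}; "
                f"accepted alphabet is the 20 amino acids plus {AMBIGUOUS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesProteome:
    """All loaded proteins of one species, keyed by accession."""

    species_id: str
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self.records:
            raise ValueError(
                f"duplicate accession {record.accession!r} in species "
                f"{self.species_id!r}"
            )
        self.records[record.accession] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records.values())

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    @property
    def accessions(self) -> list[str]:
        return list(self.records)


def read_accession_list(path: str | Path) -> list[str]:
    """Read a one-accession-per-line list.

    Blank lines and ``#`` comment lines are ignored; duplicates are dropped
    keeping the first occurrence (with a warning).  An empty result is an
    error.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    duplicates: list[str] = []
    for raw in path.read_text().splitlines():
        token = raw.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            duplicates.append(token)
        else:
            seen[token] = None
    if duplicates:
        log.warning(
            "%s: %d duplicate accession(s) ignored: %s",
            path, len(duplicates), ", ".join(duplicates),
        )
    if not seen:
        raise ValueError(f"empty accession list: {path}")
    return list(seen)


def _header_keys(record_id: str) -> list[str]:
    """Accession candidates for a FASTA ID token.

    The whole token always matches; for pipe-delimited UniProt headers the
    second field (the accession proper) matches too.
    """
    keys = [record_id]
    if "|" in record_id:
        parts = record_id.split("|")
        if len(parts) >= 2 and parts[1]:
            keys.append(parts[1])
    return keys


def _normalize(seq: str) -> str:
    return seq.upper().rstrip("*")


def read_proteome(
    fasta_path: str | Path,
    accessions: Sequence[str],
    species_id: str | None = None,
    strict: bool = False,
) -> SpeciesProteome:
    """Load the requested accessions from a FASTA file.

    Sequences are uppercased and a trailing stop (``*``) is stripped.
    Requested accessions absent from the file are dropped with a warning,
    or raise when ``strict`` is set.  A FASTA file offering two entries for
    one accession is always an error ("ambiguous sequence").
    """
    fasta_path = Path(fasta_path)
    if species_id is None:
        species_id = fasta_path.stem
    wanted = set(accessions)
    found: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        matches = [k for k in _header_keys(rec.id) if k in wanted]
        for acc in set(matches):
            if acc in found:
                raise ValueError(
                    f"ambiguous sequence: accession {acc!r} matches more "
                    f"than one entry in {fasta_path}"
                )
            found[acc] = _normalize(str(rec.seq))

    missing = [a for a in accessions if a not in found]
    if missing:
        msg = (
            f"{fasta_path}: {len(missing)} accession(s) not found: "
            + ", ".join(missing)
        )
        if strict:
            raise ValueError(msg)
        log.warning(msg)
    if not found:
        raise ValueError(f"no requested accession matched any entry in {fasta_path}")

    proteome = SpeciesProteome(species_id=species_id)
    for acc in accessions:  # preserve the list order
        if acc in found:
            proteome.add(ProteinRecord(species_id, acc, found[acc]))
    return proteome


def write_fasta(proteome: SpeciesProteome, path: str | Path) -> Path:
    """Write a proteome back to FASTA (plain ``>accession`` headers)."""
    path = Path(path)
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
        for rec in proteome
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path


def check_species_count(proteomes: Iterable[SpeciesProteome]) -> None:
    """An analysis spans two to four species."""
    n = len(list(proteomes))
    if not 2 <= n <= 4:
        raise ValueError(f"analysis requires 2-4 species, got {n}")
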