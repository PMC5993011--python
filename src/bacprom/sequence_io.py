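"""FASTA I/O, genome container, and strand arithmetic.

Coordinate conventions used throughout the package:

* annotation tables (external input) use 1-based inclusive positions,
  the convention of curated prokaryotic promoter databases;
* every internal coordinate is 0-based half-open.  The conversion
  happens exactly once, at annotation parse time.

Residue strings are normalised to uppercase on load and restricted to
the alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FastaFormatError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_residues(residues: str, context: str = "sequence") -> str:
    """Uppercase ``residues`` and reject characters outside {A,C,G,T,N}."""
    upper = residues.upper()
    for ch in upper:
        if ch not in DNA_ALPHABET:
            raise FastaFormatError(
                f"illegal residue {ch!r} in {context}; allowed alphabet is A,C,G,T,N"
            )
    return upper


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, e.g. one FASTA record."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord requires a non-empty id")
        object.__setattr__(self, "residues", _validate_residues(self.residues, f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Genome:
    """A (usually single-chromosome) bacterial genome with coordinate helpers.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header token).
    residues : str
        Uppercase DNA over {A,C,G,T,N}.
    description : str
        Free-text remainder of the FASTA header.
    circular : bool
        When True, ``fetch`` wraps windows across the origin.  Bacterial
        chromosomes are physically circular, but annotated promoters
        essentially never span the origin, so the default is linear.
    """

    id: str
    residues: str
    description: str = ""
    circular: bool = False

    def __post_init__(self):
        self.residues = _validate_residues(self.residues, f"genome {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Slice ``[start, end)`` in 0-based half-open coordinates.

        On a circular genome the slice may run past the origin
        (``end > length``); on a linear genome out-of-bounds raises.
        """
        if start < 0 or end < start:
            raise ValueError(f"invalid slice [{start}, {end})")
        if end <= self.length:
            return self.residues[start:end]
        if not self.circular:
            raise ValueError(
                f"slice [{start}, {end}) exceeds linear genome of length {self.length}"
            )
        if end - start > self.length:
            raise ValueError("window longer than the circular genome")
        return self.residues[start:] + self.residues[: end - self.length]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    Length-preserving involution; N maps to N.
    """
    upper = _validate_residues(seq, "reverse_complement input")
    # Bio.Seq implements the same table; routed through it for parity with
    # the rest of the Biopython-based I/O.
    return str(Seq(upper).reverse_complement())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated and lowercase input is
    normalised to uppercase.  Strict by design: a sequence line before
    any header, or a residue outside {A,C,G,T,N}, is a
    :class:`~bacprom.errors.FastaFormatError` naming the offending
    character and line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush():
        if current_id is not None:
            records.append(SequenceRecord(id=current_id, residues="".join(chunks)))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                current_id = header.split()[0]
                chunks = []
            else:
                if current_id is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                upper = line.upper()
                for ch in upper:
                    if ch not in DNA_ALPHABET:
                        raise FastaFormatError(
                            f"{path}:{lineno}: illegal character {ch!r} "
                            "(allowed: A,C,G,T,N)"
                        )
                chunks.append(upper)
    flush()
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[SequenceRecord],
    path: str | Path,
    line_width: int = 70,
) -> None:
    """Write records as FASTA wrapped at ``line_width`` columns.

    Round-trip guarantee: ``read_fasta`` on the written file reproduces
    ids and residues exactly.
    """
    if not records:
        raise ValueError("write_fasta requires at least one record")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    bio_records = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=line_width)
        writer.write_file(bio_records)


def load_genome(
    path: str | Path,
    record_id: str | None = None,
    circular: bool = False,
) -> Genome:
    """Load a genome from FASTA.

    A multi-record file yields the first record unless ``record_id``
    names another; a warning is logged in the multi-record case because
    the pipeline assumes a single chromosome.
    """
    records = read_fasta(path)
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise FastaFormatError(f"{path}: no record with id {record_id!r}")
        chosen = matches[0]
    else:
        chosen = records[0]
        if len(records) > 1:
            logger.warning(
                "%s contains %d records; using the first (%s) as the genome",
                path, len(records), chosen.id,
            )
    return Genome(id=chosen.id, residues=chosen.residues, circular=circular)


def records_from_strings(pairs: Iterable[tuple[str, str]]) -> list[SequenceRecord]:
    """Convenience constructor: ``[(id, residues), ...]`` to records."""
    return [SequenceRecord(id=i, residues=s) for i, s in pairs]
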