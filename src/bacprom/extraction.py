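"""Locate annotated promoters in a genome and emit fixed-length windows.

The extraction procedure mirrors how curated promoter annotations are
resolved against a genome assembly: each annotation row carries an
absolute genomic position and/or the literal polymerase binding
sequence.  Position lookup is tried first; when it fails (stale
coordinates, assembly drift) an exact sequence search over both strands
is the fallback.  Every successful lookup yields a fixed-length window
(default 80 nt) anchored at the annotated position / sequence hit.

Anchoring convention: the annotated 1-based ``absolute_position`` is the
first base of the emitted window, i.e. the window covers positions
``p .. p + window_length - 1`` (1-based inclusive).  A signed
``anchor_offset`` shifts the window start when a different placement is
wanted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import AnnotationFormatError
from .sequence_io import Genome, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LENGTH = 80


@dataclass(frozen=True)
class PromoterRecord:
    """One annotated promoter, as found in a curated annotation table."""

    operon: str
    sigma: str
    regulated_gene: str | None = None
    absolute_position: int | None = None  # 1-based, as annotated
    binding_sequence: str | None = None
    location_note: str | None = None
    evidence: str | None = None

    def __post_init__(self):
        if self.absolute_position is None and not self.binding_sequence:
            raise ValueError(
                f"record {self.operon!r}: needs absolute_position or binding_sequence"
            )
        if self.absolute_position is not None and self.absolute_position < 1:
            raise ValueError(
                f"record {self.operon!r}: absolute_position must be >= 1 (1-based)"
            )
        if self.binding_sequence:
            object.__setattr__(self, "binding_sequence", self.binding_sequence.upper())


@dataclass(frozen=True)
class PromoterWindow:
    """A fixed-length window extracted for one promoter record.

    ``start``/``end`` are internal 0-based half-open genome coordinates
    on the forward strand; ``sequence`` is the forward slice for strand
    '+' and its reverse complement for strand '-'.
    """

    record: PromoterRecord
    sequence: str
    start: int
    end: int
    strand: str  # '+' or '-'
    provenance: str  # 'position' or 'sequence_search'

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError("window coordinates inconsistent with sequence length")


@dataclass
class ExtractionReport:
    """Outcome of extracting a batch of records.

    Invariant: ``len(windows) + len(misses) == number of input records``;
    ambiguous records (multiple sequence hits) still contribute exactly
    one window.
    """

    windows: list[PromoterWindow] = field(default_factory=list)
    misses: list[tuple[PromoterRecord, str]] = field(default_factory=list)
    ambiguous: list[tuple[PromoterRecord, int]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.windows) + len(self.misses)

    def to_frame(self) -> pd.DataFrame:
        """Tabular summary (one row per input record) for CSV export."""
        rows = []
        ambiguous_ops = {r.operon: n for r, n in self.ambiguous}
        for w in self.windows:
            rows.append({
                "operon": w.record.operon,
                "sigma": w.record.sigma,
                "status": "extracted",
                "provenance": w.provenance,
                "start": w.start,
                "end": w.end,
                "strand": w.strand,
                "n_hits": ambiguous_ops.get(w.record.operon, 1),
                "reason": "",
            })
        for rec, reason in self.misses:
            rows.append({
                "operon": rec.operon,
                "sigma": rec.sigma,
                "status": "miss",
                "provenance": "",
                "start": None,
                "end": None,
                "strand": "",
                "n_hits": 0,
                "reason": reason,
            })
        return pd.DataFrame(rows)


def locate_by_position(
    genome: Genome,
    record: PromoterRecord,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    anchor_offset: int = 0,
) -> PromoterWindow | None:
    """Resolve a record by its annotated absolute position.

    Returns ``None`` (not an exception) when the window would run off a
    linear genome or when the record carries a binding sequence that the
    anchored slice does not contain — the caller then falls back to
    sequence search.
    """
    if record.absolute_position is None:
        return None
    start = (record.absolute_position - 1) + anchor_offset
    end = start + window_length
    if start < 0 or (not genome.circular and end > genome.length) or start >= genome.length:
        return None
    seq = genome.fetch(start, end)
    if record.binding_sequence and record.binding_sequence not in seq:
        return None
    return PromoterWindow(
        record=record, sequence=seq, start=start, end=end,
        strand="+", provenance="position",
    )


def locate_by_sequence(genome: Genome, binding_sequence: str) -> list[tuple[int, str]]:
    """All exact occurrences of ``binding_sequence`` on either strand.

    Returns ``(start, strand)`` pairs, 0-based forward-strand
    coordinates of the match start; forward-strand hits first, then
    reverse-strand hits, each in ascending coordinate order.
    Overlapping occurrences are all reported.
    """
    if not binding_sequence:
        raise ValueError("binding_sequence must be non-empty")
    query = binding_sequence.upper()
    hits: list[tuple[int, str]] = []
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        pos = genome.residues.find(q)
        while pos != -1:
            hits.append((pos, strand))
            pos = genome.residues.find(q, pos + 1)
    # forward hits were appended first; each strand block is already ascending
    return hits


def _window_from_hit(
    genome: Genome,
    record: PromoterRecord,
    hit: tuple[int, str],
    window_length: int,
    anchor_offset: int,
) -> PromoterWindow | None:
    """Build the window anchored at a sequence hit; None if out of bounds."""
    pos, strand = hit
    qlen = len(record.binding_sequence or "")
    if strand == "+":
        start = pos + anchor_offset
        end = start + window_length
    else:
        # the binding site reads 5'->3' on the minus strand; the window
        # extends downstream along that strand, i.e. leftward in
        # forward coordinates
        end = pos + qlen - anchor_offset
        start = end - window_length
    if start < 0 or (not genome.circular and end > genome.length):
        return None
    seq = genome.fetch(start, end)
    if strand == "-":
        seq = reverse_complement(seq)
    return PromoterWindow(
        record=record, sequence=seq, start=start, end=end,
        strand=strand, provenance="sequence_search",
    )


def extract_promoters(
    genome: Genome,
    records: list[PromoterRecord],
    window_length: int = DEFAULT_WINDOW_LENGTH,
    anchor_offset: int = 0,
    drop_ambiguous_bases: bool = True,
) -> ExtractionReport:
    """Run position-first / sequence-fallback extraction over all records.

    Per record: position lookup first; on miss, exact sequence search
    (first forward-strand hit at the lowest coordinate wins; multiple
    hits are surfaced in ``report.ambiguous``).  Windows containing N
    are dropped to misses with reason ``ambiguous_base`` unless
    ``drop_ambiguous_bases`` is False, because downstream encodings
    assume a 4-letter alphabet.
    """
    if not records:
        raise ValueError("extract_promoters requires at least one record")
    report = ExtractionReport()
    for rec in records:
        window = None
        n_hits = 0
        if rec.absolute_position is not None:
            window = locate_by_position(genome, rec, window_length, anchor_offset)
            if window is None and not rec.binding_sequence:
                report.misses.append((rec, "position_out_of_range"))
                continue
        if window is None and rec.binding_sequence:
            hits = locate_by_sequence(genome, rec.binding_sequence)
            usable = []
            for hit in hits:
                w = _window_from_hit(genome, rec, hit, window_length, anchor_offset)
                if w is not None:
                    usable.append(w)
            n_hits = len(usable)
            if n_hits == 0:
                reason = (
                    "binding_mismatch"
                    if rec.absolute_position is not None and hits == []
                    else "sequence_not_found"
                )
                if hits:
                    reason = "window_out_of_range"
                report.misses.append((rec, reason))
                continue
            window = usable[0]
            if n_hits > 1:
                report.ambiguous.append((rec, n_hits))
                logger.info(
                    "record %s: %d sequence hits; using the first (%d, %s)",
                    rec.operon, n_hits, window.start, window.strand,
                )
        if window is None:
            report.misses.append((rec, "position_out_of_range"))
            continue
        if drop_ambiguous_bases and "N" in window.sequence:
            report.misses.append((rec, "ambiguous_base"))
            continue
        report.windows.append(window)
    return report


# -- annotation-table parsing -------------------------------------------------

# accepted column spellings, case-insensitive, after stripping spaces/underscores
_COLUMN_ALIASES = {
    "operon": {"operon"},
    "sigma": {"sigma", "sigmafactor", "factor"},
    "regulated_gene": {"regulatedgene", "gene"},
    "absolute_position": {"absoluteposition", "position", "abspos"},
    "binding_sequence": {"bindingsequence", "sequence", "linksequence"},
    "location_note": {"location", "locationnote"},
    "evidence": {"evidence", "experimentalevidence"},
}


def _canon(name: str) -> str:
    return name.strip().lower().replace("_", "").replace(" ", "")


def parse_annotation_table(
    path: str | Path,
    delimiter: str | None = None,
) -> tuple[list[PromoterRecord], list[tuple[int, str]]]:
    """Parse a delimited promoter annotation table.

    The table must have a header row naming at least the operon and
    sigma columns plus one of the position / binding-sequence columns
    (several common spellings are accepted).  The delimiter is sniffed
    (tab vs comma) unless given.  1-based positions stay 1-based on the
    record; conversion to internal coordinates happens in the locate
    functions.

    Returns ``(records, row_errors)`` where ``row_errors`` is a list of
    ``(line_number, message)`` for rows that had neither locator field —
    such rows are reported, not fatal.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            header_line = fh.readline()
        delimiter = "\t" if header_line.count("\t") >= header_line.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    mapping: dict[str, str] = {}
    for col in df.columns:
        c = _canon(col)
        for field_name, aliases in _COLUMN_ALIASES.items():
            if c in aliases and field_name not in mapping:
                mapping[field_name] = col
    missing = [name for name in ("operon", "sigma") if name not in mapping]
    if "absolute_position" not in mapping and "binding_sequence" not in mapping:
        missing.append("absolute_position|binding_sequence")
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    records: list[PromoterRecord] = []
    row_errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        def cell(name):
            col = mapping.get(name)
            if col is None:
                return None
            value = str(row[col]).strip()
            return value or None

        pos_text = cell("absolute_position")
        pos = None
        if pos_text is not None:
            try:
                pos = int(float(pos_text.replace(",", "")))
            except ValueError:
                row_errors.append((lineno, f"unparseable position {pos_text!r}"))
                continue
        binding = cell("binding_sequence")
        if pos is None and binding is None:
            row_errors.append((lineno, "row has neither position nor binding sequence"))
            continue
        records.append(PromoterRecord(
            operon=cell("operon") or f"row{lineno}",
            sigma=cell("sigma") or "",
            regulated_gene=cell("regulated_gene"),
            absolute_position=pos,
            binding_sequence=binding,
            location_note=cell("location_note"),
            evidence=cell("evidence"),
        ))
    return records, row_errors


def write_annotation_table(records: list[PromoterRecord], path: str | Path) -> None:
    """Write records as a TSV in the dialect :func:`parse_annotation_table` reads."""
    df = pd.DataFrame([
        {
            "operon": r.operon,
            "sigma": r.sigma,
            "regulated_gene": r.regulated_gene or "",
            "absolute_position": r.absolute_position if r.absolute_position is not None else "",
            "binding_sequence": r.binding_sequence or "",
            "location": r.location_note or "",
            "evidence": r.evidence or "",
        }
        for r in records
    ])
    df.to_csv(path, sep="\t", index=False)
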