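"""Synthetic genomes with planted sigma-style promoters.

A fixture generator so every pipeline stage is testable without any
genome download.  The model: an i.i.d. background at a configurable GC
fraction (default 0.43, approximately the B. subtilis genomic
composition), into which promoters are planted at non-overlapping loci.
Each planted promoter is

    [-35 box] [spacer of 15-19 nt] [-10 box]

with the canonical consensus hexamers TTGACA and TATAAT, each position
independently mutated at a configurable rate.  The matching annotation
table carries the correct 1-based absolute position and the embedded
(post-mutation) binding sequence, so position-based and sequence-based
extraction can be cross-checked against planted truth.

Anchoring matches the extraction module: the annotated position is the
first base of the promoter window, i.e. the window starts at the -35
box and runs ``window_length`` nt downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import FeatureEncoding, LabeledDataset, build_dataset, sample_negatives
from .errors import CapacityError
from .extraction import (
    DEFAULT_WINDOW_LENGTH,
    ExtractionReport,
    PromoterRecord,
    PromoterWindow,
    extract_promoters,
)
from .sequence_io import Genome

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome fixture."""

    genome_length: int = 50_000
    n_promoters: int = 20
    minus35: str = "TTGACA"
    minus10: str = "TATAAT"
    spacer_range: tuple[int, int] = (15, 19)
    mutation_rate: float = 0.0
    gc_background: float = 0.43
    seed: int = 0
    window_length: int = DEFAULT_WINDOW_LENGTH
    margin: int = 10  # clearance between planted windows and from the ends
    sigma_names: tuple[str, ...] = ("SigA",)

    def __post_init__(self):
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must lie in (0, 1)")
        if self.spacer_range[0] > self.spacer_range[1] or self.spacer_range[0] < 0:
            raise ValueError("invalid spacer_range")
        if self.window_length < len(self.minus35) + self.spacer_range[1] + len(self.minus10):
            raise ValueError("window_length too short to contain the planted motif")

    @property
    def max_feasible_promoters(self) -> int:
        usable = self.genome_length - self.margin
        return max(0, usable // (self.window_length + self.margin))


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _mutate(seq: str, rate: float, gc: float, rng: np.random.Generator) -> str:
    """Per-position mutation: with probability ``rate`` the base is
    redrawn from the background composition (possibly unchanged).

    Replacement from the background — rather than 'a different base' —
    makes ``rate=1`` a true null: a fully mutated motif is statistically
    indistinguishable from background, so classifier benchmarks have a
    clean no-signal limit.
    """
    if rate == 0:
        return seq
    p = _background_probs(gc)
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _BASES[rng.choice(4, p=p)]
    return "".join(out)


def _background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=_background_probs(gc))]


def generate(
    spec: SyntheticSpec,
) -> tuple[Genome, list[PromoterRecord], list[PromoterWindow]]:
    """Build a synthetic genome, its annotation records and the truth windows.

    Promoter windows are placed non-overlapping with ``spec.margin``
    clearance; placement and all mutations are driven by
    ``spec.seed``, so an identical spec reproduces the genome
    byte-for-byte.  Raises :class:`~bacprom.errors.CapacityError`
    (reporting the maximum feasible count) when the requested promoters
    cannot be packed.
    """
    n, W, m = spec.n_promoters, spec.window_length, spec.margin
    slack = spec.genome_length - n * W - (n + 1) * m
    if n < 1 or slack < 0:
        raise CapacityError(
            f"cannot pack {n} windows of {W} nt (margin {m}) into "
            f"{spec.genome_length} nt; at most {spec.max_feasible_promoters} fit",
            achievable=spec.max_feasible_promoters,
        )
    rng = np.random.default_rng(spec.seed)

    # place windows: distribute the slack over the n+1 inter-window gaps
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts = []
    cursor = 0
    for i in range(n):
        cursor += m + int(extra[i])
        starts.append(cursor)
        cursor += W

    residues = _background(spec.genome_length, spec.gc_background, rng)

    records: list[PromoterRecord] = []
    truth: list[PromoterWindow] = []
    bindings: list[str] = []
    for i, start in enumerate(starts):
        spacer_len = int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))
        # spacer drawn from the background composition, not uniform ACGT:
        # only the boxes (and spacer length) distinguish promoters from
        # background, keeping compositional confounds out of benchmarks
        spacer = "".join(_background(spacer_len, spec.gc_background, rng))
        binding = (
            _mutate(spec.minus35, spec.mutation_rate, spec.gc_background, rng)
            + spacer
            + _mutate(spec.minus10, spec.mutation_rate, spec.gc_background, rng)
        )
        residues[start:start + len(binding)] = list(binding)
        bindings.append(binding)
        records.append(PromoterRecord(
            operon=f"synOp{i + 1:03d}",
            sigma=spec.sigma_names[i % len(spec.sigma_names)],
            absolute_position=start + 1,  # 1-based annotation convention
            binding_sequence=binding,
            location_note="synthetic",
            evidence="planted",
        ))

    genome = Genome(id="synthetic_genome", residues="".join(residues))
    for rec, start in zip(records, starts):
        truth.append(PromoterWindow(
            record=rec, sequence=genome.fetch(start, start + W),
            start=start, end=start + W, strand="+", provenance="position",
        ))
    return genome, records, truth


def unique_bindings(genome: Genome, records: list[PromoterRecord]) -> bool:
    """True when every record's binding sequence occurs exactly once
    genome-wide (forward strand) — the precondition for the
    position/sequence extraction equivalence check."""
    from .extraction import locate_by_sequence

    for rec in records:
        if len(locate_by_sequence(genome, rec.binding_sequence)) != 1:
            return False
    return True


def generate_labeled_benchmark(
    spec: SyntheticSpec,
    n_negatives: int,
    seed: int,
    encoding: FeatureEncoding | None = None,
    negative_strategy: str = "random_window",
) -> LabeledDataset:
    """End-to-end benchmark dataset: plant, extract, sample negatives, encode.

    Positives come from running the real extraction path on the planted
    annotation records (not from the truth windows directly), so this
    exercises the same code a user would.  ``seed`` drives negative
    sampling; ``spec.seed`` drives the genome.
    """
    genome, records, _ = generate(spec)
    report: ExtractionReport = extract_promoters(genome, records, spec.window_length)
    if not report.windows:
        raise CapacityError("extraction recovered no planted promoters")
    negatives = sample_negatives(
        genome, report.windows, n_negatives, seed, strategy=negative_strategy
    )
    return build_dataset(report.windows, negatives, encoding)


def truth_to_bed(truth: list[PromoterWindow], genome_id: str) -> str:
    """Render truth windows as BED (0-based half-open) text."""
    lines = [
        f"{genome_id}\t{w.start}\t{w.end}\t{w.record.operon}\t0\t{w.strand}"
        for w in truth
    ]
    return "\n".join(lines) + "\n"
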