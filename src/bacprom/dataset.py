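"""Data preparation: negative-example construction and feature encoding.

Promoter classification needs both classes.  Annotated promoters give
the positives; negatives must be constructed.  Two standard,
reproducible constructions are provided:

``random_window``
    windows drawn uniformly from the genome, rejected if they overlap
    any positive window's coordinates — captures "generic genomic
    background";
``dinucleotide_shuffle``
    each positive shuffled while preserving its exact dinucleotide
    multiset (Altschul–Erickson Euler-path shuffle) — composition- and
    neighbour-frequency-matched, so only positional motif structure
    separates the classes.

Feature encodings:

``onehot``
    position-wise 4-channel binary indicator, channel order A,C,G,T,
    feature index ``4*i + channel`` for position ``i``; dimension
    ``4 x window_length``.  Position-aware, which suits the conserved
    -35/-10 box spacing of bacterial promoters.
``kmer``
    overlapping k-mer frequencies in lexicographic order (A<C<G<T),
    each count divided by ``L - k + 1`` so rows sum to 1; dimension
    ``4**k``.  Position-free compositional alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

from .errors import CapacityError, EncodingError
from .extraction import PromoterWindow
from .sequence_io import Genome

LABEL_PROMOTER = "promoter"
LABEL_NON_PROMOTER = "non_promoter"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class FeatureEncoding:
    """Descriptor of how sequences were turned into features.

    ``window_length`` is required for onehot (dimension 4·L); ``k`` is
    required for kmer (dimension 4^k).
    """

    scheme: str  # 'onehot' or 'kmer'
    window_length: int | None = None
    k: int | None = None

    def __post_init__(self):
        if self.scheme == "onehot":
            if not self.window_length or self.window_length < 1:
                raise ValueError("onehot encoding requires a positive window_length")
        elif self.scheme == "kmer":
            if not self.k or self.k < 1:
                raise ValueError("kmer encoding requires a positive k")
        else:
            raise ValueError(f"unknown encoding scheme {self.scheme!r}")

    @property
    def dimension(self) -> int:
        if self.scheme == "onehot":
            return 4 * self.window_length
        return 4 ** self.k

    def describe(self) -> str:
        if self.scheme == "onehot":
            return f"onehot(window_length={self.window_length})"
        return f"kmer(k={self.k})"


class DnaOneHotEncoder(BaseEstimator, TransformerMixin):
    """Position-wise one-hot encoder for equal-length DNA strings.

    Channel order is A,C,G,T at every position; for a sequence of
    length L the output row has 4·L columns and exactly L ones.
    Sequences containing N cannot be one-hot encoded and raise
    :class:`~bacprom.errors.EncodingError` naming the offender.
    """

    def fit(self, X: Sequence[str], y=None):
        seqs = list(X)
        if not seqs:
            raise ValueError("cannot fit on an empty sequence list")
        self.window_length_ = len(seqs[0])
        self.encoding_ = FeatureEncoding("onehot", window_length=self.window_length_)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        seqs = list(X)
        L = self.window_length_
        out = np.zeros((len(seqs), 4 * L), dtype=np.float64)
        for row, seq in enumerate(seqs):
            if len(seq) != L:
                raise ValueError(
                    f"sequence {row} has length {len(seq)}, expected {L}"
                )
            for i, ch in enumerate(seq):
                idx = _BASE_INDEX.get(ch)
                if idx is None:
                    raise EncodingError(
                        f"sequence {row} contains {ch!r} at position {i}; "
                        "one-hot encoding requires the A,C,G,T alphabet"
                    )
                out[row, 4 * i + idx] = 1.0
        return out


class KmerFrequencyEncoder(BaseEstimator, TransformerMixin):
    """Overlapping k-mer frequency encoder.

    Features are the 4^k k-mers in lexicographic order (A<C<G<T); each
    row is normalised by the number of overlapping k-mers (L-k+1) and
    sums to 1.  k-mers containing N are skipped (their mass is
    redistributed by the fixed denominator, keeping rows comparable).
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X: Sequence[str], y=None):
        seqs = list(X)
        if not seqs:
            raise ValueError("cannot fit on an empty sequence list")
        self.window_length_ = len(seqs[0])
        self.encoding_ = FeatureEncoding("kmer", k=self.k)
        self.kmer_index_ = {
            "".join(p): i for i, p in enumerate(product(_BASES, repeat=self.k))
        }
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        seqs = list(X)
        k = self.k
        out = np.zeros((len(seqs), 4 ** k), dtype=np.float64)
        for row, seq in enumerate(seqs):
            if len(seq) != self.window_length_:
                raise ValueError(
                    f"sequence {row} has length {len(seq)}, expected {self.window_length_}"
                )
            if len(seq) < k:
                raise ValueError(f"sequence {row} shorter than k={k}")
            denom = len(seq) - k + 1
            for i in range(denom):
                idx = self.kmer_index_.get(seq[i:i + k])
                if idx is not None:
                    out[row, idx] += 1.0
            out[row] /= denom
        return out


def encode(sequences: Sequence[str], encoding: FeatureEncoding) -> np.ndarray:
    """Encode equal-length DNA strings under an encoding descriptor."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to encode")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    if encoding.scheme == "onehot":
        enc = DnaOneHotEncoder().fit(seqs)
        if enc.window_length_ != encoding.window_length:
            raise ValueError(
                f"sequences have length {enc.window_length_}, "
                f"encoding expects {encoding.window_length}"
            )
        return enc.transform(seqs)
    enc = KmerFrequencyEncoder(k=encoding.k).fit(seqs)
    return enc.transform(seqs)


# -- negative sampling --------------------------------------------------------

def _intervals_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving the exact dinucleotide multiset.

    Builds the multigraph whose edges are the sequence's dinucleotides
    and samples a random Eulerian path with the same endpoints.
    """
    if len(seq) <= 2:
        return seq
    # adjacency lists of successor characters
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    vertices = list(succ.keys())
    last = seq[-1]
    # choose a random last edge into `last` from every other vertex so the
    # remaining graph admits an Eulerian path ending at `last`
    # (standard arborescence construction, retried until connected)
    for _ in range(64):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = succ[v][rng.integers(len(succ[v]))]
        # check: from every vertex, following last_edge reaches `last`
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - tiny alphabet, arborescence always found
        return seq
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled[v] = edges
    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def sample_negatives(
    genome: Genome,
    positives: Sequence[PromoterWindow],
    n: int,
    seed: int,
    strategy: str = "random_window",
    max_attempts_per_draw: int = 1000,
) -> list[str]:
    """Construct ``n`` negative (non-promoter) example sequences.

    ``random_window`` draws are overlap-free with respect to every
    positive window's coordinates and contain no N.  Identical
    ``(genome, positives, n, seed, strategy)`` give identical output.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    if not positives:
        raise ValueError("negative sampling needs the positive windows for reference")
    window_length = len(positives[0].sequence)
    rng = np.random.default_rng(seed)

    if strategy == "dinucleotide_shuffle":
        out = []
        for i in range(n):
            src = positives[i % len(positives)].sequence
            out.append(_dinucleotide_shuffle(src, rng))
        return out

    if strategy != "random_window":
        raise ValueError(f"unknown strategy {strategy!r}")
    if genome.length < window_length:
        raise CapacityError("genome shorter than the window length", achievable=0)
    occupied = [(w.start, w.end) for w in positives]
    drawn: list[tuple[int, int]] = []
    out = []
    attempts = 0
    budget = max_attempts_per_draw * n
    while len(out) < n:
        if attempts >= budget:
            raise CapacityError(
                f"could not place {n} non-overlapping negative windows "
                f"(placed {len(out)} in {attempts} attempts)",
                achievable=len(out),
            )
        attempts += 1
        start = int(rng.integers(0, genome.length - window_length + 1))
        end = start + window_length
        if any(_intervals_overlap(start, end, s, e) for s, e in occupied):
            continue
        seq = genome.fetch(start, end)
        if "N" in seq:
            continue
        drawn.append((start, end))
        out.append(seq)
    return out


# -- labeled dataset ----------------------------------------------------------

@dataclass
class LabeledDataset:
    """Encoded feature matrix with promoter / non-promoter labels."""

    sequences: list[str]
    labels: list[str]
    features: np.ndarray
    encoding: FeatureEncoding

    def __post_init__(self):
        if not (len(self.sequences) == len(self.labels) == self.features.shape[0]):
            raise ValueError("sequences, labels and feature rows disagree in count")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must have uniform length")
        bad = set(self.labels) - {LABEL_PROMOTER, LABEL_NON_PROMOTER}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def one_class_compatible(self) -> bool:
        """True when only promoter examples are present."""
        return set(self.labels) == {LABEL_PROMOTER}

    @property
    def y(self) -> np.ndarray:
        """Numeric labels: promoter=1, non_promoter=0."""
        return np.array([1 if l == LABEL_PROMOTER else 0 for l in self.labels])

    def window_length(self) -> int:
        return len(self.sequences[0])


def build_dataset(
    positives: Sequence[PromoterWindow],
    negatives: Sequence[str],
    encoding: FeatureEncoding | None = None,
) -> LabeledDataset:
    """Assemble a labeled dataset: positives first, then negatives.

    Row order is deterministic (input order within each class).  With
    no encoding given, one-hot at the positives' window length is used.
    """
    if not positives:
        raise ValueError("build_dataset requires at least one positive window")
    pos_seqs = [w.sequence for w in positives]
    neg_seqs = list(negatives)
    window_length = len(pos_seqs[0])
    if any(len(s) != window_length for s in pos_seqs + neg_seqs):
        raise ValueError("positives and negatives must share one window length")
    if encoding is None:
        encoding = FeatureEncoding("onehot", window_length=window_length)
    sequences = pos_seqs + neg_seqs
    labels = [LABEL_PROMOTER] * len(pos_seqs) + [LABEL_NON_PROMOTER] * len(neg_seqs)
    features = encode(sequences, encoding)
    return LabeledDataset(sequences=sequences, labels=labels,
                          features=features, encoding=encoding)


# -- LibSVM-ecosystem interchange --------------------------------------------

def save_svmlight(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the dataset in the sparse ``label index:value`` training format
    (one example per line, 1-based feature indices)."""
    dump_svmlight_file(dataset.features, dataset.y, str(path), zero_based=False)


def load_svmlight(path: str | Path, n_features: int | None = None):
    """Read a sparse training file back as ``(X, y)`` with 1-based indices."""
    X, y = load_svmlight_file(str(path), n_features=n_features, zero_based=False)
    return X.toarray(), y.astype(int)
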