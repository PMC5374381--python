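"""Oligonucleotide word-frequency vectors and GC statistics.

Each read is summarised by the relative frequencies of all overlapping
di-, tri- and tetranucleotide words (16 + 64 + 256 = 336 features by
default).  Frequencies are per-word-length: within each k-block the
counts are divided by the number of windows of that length, so every
block is a probability simplex and a full row sums to the number of
blocks.  This removes read-length scaling so that Pearson correlations
between rows compare composition, not length.

Words of a given length are ordered lexicographically with A < C < G < T;
blocks are concatenated in ascending k.  Every word also carries a GC
class used for plot colouring: ``all_gc`` (only G/C), ``no_gc`` (only
A/T) or ``mixed``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import ConfigurationError, DegenerateInputError
from .sequence_io import SampleSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def gc_class_of(word: str) -> str:
    """GC class of a word: all_gc / no_gc / mixed."""
    gc = sum(c in "GC" for c in word)
    if gc == len(word):
        return "all_gc"
    if gc == 0:
        return "no_gc"
    return "mixed"


@dataclass(frozen=True)
class WordFeatureIndex:
    """Canonical ordering of nucleotide words for a set of word lengths."""

    ks: tuple[int, ...]
    words: tuple[str, ...]
    _col: dict[str, int] = field(repr=False, hash=False, compare=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.words)

    def column_of(self, word: str) -> int:
        return self._col[word]

    def gc_class_of(self, word: str) -> str:
        if word not in self._col:
            raise KeyError(f"word {word!r} not in feature index")
        return gc_class_of(word)

    def block_slices(self) -> list[slice]:
        """Half-open column ranges of each k-block, ascending k."""
        out, off = [], 0
        for k in self.ks:
            out.append(slice(off, off + 4 ** k))
            off += 4 ** k
        return out


def build_feature_index(ks: Sequence[int] = (2, 3, 4)) -> WordFeatureIndex:
    """Enumerate all words for each k, ascending k, lexicographic within k."""
    ks = tuple(ks)
    if not ks:
        raise ConfigurationError("ks must be non-empty")
    if any(k < 1 for k in ks):
        raise ConfigurationError("every word length must be >= 1")
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ConfigurationError("ks must be strictly increasing")
    words = tuple(
        "".join(p) for k in ks for p in itertools.product(BASES, repeat=k)
    )
    idx = WordFeatureIndex(ks=ks, words=words)
    idx._col.update({w: i for i, w in enumerate(words)})
    return idx


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_CODE[c] for c in sequence), dtype=np.int64,
                           count=len(sequence))
    except KeyError as exc:
        raise ConfigurationError(
            f"unexpected character {exc.args[0]!r} in sequence"
        ) from None


def frequency_vector(sequence: str, index: WordFeatureIndex) -> np.ndarray:
    """Per-block relative word frequencies of one sequence.

    For each k the overlapping windows are counted and divided by
    ``len(sequence) - k + 1``; blocks are concatenated in index order.
    """
    kmax = max(index.ks)
    if len(sequence) < kmax:
        raise DegenerateInputError(
            f"sequence of length {len(sequence)} is shorter than the longest "
            f"word length {kmax}"
        )
    codes = _encode(sequence)
    blocks = []
    for k in index.ks:
        n_win = len(codes) - k + 1
        window_codes = np.zeros(n_win, dtype=np.int64)
        for j in range(k):
            window_codes = window_codes * 4 + codes[j:j + n_win]
        blocks.append(np.bincount(window_codes, minlength=4 ** k) / n_win)
    return np.concatenate(blocks)


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases."""
    if not sequence:
        raise DegenerateInputError("empty sequence has no GC content")
    _encode(sequence)  # character validation
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


@dataclass
class FrequencyMatrix:
    """Reads x word-frequency features in fixed canonical order."""

    read_ids: list[str]
    features: WordFeatureIndex
    values: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=int)
        if self.values.shape != (len(self.read_ids), len(self.features)):
            raise ConfigurationError("values shape does not match read_ids x features")
        self._row = {rid: i for i, rid in enumerate(self.read_ids)}

    def rows_for(self, read_ids: Sequence[str]) -> np.ndarray:
        """Sub-array of rows for the given read ids (ids absent are skipped)."""
        idx = [self._row[r] for r in read_ids if r in self._row]
        return self.values[idx]

    def to_tsv(self, path: str | Path, float_fmt: str = "%.17g") -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tlength\t" + "\t".join(self.features.words) + "\n")
            for rid, length, row in zip(self.read_ids, self.lengths, self.values):
                fh.write(rid + "\t" + str(int(length)) + "\t"
                         + "\t".join(float_fmt % v for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            words = header[2:]
            ks = sorted({len(w) for w in words})
            index = build_feature_index(ks)
            if list(index.words) != words:
                raise ConfigurationError(f"{path}: column order is not canonical")
            read_ids, lengths, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                read_ids.append(parts[0])
                lengths.append(int(parts[1]))
                rows.append([float(v) for v in parts[2:]])
        return cls(read_ids, index, np.array(rows), np.array(lengths))

    @classmethod
    def concat(cls, matrices: Sequence["FrequencyMatrix"]) -> "FrequencyMatrix":
        first = matrices[0]
        for m in matrices[1:]:
            if m.features.words != first.features.words:
                raise ConfigurationError("cannot concatenate matrices with different features")
        return cls(
            read_ids=[rid for m in matrices for rid in m.read_ids],
            features=first.features,
            values=np.vstack([m.values for m in matrices]),
            lengths=np.concatenate([m.lengths for m in matrices]),
        )


def build_matrix(sample: SampleSet, index: WordFeatureIndex) -> FrequencyMatrix:
    """Featurize every read of a sample; unusable reads are dropped.

    Reads shorter than the longest word length or containing characters
    outside A/C/G/T are skipped with a logged count.  Row order follows
    sample read order.
    """
    ids, rows, lengths, dropped = [], [], [], 0
    for r in sample.reads:
        try:
            rows.append(frequency_vector(r.sequence, index))
        except (DegenerateInputError, ConfigurationError):
            dropped += 1
            continue
        ids.append(r.read_id)
        lengths.append(len(r))
    if dropped:
        logger.info("build_matrix[%s]: dropped %d unusable reads",
                    sample.sample_label, dropped)
    if not rows:
        raise DegenerateInputError(
            f"sample {sample.sample_label!r}: no usable reads to featurize"
        )
    return FrequencyMatrix(ids, index, np.array(rows), np.array(lengths))


@dataclass
class GCHistogram:
    """Binned per-read GC% distribution of one sample."""

    sample_label: str
    bin_edges: np.ndarray   # len n_bins + 1, spanning [0, 100]
    counts: np.ndarray
    modal_bin_center: float

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def gc_distribution(sample: SampleSet, bin_width: float = 0.5) -> GCHistogram:
    """Histogram of per-read GC% over [0, 100] with the stated bin width."""
    if not sample.reads:
        raise DegenerateInputError(f"sample {sample.sample_label!r} is empty")
    gcs = [100.0 * gc_content(r.sequence) for r in sample.reads if r.sequence]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, edges = np.histogram(gcs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return GCHistogram(
        sample_label=sample.sample_label,
        bin_edges=edges,
        counts=counts,
        modal_bin_center=float(centers[int(np.argmax(counts))]),
    )
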