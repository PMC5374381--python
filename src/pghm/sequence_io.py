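"""Reading, quality screening and region extraction for amplicon reads.

Reads come in as FASTA or FASTQ (Sanger/Phred+33).  The screening
conventions follow common amplicon practice: a read is retained when it
contains no ``N`` and its Phred qualities clear a threshold, either on
the per-read mean (default) or per base.  Region handling is 0-based,
half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from ._errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

_VALID_FORMATS = ("fasta", "fastq")

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass
class ReadRecord:
    """One sequencing read; ``qualities`` is absent for FASTA input."""

    read_id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ParseError(
                    f"read {self.read_id!r}: quality string length "
                    f"{len(self.qualities)} != sequence length {len(self.sequence)}"
                )
            if any(q < 0 for q in self.qualities):
                raise ParseError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleSet:
    """A labelled collection of reads plus their read -> group assignment.

    Reads absent from ``group_of`` are unassigned and are excluded from
    all group-level analyses.
    """

    sample_label: str
    reads: list[ReadRecord]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {r.read_id for r in self.reads}
        orphans = [k for k in self.group_of if k not in ids]
        if orphans:
            raise ConfigurationError(
                f"sample {self.sample_label!r}: group assignments for unknown "
                f"read ids: {orphans[:5]}"
            )

    def assigned_reads(self, group: str) -> list[ReadRecord]:
        return [r for r in self.reads if self.group_of.get(r.read_id) == group]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reads:
            g = self.group_of.get(r.read_id)
            if g is not None:
                counts[g] = counts.get(g, 0) + 1
        return counts


def read_sequences(path: str | Path, format: str) -> list[ReadRecord]:
    """Parse a FASTA/FASTQ file into ReadRecords, order preserved.

    An empty file yields an empty list; a malformed record raises
    :class:`ParseError` naming the record index.
    """
    if format not in _VALID_FORMATS:
        raise ConfigurationError(f"unknown format {format!r}; expected one of {_VALID_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    records: list[ReadRecord] = []
    iterator = SeqIO.parse(str(path), format)
    index = 0
    while True:
        try:
            rec = next(iterator)
        except StopIteration:
            break
        except ValueError as exc:
            raise ParseError(f"{path}: record {index}: {exc}") from exc
        quals = None
        if format == "fastq":
            quals = list(rec.letter_annotations["phred_quality"])
        records.append(ReadRecord(rec.id, str(rec.seq), quals))
        index += 1
    return records


def write_fasta(reads: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_fastq(reads: Sequence[ReadRecord], path: str | Path, default_phred: int = 40) -> None:
    """Write Phred+33 FASTQ; reads lacking qualities get a constant score."""
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [default_phred] * len(r)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qline}\n")


def quality_filter(
    reads: Sequence[ReadRecord],
    min_phred: int = 20,
    mode: str = "mean",
    allow_missing_qualities: bool = True,
) -> list[ReadRecord]:
    """Retain reads with no ``N`` whose Phred scores exceed ``min_phred``.

    ``mode="mean"`` requires the per-read mean Phred to be strictly
    greater than the threshold; ``mode="min"`` requires every base to
    clear it.  Reads without qualities (FASTA input) are only N-screened
    unless ``allow_missing_qualities`` is False, in which case they are a
    configuration error.
    """
    if mode not in ("mean", "min"):
        raise ConfigurationError(f"unknown quality filter mode {mode!r}")
    missing = [r.read_id for r in reads if r.qualities is None]
    if missing and not allow_missing_qualities:
        raise ConfigurationError(
            f"mode={mode!r} requires qualities; reads without them: {missing[:10]}"
        )
    kept = []
    for r in reads:
        if "N" in r.sequence:
            continue
        if r.qualities is not None and len(r.qualities) > 0:
            if mode == "mean":
                if not sum(r.qualities) / len(r.qualities) > min_phred:
                    continue
            else:
                if not min(r.qualities) > min_phred:
                    continue
        kept.append(r)
    logger.info("quality_filter: %d/%d reads retained", len(kept), len(reads))
    return kept


def truncate_region(
    reads: Sequence[ReadRecord], start: int, length: int | str
) -> list[ReadRecord]:
    """Slice every read to ``[start, start+length)``; short reads are dropped.

    ``length="to_end"`` keeps everything from ``start`` on.
    """
    if start < 0:
        raise ConfigurationError("start must be >= 0")
    to_end = length == "to_end"
    if not to_end and (not isinstance(length, int) or length <= 0):
        raise ConfigurationError(f"length must be a positive int or 'to_end', got {length!r}")
    out, dropped = [], 0
    for r in reads:
        end = len(r) if to_end else start + length
        if len(r) < (start + 1 if to_end else end):
            dropped += 1
            continue
        quals = r.qualities[start:end] if r.qualities is not None else None
        out.append(ReadRecord(r.read_id, r.sequence[start:end], quals))
    if dropped:
        logger.info("truncate_region: dropped %d reads shorter than the region", dropped)
    return out


def _best_match(sequence: str, primer: str, offsets: range) -> tuple[int, int]:
    """Return (offset, mismatches) of the best IUPAC-aware placement."""
    best = (-1, len(primer) + 1)
    for off in offsets:
        if off < 0 or off + len(primer) > len(sequence):
            continue
        mm = 0
        for p, s in zip(primer, sequence[off:off + len(primer)]):
            if s not in IUPAC.get(p, ""):
                mm += 1
                if mm >= best[1]:
                    break
        if mm < best[1]:
            best = (off, mm)
    return best


def strip_primers(
    reads: Sequence[ReadRecord],
    forward_primer: str,
    reverse_primer: str,
    max_mismatches: int = 1,
    deduplicate: bool = False,
    search_window: int = 30,
) -> list[ReadRecord]:
    """Extract the insert between the primers; unmatched reads are dropped.

    The forward primer must sit within the first ``search_window`` nt and
    the reverse-complemented reverse primer within the last
    ``search_window`` nt, each with at most ``max_mismatches`` IUPAC-aware
    mismatches.  With ``deduplicate`` identical inserts collapse to the
    first-seen representative.
    """
    if not forward_primer or not reverse_primer:
        raise ConfigurationError("primer strings must be non-empty")
    for p in (forward_primer, reverse_primer):
        bad = [c for c in p.upper() if c not in IUPAC]
        if bad:
            raise ConfigurationError(f"primer {p!r} contains non-IUPAC characters {bad}")
    fwd = forward_primer.upper()
    rev_rc = str(Seq(reverse_primer.upper()).reverse_complement())
    out, dropped = [], 0
    seen: set[str] = set()
    for r in reads:
        f_off, f_mm = _best_match(r.sequence, fwd, range(0, min(search_window, len(r))))
        tail_start = max(0, len(r) - search_window)
        r_off, r_mm = _best_match(
            r.sequence, rev_rc, range(tail_start, len(r) - len(rev_rc) + 1)
        )
        if f_off < 0 or r_off < 0 or f_mm > max_mismatches or r_mm > max_mismatches:
            dropped += 1
            continue
        lo, hi = f_off + len(fwd), r_off
        if hi <= lo:
            dropped += 1
            continue
        insert = r.sequence[lo:hi]
        if deduplicate:
            if insert in seen:
                continue
            seen.add(insert)
        quals = r.qualities[lo:hi] if r.qualities is not None else None
        out.append(ReadRecord(r.read_id, insert, quals))
    if dropped:
        logger.info("strip_primers: dropped %d reads without both primers", dropped)
    return out


def read_group_table(path: str | Path) -> dict[str, str]:
    """Parse a two-column (read_id TAB group) table; '#' starts a comment."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def write_group_table(group_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, grp in group_of.items():
            fh.write(f"{rid}\t{grp}\n")
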