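"""Raw-read processing: quality conversion, trimming, length selection, collapsing.

Turns FASTQ small-RNA reads into collapsed, length-selected sequence tags with
per-library counts.  The fixed stage order is::

    quality-convert -> adapter-trim -> quality-trim -> N-filter -> length-filter -> collapse

Every read is accounted for in exactly one :class:`ProcessingTally` bucket, so
the conservation identity ``n_input == n_adapter_only + n_quality_dropped +
n_n_dropped + n_length_dropped + n_passed`` holds on every run.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO

VALID_BASES = set("ACGTN")

#: default 20-22 nt window for mature small-RNA tags
DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 22
DEFAULT_QUALITY_THRESHOLD = 20
DEFAULT_MIN_OVERLAP = 6


@dataclass(frozen=True)
class SmallRNARead:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if any(q < 0 or q > 60 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: Phred scores must lie in [0, 60]")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CollapsedTag:
    """A distinct processed sequence with its occurrence count in one library."""

    sequence: str
    count: int
    library_label: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed tag count must be >= 1")
        if "N" in self.sequence:
            raise ValueError("collapsed tags must be N-free")


@dataclass
class ProcessingTally:
    """Audit of where every input read went."""

    n_input: int = 0
    n_adapter_only: int = 0
    n_quality_dropped: int = 0
    n_n_dropped: int = 0
    n_length_dropped: int = 0
    n_passed: int = 0

    def check(self) -> None:
        parts = (
            self.n_adapter_only
            + self.n_quality_dropped
            + self.n_n_dropped
            + self.n_length_dropped
            + self.n_passed
        )
        if parts != self.n_input:
            raise AssertionError(
                f"tally conservation violated: {parts} classified != {self.n_input} input"
            )

    def to_json(self, path: str | Path) -> None:
        self.check()
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def convert_solexa_quality(q_solexa: int) -> int:
    """Convert a legacy Solexa (odds-based) score to a Phred score.

    Solexa scores are ``10*log10(p/(1-p))`` while Phred scores are
    ``-10*log10(p)``; the standard conversion is
    ``Q_phred = 10*log10(10**(Q_solexa/10) + 1)``, rounded to the nearest
    integer.  Monotonic non-decreasing; defined for ``q_solexa >= -5``.
    """
    if q_solexa < -5:
        raise ValueError(f"Solexa quality {q_solexa} below the defined minimum of -5")
    return round(10.0 * math.log10(10.0 ** (q_solexa / 10.0) + 1.0))


def trim_adapter(
    read: SmallRNARead, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SmallRNARead:
    """Remove a 3' adapter by exact prefix matching.

    Scans left to right for the first position where either the full adapter
    occurs (read-through past the adapter) or a prefix of the adapter of
    length >= ``min_overlap`` runs to the end of the read.  The read is
    truncated at that position, qualities in lockstep.  No match returns the
    read unchanged; a read that is adapter from position 0 becomes empty.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    n, la = len(seq), len(adapter)
    for i in range(n):
        tail = n - i
        if tail >= la:
            if seq[i : i + la] == adapter:
                return _truncate(read, i)
        elif tail >= min_overlap and seq[i:] == adapter[:tail]:
            return _truncate(read, i)
    return read


def quality_trim(read: SmallRNARead, q_threshold: int = DEFAULT_QUALITY_THRESHOLD) -> SmallRNARead:
    """Trim the longest 3' suffix of bases with quality < ``q_threshold``.

    Interior low-quality bases are untouched; only the trailing run is cut.
    """
    if not 0 <= q_threshold <= 60:
        raise ValueError("q_threshold must lie in [0, 60]")
    end = len(read)
    while end > 0 and read.qualities[end - 1] < q_threshold:
        end -= 1
    if end == len(read):
        return read
    return _truncate(read, end)


def _truncate(read: SmallRNARead, end: int) -> SmallRNARead:
    return SmallRNARead(read.read_id, read.sequence[:end], read.qualities[:end])


def length_filter(
    sequences: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[str], int]:
    """Keep sequences with ``min_len <= len <= max_len`` (both inclusive).

    Returns the passed sequences and the number dropped.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    passed, dropped = [], 0
    for seq in sequences:
        if min_len <= len(seq) <= max_len:
            passed.append(seq)
        else:
            dropped += 1
    return passed, dropped


def collapse_reads(sequences: Iterable[str], library_label: str) -> list[CollapsedTag]:
    """Collapse identical sequences into counted tags.

    Output is sorted by descending count, ties broken lexicographically by
    sequence, so the result is independent of input order.
    """
    counts = Counter(sequences)
    return [
        CollapsedTag(seq, n, library_label)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass
class ReadProcessingParams:
    adapter: str
    min_overlap: int = DEFAULT_MIN_OVERLAP
    q_threshold: int = DEFAULT_QUALITY_THRESHOLD
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


DropReason = Literal["adapter_only", "quality_dropped", "n_dropped", "length_dropped"]


def process_read(
    read: SmallRNARead, params: ReadProcessingParams
) -> tuple[str | None, DropReason | None]:
    """Run one read through the trimming/filtering cascade.

    Returns ``(processed_sequence, None)`` for a surviving read or
    ``(None, reason)`` for a dropped one.  Qualities are assumed to already
    be Phred-scaled (see :func:`read_fastq`).
    """
    read = trim_adapter(read, params.adapter, params.min_overlap)
    if len(read) == 0:
        return None, "adapter_only"
    read = quality_trim(read, params.q_threshold)
    if len(read) == 0:
        return None, "quality_dropped"
    if "N" in read.sequence:
        return None, "n_dropped"
    if not params.min_len <= len(read) <= params.max_len:
        return None, "length_dropped"
    return read.sequence, None


def process_library(
    reads: Iterable[SmallRNARead],
    params: ReadProcessingParams,
    library_label: str,
) -> tuple[list[CollapsedTag], ProcessingTally]:
    """Process a whole library into collapsed tags plus an audit tally."""
    tally = ProcessingTally()
    passed: list[str] = []
    for read in reads:
        tally.n_input += 1
        seq, reason = process_read(read, params)
        if seq is None:
            setattr(tally, f"n_{reason}", getattr(tally, f"n_{reason}") + 1)
        else:
            tally.n_passed += 1
            passed.append(seq)
    tally.check()
    return collapse_reads(passed, library_label), tally


# ---------------------------------------------------------------------------
# FASTQ input


def detect_quality_encoding(path: str | Path, n_records: int = 200) -> str:
    """Guess the quality encoding of a FASTQ file.

    Any character with ordinal < 59 (``';'``) can only occur under the +33
    offset; any character above 74 (``'J'``, Phred 41 at +33) indicates the
    legacy +64 Solexa encoding.  A file whose characters all fall in the
    ambiguous 59-74 band (uniformly mid-range +33 scores, or uniformly very
    low Solexa scores) is taken as +33, the modern default.
    """
    lo, hi = 255, 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i // 4 >= n_records:
                break
            if i % 4 == 3:
                stripped = line.rstrip("\n")
                if stripped:
                    lo = min(lo, min(ord(c) for c in stripped))
                    hi = max(hi, max(ord(c) for c in stripped))
    if lo == 255:
        raise ValueError(f"{path}: no quality strings found")
    if lo < 59:
        return "phred33"
    if hi > 74:
        return "solexa64"
    return "phred33"


def read_fastq(path: str | Path, encoding: str = "auto") -> Iterator[SmallRNARead]:
    """Iterate FASTQ records as :class:`SmallRNARead` with Phred qualities.

    ``encoding`` is ``phred33``, ``solexa64`` or ``auto``.  Solexa scores are
    converted through :func:`convert_solexa_quality`.
    """
    if encoding == "auto":
        encoding = detect_quality_encoding(path)
    if encoding == "phred33":
        for rec in SeqIO.parse(str(path), "fastq"):
            yield SmallRNARead(
                rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"])
            )
    elif encoding == "solexa64":
        for rec in SeqIO.parse(str(path), "fastq-solexa"):
            quals = tuple(
                convert_solexa_quality(q) for q in rec.letter_annotations["solexa_quality"]
            )
            yield SmallRNARead(rec.id, str(rec.seq).upper(), quals)
    else:
        raise ValueError(f"unknown quality encoding {encoding!r}")


def write_tags_tsv(tags: Iterable[CollapsedTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tlibrary\n")
        for t in tags:
            fh.write(f"{t.sequence}\t{t.count}\t{t.library_label}\n")
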