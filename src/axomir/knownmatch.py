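"""Mismatch-tolerant assignment of collapsed tags to known mature miRNAs.

Re-implements, at small-RNA scale, an ungapped short-read mapper in the
style of ``bowtie -v 2``: a tag matches a reference mature miRNA if it can be
placed, in full and without gaps, at some offset inside the reference with at
most ``max_mismatch`` substitutions.  Each tag's whole count is credited to
its single best hit under a deterministic tie-break (fewest mismatches, then
lexicographically smallest miRNA name, then smallest offset).  Indels are
deliberately not modelled here; they are handled downstream by the
Levenshtein clustering of unmapped tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from axomir.readproc import CollapsedTag

DEFAULT_MAX_MISMATCH = 2

_ARM_SUFFIXES = ("-5p", "-3p")


@dataclass(frozen=True)
class MiRNAReferenceEntry:
    """One mature miRNA: name, derived family key, T-encoded sequence."""

    name: str
    family_key: str
    sequence: str


@dataclass(frozen=True)
class MatchResult:
    """Best ungapped placement of a tag, or an explicit non-match."""

    tag_sequence: str
    mirna_name: str | None
    n_mismatches: int | None
    offset: int | None

    @property
    def matched(self) -> bool:
        return self.mirna_name is not None


def family_key(mirna_name: str) -> str:
    """Derive the family key from a miRBase-style mature name.

    Strips the species prefix (token before the first hyphen) and a trailing
    arm suffix (``-5p``/``-3p``), lowercases the rest; the paralog letter or
    number is kept.  ``"aml-let-7a-5p" -> "let-7a"``.  A name with no hyphen
    is returned lowercased unchanged.
    """
    if not mirna_name:
        raise ValueError("miRNA name must be non-empty")
    name = mirna_name.lower()
    for suffix in _ARM_SUFFIXES:
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    if "-" in name:
        name = name.split("-", 1)[1]
    return name


def load_reference(fasta: str | Path) -> list[MiRNAReferenceEntry]:
    """Load a mature-miRNA FASTA (miRBase-style headers).

    U is mapped to T and sequences are uppercased.  Duplicate names, empty
    sequences and non-ACGTU characters are format errors.
    """
    entries: list[MiRNAReferenceEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate reference name {name!r}")
        seen.add(name)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"reference entry {name!r} has an empty sequence")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"reference entry {name!r} has invalid characters {sorted(bad)}")
        entries.append(MiRNAReferenceEntry(name, family_key(name), seq))
    if not entries:
        raise ValueError(f"{fasta}: no FASTA records found")
    return entries


class ReferenceIndex:
    """Reference entries plus an exact-substring fast path.

    The dictionary maps every substring (lengths ``min_tag_len..max ref
    len``) of every reference to its best 0-mismatch placement under the
    global tie-break, so the brute-force scan only runs for inexact tags.
    """

    def __init__(self, entries: Sequence[MiRNAReferenceEntry], min_tag_len: int = 15):
        self.entries = sorted(entries, key=lambda e: e.name)
        self._exact: dict[str, tuple[str, int]] = {}
        for entry in self.entries:  # name-sorted: first write wins the tie-break
            seq = entry.sequence
            for length in range(min_tag_len, len(seq) + 1):
                for off in range(len(seq) - length + 1):
                    self._exact.setdefault(seq[off : off + length], (entry.name, off))

    def exact_hit(self, tag: str) -> tuple[str, int] | None:
        return self._exact.get(tag)


def match_tag(
    tag: str,
    reference: ReferenceIndex | Sequence[MiRNAReferenceEntry],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> MatchResult:
    """Find the best ungapped placement of ``tag`` inside any reference.

    Considers every offset at which the full tag fits inside a reference
    sequence; the placement distance is the Hamming distance.  Returns the
    minimum-mismatch placement if it is ``<= max_mismatch``, with ties broken
    by (mismatches, miRNA name, offset); otherwise an unmatched result.
    Tags longer than a reference never match it.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if isinstance(reference, ReferenceIndex):
        index = reference
    else:
        index = ReferenceIndex(reference)
    hit = index.exact_hit(tag)
    if hit is not None:
        return MatchResult(tag, hit[0], 0, hit[1])
    n = len(tag)
    best: tuple[int, str, int] | None = None
    for entry in index.entries:  # sorted by name: first strict improvement wins ties
        ref = entry.sequence
        for off in range(len(ref) - n + 1):
            limit = max_mismatch if best is None else min(max_mismatch, best[0] - 1)
            mm = 0
            for a, b in zip(tag, ref[off : off + n]):
                if a != b:
                    mm += 1
                    if mm > limit:
                        break
            else:
                best = (mm, entry.name, off)
                if mm == 0:
                    return MatchResult(tag, entry.name, 0, off)
    if best is None:
        return MatchResult(tag, None, None, None)
    return MatchResult(tag, best[1], best[0], best[2])


@dataclass
class KnownCountTable:
    """Per-miRNA and per-family counts for the two libraries."""

    mirna: pd.DataFrame  # index: miRNA name; columns: one per library
    family: pd.DataFrame  # index: family key; columns: one per library

    @property
    def mapped_totals(self) -> dict[str, int]:
        return {lib: int(self.mirna[lib].sum()) for lib in self.mirna.columns}

    def write(self, mirna_path: str | Path, family_path: str | Path) -> None:
        self.mirna.rename_axis("mirna").reset_index().to_csv(
            mirna_path, sep="\t", index=False
        )
        self.family.rename_axis("family").reset_index().to_csv(
            family_path, sep="\t", index=False
        )


def count_known(
    tags_by_library: Mapping[str, Iterable[CollapsedTag]],
    reference: ReferenceIndex | Sequence[MiRNAReferenceEntry],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[KnownCountTable, pd.DataFrame]:
    """Assign tags to miRNAs and enumerate per-miRNA / per-family counts.

    Each tag's full count goes to its single best hit; unmatched tags are
    returned as a per-sequence count table (one row per sequence, one count
    column per library) that feeds novel-family discovery.  Counts are
    conserved: mapped totals + unmapped totals equal the input totals.
    """
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(reference)
    libraries = list(tags_by_library)
    name_to_family = {e.name: e.family_key for e in reference.entries}
    mirna_counts: dict[str, dict[str, int]] = {lib: {} for lib in libraries}
    unmapped: dict[str, dict[str, int]] = {}
    match_cache: dict[str, MatchResult] = {}
    for lib in libraries:
        for tag in tags_by_library[lib]:
            result = match_cache.get(tag.sequence)
            if result is None:
                result = match_tag(tag.sequence, reference, max_mismatch)
                match_cache[tag.sequence] = result
            if result.matched:
                counts = mirna_counts[lib]
                counts[result.mirna_name] = counts.get(result.mirna_name, 0) + tag.count
            else:
                row = unmapped.setdefault(tag.sequence, {l: 0 for l in libraries})
                row[lib] += tag.count

    mirna_df = (
        pd.DataFrame(mirna_counts).fillna(0).astype(int).sort_index()
        if any(mirna_counts.values())
        else pd.DataFrame(columns=libraries, dtype=int)
    )
    mirna_df = mirna_df.reindex(columns=libraries, fill_value=0)
    if len(mirna_df):
        fam = mirna_df.groupby([name_to_family[n] for n in mirna_df.index]).sum()
    else:
        fam = pd.DataFrame(columns=libraries, dtype=int)
    unmapped_df = pd.DataFrame(
        [{"sequence": s, **{f"count_{lib}": c for lib, c in row.items()}} for s, row in unmapped.items()]
    )
    if len(unmapped_df):
        unmapped_df = unmapped_df.sort_values("sequence", ignore_index=True)
    else:
        unmapped_df = pd.DataFrame(
            columns=["sequence"] + [f"count_{lib}" for lib in libraries]
        )
    return KnownCountTable(mirna=mirna_df, family=fam.sort_index()), unmapped_df
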