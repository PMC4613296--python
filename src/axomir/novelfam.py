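"""Putative novel miRNA family discovery from unmapped tags.

Unmapped sequences occurring more than ``min_occurrences`` times (default 7,
strict) in at least one library are clustered by Levenshtein distance at a
threshold of 4.  Clustering is greedy and abundance-ordered: the most
abundant unassigned candidate seeds a family, and every later unassigned
candidate within the distance threshold of that seed joins it.  This makes
the most common sequence of each group its natural seed and representative,
and the pass is deterministic.  A single-linkage mode (connected components
of the <=threshold graph) is available for sensitivity analysis.

Family representatives are annotated against the known mature reference by
exhaustive local alignment (match +1, mismatch -1, gap -2), a small-scale
stand-in for a BLAST partial-similarity search; an empty hit list is the
signature of a genuinely novel sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from axomir.knownmatch import MiRNAReferenceEntry

DEFAULT_MIN_OCCURRENCES = 7
DEFAULT_MAX_DIST = 4
FAMILY_ID_PREFIX = "miR-pn"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions).

    Full dynamic-programming matrix, vectorized one row at a time; the
    in-row insertion recurrence is resolved with a prefix minimum of
    ``candidate[j] - j``.
    """
    if not a:
        return len(b)
    if not b:
        return len(a)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    m = len(b)
    idx = np.arange(1, m + 1)
    prev = np.arange(m + 1)
    for i, ca in enumerate(a.encode(), start=1):
        sub = prev[:-1] + (bv != ca)
        cand = np.minimum(sub, prev[1:] + 1)
        cand = np.minimum(cand, i + idx)  # insertion chain rooted at cur[0] = i
        cur = np.empty(m + 1, dtype=prev.dtype)
        cur[0] = i
        cur[1:] = idx + np.minimum.accumulate(cand - idx)
        prev = cur
    return int(prev[-1])


def levenshtein_within(a: str, b: str, limit: int) -> int:
    """Banded edit distance, exact for distances <= ``limit``.

    Returns the true distance when it is <= ``limit`` and ``limit + 1``
    otherwise (pairs outside the band are correctly classified as beyond the
    threshold without computing their exact distance).
    """
    if limit < 0:
        raise ValueError("limit must be >= 0")
    if abs(len(a) - len(b)) > limit:
        return limit + 1
    if a == b:
        return 0
    n, m = len(a), len(b)
    big = limit + 1
    prev = {j: j for j in range(min(m, limit) + 1)}
    for i in range(1, n + 1):
        cur: dict[int, int] = {}
        lo, hi = max(0, i - limit), min(m, i + limit)
        for j in range(lo, hi + 1):
            if j == 0:
                cur[j] = i
                continue
            best = prev.get(j - 1, big) + (a[i - 1] != b[j - 1])
            up = prev.get(j, big) + 1
            left = cur.get(j - 1, big) + 1
            cur[j] = min(best, up, left)
        if min(cur.values()) > limit:
            return big
        prev = cur
    return min(prev.get(m, big), big)


@dataclass(frozen=True)
class CandidateTag:
    """An unmapped sequence abundant enough to enter clustering."""

    sequence: str
    count_control: int
    count_blastema: int

    @property
    def total(self) -> int:
        return self.count_control + self.count_blastema


@dataclass(frozen=True)
class AnnotationHit:
    """A partial-similarity hit of a family representative on a known miRNA."""

    mirna_name: str
    alignment_score: float
    aligned_span: tuple[int, int]  # 0-based half-open, on the representative
    identity_fraction: float


@dataclass
class NovelFamily:
    """A cluster of candidate sequences forming one putative novel miRNA family."""

    family_id: str
    representative: str
    members: list[tuple[str, int, int]]  # (sequence, count_control, count_blastema)
    total_control: int
    total_blastema: int
    annotation: list[AnnotationHit] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


def select_candidates(
    unmapped: pd.DataFrame | Iterable[CandidateTag],
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    count_columns: tuple[str, str] = ("count_control", "count_blastema"),
) -> list[CandidateTag]:
    """Apply the abundance filter: keep tags occurring strictly more than
    ``min_occurrences`` times in at least one library.

    Accepts the unmapped-tag table from ``count_known`` (columns ``sequence``
    plus per-library counts) or an iterable of :class:`CandidateTag`.
    A tag at exactly the threshold in both libraries is excluded.
    """
    if isinstance(unmapped, pd.DataFrame):
        cc, cb = count_columns
        tags = (
            CandidateTag(row.sequence, int(getattr(row, cc)), int(getattr(row, cb)))
            for row in unmapped.itertuples(index=False)
        )
    else:
        tags = iter(unmapped)
    return [
        t
        for t in tags
        if t.count_control > min_occurrences or t.count_blastema > min_occurrences
    ]


def _sort_candidates(candidates: Iterable[CandidateTag]) -> list[CandidateTag]:
    return sorted(candidates, key=lambda t: (-t.total, t.sequence))


def _make_family(family_id: str, members: list[CandidateTag]) -> NovelFamily:
    rep = min(members, key=lambda t: (-t.total, t.sequence))
    return NovelFamily(
        family_id=family_id,
        representative=rep.sequence,
        members=[(t.sequence, t.count_control, t.count_blastema) for t in members],
        total_control=sum(t.count_control for t in members),
        total_blastema=sum(t.count_blastema for t in members),
    )


def cluster_families(
    candidates: Sequence[CandidateTag],
    max_dist: int = DEFAULT_MAX_DIST,
    method: Literal["greedy", "single-linkage"] = "greedy",
) -> list[NovelFamily]:
    """Group candidate tags into families by Levenshtein distance.

    In the default greedy mode candidates are visited in order of decreasing
    summed count (ties lexicographic); each unassigned candidate joins the
    first family whose seed is within ``max_dist`` edits, otherwise it seeds
    a new family.  Family seeds are therefore pairwise more than ``max_dist``
    apart, and the seed is always its family's most abundant member, hence
    its representative.  Family ids are ``miR-pn`` plus a zero-padded ordinal
    in seed order.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    ordered = _sort_candidates(candidates)
    if not ordered:
        return []
    if method == "greedy":
        groups = _greedy_groups(ordered, max_dist)
    elif method == "single-linkage":
        groups = _single_linkage_groups(ordered, max_dist)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    width = max(4, len(str(len(groups))))
    return [
        _make_family(f"{FAMILY_ID_PREFIX}{i:0{width}d}", members)
        for i, members in enumerate(groups, start=1)
    ]


def _greedy_groups(
    ordered: list[CandidateTag], max_dist: int
) -> list[list[CandidateTag]]:
    seeds: list[str] = []
    groups: list[list[CandidateTag]] = []
    for cand in ordered:
        for gi, seed in enumerate(seeds):
            if levenshtein_within(seed, cand.sequence, max_dist) <= max_dist:
                groups[gi].append(cand)
                break
        else:
            seeds.append(cand.sequence)
            groups.append([cand])
    return groups


def _single_linkage_groups(
    ordered: list[CandidateTag], max_dist: int
) -> list[list[CandidateTag]]:
    # union-find over the <=max_dist graph; group order by most abundant member
    parent = list(range(len(ordered)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if levenshtein_within(ordered[i].sequence, ordered[j].sequence, max_dist) <= max_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[CandidateTag]] = {}
    for i, cand in enumerate(ordered):
        groups.setdefault(find(i), []).append(cand)
    # roots are the smallest ordered index in each component, i.e. its most
    # abundant member, so sorting roots preserves abundance order
    return [groups[r] for r in sorted(groups)]


# ---------------------------------------------------------------------------
# Annotation

DEFAULT_SCORE_FLOOR = 15.0


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def annotate_family(
    family: NovelFamily,
    reference: Sequence[MiRNAReferenceEntry],
    score_floor: float = DEFAULT_SCORE_FLOOR,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[AnnotationHit]:
    """Search the family representative against every known mature sequence.

    Local (Smith-Waterman) alignment with the given scores; hits scoring at
    least ``score_floor`` are reported sorted by score descending then name.
    An empty list means no known miRNA shows even partial similarity.
    """
    rep = family.representative
    if len(rep) < 10:
        raise ValueError("representative too short to annotate (< 10 nt)")
    aligner = _aligner(match, mismatch, gap)
    hits: list[AnnotationHit] = []
    for entry in reference:
        score = aligner.score(rep, entry.sequence)
        if score < score_floor:
            continue
        alignment = aligner.align(rep, entry.sequence)[0]
        counts = alignment.counts()
        aligned_cols = counts.gaps + counts.identities + counts.mismatches
        blocks = alignment.aligned[0]
        span = (int(blocks[0][0]), int(blocks[-1][1]))
        hits.append(
            AnnotationHit(
                mirna_name=entry.name,
                alignment_score=float(score),
                aligned_span=span,
                identity_fraction=counts.identities / aligned_cols,
            )
        )
    hits.sort(key=lambda h: (-h.alignment_score, h.mirna_name))
    return hits


# ---------------------------------------------------------------------------
# Output tables


def families_frame(families: Sequence[NovelFamily]) -> pd.DataFrame:
    """One row per family: representative, member count, per-library reads."""
    return pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "representative": f.representative,
                "n_member_sequences": f.n_members,
                "reads_mature": f.total_control,
                "reads_blastema": f.total_blastema,
            }
            for f in families
        ],
        columns=[
            "family_id",
            "representative",
            "n_member_sequences",
            "reads_mature",
            "reads_blastema",
        ],
    )


def members_frame(families: Sequence[NovelFamily]) -> pd.DataFrame:
    rows = [
        {
            "family_id": f.family_id,
            "sequence": seq,
            "count_control": cc,
            "count_blastema": cb,
        }
        for f in families
        for seq, cc, cb in f.members
    ]
    return pd.DataFrame(
        rows, columns=["family_id", "sequence", "count_control", "count_blastema"]
    )


def annotation_frame(families: Sequence[NovelFamily]) -> pd.DataFrame:
    rows = [
        {
            "family_id": f.family_id,
            "mirna_name": h.mirna_name,
            "alignment_score": h.alignment_score,
            "span_start": h.aligned_span[0],
            "span_end": h.aligned_span[1],
            "identity_fraction": round(h.identity_fraction, 6),
        }
        for f in families
        for h in f.annotation
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "mirna_name",
            "alignment_score",
            "span_start",
            "span_end",
            "identity_fraction",
        ],
    )


def write_representatives_fasta(families: Sequence[NovelFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in families:
            fh.write(f">{f.family_id}\n{f.representative}\n")
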