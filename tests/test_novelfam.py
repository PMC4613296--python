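"""Edit-distance clustering of abundant unmapped tags into novel families."""

import random

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from axomir.novelfam import (
    CandidateTag,
    annotate_family,
    cluster_families,
    levenshtein,
    levenshtein_within,
    select_candidates,
)

from conftest import entry

SEQ = st.text(alphabet="ACGT", min_size=0, max_size=25)


def reference_dp(a: str, b: str) -> int:
    """Textbook full-matrix edit distance, kept independent of the package."""
    n, m = len(a), len(b)
    D = list(range(m + 1))
    for i in range(1, n + 1):
        prev_diag, D[0] = D[0], i
        for j in range(1, m + 1):
            prev_diag, D[j] = D[j], min(
                prev_diag + (a[i - 1] != b[j - 1]), D[j] + 1, D[j - 1] + 1
            )
    return D[m]


def smith_waterman(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Exhaustive local-alignment DP, independent oracle for annotation scores."""
    best = 0.0
    H = [[0.0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("GATTACAGATTACAGATTAC", "GATTACAGATTACAGATTAC", 0),
            ("AAAAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAAAT", 1),
            # one 5' deletion plus one 3' insertion
            ("ACGTACGTACGTACGTACGT", "CGTACGTACGTACGTACGTA", 2),
            ("", "ACGT", 4),
            ("ACGT", "", 4),
        ],
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    @given(SEQ, SEQ)
    def test_agrees_with_reference_dp(self, a, b):
        assert levenshtein(a, b) == reference_dp(a, b)

    @given(SEQ, SEQ, SEQ)
    def test_metric_axioms(self, a, b, c):
        dab = levenshtein(a, b)
        assert (dab == 0) == (a == b)
        assert dab == levenshtein(b, a)
        assert dab <= levenshtein(a, c) + levenshtein(c, b)

    @given(SEQ, SEQ, st.integers(min_value=0, max_value=8))
    def test_banded_classification(self, a, b, limit):
        assert levenshtein_within(a, b, limit) == min(reference_dp(a, b), limit + 1)


class TestSelectCandidates:
    @pytest.mark.parametrize(
        "cc,cb,kept",
        [(7, 7, False), (0, 8, True), (8, 0, True), (8, 8, True), (0, 0, False)],
    )
    def test_strict_threshold_either_sample(self, cc, cb, kept):
        got = select_candidates([CandidateTag("A" * 20, cc, cb)])
        assert (len(got) == 1) is kept

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {
                "sequence": ["A" * 20, "C" * 20],
                "count_control": [9, 7],
                "count_blastema": [0, 7],
            }
        )
        got = select_candidates(df)
        assert [t.sequence for t in got] == ["A" * 20]


def tag(seq, cc=0, cb=10):
    return CandidateTag(seq, cc, cb)


class TestClusterFamilies:
    def test_two_near_sequences_merge(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACTTACGTACGA"  # 2 substitutions from a
        fams = cluster_families([tag(a, 5, 5), tag(b, 4, 5)], max_dist=4)
        assert len(fams) == 1
        assert fams[0].representative == a
        assert (fams[0].total_control, fams[0].total_blastema) == (9, 10)
        assert fams[0].family_id.startswith("miR-pn")

    def test_distant_sequences_stay_singletons(self):
        seqs = ["A" * 20, "C" * 20, "G" * 20]
        fams = cluster_families([tag(s) for s in seqs], max_dist=4)
        assert len(fams) == 3
        assert all(f.n_members == 1 for f in fams)

    def test_max_dist_zero_gives_exact_groups(self):
        fams = cluster_families(
            [tag("A" * 20), tag("A" * 19 + "T")], max_dist=0
        )
        assert len(fams) == 2

    def test_empty_input(self):
        assert cluster_families([], 4) == []

    def test_representative_tie_break(self):
        a, b = "A" * 20, "A" * 19 + "T"
        fams = cluster_families([tag(a, 5, 5), tag(b, 5, 5)], max_dist=4)
        assert fams[0].representative == a  # equal counts: lexicographic

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGT", min_size=18, max_size=24),
                st.integers(min_value=0, max_value=50),
                st.integers(min_value=0, max_value=50),
            ),
            min_size=1,
            max_size=25,
            unique_by=lambda t: t[0],
        )
    )
    def test_partition_and_seed_separation(self, rows):
        cands = [CandidateTag(s, cc, cb) for s, cc, cb in rows]
        fams = cluster_families(cands, max_dist=4)
        members = [m[0] for f in fams for m in f.members]
        assert sorted(members) == sorted(t.sequence for t in cands)
        assert sum(f.total_control for f in fams) == sum(t.count_control for t in cands)
        assert sum(f.total_blastema for f in fams) == sum(t.count_blastema for t in cands)
        # greedy seeds (most abundant member of each family) pairwise > max_dist
        seeds = [
            min(f.members, key=lambda m: (-(m[1] + m[2]), m[0]))[0] for f in fams
        ]
        for i in range(len(seeds)):
            for j in range(i + 1, len(seeds)):
                assert reference_dp(seeds[i], seeds[j]) > 4
        # totals match member sums
        for f in fams:
            assert f.total_control == sum(m[1] for m in f.members)
            assert f.total_blastema == sum(m[2] for m in f.members)

    def test_single_linkage_matches_greedy_when_well_separated(self):
        rng = random.Random(5)
        centers = ["".join(rng.choices("ACGT", k=21)) for _ in range(50)]
        centers = [
            c
            for i, c in enumerate(centers)
            if all(reference_dp(c, d) > 12 for d in centers[:i])
        ][:4]
        cands = []
        for ci, center in enumerate(centers):
            cands.append(tag(center, 0, 30 - ci))
            for v in range(2):
                seq = list(center)
                for _ in range(2):
                    pos = rng.randrange(len(seq))
                    seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
                cands.append(tag("".join(seq), 0, 9 - v))
        greedy = cluster_families(cands, 4, "greedy")
        single = cluster_families(cands, 4, "single-linkage")
        as_sets = lambda fams: sorted(
            sorted(m[0] for m in f.members) for f in fams
        )
        assert as_sets(greedy) == as_sets(single)
        assert len(greedy) == len(centers)


class TestAnnotation:
    def _family(self, rep):
        return cluster_families([tag(rep)], 4)[0]

    def test_self_alignment_is_top_hit(self, toy_reference):
        rep = "TGAGGTAGTAGGTTGTATAGTT"  # equals let-7a-5p, 22 nt
        hits = annotate_family(self._family(rep), toy_reference)
        assert hits[0].mirna_name == "aml-let-7a-5p"
        assert hits[0].alignment_score == 22.0
        assert hits[0].identity_fraction == 1.0
        assert hits[0].aligned_span == (0, 22)

    def test_dissimilar_representative_gets_no_hits(self, toy_reference):
        rep = "CCCCCCGGGGGGCCCCCCGG"
        for e in toy_reference:
            assert smith_waterman(rep, e.sequence) < 15
        assert annotate_family(self._family(rep), toy_reference, score_floor=15) == []

    def test_score_floor_monotone(self, toy_reference):
        rep = "TGAGGTAGTAGGTTGTATAGTT"
        assert annotate_family(self._family(rep), toy_reference, score_floor=23.0) == []

    def test_scores_match_exhaustive_dp(self, toy_reference):
        rng = random.Random(11)
        for _ in range(15):
            rep = "".join(rng.choices("ACGT", k=rng.randint(20, 22)))
            hits = annotate_family(self._family(rep), toy_reference, score_floor=1.0)
            expected = {
                e.name: smith_waterman(rep, e.sequence) for e in toy_reference
            }
            got = {h.mirna_name: h.alignment_score for h in hits}
            for name, score in expected.items():
                if score >= 1.0:
                    assert got[name] == score
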