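# Methods

`axomir` implements the computational arm of a two-library small-RNA
sequencing comparison between uninjured axolotl tail tissue ("control" /
"mature") and the three-day regeneration blastema: known-miRNA counting and
the discovery of putative novel miRNA families from the unmapped remainder.
Each library is a single pooled replicate, which constrains everything
downstream — there is no within-condition variance to estimate, so all
comparisons are descriptive count statistics, not inference over biological
replicates.

## Read processing

Raw reads pass through a fixed cascade:

1. **Quality conversion.** Legacy Solexa (+64, odds-based) scores are mapped
   to Phred via `Q_phred = 10·log10(10^(Q_solexa/10) + 1)`, rounded to the
   nearest integer. Auto-detection uses the quality-character range: any
   ordinal < 59 forces +33; any ordinal > 74 forces Solexa +64; a file
   entirely inside the ambiguous band is read as +33 (the modern default).
2. **Adapter trimming** removes the leftmost exact occurrence of the 3'
   adapter — either the full adapter anywhere in the read, or a prefix of at
   least `min_overlap` (default 6) bases running to the read's 3' end.
   Matching is exact; with ≤ 36 nt reads and a 21 nt adapter, allowing
   adapter mismatches would buy little and cost determinism.
3. **Quality trimming** removes the longest 3' suffix of bases below Q20
   (default; the source protocol names no cutoff). Interior low-quality
   bases are kept — they are handled by the mismatch tolerance downstream.
4. **N-filter, length filter.** Reads containing N are dropped; survivors
   are kept only at 20–22 nt inclusive. Note that mature miRNAs genuinely
   reach 23–24 nt, so the window deliberately discards a slice of real
   signal; the synthetic generator reproduces this so tests exercise it.
5. **Collapsing** to unique tags with counts, ordered by count descending
   then sequence, making all downstream steps independent of read order.

Every read lands in exactly one tally bucket (`adapter_only`,
`quality_dropped`, `n_dropped`, `length_dropped`, `passed`); the tally
identity is asserted on every run and re-checked across stages by the
pipeline driver.

## Known-miRNA assignment

A tag is assigned by exhaustive ungapped placement: the full tag is slid
across every offset of every reference mature sequence, the placement cost
is the Hamming distance, and the tag maps if its best placement has at most
`max_mismatch = 2` substitutions. This reproduces the semantics of an
ungapped `-v 2`-style short-read aligner without the external binary, exact
at miRNA scale. Ties are broken deterministically: fewest mismatches, then
lexicographically smallest miRNA name, then smallest offset; a tag's whole
count is credited to that single best hit (the original reporting mode is
unknown; fractional assignment would make counts non-integral and harder to
audit). Only the sense strand is searched — mature miRNA references are
single-stranded. An exact-substring index provides a fast path for the
0-mismatch majority.

Family keys are derived from names: strip the species prefix (first
hyphen-delimited token) and a trailing `-5p`/`-3p` arm suffix, lowercase,
keep the paralog letter/number (`aml-let-7a-5p` → `let-7a`). Family counts
are sums over member miRNAs. Both per-miRNA and per-family tables are
reported, since "family" has no single operational definition in miRBase
naming.

## Novel-family discovery

Unmapped tags occurring **strictly more than 7 times in at least one
library** become candidates (the filter applies to exact collapsed
sequences, before any clustering; "either sample" is read per-sample, not
pooled). Candidates are clustered by Levenshtein distance at threshold 4:

- **Distance.** Unit-cost insertions, deletions and substitutions. The
  clustering path uses a banded dynamic program of half-width equal to the
  threshold: exact for distances within the band, and pairs outside it are
  correctly classified as beyond threshold without full computation. The
  full-matrix distance (vectorized row recurrence) is exposed separately
  and is the one property-tested against a textbook DP.
- **Linkage.** The threshold alone does not define a clustering, so the
  default is a greedy abundance-ordered pass: candidates are visited by
  summed count descending (ties lexicographic); each joins the first
  existing family whose *seed* is within threshold, else seeds a new family.
  This is deterministic, O(n·k) in distance evaluations, guarantees seeds
  pairwise farther apart than the threshold, and makes each family's most
  abundant sequence its seed — hence automatically its representative. A
  single-linkage mode (connected components of the ≤ threshold graph) is
  provided for sensitivity analysis; in well-separated data (all pairwise
  distances either ≤ 4 or > 8) the two coincide, and tests verify this.
- **Representative.** The member with the highest summed count, ties to the
  lexicographically smallest sequence. Family ids are `miR-pn` plus a
  zero-padded ordinal in seed order.

Representatives are annotated against the known reference by exhaustive
local (Smith–Waterman) alignment — match +1, mismatch −1, gap −2, score
floor 15 — a deterministic, dependency-free stand-in for a BLAST
partial-similarity search at ≤ 26 nt query scale (Biopython's
`PairwiseAligner` does the DP; an independent hand-rolled DP checks it in
the tests). An empty hit list is meaningful: it is the signature of a
family with no partial similarity to any known miRNA.

## Quantification

- **RPM**: `1e6 · count / total`, where the per-library total is mapped
  known reads plus novel-candidate reads (post-filter). Whether to use
  total sequenced or post-filter reads as denominator is configurable;
  post-filter is the default.
- **Composition**: known items holding at least 5% (inclusive) of the
  total are listed individually; the sub-5% known mass collapses into
  `other_known`; all novel mass is `putative_novel`. Fractions sum to 1
  within 1e-9 by construction, asserted on every call.
- **Enrichment**: `log2((c_b + 0.5)/T_b) − log2((c_c + 0.5)/T_c)`. The
  pseudocount (0.5) keeps families absent from one library finite — exactly
  the interesting case of blastema-only families. With one library per
  condition no replicate-based test is possible; optionally a two-sided
  exact binomial test asks whether a label's blastema share of reads is
  compatible with the library-depth ratio, with Benjamini–Hochberg
  adjustment across labels. Output headers state that this definition of
  "enriched" is the package's own operationalization.

## Synthetic libraries

The generator emulates the stated world of the study at desk scale, with
exact per-read provenance:

| parameter | default | rationale |
|---|---|---|
| library depth | 50,000 reads each | desk-scale stand-in for the ~18M/22M real libraries |
| reference | 20 mature miRNAs, 20–24 nt, pairwise edit distance > 6 | identifiability under ≤ 2 mismatches |
| expression weights | independent lognormal(0, 1.5) per library | skewed abundances typical of small-RNA libraries |
| planted novel families | 5; seeds 20–22 nt, pairwise distance > 8, > 3 from every reference and unmatched at ≤ 2 mismatches | unambiguous ground truth |
| planted counts | 30 control / 120 blastema per family (fold change 4), split so the seed is strictly dominant and each variant clears the > 7 filter in the blastema | mirrors blastema-enriched novel families |
| substitution rate | 0 (recovery tests) or 0.01 (noise tests) | at 0.01, ≥ 95% of reads carry ≤ 2 substitutions |
| adapter read-through | 30% of reads, 36 nt machine read length | exercises adapter trimming |
| noise reads | 2%, random 20–30 nt | low-count background |

Substitution noise applies to known-miRNA reads only; planted reads are
exact copies of their member sequences, so family-count recovery is exact
by construction and tests can demand equality, not approximation. Errors
are substitutions only — no simulated indels, matching the mismatch-only
mapper; indel robustness is exercised solely through the Levenshtein
clustering branch. Qualities are constant Q30 except an optional
low-quality-tail mode used to exercise quality trimming. Not modelled:
hairpin precursors and secondary structure, ligation bias, PCR duplicates,
and real miRBase sequence relationships (paralog families share names, not
sequences). A green recovery test therefore establishes correct plumbing
and threshold logic, not performance on real libraries.

## Numerical and degenerate-input choices

- All RNG is `numpy.random.default_rng` seeded from the run seed; per-family
  member streams are seeded by CRC32 of `seed:family_id`, so outputs are
  byte-identical across processes and platforms.
- Empty candidate list → empty family list (not an error); a tag matching
  nothing is a valid outcome everywhere; zero library totals are argument
  errors.
- Collapsed-tag and enrichment orderings fix ties lexicographically so all
  tables are reproducible.
- The pipeline driver hard-fails on any conservation violation
  (`mapped + unmapped ≠ passed`, tally mismatch) rather than warning.

## Known limitations

- The 4564-family and 59,811-read headline figures of the motivating study
  require its deposited multi-million-read libraries and miRBase 21; this
  package validates the method on synthetic ground truth instead.
- Greedy clustering depends on abundance order; a candidate within
  threshold of two seeds joins the earlier (more abundant) one. The
  single-linkage mode quantifies sensitivity to this choice.
- No genome mapping, hairpin-folding validation, or isomiR classification.
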