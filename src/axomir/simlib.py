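"""Synthetic paired small-RNA libraries with exact ground truth.

Emulates the statistical structure the pipeline assumes of the real study:
two single-replicate libraries (uninjured control and three-day blastema)
whose reads derive from (a) known mature miRNAs sampled by library-specific
abundance weights with per-base substitution noise, (b) planted novel miRNA
families with exact per-library counts, and (c) random noise sequences, with
an optional 3' adapter read-through on any read and optional pure-adapter
artifacts.  Every read carries a provenance label, so downstream stages have
a parameter-recovery oracle.

The generator is deterministic for a fixed seed and never simulates indels
or hairpin precursors; see docs/methods.md for what that does and does not
let a green test establish.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from axomir.knownmatch import (
    MiRNAReferenceEntry,
    ReferenceIndex,
    family_key,
    match_tag,
)
from axomir.novelfam import levenshtein
from axomir.readproc import SmallRNARead, convert_solexa_quality

BASES = "ACGT"
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA 3' adapter
NOISE_LABEL = "noise"
ADAPTER_LABEL = "adapter-artifact"

#: flow-cell read length: inserts shorter than this read through into adapter
DEFAULT_MACHINE_READ_LENGTH = 36
#: constant base quality emitted unless a low-quality tail is requested
DEFAULT_QUALITY = 30
LOW_TAIL_QUALITY = 2
LOW_TAIL_LENGTH = 3


def mutate_sequence(seq: str, n_substitutions: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_substitutions`` point substitutions to ``seq``.

    Positions are chosen without replacement and each substituted base is
    drawn from the three alternatives, so the result is at Hamming distance
    exactly ``n_substitutions`` from the input.
    """
    if n_substitutions < 0 or n_substitutions > len(seq):
        raise ValueError(
            f"n_substitutions {n_substitutions} outside [0, {len(seq)}]"
        )
    if n_substitutions == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_substitutions, replace=False):
        alternatives = [b for b in BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def generate_reference(
    n_mirnas: int,
    n_families: int,
    seed: int,
    fasta_path: str | Path | None = None,
) -> list[MiRNAReferenceEntry]:
    """Generate a synthetic mature-miRNA reference (miRBase stand-in).

    Sequences are 20-24 nt, pairwise Levenshtein distance > 6 so a read with
    up to two substitutions identifies its source unambiguously.  Names
    follow ``syn-mir-<family><letter>[-5p|-3p]`` to exercise family-key
    parsing; paralogs of a family share the numeric root but have unrelated
    sequences (family membership here is nominal, as in miRBase naming).
    Deterministic for a fixed seed; optionally also written as FASTA.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if n_families > n_mirnas:
        raise ValueError(f"n_families {n_families} exceeds n_mirnas {n_mirnas}")
    rng = np.random.default_rng(seed)
    sequences: list[str] = []
    while len(sequences) < n_mirnas:
        cand = _random_seq(rng, int(rng.integers(20, 25)))
        if all(levenshtein(cand, s) > 6 for s in sequences):
            sequences.append(cand)
    entries = []
    for i, seq in enumerate(sequences):
        fam = i % n_families + 1
        paralog = i // n_families
        letter = chr(ord("a") + paralog) if n_mirnas > n_families else ""
        arm = ("-5p", "-3p", "")[i % 3]
        name = f"syn-mir-{fam}{letter}{arm}"
        entries.append(MiRNAReferenceEntry(name, family_key(name), seq))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for e in entries:
                fh.write(f">{e.name}\n{e.sequence}\n")
    return entries


@dataclass(frozen=True)
class PlantedFamily:
    """A novel miRNA family planted into the simulation with exact counts."""

    family_id: str
    seed_sequence: str
    n_variant_members: int
    member_max_edits: int
    count_control: int
    count_blastema: int

    def __post_init__(self) -> None:
        if not 20 <= len(self.seed_sequence) <= 22:
            raise ValueError(
                f"{self.family_id}: seed length {len(self.seed_sequence)} outside [20, 22]"
            )
        if self.member_max_edits < 0:
            raise ValueError("member_max_edits must be >= 0")
        if self.n_variant_members < 0:
            raise ValueError("n_variant_members must be >= 0")
        if self.count_control < 0 or self.count_blastema < 0:
            raise ValueError("planted counts must be >= 0")


@dataclass
class SimulationConfig:
    """Everything needed to generate one control/blastema library pair."""

    seed: int
    n_reads_control: int
    n_reads_blastema: int
    reference_mirnas: Sequence[MiRNAReferenceEntry]
    expression_profile: Mapping[str, tuple[float, float]]
    planted_novel_families: Sequence[PlantedFamily] = field(default_factory=list)
    substitution_rate: float = 0.0
    adapter_sequence: str = DEFAULT_ADAPTER
    adapter_readthrough_fraction: float = 0.3
    noise_fraction: float = 0.02
    adapter_artifact_fraction: float = 0.0
    quality_offset_mode: str = "phred33"
    machine_read_length: int = DEFAULT_MACHINE_READ_LENGTH
    low_quality_tail_fraction: float = 0.0
    cluster_max_dist: int = 4
    max_mismatch: int = 2

    def validate(self) -> None:
        for name, value in [
            ("substitution_rate", self.substitution_rate),
            ("adapter_readthrough_fraction", self.adapter_readthrough_fraction),
            ("noise_fraction", self.noise_fraction),
            ("adapter_artifact_fraction", self.adapter_artifact_fraction),
            ("low_quality_tail_fraction", self.low_quality_tail_fraction),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.quality_offset_mode not in ("phred33", "solexa64"):
            raise ValueError(f"unknown quality_offset_mode {self.quality_offset_mode!r}")
        if set(self.adapter_sequence) - set(BASES):
            raise ValueError("adapter must be over {A,C,G,T}")
        names = {e.name for e in self.reference_mirnas}
        unknown = set(self.expression_profile) - names
        if unknown:
            raise ValueError(f"expression profile names absent from reference: {sorted(unknown)}")
        for lib_idx, lib in ((0, "control"), (1, "blastema")):
            weights = [w[lib_idx] for w in self.expression_profile.values()]
            if any(w < 0 for w in weights):
                raise ValueError("abundance weights must be non-negative")
            if self._n_known(lib) > 0 and not any(w > 0 for w in weights):
                raise ValueError(f"no positive abundance weight for {lib} library")
        if not self.expression_profile and not self.planted_novel_families:
            raise ValueError("need an expression profile or planted families")
        self._validate_planted()

    def _validate_planted(self) -> None:
        families = self.planted_novel_families
        for i, fam in enumerate(families):
            for other in families[i + 1 :]:
                d = levenshtein(fam.seed_sequence, other.seed_sequence)
                if d <= 2 * self.cluster_max_dist:
                    raise ValueError(
                        f"planted seeds {fam.family_id}/{other.family_id} at distance "
                        f"{d} <= {2 * self.cluster_max_dist}; ground truth ambiguous"
                    )
            for entry in self.reference_mirnas:
                if levenshtein(fam.seed_sequence, entry.sequence) <= self.max_mismatch + 1:
                    raise ValueError(
                        f"planted seed {fam.family_id} too close to reference {entry.name}"
                    )

    def _planted_total(self, library: str) -> int:
        attr = "count_control" if library == "control" else "count_blastema"
        return sum(getattr(f, attr) for f in self.planted_novel_families)

    def _depth(self, library: str) -> int:
        return self.n_reads_control if library == "control" else self.n_reads_blastema

    def _n_noise(self, library: str) -> int:
        return round(self.noise_fraction * self._depth(library))

    def _n_artifact(self, library: str) -> int:
        return round(self.adapter_artifact_fraction * self._depth(library))

    def _n_known(self, library: str) -> int:
        n = (
            self._depth(library)
            - self._planted_total(library)
            - self._n_noise(library)
            - self._n_artifact(library)
        )
        if n < 0:
            raise ValueError(
                f"{library}: planted + noise + artifact reads exceed library depth"
            )
        return n


@dataclass
class GroundTruth:
    """Per-read provenance and derived per-label true counts."""

    reads: pd.DataFrame  # read_id, library, label, n_substitutions

    def label_counts(self, library: str) -> dict[str, int]:
        sub = self.reads[self.reads["library"] == library]
        return sub["label"].value_counts().to_dict()

    def family_counts(self, library: str) -> dict[str, int]:
        counts = self.label_counts(library)
        return {
            lab: c
            for lab, c in counts.items()
            if lab not in (NOISE_LABEL, ADAPTER_LABEL)
        }

    def to_tsv(self, path: str | Path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


def _planted_members(
    fam: PlantedFamily, rng: np.random.Generator
) -> list[str]:
    """Seed plus ``n_variant_members`` distinct variants within the edit budget."""
    members = [fam.seed_sequence]
    attempts = 0
    while len(members) < fam.n_variant_members + 1:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(f"{fam.family_id}: cannot generate distinct variants")
        if fam.member_max_edits == 0:
            raise ValueError(
                f"{fam.family_id}: variants requested but member_max_edits is 0"
            )
        n_edits = int(rng.integers(1, fam.member_max_edits + 1))
        variant = mutate_sequence(fam.seed_sequence, n_edits, rng)
        if variant not in members:
            members.append(variant)
    return members


def _member_allocation(total: int, n_members: int) -> list[int]:
    """Split a family's library count: seed takes the rest after each variant
    gets ``total // (2 * n_variants)``, keeping the seed strictly dominant."""
    if n_members == 1:
        return [total]
    n_var = n_members - 1
    per_variant = total // (2 * n_var)
    return [total - per_variant * n_var] + [per_variant] * n_var


def _encode_quality(quals: Sequence[int], mode: str) -> str:
    if mode == "phred33":
        return "".join(chr(q + 33) for q in quals)
    # solexa64: invert the phred->solexa mapping (defined for phred >= 1)
    out = []
    for q in quals:
        q_solexa = round(10.0 * math.log10(max(10.0 ** (q / 10.0) - 1.0, 10.0 ** -0.5)))
        out.append(chr(q_solexa + 64))
    return "".join(out)


def _finish_read(
    read_id: str,
    insert: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    force_artifact: bool = False,
) -> SmallRNARead:
    """Apply adapter read-through and quality encoding to an insert."""
    seq = insert
    if force_artifact:
        seq = config.adapter_sequence[: config.machine_read_length]
    elif rng.random() < config.adapter_readthrough_fraction:
        seq = (insert + config.adapter_sequence)[: config.machine_read_length]
        if len(seq) < len(insert):  # never truncate below the insert itself
            seq = insert
    quals = [DEFAULT_QUALITY] * len(seq)
    if config.low_quality_tail_fraction and rng.random() < config.low_quality_tail_fraction:
        for k in range(1, min(LOW_TAIL_LENGTH, len(seq)) + 1):
            quals[-k] = LOW_TAIL_QUALITY
    phred = quals
    if config.quality_offset_mode == "solexa64":
        # reads decoded from Solexa files round-trip through the converter
        phred = [
            convert_solexa_quality(
                round(10.0 * math.log10(max(10.0 ** (q / 10.0) - 1.0, 10.0 ** -0.5)))
            )
            for q in quals
        ]
    return SmallRNARead(read_id, seq, tuple(phred))


def _simulate_library(
    library: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    index: ReferenceIndex,
) -> tuple[list[SmallRNARead], list[tuple[str, str, str, int]]]:
    lib_idx = 0 if library == "control" else 1
    seq_by_name = {e.name: e.sequence for e in config.reference_mirnas}

    inserts: list[tuple[str, int, bool]] = []  # (insert | label, n_subs, is_artifact)
    labels: list[str] = []

    n_known = config._n_known(library)
    if n_known:
        names = [
            n for n, w in config.expression_profile.items() if w[lib_idx] > 0
        ]
        weights = np.array([config.expression_profile[n][lib_idx] for n in names])
        weights = weights / weights.sum()
        chosen = rng.choice(len(names), size=n_known, p=weights)
        for ci in chosen:
            name = names[int(ci)]
            mature = seq_by_name[name]
            n_sub = int(rng.binomial(len(mature), config.substitution_rate))
            inserts.append((mutate_sequence(mature, n_sub, rng), n_sub, False))
            labels.append(name)

    count_attr = "count_control" if library == "control" else "count_blastema"
    for fam in config.planted_novel_families:
        members = _planted_member_cache(config, fam)
        total = getattr(fam, count_attr)
        if total == 0:
            continue
        for member, n_copies in zip(members, _member_allocation(total, len(members))):
            for _ in range(n_copies):
                inserts.append((member, 0, False))
                labels.append(fam.family_id)
        # verify the planted sequences are invisible to the known-miRNA matcher
        for member in members:
            if match_tag(member, index, config.max_mismatch).matched:
                raise ValueError(
                    f"planted member of {fam.family_id} maps to the reference"
                )

    for _ in range(config._n_noise(library)):
        inserts.append((_random_seq(rng, int(rng.integers(20, 31))), 0, False))
        labels.append(NOISE_LABEL)
    for _ in range(config._n_artifact(library)):
        inserts.append(("", 0, True))
        labels.append(ADAPTER_LABEL)

    order = rng.permutation(len(inserts))
    reads: list[SmallRNARead] = []
    truth_rows: list[tuple[str, str, str, int]] = []
    prefix = "ctrl" if library == "control" else "blas"
    for out_i, src_i in enumerate(order):
        insert, n_sub, is_artifact = inserts[src_i]
        read_id = f"{prefix}_{out_i + 1:07d}"
        reads.append(_finish_read(read_id, insert, config, rng, force_artifact=is_artifact))
        truth_rows.append((read_id, library, labels[src_i], n_sub))
    return reads, truth_rows


_member_cache: dict[tuple[int, PlantedFamily], list[str]] = {}


def _planted_member_cache(config: SimulationConfig, fam: PlantedFamily) -> list[str]:
    """Member sequences are drawn once per (seed, family) so both libraries
    share identical family membership; the stream is seeded stably (CRC32 of
    seed + family id) so results are reproducible across processes."""
    key = (config.seed, fam)
    if key not in _member_cache:
        derived = zlib.crc32(f"{config.seed}:{fam.family_id}:members".encode()) & 0x7FFFFFFF
        _member_cache[key] = _planted_members(fam, np.random.default_rng(derived))
    return _member_cache[key]


def planted_member_sequences(config: SimulationConfig, fam: PlantedFamily) -> list[str]:
    """The exact member sequences (seed first) a simulation will emit."""
    return list(_planted_member_cache(config, fam))


def generate_libraries(
    config: SimulationConfig,
) -> tuple[list[SmallRNARead], list[SmallRNARead], GroundTruth]:
    """Generate the control and blastema libraries plus exact ground truth.

    Deterministic for a fixed ``config.seed``; each library's read count
    equals its configured depth exactly, planted-family counts are exact
    (not sampled), and noise/artifact counts are the rounded fractions of
    depth.  Substitution noise applies to known-miRNA reads only.
    """
    config.validate()
    index = ReferenceIndex(config.reference_mirnas) if config.reference_mirnas else ReferenceIndex([])
    rng = np.random.default_rng(config.seed)
    control, truth_c = _simulate_library("control", config, rng, index)
    blastema, truth_b = _simulate_library("blastema", config, rng, index)
    truth = GroundTruth(
        pd.DataFrame(
            truth_c + truth_b,
            columns=["read_id", "library", "label", "n_substitutions"],
        )
    )
    for library, depth in (("control", config.n_reads_control), ("blastema", config.n_reads_blastema)):
        n = int((truth.reads["library"] == library).sum())
        assert n == depth, f"{library}: emitted {n} reads for depth {depth}"
    return control, blastema, truth


def make_scenario(
    seed: int,
    n_reads_control: int = 50_000,
    n_reads_blastema: int = 50_000,
    n_mirnas: int = 20,
    n_families: int = 8,
    n_planted: int = 5,
    planted_count_control: int = 30,
    planted_fold_change: float = 4.0,
    n_variant_members: int = 3,
    member_max_edits: int = 4,
    substitution_rate: float = 0.0,
    noise_fraction: float = 0.02,
    adapter_readthrough_fraction: float = 0.3,
    adapter_artifact_fraction: float = 0.0,
    quality_offset_mode: str = "phred33",
) -> SimulationConfig:
    """Build a complete two-library scenario with defaults matching the
    stated world of the original study at desk scale.

    Twenty reference miRNAs with lognormal abundance weights per library;
    ``n_planted`` novel families whose seeds are pairwise more than 8 edits
    apart and invisible to the <=2-mismatch matcher, each planted at
    ``planted_count_control`` control reads and ``planted_fold_change`` times
    that in the blastema (fold change 4 by default, mirroring
    blastema-enriched novel families); 2% random-noise reads; 30% adapter
    read-through.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(zlib.crc32(f"scenario:{seed}".encode()) & 0x7FFFFFFF)
    reference = generate_reference(n_mirnas, n_families, seed)
    index = ReferenceIndex(reference)
    # independent lognormal weights per library: realistic skewed abundances
    profile = {
        e.name: (float(rng.lognormal(0.0, 1.5)), float(rng.lognormal(0.0, 1.5)))
        for e in reference
    }
    planted: list[PlantedFamily] = []
    seeds: list[str] = []
    while len(planted) < n_planted:
        cand = _random_seq(rng, int(rng.integers(20, 23)))
        if any(levenshtein(cand, s) <= 8 for s in seeds):
            continue
        if any(levenshtein(cand, e.sequence) <= 3 for e in reference):
            continue
        if match_tag(cand, index, 2).matched:
            continue
        seeds.append(cand)
        planted.append(
            PlantedFamily(
                family_id=f"planted-{len(seeds):02d}",
                seed_sequence=cand,
                n_variant_members=n_variant_members,
                member_max_edits=member_max_edits,
                count_control=planted_count_control,
                count_blastema=round(planted_count_control * planted_fold_change),
            )
        )
    return SimulationConfig(
        seed=seed,
        n_reads_control=n_reads_control,
        n_reads_blastema=n_reads_blastema,
        reference_mirnas=reference,
        expression_profile=profile,
        planted_novel_families=planted,
        substitution_rate=substitution_rate,
        noise_fraction=noise_fraction,
        adapter_readthrough_fraction=adapter_readthrough_fraction,
        adapter_artifact_fraction=adapter_artifact_fraction,
        quality_offset_mode=quality_offset_mode,
    )


def write_fastq(reads: Sequence[SmallRNARead], path: str | Path, mode: str = "phred33") -> None:
    """Write reads as 4-line FASTQ with the requested quality offset."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n"
                f"{_encode_quality(read.qualities, mode)}\n"
            )
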