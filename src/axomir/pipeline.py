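"""End-to-end orchestration: FASTQ pair + reference in, report tables out.

Stage order mirrors the study's workflow: read processing (trim, filter,
collapse) -> known-miRNA assignment -> novel-family discovery on the
unmapped remainder -> composition and enrichment reporting.  Read-count
conservation is asserted between every pair of adjacent stages and a JSON
manifest records parameters, input checksums and stage tallies, so identical
configuration and inputs yield byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from axomir import knownmatch, novelfam, quantify, readproc

LIBRARIES = ("control", "blastema")

ENRICHMENT_HEADER = (
    "# log2_fold_change: pseudocount-stabilized log2 of blastema vs control "
    "relative abundance (this package's operational definition of enrichment; "
    "the original study validated enrichment by qRT-PCR)\n"
)


@dataclass
class RunConfig:
    """Paths and parameters for one full pipeline run."""

    control_fastq: str
    blastema_fastq: str
    reference_fasta: str
    output_dir: str
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 6
    quality_threshold: int = 20
    quality_encoding: str = "auto"
    min_len: int = 20
    max_len: int = 22
    max_mismatch: int = 2
    min_occurrences: int = 7
    cluster_max_dist: int = 4
    cluster_method: str = "greedy"
    composition_threshold: float = 0.05
    annotation_score_floor: float = 15.0
    pseudocount: float = 0.5
    with_test: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.min_occurrences < 0:
            raise ValueError("min_occurrences must be >= 0")
        if self.cluster_max_dist < 0:
            raise ValueError("cluster_max_dist must be >= 0")
        if not 0 < self.composition_threshold <= 1:
            raise ValueError("composition_threshold must lie in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.quality_encoding not in ("auto", "phred33", "solexa64"):
            raise ValueError(f"unknown quality_encoding {self.quality_encoding!r}")
        if self.cluster_method not in ("greedy", "single-linkage"):
            raise ValueError(f"unknown cluster_method {self.cluster_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the output tree; returns the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = readproc.ReadProcessingParams(
        adapter=config.adapter,
        min_overlap=config.min_overlap,
        q_threshold=config.quality_threshold,
        min_len=config.min_len,
        max_len=config.max_len,
    )

    # stage 1: read processing
    tags: dict[str, list[readproc.CollapsedTag]] = {}
    tallies: dict[str, readproc.ProcessingTally] = {}
    fastqs = {"control": config.control_fastq, "blastema": config.blastema_fastq}
    for lib in LIBRARIES:
        reads = readproc.read_fastq(fastqs[lib], config.quality_encoding)
        tags[lib], tallies[lib] = readproc.process_library(reads, params, lib)
        readproc.write_tags_tsv(tags[lib], out / f"tags_{lib}.tsv")
        tallies[lib].to_json(out / f"tally_{lib}.json")

    # stage 2: known-miRNA assignment
    reference = knownmatch.load_reference(config.reference_fasta)
    index = knownmatch.ReferenceIndex(reference, min_tag_len=config.min_len)
    table, unmapped = knownmatch.count_known(tags, index, config.max_mismatch)
    table.write(out / "known_mirna_counts.tsv", out / "known_family_counts.tsv")
    unmapped.to_csv(out / "unmapped_tags.tsv", sep="\t", index=False)
    for lib in LIBRARIES:
        mapped = table.mapped_totals.get(lib, 0)
        unmapped_total = int(unmapped[f"count_{lib}"].sum()) if len(unmapped) else 0
        if mapped + unmapped_total != tallies[lib].n_passed:
            raise AssertionError(
                f"{lib}: mapped {mapped} + unmapped {unmapped_total} != "
                f"passed {tallies[lib].n_passed}"
            )

    # stage 3: novel-family discovery
    candidates = novelfam.select_candidates(unmapped, config.min_occurrences)
    families = novelfam.cluster_families(
        candidates, config.cluster_max_dist, config.cluster_method
    )
    for fam in families:
        fam.annotation = novelfam.annotate_family(
            fam, reference, config.annotation_score_floor
        )
    novelfam.families_frame(families).to_csv(out / "novel_families.tsv", sep="\t", index=False)
    novelfam.members_frame(families).to_csv(out / "novel_members.tsv", sep="\t", index=False)
    novelfam.annotation_frame(families).to_csv(out / "novel_annotation.tsv", sep="\t", index=False)
    novelfam.write_representatives_fasta(families, out / "novel_representatives.fasta")

    # stage 4: composition and enrichment
    novel_counts = {
        lib: {
            f.family_id: (f.total_control if lib == "control" else f.total_blastema)
            for f in families
        }
        for lib in LIBRARIES
    }
    totals = {
        lib: table.mapped_totals.get(lib, 0) + sum(novel_counts[lib].values())
        for lib in LIBRARIES
    }
    for lib in LIBRARIES:
        known = table.mirna[lib].to_dict() if len(table.mirna) else {}
        if totals[lib] > 0:
            summary = quantify.composition_summary(
                known,
                sum(novel_counts[lib].values()),
                config.composition_threshold,
                lib,
            )
            summary.to_frame().to_csv(out / f"composition_{lib}.tsv", sep="\t", index=False)

    known_fam = {
        lib: (table.family[lib].to_dict() if len(table.family) else {})
        for lib in LIBRARIES
    }
    for name, counts in (("known_families", known_fam), ("novel_families", novel_counts)):
        if not counts["control"] and not counts["blastema"]:
            continue
        records = quantify.enrichment_table(
            counts["control"],
            counts["blastema"],
            total_control=totals["control"] or None,
            total_blastema=totals["blastema"] or None,
            pseudocount=config.pseudocount,
            with_test=config.with_test,
        )
        path = out / f"enrichment_{name}.tsv"
        with open(path, "w") as fh:
            fh.write(ENRICHMENT_HEADER)
            quantify.enrichment_frame(records).to_csv(fh, sep="\t", index=False)

    manifest = {
        "parameters": asdict(config),
        "inputs": {
            "control_fastq": _sha256(config.control_fastq),
            "blastema_fastq": _sha256(config.blastema_fastq),
            "reference_fasta": _sha256(config.reference_fasta),
        },
        "stages": {
            "readproc": {lib: asdict(tallies[lib]) for lib in LIBRARIES},
            "knownmatch": {
                "n_reference_mirnas": len(reference),
                "n_reference_families": int(table.family.shape[0]),
                "mapped_totals": table.mapped_totals,
                "n_unmapped_tags": int(len(unmapped)),
            },
            "novelfam": {
                "n_candidates": len(candidates),
                "n_families": len(families),
                "novel_read_totals": {
                    lib: sum(novel_counts[lib].values()) for lib in LIBRARIES
                },
            },
            "quantify": {"analysis_totals": totals},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
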