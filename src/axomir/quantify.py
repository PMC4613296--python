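"""Library composition and control-vs-blastema enrichment summaries.

The composition summary mirrors the study's pie-chart convention: known
miRNAs holding at least 5% of reads are listed individually, the remaining
known mass is collapsed into ``other_known``, and all putative-novel mass is
one ``putative_novel`` slice.  The denominator is the post-filter mapped +
novel-candidate read total.

Enrichment between the two single-replicate libraries is operationalized as
a pseudocount-stabilized log2 fold change of relative abundances, optionally
with a two-sided exact binomial test (is the blastema share of a label's
reads compatible with the library-depth ratio?) and Benjamini-Hochberg
adjustment.  The study itself validated enrichment by qRT-PCR and reports no
formula; output headers label the statistic as this package's definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import pandas as pd
from scipy import stats

DEFAULT_COMPOSITION_THRESHOLD = 0.05
DEFAULT_PSEUDOCOUNT = 0.5


def rpm_normalize(counts: Mapping[str, int], library_total: int) -> dict[str, float]:
    """Reads-per-million: ``1e6 * count / library_total`` per label."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    return {label: 1e6 * c / library_total for label, c in counts.items()}


@dataclass
class CompositionSummary:
    """Per-library read composition with the >=threshold listing rule."""

    library_label: str
    listed: list[tuple[str, float]]  # known items at fraction >= threshold
    other_known: float
    putative_novel: float
    threshold: float

    def check(self) -> None:
        total = sum(f for _, f in self.listed) + self.other_known + self.putative_novel
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"composition fractions sum to {total}, not 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": lab, "read_fraction": frac} for lab, frac in self.listed]
        rows.append({"label": "other_known", "read_fraction": self.other_known})
        rows.append({"label": "putative_novel", "read_fraction": self.putative_novel})
        df = pd.DataFrame(rows, columns=["label", "read_fraction"])
        df.insert(0, "library", self.library_label)
        return df


def composition_summary(
    known_counts: Mapping[str, int],
    novel_counts: Mapping[str, int] | int,
    threshold: float = DEFAULT_COMPOSITION_THRESHOLD,
    library_label: str = "",
) -> CompositionSummary:
    """Summarize one library's composition over known + novel reads.

    Known labels with read fraction >= ``threshold`` (inclusive) are listed
    individually, sorted by descending fraction then label; the rest are
    collapsed into ``other_known``.  All novel mass is ``putative_novel``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    novel_total = novel_counts if isinstance(novel_counts, int) else sum(novel_counts.values())
    total = sum(known_counts.values()) + novel_total
    if total <= 0:
        raise ValueError("composition requires a positive read total")
    listed = sorted(
        (
            (label, count / total)
            for label, count in known_counts.items()
            if count / total >= threshold
        ),
        key=lambda kv: (-kv[1], kv[0]),
    )
    other = sum(c for l, c in known_counts.items() if c / total < threshold) / total
    summary = CompositionSummary(
        library_label=library_label,
        listed=listed,
        other_known=other,
        putative_novel=novel_total / total,
        threshold=threshold,
    )
    summary.check()
    return summary


@dataclass(frozen=True)
class EnrichmentRecord:
    """One label's counts, RPM values and blastema-over-control fold change."""

    label: str
    count_control: int
    count_blastema: int
    rpm_control: float
    rpm_blastema: float
    log2_fold_change: float
    p_value: float | None = None
    q_value: float | None = None


def enrichment_table(
    control_counts: Mapping[str, int],
    blastema_counts: Mapping[str, int],
    total_control: int | None = None,
    total_blastema: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    with_test: bool = False,
) -> list[EnrichmentRecord]:
    """Compare per-label counts between the two libraries.

    ``log2_fold_change = log2((c_b + pc)/T_b) - log2((c_c + pc)/T_c)`` with
    pseudocount ``pc`` keeping zero counts finite.  Labels missing from one
    map count as 0.  Library totals default to the map sums.  With
    ``with_test`` a two-sided exact binomial test of the blastema count
    against the expected depth share is run per label, BH-adjusted across
    labels.  Records are sorted by \\|log2 fold change\\| descending.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    labels = sorted(set(control_counts) | set(blastema_counts))
    if not labels:
        return []
    tc = sum(control_counts.values()) if total_control is None else total_control
    tb = sum(blastema_counts.values()) if total_blastema is None else total_blastema
    if tc <= 0 or tb <= 0:
        raise ValueError("both library totals must be > 0")
    rpm_c = rpm_normalize({l: control_counts.get(l, 0) for l in labels}, tc)
    rpm_b = rpm_normalize({l: blastema_counts.get(l, 0) for l in labels}, tb)
    records = []
    pvals = []
    for label in labels:
        cc = control_counts.get(label, 0)
        cb = blastema_counts.get(label, 0)
        lfc = math.log2((cb + pseudocount) / tb) - math.log2((cc + pseudocount) / tc)
        p = None
        if with_test:
            n = cc + cb
            p = stats.binomtest(cb, n, tb / (tb + tc)).pvalue if n > 0 else 1.0
            pvals.append(p)
        records.append(
            EnrichmentRecord(
                label=label,
                count_control=cc,
                count_blastema=cb,
                rpm_control=rpm_c[label],
                rpm_blastema=rpm_b[label],
                log2_fold_change=lfc,
                p_value=p,
            )
        )
    if with_test and records:
        qvals = stats.false_discovery_control(pvals, method="bh")
        records = [
            EnrichmentRecord(
                r.label,
                r.count_control,
                r.count_blastema,
                r.rpm_control,
                r.rpm_blastema,
                r.log2_fold_change,
                r.p_value,
                float(q),
            )
            for r, q in zip(records, qvals)
        ]
    records.sort(key=lambda r: (-abs(r.log2_fold_change), r.label))
    return records


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    cols = [
        "label",
        "count_control",
        "count_blastema",
        "rpm_control",
        "rpm_blastema",
        "log2_fold_change",
        "p_value",
        "q_value",
    ]
    df = pd.DataFrame([r.__dict__ for r in records], columns=cols)
    if df["p_value"].isna().all():
        df = df.drop(columns=["p_value", "q_value"])
    return df
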