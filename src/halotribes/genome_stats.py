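"""Per-assembly summary statistics and cross-group comparison numbers.

Covers the quantities a genome-announcement table reports per assembly
(contig counts above 200 bp, assembled bp, fold coverage, %GC, %coding)
plus two comparison summaries: genus-vs-genus means (percent genome-size
difference, absolute and percent CDS difference, contig-count ratio) and
a resequencing-control report (single-base discrepancy rate in Kbp per
discrepancy, and count/median/total summaries of missing and extra
regions relative to the reference assembly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeStats",
    "DiscrepancyReport",
    "GenusComparison",
    "assembly_summary",
    "genus_comparison",
    "control_discrepancy_summary",
]

#: Contigs at or below this length are excluded from the reported count.
MIN_CONTIG_BP = 200


@dataclass
class GenomeStats:
    """Summary numbers for one assembly."""

    genome_id: str
    contig_lengths: list
    gc_count: int
    read_bp: int | None = None
    cds_count: int | None = None
    coding_bp: int | None = None
    rna_count: int | None = None

    def __post_init__(self):
        self.contig_lengths = [int(x) for x in self.contig_lengths]
        if not self.contig_lengths:
            raise ValueError("empty contig set")
        if self.gc_count > self.assembled_bp:
            raise ValueError("gc_count exceeds assembled_bp")
        if self.coding_bp is not None and self.coding_bp > self.assembled_bp:
            raise ValueError("coding_bp exceeds assembled_bp")

    @property
    def assembled_bp(self) -> int:
        return sum(self.contig_lengths)

    @property
    def n_contigs(self) -> int:
        """Number of contigs strictly longer than 200 bp."""
        return sum(1 for x in self.contig_lengths if x > MIN_CONTIG_BP)

    @property
    def pct_gc(self) -> float:
        return 100.0 * self.gc_count / self.assembled_bp

    @property
    def coverage(self) -> float | None:
        if self.read_bp is None:
            return None
        return self.read_bp / self.assembled_bp

    @property
    def pct_coding(self) -> float | None:
        if self.coding_bp is None:
            return None
        return 100.0 * self.coding_bp / self.assembled_bp


def assembly_summary(
    genome_id: str,
    contigs,
    reads_bp: int | None = None,
    cds_count: int | None = None,
    coding_bp: int | None = None,
    rna_count: int | None = None,
) -> GenomeStats:
    """Summarise an assembly from its contig sequences.

    ``contigs`` is a mapping or iterable of nucleotide sequences.  GC
    counting is case-insensitive; coverage is reads_bp / assembled_bp
    when read totals are supplied.
    """
    seqs = list(contigs.values()) if hasattr(contigs, "values") else list(contigs)
    if not seqs:
        raise ValueError("empty contig set")
    lengths = [len(s) for s in seqs]
    gc = sum(s.upper().count("G") + s.upper().count("C") for s in seqs)
    return GenomeStats(
        genome_id=genome_id,
        contig_lengths=lengths,
        gc_count=gc,
        read_bp=reads_bp,
        cds_count=cds_count,
        coding_bp=coding_bp,
        rna_count=rna_count,
    )


@dataclass(frozen=True)
class GenusComparison:
    """Mean-level comparison of group A against group B.

    Percentages and the ratio are rounded to one decimal, gene counts to
    the nearest integer, matching how such numbers are conventionally
    reported.
    """

    pct_size_smaller: float  # (1 - mean_bp(A)/mean_bp(B)) * 100
    cds_fewer: int  # mean_cds(B) - mean_cds(A)
    pct_cds_fewer: float  # cds_fewer / mean_cds(B) * 100
    contig_ratio: float  # mean_contigs(B) / mean_contigs(A)


def _mean(values) -> float:
    arr = np.asarray([v for v in values if v is not None and not pd.isna(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("no values to average")
    return float(arr.mean())


def genus_comparison(stats: pd.DataFrame, group_a, group_b) -> GenusComparison:
    """Compare two genome groups on assembled size, CDS count and contigs.

    ``stats`` is indexed by genome id with columns ``assembled_bp``,
    ``cds_count`` and ``n_contigs`` (NaN entries are excluded from the
    relevant mean).  Group A is conventionally the genus with the
    smaller genomes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    unknown = (set(group_a) | set(group_b)) - set(stats.index)
    if unknown:
        raise ValueError(f"unknown genome(s): {sorted(unknown)}")
    a, b = stats.loc[group_a], stats.loc[group_b]
    mean_bp_a, mean_bp_b = _mean(a["assembled_bp"]), _mean(b["assembled_bp"])
    mean_cds_a, mean_cds_b = _mean(a["cds_count"]), _mean(b["cds_count"])
    mean_ct_a, mean_ct_b = _mean(a["n_contigs"]), _mean(b["n_contigs"])
    cds_diff = mean_cds_b - mean_cds_a
    return GenusComparison(
        pct_size_smaller=round((1.0 - mean_bp_a / mean_bp_b) * 100.0, 1),
        cds_fewer=int(round(cds_diff)),
        pct_cds_fewer=round(cds_diff / mean_cds_b * 100.0, 1),
        contig_ratio=round(mean_ct_b / mean_ct_a, 1),
    )


@dataclass(frozen=True)
class DiscrepancyReport:
    """Control-vs-reference comparison summary."""

    n_base_discrepancies: int
    rate_kbp_per_discrepancy: int | None  # mean assembly length / n / 1000
    missing_regions: dict = field(default_factory=dict)
    extra_regions: dict = field(default_factory=dict)


def _region_summary(lengths) -> dict:
    lengths = [int(x) for x in lengths]
    if any(x <= 0 for x in lengths):
        raise ValueError("region lengths must be positive")
    return {
        "count": len(lengths),
        "median_bp": float(np.median(lengths)) if lengths else None,
        "total_bp": sum(lengths),
    }


def control_discrepancy_summary(
    n_discrepancies: int,
    assembly_lengths,
    missing_regions=(),
    extra_regions=(),
) -> DiscrepancyReport:
    """Summarise a resequencing control against its reference.

    The discrepancy rate is the mean of the two assembly lengths divided
    by the number of single-base discrepancies, reported to the nearest
    Kbp; it is undefined (None) when there are no discrepancies.  Region
    lists are summarised as count, median and total bp (median of an
    even-length list is the mean of the middle pair).
    """
    if n_discrepancies < 0:
        raise ValueError("n_discrepancies must be non-negative")
    lengths = [int(x) for x in assembly_lengths]
    if not lengths or any(x <= 0 for x in lengths):
        raise ValueError("assembly lengths must be positive")
    if n_discrepancies == 0:
        rate = None
    else:
        rate = int(round(float(np.mean(lengths)) / n_discrepancies / 1000.0))
    return DiscrepancyReport(
        n_base_discrepancies=n_discrepancies,
        rate_kbp_per_discrepancy=rate,
        missing_regions=_region_summary(missing_regions),
        extra_regions=_region_summary(extra_regions),
    )
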