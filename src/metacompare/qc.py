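"""Read quality control: emPCR duplicate removal and GC-bias filtering.

Pyrosequencing libraries accumulate two artifact classes that inflate
abundance estimates: emulsion-PCR duplicates (near-identical reads sharing
a start coordinate) and reads whose duplication was coupled to extreme GC
content. This module removes both.

Duplicate detection clusters reads that share an identical prefix
(default 50 bp, case-insensitive) and whose lengths agree within a relative
tolerance (default 2%); the longest member of each cluster is retained,
ties broken toward the earliest read. Reads with an N in the prefix never
cluster — conservative toward retention. The GC filter removes reads whose
GC fraction lies more than ``z_cutoff`` sample standard deviations
(default 3) from the sample mean.

The canonical composition order is duplicates first, then GC; ``run_qc``
applies both and records the order in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .community import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_PREFIX_LEN = 50
DEFAULT_LENGTH_TOLERANCE = 0.02
DEFAULT_GC_Z_CUTOFF = 3.0


@dataclass
class QCReport:
    """Accounting for a QC run; output = input − duplicates − GC outliers."""

    sample_id: str
    input_reads: int
    duplicates_removed: int = 0
    gc_outliers_removed: int = 0
    mean_length_in: float = 0.0
    mean_length_out: float = 0.0
    filter_order: tuple = ("duplicates", "gc")

    @property
    def output_reads(self) -> int:
        return self.input_reads - self.duplicates_removed - self.gc_outliers_removed

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "input_reads": self.input_reads,
            "duplicates_removed": self.duplicates_removed,
            "gc_outliers_removed": self.gc_outliers_removed,
            "output_reads": self.output_reads,
            "mean_length_in": round(self.mean_length_in, 2),
            "mean_length_out": round(self.mean_length_out, 2),
            "filter_order": ",".join(self.filter_order),
        }


def _lengths_within(a: int, b: int, tol: float) -> bool:
    return abs(a - b) <= tol * max(a, b)


def remove_duplicates(
    readset: ReadSet,
    prefix_len: int = DEFAULT_PREFIX_LEN,
    length_tolerance: float = DEFAULT_LENGTH_TOLERANCE,
) -> tuple[ReadSet, QCReport]:
    """Collapse emPCR duplicate clusters, keeping the longest member.

    Reads sharing an identical first-``prefix_len``-base prefix AND lengths
    within ``length_tolerance`` (single-linkage on sorted lengths) form a
    cluster; one representative per cluster survives. Output preserves the
    input order of retained reads. Reads shorter than the prefix length are
    compared over their full sequence.
    """
    if prefix_len < 20:
        raise ValueError(f"prefix_len must be >= 20, got {prefix_len}")
    report = QCReport(
        sample_id=readset.sample_id,
        input_reads=readset.total_count,
        mean_length_in=readset.mean_length(),
        filter_order=("duplicates",),
    )
    if readset.total_count == 0:
        report.mean_length_out = 0.0
        return ReadSet(readset.sample_id, []), report

    groups: dict[str, list[int]] = {}
    for i, r in enumerate(readset.reads):
        key = r.sequence[:prefix_len].upper()
        if "N" in key:
            key = f"__n_{i}"  # never clusters with anything
        groups.setdefault(key, []).append(i)

    drop = set()
    for members in groups.values():
        if len(members) == 1:
            continue
        # single-linkage sub-clustering on length
        by_len = sorted(members, key=lambda i: len(readset.reads[i]))
        cluster = [by_len[0]]
        clusters = [cluster]
        for idx in by_len[1:]:
            if _lengths_within(
                len(readset.reads[idx]), len(readset.reads[cluster[-1]]), length_tolerance
            ):
                cluster.append(idx)
            else:
                cluster = [idx]
                clusters.append(cluster)
        for cl in clusters:
            if len(cl) == 1:
                continue
            # keep the longest; ties broken toward the earliest input read
            keep = min(cl, key=lambda i: (-len(readset.reads[i]), i))
            drop.update(i for i in cl if i != keep)

    kept = [r for i, r in enumerate(readset.reads) if i not in drop]
    out = ReadSet(readset.sample_id, kept)
    report.duplicates_removed = len(drop)
    report.mean_length_out = out.mean_length()
    return out, report


def filter_gc_bias(readset: ReadSet, z_cutoff: float = DEFAULT_GC_Z_CUTOFF) -> tuple[ReadSet, QCReport]:
    """Remove reads whose GC fraction is a > ``z_cutoff``-sigma outlier.

    Trimming is iterated to a fixed point (sigma clipping): after removing
    outliers the sample mean and SD are recomputed and the test reapplied
    until no read is excluded. This makes the filter idempotent — a second
    application never removes anything — at the cost of occasionally
    trimming a few near-threshold reads beyond the single-pass result.
    """
    if not z_cutoff > 0:
        raise ValueError(f"z_cutoff must be positive, got {z_cutoff}")
    report = QCReport(
        sample_id=readset.sample_id,
        input_reads=readset.total_count,
        mean_length_in=readset.mean_length(),
        filter_order=("gc",),
    )
    if readset.total_count < 2:
        logger.warning(
            "GC filter needs at least 2 reads (%s has %d); skipping",
            readset.sample_id,
            readset.total_count,
        )
        report.mean_length_out = report.mean_length_in
        return ReadSet(readset.sample_id, list(readset.reads)), report

    gc = np.array([r.gc for r in readset.reads])
    keep = np.ones(len(gc), dtype=bool)
    if np.isfinite(z_cutoff):
        while keep.sum() >= 2:
            sub = gc[keep]
            mean, sd = float(sub.mean()), float(sub.std())
            if sd == 0.0:
                break
            new_keep = keep & (np.abs(gc - mean) <= z_cutoff * sd)
            if new_keep.sum() == keep.sum():
                break
            keep = new_keep
    kept = [r for r, k in zip(readset.reads, keep) if k]
    out = ReadSet(readset.sample_id, kept)
    report.gc_outliers_removed = readset.total_count - len(kept)
    report.mean_length_out = out.mean_length()
    return out, report


def run_qc(
    readset: ReadSet,
    prefix_len: int = DEFAULT_PREFIX_LEN,
    length_tolerance: float = DEFAULT_LENGTH_TOLERANCE,
    z_cutoff: float = DEFAULT_GC_Z_CUTOFF,
) -> tuple[ReadSet, QCReport]:
    """Apply duplicate removal then GC filtering (the fixed canonical order)."""
    dedup, rep1 = remove_duplicates(readset, prefix_len, length_tolerance)
    out, rep2 = filter_gc_bias(dedup, z_cutoff)
    report = QCReport(
        sample_id=readset.sample_id,
        input_reads=readset.total_count,
        duplicates_removed=rep1.duplicates_removed,
        gc_outliers_removed=rep2.gc_outliers_removed,
        mean_length_in=rep1.mean_length_in,
        mean_length_out=rep2.mean_length_out,
        filter_order=("duplicates", "gc"),
    )
    logger.info(
        "QC %s: %d reads in, %d duplicates, %d GC outliers, %d out",
        readset.sample_id,
        report.input_reads,
        report.duplicates_removed,
        report.gc_outliers_removed,
        report.output_reads,
    )
    return out, report


def sequence_information_mbp(n_reads: int, mean_read_length: float) -> float:
    """Dataset size in mega base pairs: reads × mean length / 1e6, to 1 decimal.

    The figure sequencing summaries print next to read counts and mean
    lengths; rounded half-up.
    """
    from decimal import ROUND_HALF_UP, Decimal

    if n_reads < 0 or mean_read_length < 0:
        raise ValueError("read count and mean length must be non-negative")
    mbp = Decimal(n_reads) * Decimal(str(mean_read_length)) / Decimal(1_000_000)
    return float(mbp.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_report_tsv(report: QCReport, path) -> None:
    import pandas as pd

    pd.DataFrame([report.to_dict()]).to_csv(path, sep="\t", index=False)
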