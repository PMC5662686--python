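"""Compile per-sample CNV calls into CNV regions (CNVRs).

A CNVR is the transitive closure of calls overlapping by at least 1 bp
(closed intervals: abutting calls do not merge), the union-span convention
of a BEDTools-style merge across samples. Regions mixing gain and loss
events are typed "both". Summary statistics follow the usual
per-cohort reporting: totals, type breakdown, mean lengths, per-sample rate
and the fraction of the genome covered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .types import BOTH, GAIN, LOSS, Cnvr, CnvCall, GroupAssignment, chrom_sort_key

logger = logging.getLogger(__name__)

# Bovine genome sizes (Mb) used for coverage percentages; config constants,
# not computed from an assembly.
DEFAULT_AUTOSOMAL_GENOME_MB = 2545.9
DEFAULT_WHOLE_GENOME_MB = 2918.0


@dataclass(frozen=True)
class CnvrSummary:
    n_cnv: int
    n_cnvr: int
    n_gain: int
    n_loss: int
    n_both: int
    n_unique: int
    total_cnv_length_bp: int
    total_cnvr_length_bp: int
    mean_cnv_length_bp: float
    mean_cnvr_length_bp: float
    cnv_per_sample: float
    pct_autosomal_genome: float
    pct_whole_genome: float


def merge_calls(calls: Sequence[CnvCall], id_prefix: str = "CNVR") -> list[Cnvr]:
    """Merge calls into CNVRs by single-linkage >= 1 bp overlap per chromosome.

    Regions are emitted in genome order with sequential ids ``CNVR1, ...``.
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for call in calls:
        by_chrom.setdefault(call.chrom, []).append(call)

    regions: list[Cnvr] = []
    counter = 0
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cluster: list[CnvCall] = []
        cluster_end = -1
        for call in chrom_calls:
            if cluster and call.start <= cluster_end:
                cluster.append(call)
                cluster_end = max(cluster_end, call.end)
            else:
                if cluster:
                    counter += 1
                    regions.append(_build_region(cluster, f"{id_prefix}{counter}"))
                cluster = [call]
                cluster_end = call.end
        if cluster:
            counter += 1
            regions.append(_build_region(cluster, f"{id_prefix}{counter}"))
    return regions


def _build_region(members: list[CnvCall], cnvr_id: str) -> Cnvr:
    states = {c.state for c in members}
    if states == {GAIN}:
        rtype = GAIN
    elif states == {LOSS}:
        rtype = LOSS
    else:
        rtype = BOTH
    carriers = frozenset(c.sample_id for c in members)
    return Cnvr(
        cnvr_id=cnvr_id,
        chrom=members[0].chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        type=rtype,
        event_count=len(members),
        carrier_samples=carriers,
        is_unique=len(carriers) == 1,
        members=tuple(members),
    )


def filter_singletons(cnvrs: Iterable[Cnvr], min_events: int = 2) -> list[Cnvr]:
    """Drop regions supported by fewer than ``min_events`` CNV events.

    Single-event regions are the most likely false positives of array-based
    calling; removing them is the standard step before a selection scan.
    """
    return [c for c in cnvrs if c.event_count >= min_events]


def group_cnvrs(
    calls: Sequence[CnvCall], groups: GroupAssignment
) -> dict[str, list[Cnvr]]:
    """Merge each group's calls separately into group-specific CNVR sets."""
    missing = sorted({c.sample_id for c in calls} - set(groups.samples))
    if missing:
        raise ValidationError(f"calls from sample(s) without a group: {missing}")
    out: dict[str, list[Cnvr]] = {}
    for label in groups.labels:
        members = set(groups.members(label))
        out[label] = merge_calls([c for c in calls if c.sample_id in members])
    return out


def summarize(
    calls: Sequence[CnvCall],
    cnvrs: Sequence[Cnvr],
    n_samples: int,
    autosomal_genome_mb: float = DEFAULT_AUTOSOMAL_GENOME_MB,
    whole_genome_mb: float = DEFAULT_WHOLE_GENOME_MB,
) -> CnvrSummary:
    """Cohort-level CNV/CNVR summary (counts, lengths, rates, coverage)."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    return summary_from_totals(
        n_cnv=len(calls),
        total_cnv_length_bp=sum(c.length for c in calls),
        n_cnvr=len(cnvrs),
        n_gain=sum(c.type == GAIN for c in cnvrs),
        n_loss=sum(c.type == LOSS for c in cnvrs),
        n_both=sum(c.type == BOTH for c in cnvrs),
        n_unique=sum(c.is_unique for c in cnvrs),
        total_cnvr_length_bp=sum(c.length for c in cnvrs),
        n_samples=n_samples,
        autosomal_genome_mb=autosomal_genome_mb,
        whole_genome_mb=whole_genome_mb,
    )


def summary_from_totals(
    n_cnv: int,
    total_cnv_length_bp: int,
    n_cnvr: int,
    n_gain: int,
    n_loss: int,
    n_both: int,
    n_unique: int,
    total_cnvr_length_bp: int,
    n_samples: int,
    autosomal_genome_mb: float = DEFAULT_AUTOSOMAL_GENOME_MB,
    whole_genome_mb: float = DEFAULT_WHOLE_GENOME_MB,
) -> CnvrSummary:
    """Derive the summary from aggregate totals (shared by ``summarize``)."""
    if autosomal_genome_mb <= 0 or whole_genome_mb <= 0:
        raise ValidationError("genome sizes must be positive")
    if n_cnv == 0 or n_cnvr == 0:
        logger.warning("empty input to summary: counts are zero")
    total_cnvr_mb = total_cnvr_length_bp / 1e6
    return CnvrSummary(
        n_cnv=n_cnv,
        n_cnvr=n_cnvr,
        n_gain=n_gain,
        n_loss=n_loss,
        n_both=n_both,
        n_unique=n_unique,
        total_cnv_length_bp=total_cnv_length_bp,
        total_cnvr_length_bp=total_cnvr_length_bp,
        mean_cnv_length_bp=total_cnv_length_bp / n_cnv if n_cnv else 0.0,
        mean_cnvr_length_bp=total_cnvr_length_bp / n_cnvr if n_cnvr else 0.0,
        cnv_per_sample=n_cnv / n_samples,
        pct_autosomal_genome=100.0 * total_cnvr_mb / autosomal_genome_mb,
        pct_whole_genome=100.0 * total_cnvr_mb / whole_genome_mb,
    )
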