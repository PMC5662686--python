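"""End-to-end orchestration: calls + LRR + groups -> candidate regions.

The canonical order is: (optional sample QC) -> merge calls into CNVRs ->
drop single-event regions -> region-mean LRR on the analysis set ->
V_ST / V_i scan -> per-group top-quantile candidates -> shared/specific
partition. Genome-wide moments for V_i standardization come from the
singleton-filtered analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import cnvr as cnvr_mod
from . import comparison, divergence
from .divergence import CandidateSet, RegionLrr, ViTable, VstTable
from .types import Cnvr, CnvCall, GroupAssignment, LrrMatrix


@dataclass
class ScanResult:
    cnvrs: list[Cnvr]
    analysis_cnvrs: list[Cnvr]
    region_lrrs: list[RegionLrr]
    vst_table: VstTable
    vi_table: ViTable
    candidates: dict[float, dict[str, CandidateSet]]
    venn: dict[float, comparison.VennPartition]


def run_scan(
    calls: Sequence[CnvCall],
    lrr: LrrMatrix,
    groups: GroupAssignment,
    quantiles: Sequence[float] = (0.01, 0.05),
    min_events: int = 2,
    drop_probeless: bool = True,
) -> ScanResult:
    """Run the full divergence scan on a cohort."""
    keep = set(groups.samples)
    cohort_calls = [c for c in calls if c.sample_id in keep]
    cnvrs = cnvr_mod.merge_calls(cohort_calls)
    analysis = cnvr_mod.filter_singletons(cnvrs, min_events=min_events)
    region_lrrs = divergence.region_mean_lrr_many(
        lrr, analysis, on_empty="drop" if drop_probeless else "error"
    )
    vst_table, vi_table = divergence.vi_scan(region_lrrs, groups)
    candidates: dict[float, dict[str, CandidateSet]] = {}
    venn: dict[float, comparison.VennPartition] = {}
    for q in quantiles:
        per_group = {
            g: divergence.select_candidates(vi_table, g, q) for g in groups.labels
        }
        candidates[q] = per_group
        venn[q] = comparison.venn_partition(per_group)
    return ScanResult(
        cnvrs=cnvrs,
        analysis_cnvrs=analysis,
        region_lrrs=region_lrrs,
        vst_table=vst_table,
        vi_table=vi_table,
        candidates=candidates,
        venn=venn,
    )
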