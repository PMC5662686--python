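"""Shared vs. group-specific partition of candidate regions, and per-group
LRR summaries for the regions a scan flags.

Candidate sets from different groups are drawn from one global CNVR list,
so membership is compared by region id, not by coordinate overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .divergence import CandidateSet, RegionLrr
from .types import GroupAssignment


@dataclass
class VennPartition:
    """Exact set-membership partition of the candidate-set union.

    ``cells`` maps each non-empty subset of groups to the regions belonging
    to exactly those groups' candidate sets.
    """

    cells: dict[frozenset[str], list[str]]
    groups: list[str]

    @property
    def shared(self) -> list[str]:
        """Regions present in every group's candidate set."""
        return self.cells.get(frozenset(self.groups), [])

    def specific(self, group: str) -> list[str]:
        """Regions present only in one group's candidate set."""
        return self.cells.get(frozenset((group,)), [])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(subset)), len(ids), ",".join(ids))
            for subset, ids in sorted(
                self.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "count", "cnvr_ids"])


def venn_partition(candidates: Mapping[str, CandidateSet]) -> VennPartition:
    """Partition candidate regions by exactly which groups flagged them."""
    membership: dict[str, set[str]] = {}
    for group, cs in candidates.items():
        for cid in cs.cnvr_ids:
            membership.setdefault(cid, set()).add(group)
    cells: dict[frozenset[str], list[str]] = {}
    for cid, owners in membership.items():
        cells.setdefault(frozenset(owners), []).append(cid)
    for ids in cells.values():
        ids.sort()
    return VennPartition(cells=cells, groups=sorted(candidates))


def group_lrr_summary(
    region_lrrs: Sequence[RegionLrr],
    groups: GroupAssignment,
    cnvr_ids: Iterable[str],
) -> pd.DataFrame:
    """Box-plot-ready five-number summary (+ mean) of region LRR per group."""
    by_id = {r.cnvr_id: r for r in region_lrrs}
    rows = []
    for cid in cnvr_ids:
        if cid not in by_id:
            raise ValidationError(f"unknown region id {cid!r}")
        values = by_id[cid].values
        for group in groups.labels:
            sub = values.reindex(groups.members(group)).dropna().to_numpy()
            if sub.size == 0:
                rows.append((cid, group, 0) + (np.nan,) * 6)
                continue
            q25, q50, q75 = np.percentile(sub, [25, 50, 75])
            rows.append(
                (
                    cid,
                    group,
                    int(sub.size),
                    float(np.mean(sub)),
                    float(np.min(sub)),
                    float(q25),
                    float(q50),
                    float(q75),
                    float(np.max(sub)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cnvr_id",
            "group",
            "n",
            "mean",
            "min",
            "q25",
            "median",
            "q75",
            "max",
        ],
    )
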