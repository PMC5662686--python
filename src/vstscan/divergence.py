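"""Population-divergence statistics on region-averaged LRR.

The quantitative CNV signal for a region is the mean LRR over all probes
falling within its span, one value per sample. Differentiation between two
groups i and j is measured by

    V_ST = (V_T - V_S) / V_T

where V_T is the sample variance (denominator n-1) of the pooled values of
the two groups and V_S = (n_i v_i + n_j v_j) / (n_i + n_j) is the
size-weighted mean of the within-group sample variances — the quantitative
analogue of F_ST for copy-number intensity. V_ST <= 1; negative values are
retained. V_T = 0 (no variance at all) is defined as V_ST = 0.

The group-specific divergence statistic for group i at one region is

    V_i = sum over j != i of (V_ST^ij - E[V_ST^ij]) / sd[V_ST^ij]

where the mean E and standard deviation sd of each pair's V_ST are taken
across the whole analysis region set, so each term is a genome-wide
standardized deviation. Large positive V_i flags regions unusually
differentiated between group i and the rest — candidates for
group-specific selection. Candidates are the top empirical quantile
(typically 1% and 5%) of V_i per group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import Cnvr, GroupAssignment, LrrMatrix

logger = logging.getLogger(__name__)


@dataclass
class RegionLrr:
    """Per-sample mean LRR over the probes inside one CNVR span."""

    cnvr_id: str
    values: pd.Series  # indexed by sample_id; NaN where all in-region probes missing
    n_probes: int

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValidationError(f"{self.cnvr_id}: region has no probes")


@dataclass
class VstTable:
    """Pairwise V_ST per region plus each pair's genome-wide moments."""

    table: pd.DataFrame  # columns: cnvr_id, group_i, group_j, vst
    moments: pd.DataFrame  # columns: group_i, group_j, mean, sd

    def pair_values(self, group_i: str, group_j: str) -> pd.Series:
        gi, gj = sorted((group_i, group_j))
        sub = self.table[(self.table.group_i == gi) & (self.table.group_j == gj)]
        return pd.Series(sub.vst.to_numpy(), index=sub.cnvr_id.to_numpy())


@dataclass
class ViTable:
    """Per-region, per-group V_i values (long format)."""

    table: pd.DataFrame  # columns: cnvr_id, group, vi

    def group_values(self, group: str) -> pd.Series:
        sub = self.table[self.table.group == group]
        return pd.Series(sub.vi.to_numpy(), index=sub.cnvr_id.to_numpy())


@dataclass
class CandidateSet:
    """Top-quantile regions for one group, ranked by descending V_i."""

    group: str
    quantile: float
    threshold_vi: float
    cnvr_ids: list[str]
    vi_values: list[float] = field(default_factory=list)


def region_mean_lrr(lrr: LrrMatrix, cnvr: Cnvr) -> RegionLrr:
    """Average LRR across all probes inside the region span, per sample.

    The span is a closed interval: probes exactly at the start or end
    coordinate are included. Missing probe values are excluded from the
    mean; a sample with no observed in-region probe is NaN for this region.
    """
    mask = lrr.probe_mask(cnvr.chrom, cnvr.start, cnvr.end)
    n_probes = int(mask.sum())
    if n_probes == 0:
        raise ValidationError(
            f"{cnvr.cnvr_id} ({cnvr.chrom}:{cnvr.start}-{cnvr.end}): "
            "no probes fall within the region"
        )
    block = lrr.values.iloc[mask]
    return RegionLrr(
        cnvr_id=cnvr.cnvr_id, values=block.mean(axis=0, skipna=True), n_probes=n_probes
    )


def region_mean_lrr_many(
    lrr: LrrMatrix, cnvrs: Sequence[Cnvr], on_empty: str = "error"
) -> list[RegionLrr]:
    """Region means for many CNVRs; ``on_empty='drop'`` skips probe-less spans."""
    out: list[RegionLrr] = []
    for cnvr in cnvrs:
        try:
            out.append(region_mean_lrr(lrr, cnvr))
        except ValidationError:
            if on_empty == "drop":
                logger.warning("%s: no probes in span, region dropped", cnvr.cnvr_id)
                continue
            raise
    return out


def vst(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[str],
    group_i: str,
    group_j: str,
) -> float:
    """Pairwise V_ST = (V_T - V_S)/V_T between two groups (NaN-aware).

    Samples with a missing value are dropped pairwise; each group must
    retain at least two observed values.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if x.shape != lab.shape:
        raise ValidationError("values and labels differ in length")
    xi = x[(lab == group_i) & ~np.isnan(x)]
    xj = x[(lab == group_j) & ~np.isnan(x)]
    for name, arr in ((group_i, xi), (group_j, xj)):
        if arr.size < 2:
            raise ValidationError(
                f"group {name!r} has {arr.size} non-missing value(s); need >= 2"
            )
    v_i = float(np.var(xi, ddof=1))
    v_j = float(np.var(xj, ddof=1))
    n_i, n_j = xi.size, xj.size
    v_s = (n_i * v_i + n_j * v_j) / (n_i + n_j)
    v_t = float(np.var(np.concatenate([xi, xj]), ddof=1))
    if v_t == 0.0:
        return 0.0
    return (v_t - v_s) / v_t


def _pairwise_vst_matrix(
    X: np.ndarray, mask_i: np.ndarray, mask_j: np.ndarray, region_ids: Sequence[str]
) -> np.ndarray:
    """Vectorized V_ST for all regions (rows of X) for one group pair."""
    xi, xj = X[:, mask_i], X[:, mask_j]
    n_i = np.sum(~np.isnan(xi), axis=1)
    n_j = np.sum(~np.isnan(xj), axis=1)
    bad = (n_i < 2) | (n_j < 2)
    if bad.any():
        first = region_ids[int(np.flatnonzero(bad)[0])]
        raise ValidationError(
            f"region {first}: fewer than 2 non-missing values in a group"
        )
    v_i = np.nanvar(xi, axis=1, ddof=1)
    v_j = np.nanvar(xj, axis=1, ddof=1)
    v_s = (n_i * v_i + n_j * v_j) / (n_i + n_j)
    v_t = np.nanvar(np.concatenate([xi, xj], axis=1), axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(v_t > 0.0, (v_t - v_s) / np.where(v_t > 0.0, v_t, 1.0), 0.0)
    return out


def vi_scan(
    region_lrrs: Sequence[RegionLrr],
    groups: GroupAssignment,
    analysis_ids: Iterable[str] | None = None,
) -> tuple[VstTable, ViTable]:
    """Genome-wide V_ST / V_i scan over an analysis region set.

    ``analysis_ids`` selects the regions entering the scan (typically the
    singleton-filtered set); both the per-region V_ST values and the
    genome-wide moments E and sd are computed on exactly that set, so the
    standardized terms have mean 0 and sd 1 across it by construction.
    """
    by_id = {r.cnvr_id: r for r in region_lrrs}
    if analysis_ids is None:
        ids = [r.cnvr_id for r in region_lrrs]
    else:
        ids = list(analysis_ids)
        unknown = sorted(set(ids) - set(by_id))
        if unknown:
            raise ValidationError(f"analysis ids without region LRR: {unknown[:5]}")
    labels = groups.labels
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    if len(ids) < 2:
        raise ValidationError("need at least 2 analysis regions (sd undefined)")

    samples = groups.samples
    X = np.vstack([by_id[i].values.reindex(samples).to_numpy(dtype=float) for i in ids])
    sample_group = np.asarray([groups.group_of(s) for s in samples], dtype=object)
    masks = {g: sample_group == g for g in labels}

    pairs = [
        (labels[a], labels[b])
        for a in range(len(labels))
        for b in range(a + 1, len(labels))
    ]
    vst_rows: list[pd.DataFrame] = []
    moment_rows: list[tuple[str, str, float, float]] = []
    z_by_pair: dict[tuple[str, str], np.ndarray] = {}
    for gi, gj in pairs:
        v = _pairwise_vst_matrix(X, masks[gi], masks[gj], ids)
        e = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
        if sd == 0.0:
            raise ValidationError(
                f"pair ({gi}, {gj}): all V_ST values identical; sd = 0"
            )
        z_by_pair[(gi, gj)] = (v - e) / sd
        moment_rows.append((gi, gj, e, sd))
        vst_rows.append(
            pd.DataFrame(
                {"cnvr_id": ids, "group_i": gi, "group_j": gj, "vst": v}
            )
        )

    vi_frames = []
    for g in labels:
        z_total = np.zeros(len(ids))
        for (gi, gj), z in z_by_pair.items():
            if g in (gi, gj):
                z_total = z_total + z
        vi_frames.append(pd.DataFrame({"cnvr_id": ids, "group": g, "vi": z_total}))

    vst_table = VstTable(
        table=pd.concat(vst_rows, ignore_index=True),
        moments=pd.DataFrame(
            moment_rows, columns=["group_i", "group_j", "mean", "sd"]
        ),
    )
    vi_table = ViTable(table=pd.concat(vi_frames, ignore_index=True))
    return vst_table, vi_table


def select_candidates(
    vi_table: ViTable, group: str, quantile: float
) -> CandidateSet:
    """Top-quantile regions by V_i for one group.

    k = round-half-up(quantile * n). Regions are ranked by descending V_i;
    ties at the cut are broken by ascending cnvr_id so selection is
    deterministic.
    """
    if not 0.0 < quantile < 1.0:
        raise ValidationError(f"quantile {quantile} outside (0, 1)")
    values = vi_table.group_values(group)
    if values.empty:
        raise ValidationError(f"no V_i values for group {group!r}")
    if not np.isfinite(values.to_numpy()).all():
        raise ValidationError(f"non-finite V_i values for group {group!r}")
    n = len(values)
    k = int(math.floor(quantile * n + 0.5))
    if k == 0:
        raise ValidationError(
            f"quantile {quantile} of {n} regions selects 0 candidates; "
            "use a larger region set or quantile"
        )
    ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen = ranked[:k]
    return CandidateSet(
        group=group,
        quantile=quantile,
        threshold_vi=float(chosen[-1][1]),
        cnvr_ids=[cid for cid, _ in chosen],
        vi_values=[float(v) for _, v in chosen],
    )


def manhattan_table(
    vi_table: ViTable, cnvrs: Sequence[Cnvr]
) -> pd.DataFrame:
    """Plot-ready table (cnvr_id, chrom, midpoint, group, vi) for a genome scan."""
    coords = {c.cnvr_id: (c.chrom, (c.start + c.end) // 2) for c in cnvrs}
    rows = []
    for row in vi_table.table.itertuples():
        chrom, mid = coords.get(row.cnvr_id, (None, None))
        rows.append((row.cnvr_id, chrom, mid, row.group, row.vi))
    return pd.DataFrame(rows, columns=["cnvr_id", "chrom", "midpoint", "group", "vi"])
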