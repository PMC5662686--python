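"""Domain types shared by every pipeline stage.

All genomic intervals are 1-based and inclusive at both ends (the native
convention of PennCNV call lists, the primary input format). BED files are
converted at the I/O boundary, never internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

GAIN = "gain"
LOSS = "loss"
BOTH = "both"

FEATURES = ("gene", "CDS", "exon")


def chrom_sort_key(chrom: str) -> tuple[int, object]:
    """Natural ordering for chromosome labels: numeric autosomes first."""
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass(frozen=True)
class CnvCall:
    """One CNV event in one sample: a closed interval plus its copy number.

    A call with copy number 2 is invalid by construction — a "CNV" at the
    normal diploid state is not an event.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    num_probes: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"CNV call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )
        if self.copy_number < 0:
            raise ValidationError(f"negative copy number {self.copy_number}")
        if self.copy_number == 2:
            raise ValidationError(
                f"CNV call {self.sample_id} {self.chrom}:{self.start}-{self.end} "
                "has copy number 2 (normal state, not an event)"
            )
        if self.num_probes < 1:
            raise ValidationError(f"num_probes must be >= 1, got {self.num_probes}")

    @property
    def state(self) -> str:
        return LOSS if self.copy_number < 2 else GAIN

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LrrMatrix:
    """Probe-level Log R Ratio, probes x samples, with probe coordinates.

    ``probes`` has columns probe_id/chrom/pos sorted by (chrom, pos);
    ``values`` is indexed by probe_id with one column per sample. Missing
    entries are NaN and stay missing — they are excluded from region means,
    never imputed.
    """

    probes: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos"}
        if not required.issubset(self.probes.columns):
            raise ValidationError(f"probe table needs columns {sorted(required)}")
        if self.probes["probe_id"].duplicated().any():
            dupes = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"]
            raise ValidationError(f"duplicate probe ids: {sorted(set(dupes))[:5]}")
        if self.probes.duplicated(subset=["chrom", "pos"]).any():
            raise ValidationError("duplicate probe positions within a chromosome")
        order = sorted(
            range(len(self.probes)),
            key=lambda i: (
                chrom_sort_key(str(self.probes["chrom"].iloc[i])),
                int(self.probes["pos"].iloc[i]),
            ),
        )
        self.probes = self.probes.iloc[order].reset_index(drop=True)
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in LRR matrix")
        self.values = self.values.reindex(self.probes["probe_id"])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def probe_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask over probes falling within a closed interval."""
        p = self.probes
        return (
            (p["chrom"].astype(str) == str(chrom))
            & (p["pos"] >= start)
            & (p["pos"] <= end)
        ).to_numpy()


@dataclass
class GroupAssignment:
    """Mapping sample_id -> group label; each group needs >= 2 samples."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for g in self.assignments.values():
            counts[g] = counts.get(g, 0) + 1
        small = sorted(g for g, n in counts.items() if n < 2)
        if small:
            raise ValidationError(
                f"groups with fewer than 2 samples (variance undefined): {small}"
            )
        self.assignments = dict(self.assignments)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def group_of(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class GeneInterval:
    """A gene/CDS/exon interval in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    feature: str = "gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene interval {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.feature not in FEATURES:
            raise ValidationError(
                f"feature must be one of {FEATURES}, got {self.feature!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleQcMetrics:
    """Per-sample array QC: call rate plus PennCNV-style signal metrics."""

    sample_id: str
    call_rate: float
    lrr_sd: float
    baf_drift: float
    waviness: float

    def __post_init__(self) -> None:
        for name in ("call_rate", "lrr_sd", "baf_drift", "waviness"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{self.sample_id}: {name} is not finite")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValidationError(
                f"{self.sample_id}: call_rate {self.call_rate} outside [0, 1]"
            )
        for name in ("lrr_sd", "baf_drift"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.sample_id}: {name} negative")


@dataclass(frozen=True)
class Cnvr:
    """A CNV region: the union span of overlapping calls across samples."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    type: str
    event_count: int
    carrier_samples: frozenset[str] = field(default_factory=frozenset)
    is_unique: bool = False
    members: tuple[CnvCall, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.cnvr_id}: start > end")
        if self.type not in (GAIN, LOSS, BOTH):
            raise ValidationError(f"{self.cnvr_id}: bad type {self.type!r}")
        if self.event_count < 1:
            raise ValidationError(f"{self.cnvr_id}: event_count < 1")
        if self.is_unique and len(self.carrier_samples) > 1:
            raise ValidationError(f"{self.cnvr_id}: unique but multiple carriers")

    @property
    def sample_count(self) -> int:
        return len(self.carrier_samples)

    @property
    def length(self) -> int:
        return self.end - self.start + 1
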