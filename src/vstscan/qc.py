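"""Sample-level quality control applied before any population statistic.

Three filters, mirroring a standard SNP-array CNV workflow: array call rate
(strictly greater than the threshold passes), relatedness pruning on pairwise
PI-HAT, and PennCNV-style per-sample signal quality (LRR SD, BAF drift,
waviness factor; at-or-below the threshold passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import ValidationError
from .types import SampleQcMetrics

# PennCNV-convention defaults for per-sample signal quality.
DEFAULT_LRR_SD_MAX = 0.35
DEFAULT_BAF_DRIFT_MAX = 0.01
DEFAULT_WAVINESS_MAX = 0.05
DEFAULT_CALL_RATE_MIN = 0.95
DEFAULT_PIHAT_MAX = 0.25


@dataclass
class RelatednessTable:
    """Symmetric pairwise PI-HAT values (proportion IBD), no self-pairs."""

    pihat: dict[frozenset[str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, value in self.pihat.items():
            if len(pair) != 2:
                raise ValidationError(f"not an unordered sample pair: {set(pair)}")
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"PI-HAT {value} outside [0, 1] for {set(pair)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "RelatednessTable":
        table: dict[frozenset[str], float] = {}
        for a, b, value in pairs:
            if a == b:
                raise ValidationError(f"self-pair for sample {a}")
            table[frozenset((a, b))] = float(value)
        return cls(table)

    @property
    def samples(self) -> set[str]:
        return {s for pair in self.pihat for s in pair}


def filter_call_rate(
    metrics: Iterable[SampleQcMetrics], threshold: float = DEFAULT_CALL_RATE_MIN
) -> set[str]:
    """Keep samples whose call rate strictly exceeds ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"call-rate threshold {threshold} outside (0, 1]")
    return {m.sample_id for m in metrics if m.call_rate > threshold}


def filter_unrelated(
    pihat: RelatednessTable,
    threshold: float = DEFAULT_PIHAT_MAX,
    samples: Iterable[str] | None = None,
) -> set[str]:
    """Prune samples until no surviving pair has PI-HAT >= ``threshold``.

    Greedy: repeatedly remove the sample participating in the most
    at-or-above-threshold pairs; ties broken by lexicographically smallest
    sample_id. Deterministic, and on small graphs it matches a minimum
    vertex cover (verified by brute force in the test suite).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"PI-HAT threshold {threshold} outside (0, 1]")
    kept = set(samples) if samples is not None else set(pihat.samples)
    edges = {
        pair
        for pair, value in pihat.pihat.items()
        if value >= threshold and pair <= kept
    }
    while edges:
        degree: dict[str, int] = {}
        for pair in edges:
            for s in pair:
                degree[s] = degree.get(s, 0) + 1
        worst = min(degree, key=lambda s: (-degree[s], s))
        kept.discard(worst)
        edges = {pair for pair in edges if worst not in pair}
    return kept


def filter_cnv_quality(
    metrics: Iterable[SampleQcMetrics],
    lrr_sd_max: float = DEFAULT_LRR_SD_MAX,
    baf_drift_max: float = DEFAULT_BAF_DRIFT_MAX,
    waviness_max: float = DEFAULT_WAVINESS_MAX,
) -> set[str]:
    """Keep samples passing all three signal-quality thresholds (<= passes)."""
    for name, value in (
        ("lrr_sd_max", lrr_sd_max),
        ("baf_drift_max", baf_drift_max),
        ("waviness_max", waviness_max),
    ):
        if value <= 0:
            raise ValidationError(f"{name} must be > 0, got {value}")
    return {
        m.sample_id
        for m in metrics
        if m.lrr_sd <= lrr_sd_max
        and m.baf_drift <= baf_drift_max
        and abs(m.waviness) <= waviness_max
    }
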