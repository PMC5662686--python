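"""Synthetic SNP-array cohorts with group-structured CNV carriers.

The generator emulates the statistical structure the scan assumes: a
cohort of four geographic groups (default sizes 35/17/63/42, 157 samples),
29 autosomes carrying a regular probe grid, and a truth set of CNV regions
each sample carries independently with its group's Bernoulli frequency.
Probe LRR is Gaussian around a copy-number-dependent mean — the canonical
SNP-array signal model (cn1 about -0.45, cn3 about +0.3, cn2 at 0) — with
homoscedastic noise. Carried regions also emit a CNV call directly (the
HMM calling step is out of scope), so every downstream stage can be tested
against known truth with no external data.

``expected_vst`` gives the closed-form V_ST of the Bernoulli-mixture model
for a region, the analytic oracle the simulation tests converge to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from . import io as vio
from .types import CnvCall, GroupAssignment, LrrMatrix

DELETION = "deletion"
DUPLICATION = "duplication"

#: Canonical LRR state means for integer copy numbers on Illumina-style arrays.
DEFAULT_LRR_MEANS = {0: -3.5, 1: -0.45, 2: 0.0, 3: 0.3, 4: 0.75}

DEFAULT_GROUPS = (("North", 35), ("Northwest", 17), ("Southwest", 63), ("South", 42))


@dataclass(frozen=True)
class TruthRegion:
    """One simulated CNV region with per-group carrier frequencies."""

    region_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str  # deletion | duplication
    copy_number: int
    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.region_id}: start > end")
        if self.cnv_type not in (DELETION, DUPLICATION):
            raise ValidationError(f"{self.region_id}: bad cnv_type {self.cnv_type!r}")
        if (self.cnv_type == DELETION) != (self.copy_number < 2):
            raise ValidationError(f"{self.region_id}: cnv_type/copy_number mismatch")
        for g, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{self.region_id}: frequency {f} for {g}")
        if not any(f > 0 for f in self.frequencies.values()):
            raise ValidationError(f"{self.region_id}: all carrier frequencies zero")


def default_truth_regions(
    groups: Sequence[tuple[str, int]] = DEFAULT_GROUPS,
    n_chrom: int = 29,
    chrom_length_bp: int = 10_000_000,
) -> list[TruthRegion]:
    """A default truth set mixing the region classes a real cohort shows.

    One strongly group-differentiated region per group (carrier frequency
    0.8 there, 0.05 elsewhere), 24 undifferentiated common regions
    (frequency 0.25 everywhere) and 8 rare regions (0.02 everywhere, the
    singleton fodder), alternating deletions and duplications, laid out
    round-robin across chromosomes.
    """
    labels = [g for g, _ in groups]
    regions: list[TruthRegion] = []
    n_regions = len(labels) + 24 + 8
    slots_per_chrom = -(-n_regions // n_chrom)  # ceil
    pitch = chrom_length_bp // (slots_per_chrom + 1)
    region_len = min(40_000, max(pitch // 2, 1))
    k = 0

    def place(freqs: Mapping[str, float]) -> None:
        nonlocal k
        chrom = str((k % n_chrom) + 1)
        start = (k // n_chrom + 1) * pitch
        end = start + region_len - 1
        if end > chrom_length_bp:
            raise ValidationError("truth region beyond chromosome end")
        deletion = k % 2 == 0
        regions.append(
            TruthRegion(
                region_id=f"TR{k + 1}",
                chrom=chrom,
                start=start,
                end=end,
                cnv_type=DELETION if deletion else DUPLICATION,
                copy_number=1 if deletion else 3,
                frequencies=dict(freqs),
            )
        )
        k += 1

    for target in labels:
        place({g: (0.8 if g == target else 0.05) for g in labels})
    for _ in range(24):
        place({g: 0.25 for g in labels})
    for _ in range(8):
        place({g: 0.02 for g in labels})
    return regions


@dataclass
class SimConfig:
    """Cohort-generator settings; the defaults are the study conditions."""

    seed: int = 0
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_chrom: int = 29
    chrom_length_bp: int = 10_000_000
    probe_spacing_bp: int = 2_000
    truth_regions: list[TruthRegion] = field(default_factory=list)
    lrr_noise_sd: float = 0.2
    lrr_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    miscall_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.truth_regions:
            self.truth_regions = default_truth_regions(
                self.groups, self.n_chrom, self.chrom_length_bp
            )
        if self.lrr_noise_sd < 0:
            raise ValidationError("lrr_noise_sd must be >= 0")
        if not 0.0 <= self.miscall_rate < 1.0:
            raise ValidationError("miscall_rate must be in [0, 1)")
        if 2 not in self.lrr_means:
            raise ValidationError("lrr_means must define the cn=2 baseline")
        labels = {g for g, _ in self.groups}
        for region in self.truth_regions:
            if int(region.chrom) > self.n_chrom:
                raise ValidationError(f"{region.region_id}: chromosome out of range")
            if region.end > self.chrom_length_bp:
                raise ValidationError(f"{region.region_id}: beyond chromosome end")
            if self.probes_in(region) == 0:
                raise ValidationError(f"{region.region_id}: contains no probes")
            if region.copy_number not in self.lrr_means:
                raise ValidationError(
                    f"{region.region_id}: no LRR mean for cn={region.copy_number}"
                )
            unknown = set(region.frequencies) - labels
            if unknown:
                raise ValidationError(
                    f"{region.region_id}: unknown group(s) {sorted(unknown)}"
                )

    def probes_in(self, region: TruthRegion) -> int:
        """Number of grid probes falling within the region's closed span."""
        sp = self.probe_spacing_bp
        return region.end // sp - (region.start - 1) // sp

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        if "groups" in raw:
            raw["groups"] = tuple((str(g), int(n)) for g, n in raw["groups"])
        if "lrr_means" in raw:
            raw["lrr_means"] = {int(k): float(v) for k, v in raw["lrr_means"].items()}
        if "truth_regions" in raw:
            raw["truth_regions"] = [
                TruthRegion(
                    region_id=str(r["region_id"]),
                    chrom=str(r["chrom"]),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    cnv_type=str(r["cnv_type"]),
                    copy_number=int(r["copy_number"]),
                    frequencies={str(g): float(f) for g, f in r["frequencies"].items()},
                )
                for r in raw["truth_regions"]
            ]
        return cls(**raw)


@dataclass
class SimCohort:
    """One simulated cohort: signal, calls, groups and the truth table."""

    lrr: LrrMatrix
    calls: list[CnvCall]
    groups: GroupAssignment
    truth: pd.DataFrame
    config: SimConfig


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimCohort:
    """Draw one cohort; identical seed and config give identical output."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sp = config.probe_spacing_bp

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for label, n in config.groups:
        for i in range(n):
            sid = f"{label}_{i + 1:03d}"
            sample_ids.append(sid)
            assignments[sid] = label
    groups = GroupAssignment(assignments)
    n_samples = len(sample_ids)

    chrom_probe_offset: dict[str, int] = {}
    probe_rows: list[tuple[str, str, int]] = []
    for c in range(1, config.n_chrom + 1):
        chrom = str(c)
        chrom_probe_offset[chrom] = len(probe_rows)
        for j, pos in enumerate(range(sp, config.chrom_length_bp + 1, sp)):
            probe_rows.append((f"p{chrom}_{j + 1}", chrom, pos))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])

    baseline = config.lrr_means[2]
    values = rng.normal(baseline, config.lrr_noise_sd, size=(len(probes), n_samples))

    calls: list[CnvCall] = []
    truth_rows = []
    group_labels = [g for g, _ in config.groups]
    sample_group = np.asarray([assignments[s] for s in sample_ids], dtype=object)
    for region in config.truth_regions:
        freq = np.asarray(
            [region.frequencies.get(g, 0.0) for g in sample_group], dtype=float
        )
        carried = rng.random(n_samples) < freq
        first = chrom_probe_offset[region.chrom] + (region.start - 1) // sp
        m = config.probes_in(region)
        carrier_idx = np.flatnonzero(carried)
        if carrier_idx.size:
            values[first : first + m, carrier_idx] = rng.normal(
                config.lrr_means[region.copy_number],
                config.lrr_noise_sd,
                size=(m, carrier_idx.size),
            )
        missed = (
            rng.random(carrier_idx.size) < config.miscall_rate
            if config.miscall_rate > 0
            else np.zeros(carrier_idx.size, dtype=bool)
        )
        for idx, miss in zip(carrier_idx, missed):
            if miss:
                continue
            calls.append(
                CnvCall(
                    sample_id=sample_ids[idx],
                    chrom=region.chrom,
                    start=region.start,
                    end=region.end,
                    copy_number=region.copy_number,
                    num_probes=m,
                )
            )
        row = {
            "region_id": region.region_id,
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
            "cnv_type": region.cnv_type,
            "copy_number": region.copy_number,
        }
        for g in group_labels:
            row[f"freq_{g}"] = region.frequencies.get(g, 0.0)
            row[f"carriers_{g}"] = int(np.sum(carried & (sample_group == g)))
        truth_rows.append(row)

    lrr = LrrMatrix(
        probes=probes,
        values=pd.DataFrame(values, index=probes["probe_id"], columns=sample_ids),
    )
    return SimCohort(
        lrr=lrr,
        calls=calls,
        groups=groups,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def write_cohort(cohort: SimCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write lrr.tsv, calls.rawcnv, groups.tsv and truth.tsv for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lrr": out / "lrr.tsv",
        "calls": out / "calls.rawcnv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.tsv",
    }
    vio.write_lrr_matrix(cohort.lrr, paths["lrr"])
    vio.write_penncnv_calls(cohort.calls, paths["calls"])
    vio.write_groups(cohort.groups, paths["groups"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def expected_vst(
    config: SimConfig, region: TruthRegion, group_i: str, group_j: str
) -> float:
    """Closed-form V_ST of the Bernoulli-mixture LRR model for one region.

    A sample's region-mean LRR is baseline + Z * delta + noise with
    Z ~ Bernoulli(f_g), delta the carrier LRR shift, and noise variance
    sigma^2 / m after averaging over the region's m probes. Within-group
    variance is v_g = sigma^2/m + f_g (1 - f_g) delta^2; the pooled
    variance adds the between-group mean spread with sample-size weights,
    and V_ST = (V_T - V_S) / V_T.
    """
    sizes = dict(config.groups)
    for g in (group_i, group_j):
        if g not in sizes:
            raise ValidationError(f"unknown group {g!r}")
    m = config.probes_in(region)
    sigma2 = config.lrr_noise_sd**2 / m
    delta = config.lrr_means[region.copy_number] - config.lrr_means[2]
    f = {g: region.frequencies.get(g, 0.0) for g in (group_i, group_j)}
    n = {g: sizes[g] for g in (group_i, group_j)}
    total = n[group_i] + n[group_j]
    w = {g: n[g] / total for g in (group_i, group_j)}
    mu = {g: f[g] * delta for g in (group_i, group_j)}
    v = {g: sigma2 + f[g] * (1.0 - f[g]) * delta**2 for g in (group_i, group_j)}
    v_s = sum(w[g] * v[g] for g in (group_i, group_j))
    mean = sum(w[g] * mu[g] for g in (group_i, group_j))
    v_t = sum(w[g] * (v[g] + mu[g] ** 2) for g in (group_i, group_j)) - mean**2
    if v_t == 0.0:
        return 0.0
    return (v_t - v_s) / v_t
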