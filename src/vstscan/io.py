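"""Readers and writers for every external format the pipeline touches.

Formats
-------
* PennCNV ``rawcnv`` call lists (read/write), whitespace-separated:
  ``chr1:1000-2000  numsnp=25  length=1001  state2,cn=1  S1  startsnp=.. endsnp=..``
* LRR matrix TSV: columns ``Name``/``Chr``/``Position`` then one column per
  sample; ``NA`` marks a missing entry.
* Groups TSV: ``sample_id<TAB>group``.
* Gene annotation: 5-column BED (chrom, start, end, gene_id, feature) in the
  usual 0-based half-open convention, converted to 1-based inclusive on read.
* QC metrics TSV, PI-HAT TSV, and the pipeline's own CNVR / V_ST / V_i /
  candidate tables (plain TSV, loss-free round trips).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .qc import RelatednessTable
from .types import (
    Cnvr,
    CnvCall,
    GeneInterval,
    GroupAssignment,
    LrrMatrix,
    SampleQcMetrics,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

N_AUTOSOMES = 29  # cattle; chrX/chrY/chrUn/chrMT are never analysed

_RAWCNV_RE = re.compile(
    r"^(?:chr)?(?P<chrom>\S+?):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
)

# PennCNV HMM state labels for each integer copy number (cn2 has no CNV state).
_CN_TO_STATE = {0: 1, 1: 2, 3: 5, 4: 6, 5: 6, 6: 6}


def autosome_labels(n_autosomes: int = N_AUTOSOMES) -> set[str]:
    return {str(i) for i in range(1, n_autosomes + 1)}


def read_penncnv_calls(
    path: str | Path, n_autosomes: int = N_AUTOSOMES
) -> list[CnvCall]:
    """Parse a PennCNV rawcnv file into validated autosomal CNV calls.

    Calls on non-autosomes (chrX, chrY, chrUn, chrMT, ...) are dropped; the
    dropped count is logged, matching the usual array-CNV practice of
    analysing autosomes only.
    """
    path = Path(path)
    autosomes = autosome_labels(n_autosomes)
    calls: list[CnvCall] = []
    skipped = 0
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: unparseable rawcnv line: {line!r}")
            chrom = m.group("chrom")
            if chrom not in autosomes:
                skipped += 1
                continue
            cn = int(m.group("cn"))
            if cn == 2:
                raise ValidationError(
                    f"{path}:{lineno}: cn=2 is the normal state, not a CNV"
                )
            calls.append(
                CnvCall(
                    sample_id=m.group("sample"),
                    chrom=chrom,
                    start=int(m.group("start")),
                    end=int(m.group("end")),
                    copy_number=cn,
                    num_probes=int(m.group("numsnp").replace(",", "")),
                )
            )
    if skipped:
        logger.info("%s: skipped %d non-autosomal call(s)", path, skipped)
    if not calls:
        logger.warning("%s: no autosomal CNV calls found", path)
    return calls


def write_penncnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the rawcnv dialect ``read_penncnv_calls`` accepts."""
    path = Path(path)
    with path.open("w") as handle:
        for c in calls:
            state = _CN_TO_STATE.get(c.copy_number, 6)
            handle.write(
                f"chr{c.chrom}:{c.start}-{c.end}\t"
                f"numsnp={c.num_probes}\tlength={c.length}\t"
                f"state{state},cn={c.copy_number}\t{c.sample_id}\t"
                f"startsnp=p{c.chrom}_{c.start} endsnp=p{c.chrom}_{c.end}\n"
            )


def read_lrr_matrix(path: str | Path) -> LrrMatrix:
    """Read a probes x samples LRR TSV (Name/Chr/Position + sample columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"Name": str, "Chr": str}, na_values=["NA"])
    required = ("Name", "Chr", "Position")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing header column(s) {missing}")
    if df["Name"].duplicated().any():
        dupes = sorted(set(df.loc[df["Name"].duplicated(), "Name"]))
        raise ParseError(f"{path}: duplicate probe id(s) {dupes[:5]}")
    sample_cols = [c for c in df.columns if c not in required]
    for col in sample_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric LRR value {df[col].iloc[row]!r} "
                f"at probe {df['Name'].iloc[row]!r}, sample {col!r}"
            )
        df[col] = coerced
    probes = pd.DataFrame(
        {
            "probe_id": df["Name"],
            "chrom": df["Chr"].astype(str),
            "pos": df["Position"].astype(int),
        }
    )
    values = df[sample_cols].copy()
    values.index = df["Name"]
    return LrrMatrix(probes=probes, values=values)


def write_lrr_matrix(lrr: LrrMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "Name": lrr.probes["probe_id"].to_numpy(),
            "Chr": lrr.probes["chrom"].to_numpy(),
            "Position": lrr.probes["pos"].to_numpy(),
        }
    )
    vals = lrr.values.reset_index(drop=True)
    out = pd.concat([df, vals], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.4f")


def read_groups(
    path: str | Path, samples: Sequence[str] | None = None
) -> GroupAssignment:
    """Read ``sample_id<TAB>group``; optionally check against a cohort."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    if df["sample_id"].duplicated().any():
        dupes = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise ParseError(f"{path}: duplicate sample id(s) {dupes[:5]}")
    if samples is not None:
        known = set(samples)
        offenders = sorted(s for s in df["sample_id"] if s not in known)
        if offenders:
            raise ValidationError(
                f"{path}: sample(s) absent from the cohort: {offenders}"
            )
    return GroupAssignment(dict(zip(df["sample_id"], df["group"])))


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for sample, group in groups.assignments.items():
            handle.write(f"{sample}\t{group}\n")


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read a 5-column BED (chrom, start, end, gene_id, feature).

    BED is 0-based half-open; internal coordinates are 1-based inclusive, so
    start is shifted by +1 and end is kept.
    """
    path = Path(path)
    intervals: list[GeneInterval] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 BED columns, got {len(fields)}"
                )
            chrom = fields[0].removeprefix("chr")
            intervals.append(
                GeneInterval(
                    gene_id=fields[3],
                    chrom=chrom,
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    feature=fields[4],
                )
            )
    return intervals


def write_gene_bed(genes: Iterable[GeneInterval], path: str | Path) -> None:
    """Write gene intervals back to 0-based half-open 5-column BED."""
    with Path(path).open("w") as handle:
        for g in genes:
            handle.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t{g.feature}\n")


def read_qc_metrics(path: str | Path) -> list[SampleQcMetrics]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "call_rate", "lrr_sd", "baf_drift", "waviness"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing QC column(s) {sorted(missing)}")
    return [
        SampleQcMetrics(
            sample_id=row.sample_id,
            call_rate=float(row.call_rate),
            lrr_sd=float(row.lrr_sd),
            baf_drift=float(row.baf_drift),
            waviness=float(row.waviness),
        )
        for row in df.itertuples()
    ]


def write_qc_metrics(metrics: Iterable[SampleQcMetrics], path: str | Path) -> None:
    rows = [
        (m.sample_id, m.call_rate, m.lrr_sd, m.baf_drift, m.waviness) for m in metrics
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "call_rate", "lrr_sd", "baf_drift", "waviness"]
    ).to_csv(path, sep="\t", index=False)


def read_pihat(path: str | Path) -> RelatednessTable:
    """Read a ``sample_a sample_b pihat`` TSV into a relatedness table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    required = {"sample_a", "sample_b", "pihat"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing PI-HAT column(s) {sorted(missing)}")
    return RelatednessTable.from_pairs(
        (row.sample_a, row.sample_b, float(row.pihat)) for row in df.itertuples()
    )


_CNVR_COLUMNS = [
    "cnvr_id",
    "chrom",
    "start",
    "end",
    "type",
    "event_count",
    "sample_count",
    "is_unique",
]


def write_cnvr_table(cnvrs: Iterable[Cnvr], path: str | Path) -> None:
    rows = [
        (
            c.cnvr_id,
            c.chrom,
            c.start,
            c.end,
            c.type,
            c.event_count,
            c.sample_count,
            int(c.is_unique),
        )
        for c in cnvrs
    ]
    pd.DataFrame(rows, columns=_CNVR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cnvr_table(path: str | Path) -> pd.DataFrame:
    """Read a CNVR table written by :func:`write_cnvr_table`.

    Member calls and carrier identities are not stored in the table, so the
    result is a plain DataFrame rather than :class:`Cnvr` objects.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cnvr_id": str, "chrom": str})
    missing = set(_CNVR_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing CNVR column(s) {sorted(missing)}")
    df = df.sort_values(
        by=["chrom", "start"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    return df


def cnvrs_from_table(df: pd.DataFrame) -> list[Cnvr]:
    """Rehydrate region records (without members/carrier ids) from a table."""
    return [
        Cnvr(
            cnvr_id=row.cnvr_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            type=row.type,
            event_count=int(row.event_count),
            carrier_samples=frozenset(),
            is_unique=bool(row.is_unique),
        )
        for row in df.itertuples()
    ]


def write_vst_table(vst_long: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format pairwise V_ST table (cnvr_id, group_i, group_j, vst)."""
    vst_long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_vi_table(vi_long: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format V_i table (cnvr_id, group, vi)."""
    vi_long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vi_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cnvr_id": str, "group": str})
    missing = {"cnvr_id", "group", "vi"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing V_i column(s) {sorted(missing)}")
    return df


def write_candidates(candidates, path: str | Path) -> None:
    """Write one candidate set (rank, cnvr_id, vi, threshold columns)."""
    rows = [
        (rank + 1, cnvr_id, vi)
        for rank, (cnvr_id, vi) in enumerate(zip(candidates.cnvr_ids, candidates.vi_values))
    ]
    df = pd.DataFrame(rows, columns=["rank", "cnvr_id", "vi"])
    df.insert(0, "group", candidates.group)
    df["quantile"] = candidates.quantile
    df["threshold_vi"] = candidates.threshold_vi
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
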