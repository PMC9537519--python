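"""Readers and writers for CNV calls, gene tracks, phenotype, incidence and results.

Supported formats
-----------------
* PennCNV ``.rawcnv`` text dialect and a plain TSV dialect for CNV calls.
* BED4 for gene tracks and CNV maps (0-based half-open on disk, converted
  to the internal 1-based closed convention at the boundary).
* TSV with a mandatory header for phenotype tables and QC metrics.
* YAML for incidence tables and QC threshold configuration.
* TSV for association-result exports.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    DELETION,
    DUPLICATION,
    AssocResult,
    CnvCall,
    GeneRegion,
    IncidenceTable,
    SampleQcMetrics,
    coerce_subject_frame,
    normalise_chrom,
)

_RAWCNV_RE = re.compile(
    r"^(?P<loc>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)


def _cn_to_type(cn: int, where: str) -> str:
    if cn == 2:
        raise ValueError(f"{where}: neutral copy number (cn=2) is not a CNV call")
    return DELETION if cn < 2 else DUPLICATION


def read_cnv_calls(path: str | Path, dialect: str = "penncnv_rawcnv") -> list[CnvCall]:
    """Read CNV calls from a PennCNV rawcnv file or a plain TSV.

    The TSV dialect is headerless with columns
    ``sample chrom start end cnv_type n_probes [copy_number]``.
    Malformed lines raise ``ValueError`` naming the line number; cn=2
    records are rejected rather than dropped so upstream errors surface.
    """
    path = Path(path)
    if dialect not in ("penncnv_rawcnv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            where = f"{path.name}:{lineno}"
            if dialect == "penncnv_rawcnv":
                m = _RAWCNV_RE.match(line)
                if m is None:
                    raise ValueError(f"{where}: malformed rawcnv line: {line!r}")
                cn = int(m.group("cn"))
                calls.append(
                    CnvCall(
                        sample_id=m.group("sample"),
                        chrom=normalise_chrom(m.group("loc")),
                        start=int(m.group("start")),
                        end=int(m.group("end")),
                        cnv_type=_cn_to_type(cn, where),
                        n_probes=int(m.group("numsnp")),
                        copy_number=cn,
                    )
                )
            else:
                fields = line.split()
                if len(fields) not in (6, 7):
                    raise ValueError(f"{where}: expected 6 or 7 columns, got {len(fields)}")
                sample, chrom, start, end, cnv_type, n_probes = fields[:6]
                if cnv_type not in (DELETION, DUPLICATION):
                    raise ValueError(f"{where}: invalid cnv_type {cnv_type!r}")
                cn = int(fields[6]) if len(fields) == 7 else None
                if cn == 2:
                    raise ValueError(f"{where}: neutral copy number (cn=2) is not a CNV call")
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        chrom=normalise_chrom(chrom),
                        start=int(start),
                        end=int(end),
                        cnv_type=cnv_type,
                        n_probes=int(n_probes),
                        copy_number=cn,
                    )
                )
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the TSV dialect (round-trips with ``read_cnv_calls``)."""
    with open(path, "w") as fh:
        for c in calls:
            cols = [c.sample_id, c.chrom, str(c.start), str(c.end), c.cnv_type, str(c.n_probes)]
            if c.copy_number is not None:
                cols.append(str(c.copy_number))
            fh.write("\t".join(cols) + "\n")


def read_gene_track(path: str | Path) -> list[GeneRegion]:
    """Read a BED4 gene track into 1-based closed GeneRegions.

    Rows sharing a (symbol, chromosome) pair are collapsed to one region
    spanning their union — the non-redundant gene-centric convention.
    The same symbol on different chromosomes stays distinct.
    """
    path = Path(path)
    spans: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path.name}:{lineno}: missing name column (BED4 required)")
            chrom = normalise_chrom(fields[0])
            bed_start, bed_end = int(fields[1]), int(fields[2])
            if bed_start >= bed_end:
                raise ValueError(f"{path.name}:{lineno}: BED start {bed_start} >= end {bed_end}")
            symbol = fields[3]
            start, end = bed_start + 1, bed_end  # half-open 0-based -> closed 1-based
            key = (symbol, chrom)
            if key in spans:
                spans[key][0] = min(spans[key][0], start)
                spans[key][1] = max(spans[key][1], end)
            else:
                spans[key] = [start, end]
                order.append(key)
    return [
        GeneRegion(gene_symbol=sym, chrom=chrom, start=spans[(sym, chrom)][0], end=spans[(sym, chrom)][1])
        for sym, chrom in order
    ]


def write_gene_track(regions: Iterable[GeneRegion], path: str | Path) -> None:
    """Write regions as BED4 (inverse of the read-side coordinate shift)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_symbol}\n")


def read_cnv_map(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a population CNV map: BED with the CNV type in column 4.

    Returns (chrom, start, end, cnv_type) tuples in internal coordinates.
    """
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path.name}:{lineno}: CNV map needs chrom,start,end,type")
            if fields[3] not in (DELETION, DUPLICATION):
                raise ValueError(f"{path.name}:{lineno}: invalid CNV type {fields[3]!r}")
            out.append((normalise_chrom(fields[0]), int(fields[1]) + 1, int(fields[2]), fields[3]))
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV (mandatory header) into the cohort DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
    return coerce_subject_frame(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["affected"] = out["affected"].astype(int)
    out["aj"] = out["aj"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_qc_metrics(path: str | Path) -> list[SampleQcMetrics]:
    """Read per-sample QC metrics from TSV with a mandatory header."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "lrr_sd", "baf_drift", "waviness_factor",
                "lrr_outlier_rate", "baf_sd", "n_cnvs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"QC metrics table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        for fieldname in required[1:]:
            v = getattr(row, fieldname)
            if pd.isna(v):
                raise ValueError(f"sample {row.sample_id}: missing QC metric {fieldname}")
        out.append(
            SampleQcMetrics(
                sample_id=row.sample_id,
                lrr_sd=float(row.lrr_sd),
                baf_drift=float(row.baf_drift),
                waviness_factor=float(row.waviness_factor),
                lrr_outlier_rate=float(row.lrr_outlier_rate),
                baf_sd=float(row.baf_sd),
                n_cnvs=int(row.n_cnvs),
            )
        )
    return out


def write_qc_metrics(metrics: Iterable[SampleQcMetrics], path: str | Path) -> None:
    pd.DataFrame([m.__dict__ for m in metrics]).to_csv(path, sep="\t", index=False)


def read_incidence(path: str | Path) -> IncidenceTable:
    """Read an incidence table from YAML with keys ``age_breaks`` and ``hazard``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "age_breaks" not in doc or "hazard" not in doc:
        raise ValueError("incidence YAML must contain 'age_breaks' and 'hazard'")
    return IncidenceTable(doc["age_breaks"], doc["hazard"])


def write_incidence(tbl: IncidenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"age_breaks": [float(x) for x in tbl.age_breaks],
             "hazard": [float(x) for x in tbl.hazard]},
            fh,
        )


RESULT_COLUMNS = ["region", "type", "group", "n_cnv", "U", "V", "p", "HR", "CI_low", "CI_high", "pass"]


def write_results(results: Iterable[AssocResult], path: str | Path) -> None:
    rows = [
        {
            "region": r.region_id, "type": r.cnv_type, "group": r.gene_group,
            "n_cnv": r.n_carriers_with_cnv, "U": r.score_u, "V": r.variance_v,
            "p": r.p_value, "HR": r.hr, "CI_low": r.ci_low, "CI_high": r.ci_high,
            "pass": int(r.threshold_passed),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    return df


def cumulative_hazard(tbl: IncidenceTable, t: float) -> float:
    """Lambda0(t) for a piecewise-constant incidence table (module-level alias)."""
    return tbl.cumulative_hazard(t)
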