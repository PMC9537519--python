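"""Sample QC, call filtering, PennCNV-style merging and gene-centric genotypes.

The processing order mirrors the upstream calling workflow: exclude
QC-failing samples, drop calls supported by fewer than five probes,
merge neighbouring same-type calls separated by a small gap, scan the
surviving calls against a gene track, and flag deletion/duplication
conflicts within a gene region.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneRegion,
    GenotypeMatrix,
    SampleQcMetrics,
)


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs. Comparison strictness follows the stated criteria
    verbatim: strict ``>`` for lrr_sd_max, baf_drift, waviness and LRR
    outliers; non-strict ``>=`` for baf_sd and the hard LRR-sd cap.
    Both LRR-sd cutoffs are applied; the stricter one dominates."""

    lrr_sd_max: float = 0.28
    baf_drift_max: float = 0.01
    waviness_abs_max: float = 0.05
    lrr_outlier_max: float = 0.1
    baf_sd_max: float = 0.2
    lrr_sd_hard_max: float = 0.4
    max_cnvs_per_sample: int = 100
    min_probes_per_call: int = 5
    merge_gap_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.merge_gap_fraction < 1:
            raise ValueError("merge_gap_fraction must lie in (0, 1)")
        for name in ("lrr_sd_max", "baf_drift_max", "waviness_abs_max",
                     "lrr_outlier_max", "baf_sd_max", "lrr_sd_hard_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_samples(
    metrics: list[SampleQcMetrics], thr: QcThresholds = QcThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Apply per-sample QC; a sample is excluded iff any criterion is breached.

    Returns the kept sample ids (input order) and an exclusion report
    listing every breached criterion per excluded sample.
    """
    kept: list[str] = []
    report_rows: list[dict] = []
    for m in metrics:
        reasons = []
        if m.lrr_sd > thr.lrr_sd_max:
            reasons.append("lrr_sd")
        if m.baf_drift > thr.baf_drift_max:
            reasons.append("baf_drift")
        if abs(m.waviness_factor) > thr.waviness_abs_max:
            reasons.append("waviness")
        if m.lrr_outlier_rate > thr.lrr_outlier_max:
            reasons.append("lrr_outliers")
        if m.baf_sd >= thr.baf_sd_max:
            reasons.append("baf_sd")
        if m.lrr_sd >= thr.lrr_sd_hard_max:
            reasons.append("lrr_sd_hard")
        if m.n_cnvs > thr.max_cnvs_per_sample:
            reasons.append("max_cnvs")
        if reasons:
            report_rows.append({"sample_id": m.sample_id, "reasons": ",".join(reasons)})
        else:
            kept.append(m.sample_id)
    report = pd.DataFrame(report_rows, columns=["sample_id", "reasons"])
    return kept, report


def filter_calls(calls: list[CnvCall], thr: QcThresholds = QcThresholds()) -> list[CnvCall]:
    """Retain only calls supported by ``min_probes_per_call`` or more probes."""
    return [c for c in calls if c.n_probes >= thr.min_probes_per_call]


def _merge_run(run: list[CnvCall], fraction: float) -> list[CnvCall]:
    """One left-to-right merging pass over same (sample, chrom, type) calls."""
    out: list[CnvCall] = []
    cur = run[0]
    for nxt in run[1:]:
        gap = nxt.start - cur.end - 1
        span = max(nxt.end, cur.end) - cur.start + 1
        if gap / span < fraction:
            cur = CnvCall(
                sample_id=cur.sample_id,
                chrom=cur.chrom,
                start=cur.start,
                end=max(cur.end, nxt.end),
                cnv_type=cur.cnv_type,
                n_probes=cur.n_probes + nxt.n_probes,
                copy_number=cur.copy_number if cur.copy_number == nxt.copy_number else None,
            )
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def merge_adjacent(calls: list[CnvCall], fraction: float = 0.2) -> list[CnvCall]:
    """Merge neighbouring same-type calls with a small intervening gap.

    Two neighbours merge when ``gap / span < fraction`` with
    ``gap = next.start - prev.end - 1`` (bases strictly between them;
    negative when they overlap) and ``span`` the merged extent
    ``end - start + 1``. Probe counts add. Passes repeat until a fixed
    point, so a merge can enable further merges.
    """
    groups: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls:
        groups[(c.sample_id, c.chrom, c.cnv_type)].append(c)
    merged: list[CnvCall] = []
    for key in sorted(groups):
        run = sorted(groups[key], key=lambda c: (c.start, c.end))
        while True:
            new = _merge_run(run, fraction)
            if len(new) == len(run):
                run = new
                break
            run = new
        merged.extend(run)
    return merged


def _region_tree(regions: list[GeneRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, r in enumerate(regions):
        # closed 1-based [start, end] -> half-open tree interval [start, end+1)
        trees[r.chrom].addi(r.start, r.end + 1, j)
    return trees


def overlap_genes(
    calls: list[CnvCall],
    regions: list[GeneRegion],
    exclude_symbols: set[str] | None = None,
    sample_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Gene-centric genotype scan: indicator = 1 iff a call of that type
    overlaps the gene region by one or more base pairs.

    ``exclude_symbols`` drops hypervariable gene families (HLA,
    immunoglobulin superfamily, olfactory receptors, ...) supplied as a
    symbol list. ``sample_ids`` fixes the matrix rows (defaults to the
    samples present in ``calls``). Interval-indexed, so the scan is
    O((N + M) log(N + M)) rather than all-pairs.
    """
    exclude = exclude_symbols or set()
    kept_regions = [
        r for r in regions if not r.excluded_hypervariable and r.gene_symbol not in exclude
    ]
    if sample_ids is None:
        sample_ids = sorted({c.sample_id for c in calls})
    gm = GenotypeMatrix(sample_ids, kept_regions)
    trees = _region_tree(kept_regions)
    sample_index = gm._sample_index
    for c in calls:
        if c.sample_id not in sample_index:
            continue
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        mat = gm.deletion if c.cnv_type == DELETION else gm.duplication
        i = sample_index[c.sample_id]
        for iv in tree.overlap(c.start, c.end + 1):
            mat[i, iv.data] = True
    return gm


def flag_conflicts(matrix: GenotypeMatrix, calls: list[CnvCall]) -> GenotypeMatrix:
    """Flag (subject, region) pairs with a non-overlapping deletion and
    duplication both hitting the region.

    The pair is excluded when any deletion/duplication pair overlapping
    the region does not mutually overlap; a deletion and duplication that
    overlap each other (a plausible complex rearrangement or boundary
    artefact of a single event) are not treated as a conflict.
    Modifies ``matrix.excluded`` in place and returns the matrix.
    """
    trees = _region_tree(matrix.regions)
    hits: dict[tuple[int, int], dict[str, list[CnvCall]]] = defaultdict(lambda: {DELETION: [], DUPLICATION: []})
    for c in calls:
        if c.sample_id not in matrix._sample_index:
            continue
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        i = matrix._sample_index[c.sample_id]
        for iv in tree.overlap(c.start, c.end + 1):
            hits[(i, iv.data)][c.cnv_type].append(c)
    for (i, j), by_type in hits.items():
        dels, dups = by_type[DELETION], by_type[DUPLICATION]
        if not dels or not dups:
            continue
        conflict = any(
            not (d.start <= p.end and p.start <= d.end) for d in dels for p in dups
        )
        if conflict:
            matrix.excluded[i, j] = True
    return matrix


def unique_cnvs(calls: list[CnvCall]) -> list[CnvCall]:
    """Collapse calls shared across samples to distinct (chrom, start, end, type)."""
    seen: dict[tuple, CnvCall] = {}
    for c in calls:
        key = (c.chrom, c.start, c.end, c.cnv_type)
        if key not in seen:
            seen[key] = c
    return list(seen.values())


def map_support(
    cnvs: list[CnvCall],
    cnv_map: list[tuple[str, int, int, str]],
    regions: list[GeneRegion],
) -> dict[str, float]:
    """Fraction of unique CNVs per gene region represented in a CNV map.

    A CNV is "represented" iff it overlaps a same-type map interval by at
    least one base pair. Regions whose CNV list is empty are reported as
    missing (absent from the result), since the proportion is undefined.
    """
    uniq = unique_cnvs(cnvs)
    map_trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end, cnv_type in cnv_map:
        map_trees[(chrom, cnv_type)].addi(start, end + 1)
    supported = [
        bool(map_trees.get((c.chrom, c.cnv_type), IntervalTree()).overlap(c.start, c.end + 1))
        for c in uniq
    ]
    region_trees = _region_tree(regions)
    totals = np.zeros(len(regions), dtype=int)
    hits = np.zeros(len(regions), dtype=int)
    for c, sup in zip(uniq, supported):
        tree = region_trees.get(c.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(c.start, c.end + 1):
            totals[iv.data] += 1
            hits[iv.data] += sup
    return {
        r.region_id: hits[j] / totals[j]
        for j, r in enumerate(regions)
        if totals[j] > 0
    }


def run_pipeline(
    calls: list[CnvCall],
    metrics: list[SampleQcMetrics],
    regions: list[GeneRegion],
    thr: QcThresholds = QcThresholds(),
    exclude_symbols: set[str] | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """QC -> probe filter -> merge -> gene scan -> conflict flags.

    Returns the genotype matrix (rows: QC-passing samples, or the
    QC-passing subset of ``sample_ids``) and the QC exclusion report.
    """
    kept, report = filter_samples(metrics, thr)
    kept_set = set(kept)
    calls = [c for c in calls if c.sample_id in kept_set]
    calls = filter_calls(calls, thr)
    calls = merge_adjacent(calls, thr.merge_gap_fraction)
    if sample_ids is not None:
        sample_ids = [s for s in sample_ids if s in kept_set]
    else:
        sample_ids = kept
    gm = overlap_genes(calls, regions, exclude_symbols, sample_ids=sample_ids)
    flag_conflicts(gm, calls)
    return gm, report
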