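"""Synthetic carrier-family cohorts and noisy CNV call sets with known truth.

The generator emulates the statistical structure every downstream stage
assumes: family-clustered carriers with Mendelian CNV genotypes, age at
breast cancer onset under a proportional-hazards modifier of a
piecewise-constant baseline incidence, independent censoring plus a
competing-event clock (ovarian cancer / prophylactic mastectomy),
clinic-style ascertainment through affected probands, and probe-backed
CNV calls with type-specific detection sensitivity and false calls.

Families are sibships: two unobserved parents draw CNV alleles at the
population frequency and transmit them Mendelianly, which induces the
within-family genotype correlation that the family-clustered variance
estimators downstream must absorb. Multi-generation pedigrees are not
modelled; family clusters are what the analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ARRAYS,
    BIRTH_COHORTS,
    CNV_TYPES,
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneRegion,
    GenotypeMatrix,
    IncidenceTable,
    SampleQcMetrics,
    coerce_subject_frame,
    default_brca1_incidence,
)

# Clinically known BRCA CNV loci (GRCh37) used for the diagnostic truth set.
BRCA_LOCI = {
    "BRCA1": ("17", 41196312, 41277500),
    "BRCA2": ("13", 32889611, 32973805),
}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ``cnv_frequency`` and ``true_log_hr`` may be scalars (shared by every
    region) or per-region sequences. ``family_size_probs`` are the
    probabilities of sibship sizes 1-4. ``target_subjects`` truncates the
    retained cohort at whole-family boundaries once that many subjects
    have been collected.
    """

    n_families: int = 500
    family_size_probs: Sequence[float] = (0.35, 0.35, 0.20, 0.10)
    n_regions: int = 10
    cnv_frequency: float | Sequence[float] = 0.05
    true_log_hr: float | Sequence[float] = 0.0
    region_cnv_type: Sequence[str] | None = None  # default alternates deletion/duplication
    incidence: IncidenceTable = field(default_factory=default_brca1_incidence)
    censor_age_range: tuple[float, float] = (25.0, 80.0)
    competing_event_rate: float = 0.005  # per-year ovarian cancer / mastectomy hazard
    ascertainment: str = "random"  # "random", "proband_affected" or "clinic"
    proband_fraction: float = 0.75  # under "clinic": share of families requiring an affected proband
    gene_group: str = "BRCA1"
    countries: Sequence[str] = ("UK", "US", "AUS")
    aj_fraction: float = 0.1
    mutation_type_probs: Sequence[float] = (0.85, 0.10, 0.05)  # other, deletion, duplication
    mutation_type_log_hr: dict = field(default_factory=lambda: {DELETION: 0.0, DUPLICATION: 0.0})
    detection_sensitivity: dict = field(default_factory=lambda: {DELETION: 0.9, DUPLICATION: 0.75})
    false_call_rate: dict = field(default_factory=lambda: {DELETION: 0.3, DUPLICATION: 0.6})
    probe_density: float = 0.17  # probes per kb, OncoArray-like genome-wide average
    breakpoint_jitter: int = 0  # bp; array breakpoints are probe-quantised, default exact
    qc_fail_fraction: float = 0.02
    cnv_flank: int = 20_000  # true CNVs extend past the gene by up to this many bp
    min_age: float = 18.0  # recruitment eligibility
    target_subjects: int | None = None
    generate_truth_intervals: bool = True
    seed: int = 0

    def frequencies(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.cnv_frequency, dtype=float), (self.n_regions,)).copy()
        if np.any((f <= 0) | (f >= 0.5)):
            raise ValueError("cnv_frequency must lie in (0, 0.5)")
        return f

    def log_hrs(self) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.true_log_hr, dtype=float), (self.n_regions,)).copy()
        if not np.all(np.isfinite(b)):
            raise ValueError("true_log_hr must be finite")
        return b

    def region_types(self) -> list[str]:
        if self.region_cnv_type is None:
            return [CNV_TYPES[i % 2] for i in range(self.n_regions)]
        types = list(self.region_cnv_type)
        if len(types) != self.n_regions or any(t not in CNV_TYPES for t in types):
            raise ValueError("region_cnv_type must give a valid type per region")
        return types


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated cohort.

    ``genotype`` holds the true per-subject, per-region carrier indicator;
    each region has a single CNV type (``region_types``). ``true_cnvs``
    are the underlying genomic intervals (including the diagnostic BRCA
    CNVs); ``call_supported`` is filled by :func:`simulate_calls` with a
    supported/unsupported label per emitted call.
    """

    sample_ids: list[str]
    regions: list[GeneRegion]
    region_types: list[str]
    genotype: np.ndarray  # bool, subjects x regions
    true_cnvs: list[CnvCall]
    diagnostic_cnvs: list[CnvCall]
    call_supported: list[bool] | None = None

    def to_genotype_matrix(self) -> GenotypeMatrix:
        gm = GenotypeMatrix(self.sample_ids, self.regions)
        for j, t in enumerate(self.region_types):
            mat = gm.deletion if t == DELETION else gm.duplication
            mat[:, j] = self.genotype[:, j]
        return gm


def make_regions(n_regions: int, seed: int = 0) -> list[GeneRegion]:
    """Synthetic gene regions spread over the autosomes, 20-200 kb long."""
    rng = np.random.default_rng([seed, 7])
    regions = []
    for i in range(n_regions):
        chrom = str((i % 22) + 1)
        start = 5_000_000 + (i // 22) * 3_000_000 + int(rng.integers(0, 500_000))
        length = int(rng.integers(20_000, 200_000))
        regions.append(GeneRegion(f"GENE{i:04d}", chrom, start, start + length - 1))
    return regions


def sample_onset_age(cum_hazard, beta: float, g: int, u: float) -> float:
    """Invert the proportional-hazards model for one subject.

    Solves ``Lambda0(t) * exp(beta * g) = -log(u)`` for t by piecewise-linear
    inversion of the cumulative hazard; returns ``inf`` (never affected
    within the table's age span) when the drawn total hazard exceeds the
    lifetime cumulative hazard.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie strictly in (0, 1)")
    tbl = cum_hazard if isinstance(cum_hazard, IncidenceTable) else None
    if tbl is None:
        raise TypeError("cum_hazard must be an IncidenceTable")
    target = -np.log(u) * np.exp(-beta * g)
    return tbl.inverse_cumulative_hazard(target)


def simulate_cohort(cfg: SimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Generate an ascertained carrier cohort with its ground truth.

    Returns the phenotype DataFrame (one row per retained subject, the
    canonical cohort container) and the matching :class:`TruthSet`.
    Identical configs (including seed) give byte-identical output.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    probs = np.asarray(cfg.family_size_probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1) > 1e-9 or np.any(probs < 0):
        raise ValueError("family_size_probs must be 4 probabilities summing to 1")
    freqs = cfg.frequencies()
    betas = cfg.log_hrs()
    region_types = cfg.region_types()
    regions = make_regions(cfg.n_regions, cfg.seed)
    tbl = cfg.incidence
    lo, hi = cfg.censor_age_range
    if not (0 <= lo < hi <= tbl.max_age):
        raise ValueError("censor_age_range must lie within the incidence table span")

    n_fam = cfg.n_families
    sizes = rng.choice(np.arange(1, 5), size=n_fam, p=probs)
    fam_of = np.repeat(np.arange(n_fam), sizes)
    n_sub = fam_of.size

    # Mendelian genotypes: carrier status is a dominant allele with
    # frequency q such that the carrier frequency is p = 1 - (1-q)^2.
    q = 1.0 - np.sqrt(1.0 - freqs)  # per region
    parent_alleles = rng.random((n_fam, 4, cfg.n_regions)) < q  # father x2, mother x2
    pick_f = rng.integers(0, 2, size=(n_sub, cfg.n_regions))
    pick_m = rng.integers(2, 4, size=(n_sub, cfg.n_regions))
    cols = np.arange(cfg.n_regions)
    allele_f = parent_alleles[fam_of[:, None], pick_f, cols]
    allele_m = parent_alleles[fam_of[:, None], pick_m, cols]
    genotype = allele_f | allele_m  # subjects x regions

    # clinically diagnosed BRCA variant class, shared within a family
    mt_codes_fam = rng.choice(3, size=n_fam, p=np.asarray(cfg.mutation_type_probs, dtype=float))
    mt_codes = mt_codes_fam[fam_of]
    mt_labels = np.array(["other", DELETION, DUPLICATION])
    mt_log_hr = np.array([0.0,
                          cfg.mutation_type_log_hr.get(DELETION, 0.0),
                          cfg.mutation_type_log_hr.get(DUPLICATION, 0.0)])

    eta = genotype.astype(float) @ betas + mt_log_hr[mt_codes]
    u = rng.uniform(size=n_sub)
    u = np.clip(u, np.finfo(float).tiny, 1 - 1e-16)
    onset = tbl.inverse_cumulative_hazard(-np.log(u) * np.exp(-eta))
    censor = rng.uniform(lo, hi, size=n_sub)
    if cfg.competing_event_rate > 0:
        competing = rng.exponential(1.0 / cfg.competing_event_rate, size=n_sub)
    else:
        competing = np.full(n_sub, np.inf)
    censor_all = np.minimum(censor, competing)
    affected = onset <= censor_all
    age_end = np.where(affected, onset, censor_all)
    age_end = np.minimum(age_end, tbl.max_age)

    # covariates
    country_fam = rng.choice(np.asarray(cfg.countries), size=n_fam)
    aj_fam = rng.random(n_fam) < cfg.aj_fraction
    birth_cohort = rng.choice(np.asarray(BIRTH_COHORTS), size=n_sub)
    array = rng.choice(np.asarray(ARRAYS), size=n_sub)

    # recruitment eligibility: subjects reaching age 18 before their end age
    keep = age_end >= cfg.min_age
    if cfg.ascertainment in ("proband_affected", "clinic"):
        # proband = first-listed eligible member of each family
        first_idx = np.full(n_fam, n_sub)
        order = np.flatnonzero(keep)
        np.minimum.at(first_idx, fam_of[order], order)
        fam_retained = np.zeros(n_fam, dtype=bool)
        valid = first_idx < n_sub
        fam_retained[valid] = affected[first_idx[valid]]
        if cfg.ascertainment == "clinic":
            # clinic-style recruitment: a share of families enters through an
            # affected proband, the remainder through cascade carrier testing
            # irrespective of phenotype
            cascade = rng.random(n_fam) >= cfg.proband_fraction
            fam_retained |= cascade
        keep &= fam_retained[fam_of]
    elif cfg.ascertainment != "random":
        raise ValueError(f"unknown ascertainment mode {cfg.ascertainment!r}")

    if cfg.target_subjects is not None:
        kept_cum = np.cumsum(keep)
        # truncate at whole-family boundaries once target is reached
        fam_last = np.zeros(n_fam, dtype=np.int64)
        np.maximum.at(fam_last, fam_of, np.arange(n_sub))
        fam_total = kept_cum[fam_last]  # kept subjects up to end of each family
        fams_in = fam_total <= cfg.target_subjects
        if kept_cum[-1] < cfg.target_subjects:
            raise ValueError(
                f"only {kept_cum[-1]} subjects retained; increase n_families"
            )
        keep &= fams_in[fam_of]

    if not keep.any():
        raise ValueError("zero families retained; increase n_families")

    idx = np.flatnonzero(keep)
    fam_sel = fam_of[idx]
    sample_ids = [f"F{f:05d}_S{k}" for f, k in zip(fam_sel, idx)]
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "family_id": [f"F{f:05d}" for f in fam_sel],
            "gene_group": cfg.gene_group,
            "affected": affected[idx],
            "age_end": age_end[idx],
            "country": country_fam[fam_sel],
            "aj": aj_fam[fam_sel],
            "birth_cohort": birth_cohort[idx],
            "array": array[idx],
            "mutation_type": mt_labels[mt_codes[idx]],
        }
    )
    df = coerce_subject_frame(df)

    geno_kept = genotype[idx]
    true_cnvs: list[CnvCall] = []
    diagnostic: list[CnvCall] = []
    if cfg.generate_truth_intervals:
        starts = np.array([r.start for r in regions])
        ends = np.array([r.end for r in regions])
        sub_j, reg_j = np.nonzero(geno_kept)
        fl = rng.integers(0, cfg.cnv_flank + 1, size=sub_j.size)
        fr = rng.integers(0, cfg.cnv_flank + 1, size=sub_j.size)
        for s, j, a, b in zip(sub_j, reg_j, fl, fr):
            true_cnvs.append(
                CnvCall(
                    sample_id=sample_ids[s],
                    chrom=regions[j].chrom,
                    start=max(1, int(starts[j] - a)),
                    end=int(ends[j] + b),
                    cnv_type=region_types[j],
                    n_probes=1,  # placeholder; probe support is drawn at call time
                )
            )
        chrom, bstart, bend = BRCA_LOCI[cfg.gene_group]
        for s in np.flatnonzero(mt_codes[idx] > 0):
            diagnostic.append(
                CnvCall(
                    sample_id=sample_ids[s],
                    chrom=chrom,
                    start=bstart,
                    end=bend,
                    cnv_type=mt_labels[mt_codes[idx][s]],
                    n_probes=1,
                )
            )
    truth = TruthSet(
        sample_ids=sample_ids,
        regions=regions,
        region_types=region_types,
        genotype=geno_kept,
        true_cnvs=true_cnvs,
        diagnostic_cnvs=diagnostic,
    )
    return df, truth


def simulate_calls(truth: TruthSet, cfg: SimConfig) -> tuple[list[CnvCall], list[SampleQcMetrics]]:
    """Emulate array-based CNV calling over a truth set.

    Each true CNV (gene-region CNVs and diagnostic BRCA CNVs) is emitted
    with the type-specific detection sensitivity; its probe count is drawn
    as Poisson(probe_density x length), minimum one probe. False calls are
    added per genome at the configured per-type rate with random placement.
    QC metrics mimic clean arrays except for a configured fraction of
    failing samples, which draw an LRR standard deviation above 0.28.

    Fills ``truth.call_supported`` and returns (calls, per-sample metrics).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    calls: list[CnvCall] = []
    supported: list[bool] = []

    def n_probes_for(length: int) -> int:
        return max(1, int(rng.poisson(cfg.probe_density * length / 1000.0)))

    for cnv in list(truth.true_cnvs) + list(truth.diagnostic_cnvs):
        if rng.random() >= cfg.detection_sensitivity[cnv.cnv_type]:
            continue
        start, end = cnv.start, cnv.end
        if cfg.breakpoint_jitter > 0:
            j = cfg.breakpoint_jitter
            start = max(1, start + int(rng.integers(-j, j + 1)))
            end = max(start, end + int(rng.integers(-j, j + 1)))
        calls.append(
            CnvCall(
                sample_id=cnv.sample_id,
                chrom=cnv.chrom,
                start=start,
                end=end,
                cnv_type=cnv.cnv_type,
                n_probes=n_probes_for(end - start + 1),
                copy_number=1 if cnv.cnv_type == DELETION else 3,
            )
        )
        supported.append(True)

    for sample in truth.sample_ids:
        for cnv_type in CNV_TYPES:
            rate = cfg.false_call_rate.get(cnv_type, 0.0)
            for _ in range(rng.poisson(rate) if rate > 0 else 0):
                chrom = str(int(rng.integers(1, 23)))
                length = int(rng.integers(10_000, 100_000))
                start = int(rng.integers(1_000_000, 100_000_000))
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        chrom=chrom,
                        start=start,
                        end=start + length - 1,
                        cnv_type=cnv_type,
                        n_probes=n_probes_for(length),
                        copy_number=1 if cnv_type == DELETION else 3,
                    )
                )
                supported.append(False)

    truth.call_supported = supported

    counts = {s: 0 for s in truth.sample_ids}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    n = len(truth.sample_ids)
    qc_fail = rng.random(n) < cfg.qc_fail_fraction
    lrr_sd = np.abs(rng.normal(0.12, 0.04, size=n)).clip(0.01, 0.27)
    lrr_sd[qc_fail] = rng.uniform(0.29, 0.45, size=int(qc_fail.sum()))
    metrics = [
        SampleQcMetrics(
            sample_id=s,
            lrr_sd=float(lrr_sd[i]),
            baf_drift=float(rng.uniform(0.0, 0.008)),
            waviness_factor=float(np.clip(rng.normal(0.0, 0.015), -0.049, 0.049)),
            lrr_outlier_rate=float(rng.uniform(0.0, 0.05)),
            baf_sd=float(rng.uniform(0.05, 0.15)),
            n_cnvs=counts[s],
        )
        for i, s in enumerate(truth.sample_ids)
    ]
    return calls, metrics
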