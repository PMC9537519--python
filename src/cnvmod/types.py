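"""Core domain types for the CNV modifier analysis.

Coordinate convention: all genomic intervals are 1-based and closed on
both ends (the PennCNV convention, since CNV calls originate there).
BED input/output converts at the boundary.

Chromosomes are restricted to autosomes 1-22 and chromosome X; the Y
chromosome is not analysed and Y records are rejected at parse time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X",)

DELETION = "deletion"
DUPLICATION = "duplication"
CNV_TYPES = (DELETION, DUPLICATION)

GENE_GROUPS = ("BRCA1", "BRCA2")
BIRTH_COHORTS = ("<1920", "1920-29", "1930-39", "1940-49", ">=1950")
ARRAYS = ("iCOGS", "OncoArray")
MUTATION_TYPES = ("other", "deletion", "duplication")


def normalise_chrom(chrom: str) -> str:
    """Map a chromosome label onto the internal '1'..'22', 'X' vocabulary.

    Strips a leading ``chr`` prefix and maps the numeric alias 23 to X.
    Raises ``ValueError`` for chromosome Y or anything unrecognised.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    if c in ("Y", "24", "y"):
        raise ValueError(f"chromosome Y is excluded from analysis (got {chrom!r})")
    if c not in VALID_CHROMS:
        raise ValueError(f"unrecognised chromosome label {chrom!r}")
    return c


@dataclass(frozen=True)
class CnvCall:
    """One called deletion or duplication interval in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    n_probes: int
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"CNV call start {self.start} > end {self.end} for {self.sample_id}"
            )
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}")
        if self.copy_number is not None:
            if not 0 <= self.copy_number <= 4:
                raise ValueError("copy_number must be in 0..4 when known")
            if self.copy_number <= 1 and self.cnv_type != DELETION:
                raise ValueError("copy_number <= 1 implies a deletion")
            if self.copy_number >= 3 and self.cnv_type != DUPLICATION:
                raise ValueError("copy_number >= 3 implies a duplication")
            if self.copy_number == 2:
                raise ValueError("neutral copy number (cn=2) is not a CNV")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "CnvCall | GeneRegion") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class SampleQcMetrics:
    """Per-sample array quality metrics used for cohort-level QC."""

    sample_id: str
    lrr_sd: float
    baf_drift: float
    waviness_factor: float
    lrr_outlier_rate: float
    baf_sd: float
    n_cnvs: int

    def __post_init__(self) -> None:
        for name in ("lrr_sd", "baf_drift", "lrr_outlier_rate", "baf_sd"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValueError(f"metric {name} for sample {self.sample_id} must be a finite non-negative number")
        if self.waviness_factor is None or not np.isfinite(self.waviness_factor):
            raise ValueError(f"metric waviness_factor for sample {self.sample_id} missing or non-finite")
        if self.n_cnvs < 0:
            raise ValueError("n_cnvs must be non-negative")


@dataclass(frozen=True)
class GeneRegion:
    """A gene-centric genomic region (1-based closed coordinates)."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    excluded_hypervariable: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene region start {self.start} > end {self.end} ({self.gene_symbol})")

    @property
    def region_id(self) -> str:
        return f"{self.gene_symbol}@{self.chrom}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class IncidenceTable:
    """Piecewise-constant age-specific incidence lambda0(t).

    Parameters
    ----------
    age_breaks
        Increasing ages (years) starting at 0, length k+1.
    hazard
        Per-interval incidence (events / person-year), length k.

    The cumulative hazard Lambda0(t) is the exact integral of the step
    function: piecewise linear, non-decreasing, Lambda0(0) = 0.
    """

    def __init__(self, age_breaks: Sequence[float], hazard: Sequence[float]):
        breaks = np.asarray(age_breaks, dtype=float)
        haz = np.asarray(hazard, dtype=float)
        if breaks.ndim != 1 or haz.ndim != 1 or len(breaks) != len(haz) + 1:
            raise ValueError("age_breaks must have one more entry than hazard")
        if breaks[0] != 0:
            raise ValueError("age_breaks must start at 0")
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("age_breaks must be strictly increasing")
        if np.any(haz < 0) or not np.all(np.isfinite(haz)):
            raise ValueError("hazard values must be finite and >= 0")
        self.age_breaks = breaks
        self.hazard = haz
        # cumulative hazard evaluated at each break
        self._cum_at_breaks = np.concatenate([[0.0], np.cumsum(haz * np.diff(breaks))])

    @property
    def max_age(self) -> float:
        return float(self.age_breaks[-1])

    @property
    def total_cumulative_hazard(self) -> float:
        return float(self._cum_at_breaks[-1])

    def cumulative_hazard(self, t):
        """Lambda0(t), exact piecewise-linear interpolation. No extrapolation."""
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0) or np.any(arr > self.max_age):
            raise ValueError(
                f"age outside incidence table range [0, {self.max_age}]"
            )
        out = np.interp(arr, self.age_breaks, self._cum_at_breaks)
        return float(out) if np.isscalar(t) else out

    def inverse_cumulative_hazard(self, h):
        """Smallest t with Lambda0(t) = h; +inf where h exceeds the lifetime total."""
        arr = np.atleast_1d(np.asarray(h, dtype=float))
        if np.any(arr < 0):
            raise ValueError("cumulative hazard must be >= 0")
        out = np.full(arr.shape, np.inf)
        within = arr <= self._cum_at_breaks[-1]
        idx = np.searchsorted(self._cum_at_breaks, arr[within], side="right") - 1
        idx = np.clip(idx, 0, len(self.hazard) - 1)
        lam = self.hazard[idx]
        base = self.age_breaks[idx]
        dh = arr[within] - self._cum_at_breaks[idx]
        t = np.where(lam > 0, base + np.divide(dh, lam, out=np.zeros_like(dh), where=lam > 0), base)
        out[within] = t
        return float(out[0]) if np.isscalar(h) else out

    def cumulative_distribution(self, t):
        """F(t) = 1 - exp(-Lambda0(t)): probability of onset by age t."""
        return 1.0 - np.exp(-self.cumulative_hazard(t))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IncidenceTable)
            and np.array_equal(self.age_breaks, other.age_breaks)
            and np.array_equal(self.hazard, other.hazard)
        )

    def __repr__(self) -> str:
        return f"IncidenceTable({len(self.hazard)} bands, max age {self.max_age:g})"


def default_brca1_incidence() -> IncidenceTable:
    """A BRCA1-carrier-style breast cancer incidence curve in 5-year bands.

    Shaped so cumulative risk to age 80 is roughly 70%, consistent with
    published carrier penetrance estimates. These values are configuration
    defaults for simulation and weighting, not epidemiological claims.
    """
    breaks = np.arange(0.0, 85.0, 5.0)
    hazard = np.array(
        [0.0, 0.0, 0.0, 0.0,       # 0-20
         0.001, 0.004, 0.011, 0.021,  # 20-40
         0.030, 0.031, 0.030, 0.027,  # 40-60
         0.026, 0.025, 0.023, 0.021]  # 60-80
    )
    return IncidenceTable(breaks, hazard)


@dataclass(frozen=True)
class SubjectRecord:
    """Phenotype record for one pathogenic-variant carrier.

    ``age_end`` is the age at first breast cancer diagnosis for affected
    subjects, otherwise the censoring age (ovarian cancer, bilateral
    prophylactic mastectomy or last observation, whichever came first).
    """

    sample_id: str
    family_id: str
    gene_group: str
    affected: bool
    age_end: float
    country: str
    aj: bool
    birth_cohort: str
    array: str
    mutation_type: str = "other"

    def __post_init__(self) -> None:
        if self.gene_group not in GENE_GROUPS:
            raise ValueError(f"gene_group must be one of {GENE_GROUPS}")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"mutation_type must be one of {MUTATION_TYPES}")
        if not np.isfinite(self.age_end) or self.age_end < 0:
            raise ValueError("age_end must be a finite non-negative age")


SUBJECT_COLUMNS = [
    "sample_id", "family_id", "gene_group", "affected", "age_end",
    "country", "aj", "birth_cohort", "array", "mutation_type",
]


def subjects_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Assemble SubjectRecords into the canonical cohort DataFrame."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=SUBJECT_COLUMNS)
    return coerce_subject_frame(df)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    return [SubjectRecord(**row) for row in df[SUBJECT_COLUMNS].to_dict("records")]


def coerce_subject_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a cohort phenotype DataFrame in place."""
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["family_id"] = df["family_id"].astype(str)
    df["affected"] = df["affected"].astype(bool)
    df["aj"] = df["aj"].astype(bool)
    df["age_end"] = df["age_end"].astype(float)
    for col, allowed in [("gene_group", GENE_GROUPS), ("birth_cohort", BIRTH_COHORTS),
                         ("array", ARRAYS), ("mutation_type", MUTATION_TYPES)]:
        df[col] = df[col].astype(str)
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    return df


class GenotypeMatrix:
    """Subject x gene-region x {deletion, duplication} indicator matrix.

    Backed by dense boolean arrays (cohorts here are thousands of subjects
    by thousands of regions at most). A (subject, region) pair flagged in
    ``excluded`` carries a non-overlapping deletion/duplication conflict
    and contributes to no test for that region.
    """

    def __init__(self, sample_ids: Sequence[str], regions: Sequence[GeneRegion]):
        self.sample_ids = list(sample_ids)
        self.regions = list(regions)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._region_index = {r.region_id: j for j, r in enumerate(self.regions)}
        n, m = len(self.sample_ids), len(self.regions)
        self.deletion = np.zeros((n, m), dtype=bool)
        self.duplication = np.zeros((n, m), dtype=bool)
        self.excluded = np.zeros((n, m), dtype=bool)

    def _matrix(self, cnv_type: str) -> np.ndarray:
        if cnv_type == DELETION:
            return self.deletion
        if cnv_type == DUPLICATION:
            return self.duplication
        raise ValueError(f"unknown cnv_type {cnv_type!r}")

    def set_indicator(self, sample_id: str, region_id: str, cnv_type: str) -> None:
        self._matrix(cnv_type)[self._sample_index[sample_id], self._region_index[region_id]] = True

    def genotypes(self, region_id: str, cnv_type: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """0/1 genotype vector for a region; NaN marks conflict-excluded subjects."""
        j = self._region_index[region_id]
        mat = self._matrix(cnv_type)
        rows = (
            np.arange(len(self.sample_ids))
            if sample_ids is None
            else np.array([self._sample_index[s] for s in sample_ids])
        )
        g = mat[rows, j].astype(float)
        g[self.excluded[rows, j]] = np.nan
        return g

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def n_carriers(self, region_id: str, cnv_type: str) -> int:
        j = self._region_index[region_id]
        return int((self._matrix(cnv_type)[:, j] & ~self.excluded[:, j]).sum())

    def regions_with_carriers(self, cnv_type: str) -> list[str]:
        """Region ids with at least one non-excluded carrier of the type
        (the denominator of the effective-test threshold)."""
        mat = self._matrix(cnv_type) & ~self.excluded
        keep = mat.any(axis=0)
        return [r.region_id for r, k in zip(self.regions, keep) if k]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and [r.region_id for r in self.regions] == [r.region_id for r in other.regions]
            and np.array_equal(self.deletion, other.deletion)
            and np.array_equal(self.duplication, other.duplication)
            and np.array_equal(self.excluded, other.excluded)
        )


@dataclass
class AssocResult:
    """Per-region association result (score test or weighted Cox model)."""

    region_id: str
    cnv_type: str
    gene_group: str
    n_carriers_with_cnv: int
    score_u: float
    variance_v: float
    p_value: float
    hr: float
    ci_low: float
    ci_high: float
    threshold_passed: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.hr):
            if not (self.ci_low <= self.hr <= self.ci_high):
                raise ValueError("confidence interval must bracket the hazard ratio")
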