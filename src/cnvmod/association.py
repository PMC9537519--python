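"""Association engines for carrier cohorts sampled through clinics.

Two complementary models, both built for cohorts ascertained non-randomly
with respect to disease status:

1. A score test based on the retrospective likelihood of observing the
   CNV genotype conditional on the observed phenotype, which removes the
   ascertainment bias because the phenotype is conditioned on rather than
   modelled. Under the proportional-hazards model
   ``lambda_i(t) = lambda0(t) * exp(beta * g_i)`` with stratum-specific
   genotype frequency p_s as nuisance, the per-subject score at beta = 0 is

       u_i = (g_i - p_s) * (delta_i - Lambda0(t_i)),

   i.e. genotype residual times martingale residual. The statistic
   U^2 / V with family-cluster-robust V = sum over families of
   (sum of u_i within the family)^2 is compared with chi-square(1).
   A one-step estimator beta_hat = U / I with model information
   I = sum p_s (1 - p_s) (delta_i - Lambda0(t_i))^2 yields an
   approximate hazard ratio and confidence interval.

2. A weighted-cohort Cox model in which affected and unaffected subjects
   are reweighted within age bands so the sample's affected fraction
   matches that expected under the population carrier incidence; fitted
   with age as the time scale, stratified baselines, covariate adjustment,
   and a family-clustered sandwich variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    DELETION,
    DUPLICATION,
    AssocResult,
    IncidenceTable,
    default_brca1_incidence,
)

Z95 = 1.959963984540054


@dataclass
class RetroTestSpec:
    """Configuration for the retrospective-likelihood score test."""

    incidence: IncidenceTable = field(default_factory=default_brca1_incidence)
    strata_cols: Sequence[str] = ("country", "aj")
    cluster_col: str = "family_id"
    min_carriers: int = 2
    min_stratum_carriers: int = 2  # strata with fewer carriers pool into a residual stratum


@dataclass
class WeightedCohortSpec:
    """Configuration for the weighted-cohort hazard model."""

    incidence: IncidenceTable = field(default_factory=default_brca1_incidence)
    age_band_edges: np.ndarray = field(
        default_factory=lambda: np.concatenate([[18.0], np.arange(25.0, 85.0, 5.0)])
    )
    covariates: Sequence[str] = ("birth_cohort", "array")
    strata_cols: Sequence[str] = ("country", "aj")
    cluster_col: str = "family_id"

    def __post_init__(self) -> None:
        edges = np.asarray(self.age_band_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("age_band_edges must be increasing with >= 2 entries")
        self.age_band_edges = edges


def _stratum_codes(subjects: pd.DataFrame, strata_cols: Sequence[str]) -> np.ndarray:
    """Integer stratum code per subject from the cross of the strata columns."""
    if not strata_cols:
        return np.zeros(len(subjects), dtype=np.int64)
    key = subjects[strata_cols[0]].astype(str)
    for c in strata_cols[1:]:
        key = key + "\x1f" + subjects[c].astype(str)
    return pd.factorize(key, sort=True)[0]


def retro_score_test(
    g: np.ndarray,
    subjects: pd.DataFrame,
    spec: RetroTestSpec = RetroTestSpec(),
    region_id: str = "",
    cnv_type: str = DELETION,
) -> AssocResult:
    """Ascertainment-corrected score test for one gene region.

    ``g`` is the 0/1 carrier vector aligned with ``subjects``; entries of
    NaN (conflict-excluded subjects) are dropped together with their
    subject rows. Raises ``ValueError`` when fewer than
    ``spec.min_carriers`` carriers remain. A genotype that is monomorphic
    within every stratum gives U = 0, p = 1 and an undefined (NaN) hazard
    ratio.
    """
    g = np.asarray(g, dtype=float)
    if g.shape[0] != len(subjects):
        raise ValueError("genotype vector and subject table are misaligned")
    subjects = subjects.reset_index(drop=True)
    mask = ~np.isnan(g)
    g = g[mask]
    sub = subjects.loc[mask] if not mask.all() else subjects
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("genotypes must be 0/1 (NaN allowed for exclusions)")
    n_carriers = int(g.sum())
    if n_carriers < spec.min_carriers:
        raise ValueError(
            f"{n_carriers} carriers < minimum {spec.min_carriers} required for testing"
        )

    lam = spec.incidence.cumulative_hazard(sub["age_end"].to_numpy())
    delta = sub["affected"].to_numpy(dtype=float)
    resid = delta - lam

    strata = _stratum_codes(sub, spec.strata_cols)
    # pool sparse strata (fewer than min_stratum_carriers carriers) to
    # avoid degenerate centering
    carrier_per_stratum = np.bincount(strata, weights=g)
    sparse = carrier_per_stratum[strata] < spec.min_stratum_carriers
    strata = np.where(sparse, -1, strata)
    strata = pd.factorize(strata, sort=True)[0]

    n_strata = strata.max() + 1
    stratum_n = np.bincount(strata, minlength=n_strata)
    p_s = np.bincount(strata, weights=g, minlength=n_strata) / stratum_n
    p_i = p_s[strata]

    # Efficient (profile) score: centre the martingale residual within
    # stratum. The score sum U is unchanged (the centring term cancels
    # against the estimated stratum frequency), but under clinic-style
    # ascertainment the residuals have a large positive mean, and without
    # centring the cluster-robust variance grossly overstates Var(U).
    resid_c = resid - (np.bincount(strata, weights=resid, minlength=n_strata) / stratum_n)[strata]
    u = (g - p_i) * resid_c
    score_u = float(u.sum())
    fam = pd.factorize(sub[spec.cluster_col], sort=True)[0]
    fam_sums = np.bincount(fam, weights=u)
    variance_v = float((fam_sums**2).sum())
    info = float((p_i * (1 - p_i) * resid_c**2).sum())

    monomorphic = np.all((p_s == 0) | (p_s == 1))
    if monomorphic or variance_v <= 0 or info <= 0:
        return AssocResult(
            region_id=region_id, cnv_type=cnv_type,
            gene_group=str(sub["gene_group"].iloc[0]) if len(sub) else "",
            n_carriers_with_cnv=n_carriers, score_u=0.0, variance_v=variance_v,
            p_value=1.0, hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        )

    chi2 = score_u**2 / variance_v
    p_value = float(stats.chi2.sf(chi2, df=1))
    beta = score_u / info
    se = np.sqrt(variance_v) / info
    return AssocResult(
        region_id=region_id,
        cnv_type=cnv_type,
        gene_group=str(sub["gene_group"].iloc[0]),
        n_carriers_with_cnv=n_carriers,
        score_u=score_u,
        variance_v=variance_v,
        p_value=p_value,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
    )


def retro_loglik(
    beta: float,
    g: np.ndarray,
    delta: np.ndarray,
    lam: np.ndarray,
    p: float,
) -> float:
    """Full retrospective log-likelihood sum_i log P(g_i | delta_i, t_i).

    With P(delta, t | g) proportional to
    ``lambda0(t)^delta * exp(delta * beta * g) * exp(-Lambda0(t) e^{beta g})``
    and P(g) = p^g (1-p)^(1-g); the lambda0(t)^delta factor cancels in the
    conditional. Exposed for validation of the one-step estimator against
    a brute-force maximiser.
    """
    g = np.asarray(g, dtype=float)
    log_num1 = np.log(p) + delta * beta - lam * np.exp(beta)  # g = 1
    log_num0 = np.log1p(-p) - lam  # g = 0
    log_den = np.logaddexp(log_num1, log_num0)
    return float(np.sum(np.where(g == 1, log_num1, log_num0) - log_den))


def retro_mle_grid(
    g: np.ndarray,
    delta: np.ndarray,
    lam: np.ndarray,
    beta_grid: np.ndarray | None = None,
) -> float:
    """Grid-search maximiser of the retrospective likelihood over beta,
    profiling the genotype-frequency nuisance p on an inner grid."""
    if beta_grid is None:
        beta_grid = np.linspace(-2.0, 2.0, 801)
    p_grid = np.linspace(0.01, 0.99, 197)
    best_beta, best_ll = 0.0, -np.inf
    for b in beta_grid:
        ll = max(retro_loglik(b, g, delta, lam, p) for p in p_grid)
        if ll > best_ll:
            best_ll, best_beta = ll, float(b)
    return best_beta


def compute_weights(subjects: pd.DataFrame, spec: WeightedCohortSpec) -> np.ndarray:
    """Weights that make each age band's affected fraction match expectation.

    Subjects are banded by their end-of-follow-up age. The expected
    affected proportion per band comes from the population incidence
    combined with the censoring-age distribution reconstructed from the
    unaffected subjects (see :func:`_expected_affected_proportion`); with
    observed proportion f_a, affected subjects receive weight
    expected/f_a and unaffected (1-expected)/(1-f_a), so the weighted
    affected fraction equals the expected one exactly. Bands with f_a of
    0 or 1 get unit weights with a warning; empty bands are skipped.
    """
    edges = spec.age_band_edges
    n_bands = len(edges) - 1
    ages = subjects["age_end"].to_numpy(dtype=float)
    affected = subjects["affected"].to_numpy(dtype=bool)
    band = np.digitize(np.clip(ages, edges[0], edges[-1] - 1e-9), edges) - 1
    band = np.clip(band, 0, n_bands - 1)

    expected = _expected_affected_proportion(
        spec.incidence, edges,
        np.bincount(band[~affected], minlength=n_bands).astype(float),
    )
    weights = np.ones(len(subjects))
    for a in range(n_bands):
        in_band = band == a
        n = int(in_band.sum())
        if n == 0:
            continue
        f = float(affected[in_band].mean())
        if f in (0.0, 1.0):
            warnings.warn(
                f"age band [{edges[a]:g}, {edges[a + 1]:g}) has observed affected "
                f"fraction {f:g}; unit weights used", stacklevel=2,
            )
            continue
        if not np.isfinite(expected[a]):
            continue
        weights[in_band & affected] = expected[a] / f
        weights[in_band & ~affected] = (1 - expected[a]) / (1 - f)
    return weights


def _expected_affected_proportion(
    incidence: IncidenceTable, edges: np.ndarray, n_unaffected_per_band: np.ndarray
) -> np.ndarray:
    """Population proportion affected among carriers ending follow-up in each band.

    The proportion affected among subjects whose follow-up *ends* in an age
    band depends on the end-of-follow-up (censoring) age distribution, not
    only on the penetrance F. Unaffected subjects are recruited with a
    probability that does not depend on their own phenotype timing, so the
    censoring-age distribution is recoverable from the observed unaffected
    band counts u_a: the population censoring mass in band a is
    g_a proportional to u_a / (1 - F(mid_a)). The expected affected mass in
    band a is then dF_a * S_c(mid_a) (onsets in the band among those still
    under observation) and the expected unaffected mass g_a (1 - F(mid_a)),
    which reproduces the observed composition exactly under random sampling.
    """
    f_edge = 1.0 - np.exp(-incidence.cumulative_hazard(np.clip(edges, 0, incidence.max_age)))
    d_f = np.diff(f_edge)
    f_mid = 0.5 * (f_edge[:-1] + f_edge[1:])
    surv_mid = 1.0 - f_mid
    with np.errstate(divide="ignore", invalid="ignore"):
        g_raw = np.where(surv_mid > 0, n_unaffected_per_band / surv_mid, 0.0)
    if g_raw.sum() <= 0:
        return np.full(len(d_f), np.nan)
    g = g_raw / g_raw.sum()
    censor_surv = np.concatenate([np.cumsum(g[::-1])[::-1], [0.0]])  # at band starts
    censor_surv_mid = np.clip(censor_surv[:-1] - g / 2, 0.0, None)
    affected_mass = d_f * censor_surv_mid
    unaffected_mass = g * surv_mid
    total = affected_mass + unaffected_mass
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, affected_mass / total, np.nan)


EXPOSURE_CODINGS = ("del_vs_other", "dup_vs_other_excl_del", "three_level")


def weighted_cohort_fit(
    subjects: pd.DataFrame,
    exposure_coding: str = "three_level",
    weights: np.ndarray | None = None,
    spec: WeightedCohortSpec = WeightedCohortSpec(),
) -> list[AssocResult]:
    """Weighted Cox model of breast cancer risk by pathogenic-variant class.

    Age is the time scale; the baseline hazard is stratified by the cross
    of ``spec.strata_cols``; birth cohort and genotyping array enter as
    fixed effects; the sandwich variance clusters on families. Exposure
    codings (reference = "other" pathogenic variants):

    * ``del_vs_other``: deletions vs other, duplications retained as a
      third level; the deletion contrast is reported.
    * ``dup_vs_other_excl_del``: duplications vs other with deletion
      carriers excluded from the data.
    * ``three_level``: deletion and duplication contrasts reported.

    Returns one :class:`AssocResult` per reported non-reference level.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if exposure_coding not in EXPOSURE_CODINGS:
        raise ValueError(f"exposure_coding must be one of {EXPOSURE_CODINGS}")
    df = subjects.reset_index(drop=True).copy()
    if weights is None:
        weights = compute_weights(df, spec)
    df["_w"] = np.asarray(weights, dtype=float)
    if exposure_coding == "dup_vs_other_excl_del":
        keep = df["mutation_type"] != DELETION
        df = df.loc[keep].reset_index(drop=True)
        report_levels = [DUPLICATION]
    elif exposure_coding == "del_vs_other":
        report_levels = [DELETION]
    else:
        report_levels = [DELETION, DUPLICATION]

    present = [lv for lv in (DELETION, DUPLICATION) if (df["mutation_type"] == lv).any()]
    for lv in report_levels:
        if lv not in present:
            raise ValueError(f"no {lv} carriers present for exposure coding {exposure_coding}")
    for lv in present:
        df[f"mt_{lv}"] = (df["mutation_type"] == lv).astype(float)
    exposure_cols = [f"mt_{lv}" for lv in present]

    covar_cols: list[str] = []
    for cov in spec.covariates:
        dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True, dtype=float)
        covar_cols.extend(dummies.columns)
        df = pd.concat([df, dummies], axis=1)
    # drop constant covariate columns (a level absent from this cohort)
    covar_cols = [c for c in covar_cols if df[c].nunique() > 1]

    strata = _stratum_codes(df, spec.strata_cols)
    df["_stratum"] = strata
    events_per_stratum = df.groupby("_stratum")["affected"].sum()
    dead_strata = events_per_stratum[events_per_stratum == 0].index
    if len(dead_strata) > 0:
        warnings.warn(
            f"dropping {len(dead_strata)} stratum/strata with no events", stacklevel=2
        )
        df = df.loc[~df["_stratum"].isin(dead_strata)].reset_index(drop=True)

    model_df = df[
        ["age_end", "affected", "_w", "_stratum", spec.cluster_col]
        + exposure_cols + covar_cols
    ].copy()
    model_df["affected"] = model_df["affected"].astype(int)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                model_df,
                duration_col="age_end",
                event_col="affected",
                weights_col="_w",
                cluster_col=spec.cluster_col,
                strata=["_stratum"],
                robust=True,
            )
    except ConvergenceError as err:
        raise RuntimeError(f"weighted Cox model failed to converge: {err}") from err

    summary = cph.summary
    results = []
    gene_group = str(df["gene_group"].iloc[0])
    for lv in report_levels:
        row = summary.loc[f"mt_{lv}"]
        results.append(
            AssocResult(
                region_id=f"mutation_type:{lv}",
                cnv_type=lv,
                gene_group=gene_group,
                n_carriers_with_cnv=int((df["mutation_type"] == lv).sum()),
                score_u=float(row["coef"]),
                variance_v=float(row["se(coef)"] ** 2),
                p_value=float(row["p"]),
                hr=float(np.exp(row["coef"])),
                ci_low=float(np.exp(row["coef"] - Z95 * row["se(coef)"])),
                ci_high=float(np.exp(row["coef"] + Z95 * row["se(coef)"])),
            )
        )
    return results


@dataclass(frozen=True)
class TestThreshold:
    """Bonferroni threshold over the effective number of tests."""

    n_tests: int
    exact: float
    display: float  # rounded to one significant figure, as printed


def effective_test_threshold(n_regions_tested: int, alpha: float = 0.05) -> TestThreshold:
    """alpha / n over the regions actually testable (>= 1 overlapping CNV).

    The display value rounds to one significant figure.
    """
    if n_regions_tested < 1:
        raise ValueError("at least one tested region is required")
    exact = alpha / n_regions_tested
    display = float(f"{exact:.0e}")
    return TestThreshold(n_tests=n_regions_tested, exact=exact, display=display)


def genome_wide_scan(
    matrix,
    subjects: pd.DataFrame,
    cnv_type: str,
    spec: RetroTestSpec = RetroTestSpec(),
    alpha: float = 0.05,
) -> tuple[list[AssocResult], TestThreshold]:
    """Score-test every region with enough carriers; flag threshold passers.

    The effective-test denominator counts regions with at least one
    overlapping CNV of the requested type, as in the threshold definition;
    regions below ``spec.min_carriers`` are counted but not tested.
    """
    sample_ids = subjects["sample_id"].tolist()
    testable = matrix.regions_with_carriers(cnv_type)
    if not testable:
        raise ValueError(f"no regions with {cnv_type} carriers")
    thr = effective_test_threshold(len(testable), alpha)
    results = []
    for rid in testable:
        g = matrix.genotypes(rid, cnv_type, sample_ids)
        if np.nansum(g) < spec.min_carriers:
            continue
        res = retro_score_test(g, subjects, spec, region_id=rid, cnv_type=cnv_type)
        res.threshold_passed = bool(res.p_value <= thr.exact)
        results.append(res)
    return results, thr
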