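"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cnvmod as cm
from cnvmod.types import DELETION, DUPLICATION, CnvCall, GeneRegion, GenotypeMatrix


def brute_force_overlap(calls, regions, sample_ids) -> GenotypeMatrix:
    """Quadratic all-pairs genotype matrix, independent of the interval index."""
    gm = GenotypeMatrix(sample_ids, regions)
    for c in calls:
        if c.sample_id not in gm._sample_index:
            continue
        for j, r in enumerate(regions):
            if c.chrom == r.chrom and c.start <= r.end and r.start <= c.end:
                mat = gm.deletion if c.cnv_type == DELETION else gm.duplication
                mat[gm._sample_index[c.sample_id], j] = True
    return gm


def brute_force_match(calls, truth) -> list[bool]:
    """Quadratic all-pairs supported labels."""
    out = []
    for c in calls:
        out.append(
            any(
                t.chrom == c.chrom
                and t.cnv_type == c.cnv_type
                and t.start <= c.end
                and c.start <= t.end
                for t in truth
            )
        )
    return out


def random_instance(rng, n_calls=40, n_regions=15, n_samples=8):
    """A random overlap-test instance on a couple of chromosomes."""
    chroms = ["1", "2"]
    calls = []
    for _ in range(n_calls):
        start = int(rng.integers(1, 500_000))
        calls.append(
            CnvCall(
                sample_id=f"S{rng.integers(n_samples)}",
                chrom=chroms[rng.integers(2)],
                start=start,
                end=start + int(rng.integers(1, 80_000)),
                cnv_type=DELETION if rng.random() < 0.5 else DUPLICATION,
                n_probes=int(rng.integers(1, 40)),
            )
        )
    regions = []
    for j in range(n_regions):
        start = int(rng.integers(1, 500_000))
        regions.append(
            GeneRegion(f"G{j}", chroms[int(rng.integers(2))], start, start + int(rng.integers(1, 60_000)))
        )
    samples = sorted({c.sample_id for c in calls})
    return calls, regions, samples


def make_subject_frame(g, delta, ages, one_per_family=False) -> pd.DataFrame:
    """Minimal single-stratum cohort frame for score-test unit tests."""
    n = len(g)
    fam = [f"F{i}" for i in range(n)] if one_per_family else [f"F{i // 2}" for i in range(n)]
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "family_id": fam,
            "gene_group": "BRCA1",
            "affected": np.asarray(delta, dtype=bool),
            "age_end": np.asarray(ages, dtype=float),
            "country": "UK",
            "aj": False,
            "birth_cohort": "1940-49",
            "array": "OncoArray",
            "mutation_type": "other",
        }
    )
    return cm.coerce_subject_frame(df)


# Frozen 20-subject fixtures for the one-step-vs-MLE agreement check.
# Each row: (carrier genotype, affected, age at diagnosis/censoring).
ONE_STEP_FIXTURES = {
    "risk_increasing": (
        [(1, 1, 42)] * 3 + [(1, 1, 52)] * 2 + [(1, 0, 55)] * 3 + [(1, 0, 65)] * 2
        + [(0, 1, 48)] * 3 + [(0, 1, 58)] * 1 + [(0, 0, 60)] * 4 + [(0, 0, 70)] * 2
    ),
    "null": (
        [(1, 1, 45)] * 3 + [(1, 0, 60)] * 7 + [(0, 1, 45)] * 3 + [(0, 0, 60)] * 7
    ),
    "protective": (
        [(1, 1, 55)] * 2 + [(1, 0, 60)] * 8 + [(0, 1, 47)] * 4 + [(0, 0, 58)] * 6
    ),
}


@pytest.fixture(scope="session")
def incidence():
    return cm.default_brca1_incidence()


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Small cohort with perfect calling (identity between truth and calls)."""
    return cm.SimConfig(
        n_families=150,
        n_regions=12,
        cnv_frequency=0.08,
        seed=42,
        detection_sensitivity={DELETION: 1.0, DUPLICATION: 1.0},
        false_call_rate={DELETION: 0.0, DUPLICATION: 0.0},
        probe_density=2.0,
        qc_fail_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_cfg):
    subjects, truth = cm.simulate_cohort(noiseless_cfg)
    calls, metrics = cm.simulate_calls(truth, noiseless_cfg)
    return subjects, truth, calls, metrics
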