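"""Shared fixtures: random pedigrees, a small single-step instance, and one
session-scoped standard simulated study used by the slower end-to-end tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from ssgblup import (
    GenotypeMatrix,
    MarkerScaling,
    RegularizationSpec,
    SimConfig,
    allele_frequencies,
    a_submatrix,
    build_genomic_factor,
    make_pedigree,
)
from ssgblup.workflow import run_study


def random_pedigree(rng: np.random.Generator, n: int, founders: int = 6):
    """Random valid pedigree: first ``founders`` animals are founders, later
    animals draw parents among strictly earlier ones (possibly unknown)."""
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(founders, n):
        if rng.random() < 0.9:
            sire[i] = rng.integers(1, i + 1)
        if rng.random() < 0.9:
            dam[i] = rng.integers(1, i + 1)
        if sire[i] == dam[i] != 0:  # avoid selfing for realism
            dam[i] = 0
    return make_pedigree(sire, dam)


@dataclass
class SmallInstance:
    """A desk-scale single-step problem with every ingredient assembled."""

    ped: object
    gcodes: np.ndarray
    counts: np.ndarray
    p: np.ndarray
    w: float
    reg: RegularizationSpec
    scaling: MarkerScaling
    factor: object
    phenotypes: pd.DataFrame
    lambda_: float


def make_small_instance(seed: int, n: int = 35, n_g: int = 14, m: int = 10,
                        w: float = 0.2, n_rec: int = 60,
                        reg_kind: str = "w_agg",
                        with_T: bool = True) -> SmallInstance:
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n)
    gcodes = np.sort(rng.choice(np.arange(n // 3, n + 1), size=n_g,
                                replace=False))
    counts = rng.integers(0, 3, size=(n_g, m)).astype(np.int8)
    # guard against monomorphic columns in tiny draws
    counts[0] = 1
    counts[1] = np.where(counts[1] == 1, 0, counts[1])
    p = allele_frequencies(counts)
    if reg_kind == "w_agg":
        reg = RegularizationSpec.w_agg(w, a_submatrix(ped, gcodes))
        scaling = MarkerScaling.vanraden(p, w=w)
    else:
        reg = RegularizationSpec.epsilon_identity(0.5)
        scaling = MarkerScaling.vanraden(p, w=0.0)
    factor = build_genomic_factor(counts, scaling, reg, with_T=with_T)
    phen = pd.DataFrame(
        {
            "animal": [str(a) for a in rng.integers(1, n + 1, size=n_rec)],
            "herd": rng.choice(["h1", "h2", "h3"], size=n_rec),
            "y": rng.standard_normal(n_rec) + 5.0,
        }
    )
    return SmallInstance(ped=ped, gcodes=gcodes, counts=counts, p=p, w=w,
                         reg=reg, scaling=scaling, factor=factor,
                         phenotypes=phen, lambda_=7.0 / 3.0)


@pytest.fixture
def small_instance() -> SmallInstance:
    return make_small_instance(seed=11)


@pytest.fixture(scope="session")
def standard_study():
    """The standard simulated study solved end to end (seed 1): full and
    reduced breeding-value solves plus the marker-equation solve."""
    return run_study(SimConfig(seed=1), tol=1e-7)


@pytest.fixture(scope="session")
def mini_study():
    """A faster end-to-end study for tests that only need structure."""
    return run_study(SimConfig(seed=5, n_founders=100, n_generations=5,
                               m_markers=200), tol=1e-7)


def geno_from_counts(counts: np.ndarray) -> GenotypeMatrix:
    counts = np.asarray(counts, dtype=np.int8)
    return GenotypeMatrix(
        counts=counts,
        animal_ids=[f"a{i + 1}" for i in range(counts.shape[0])],
        marker_ids=[f"m{j + 1}" for j in range(counts.shape[1])],
        allele_freq=allele_frequencies(counts),
    )
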