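"""Synthetic breeding population with the structure single-step assumes.

The generator produces a multi-generation pedigree with discrete,
non-overlapping generations; gene-dropped unlinked biallelic markers; true
breeding values split into a marker part Z a (proportion 1 - w of the
additive variance) and a pedigree-correlated residual polygenic part d
(proportion w); phenotypes with a chosen narrow-sense heritability on all
non-candidate animals from the third generation on; and partial genotyping
of the phenotyped generations.  The final generation are the genotyped
selection candidates: no phenotype records, no progeny.

A designated half of the founders carries a mean shift of
``jfactor_shift`` genetic standard deviations in its residual polygenic
values.  The shift propagates to descendants through the parent-average
recursion, which installs a mean difference between the pedigree base and
the genotyped (late-generation) animals — exactly the base difference the
J-factor covariate must absorb in the evaluations.

The full genotype set contains every genotyped animal including the
candidates; the reduced set removes exactly the candidates, mirroring an
evaluation run before the candidates were genotyped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, allele_frequencies, write_plink
from .pedigree import Pedigree, make_pedigree, write_pedigree


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic population.

    Defaults give ~3,000 animals over 6 generations with ~1,550 genotyped
    animals of which the ~500 final-generation animals are selection
    candidates, heritability 0.3 and an RPG proportion w = 0.20.
    """

    n_founders: int = 500
    n_generations: int = 6
    offspring_per_mating: int = 2
    m_markers: int = 1000
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    h2: float = 0.3
    w: float = 0.2
    sigma_u2: float = 1.0
    genotyping_rate_parents: float = 0.7
    jfactor_shift: float = 0.3
    phenotype_mean: float = 10.0
    first_phenotyped_generation: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if not 0.0 < self.w < 1.0:
            raise ValueError("w must be in (0, 1)")
        if not 0.0 <= self.genotyping_rate_parents <= 1.0:
            raise ValueError("genotyping rate must be in [0, 1]")

    @property
    def sigma_e2(self) -> float:
        return self.sigma_u2 * (1.0 - self.h2) / self.h2

    @property
    def lambda_(self) -> float:
        return self.sigma_e2 / self.sigma_u2


@dataclass
class SimulatedStudy:
    """A simulated dataset plus the truth used to generate it."""

    config: SimConfig
    ped: Pedigree
    generation: np.ndarray
    haplo1: np.ndarray = field(repr=False)
    haplo2: np.ndarray = field(repr=False)
    founder_freq: np.ndarray
    true_a: np.ndarray
    true_d: np.ndarray
    true_u: np.ndarray
    phenotypes: pd.DataFrame
    genotyped_full: np.ndarray   # 1-based codes, ascending
    candidates: np.ndarray       # 1-based codes, ascending

    @property
    def counts(self) -> np.ndarray:
        return (self.haplo1 + self.haplo2).astype(np.int8)

    @property
    def genotyped_reduced(self) -> np.ndarray:
        return np.setdiff1d(self.genotyped_full, self.candidates)


def simulate_pedigree(config: SimConfig, rng: np.random.Generator):
    """Discrete-generation pedigree with random pairing of the previous
    generation; returns (Pedigree, generation index per animal)."""
    sires: list[int] = [0] * config.n_founders
    dams: list[int] = [0] * config.n_founders
    generation = [0] * config.n_founders
    prev = list(range(1, config.n_founders + 1))
    for gen in range(1, config.n_generations):
        order = rng.permutation(len(prev))
        half = len(prev) // 2
        pairs = [(prev[order[i]], prev[order[half + i]]) for i in range(half)]
        nxt = []
        for s, d in pairs:
            for _ in range(config.offspring_per_mating):
                sires.append(s)
                dams.append(d)
                generation.append(gen)
                nxt.append(len(sires))
        prev = nxt
    ped = make_pedigree(np.array(sires, dtype=np.int64),
                        np.array(dams, dtype=np.int64))
    return ped, np.array(generation, dtype=np.int64)


def simulate_genotypes(ped: Pedigree, config: SimConfig,
                       rng: np.random.Generator):
    """Gene-drop unlinked biallelic markers; returns (haplo1, haplo2, p0).

    Founder haplotype alleles are Bernoulli(p_i) with p_i drawn uniformly
    from ``founder_freq_range``; each descendant inherits one uniformly
    chosen allele per parent per marker (no linkage).
    """
    n, m = ped.n, config.m_markers
    lo, hi = config.founder_freq_range
    p0 = rng.uniform(lo, hi, size=m)
    h1 = np.zeros((n, m), dtype=np.uint8)
    h2 = np.zeros((n, m), dtype=np.uint8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == 0:
            h1[i] = rng.random(m) < p0
        else:
            pick = rng.random(m) < 0.5
            h1[i] = np.where(pick, h1[s - 1], h2[s - 1])
        if d == 0:
            h2[i] = rng.random(m) < p0
        else:
            pick = rng.random(m) < 0.5
            h2[i] = np.where(pick, h1[d - 1], h2[d - 1])
    return h1, h2, p0


def simulate_true_values(ped: Pedigree, counts: np.ndarray, p0: np.ndarray,
                         config: SimConfig, rng: np.random.Generator):
    """True marker effects, RPG deviations and breeding values.

    Marker effects a ~ N(0, (1-w) sigma_u^2 / k0) i.i.d. with
    k0 = 2 sum p0 (1 - p0) over the founder frequencies; the marker part is
    Z a with Z centred at the founder frequencies.  The RPG part d is
    gene-dropped infinitesimally: founders d ~ N(shift_i, w sigma_u^2) with
    shift_i = jfactor_shift * sigma_u for a designated half of the
    founders, descendants d = parent average + Mendelian sampling
    N(0, 0.5 w sigma_u^2 (1 - (F_s + F_d)/2)).
    """
    n = ped.n
    su2 = config.sigma_u2
    k0 = 2.0 * np.sum(p0 * (1.0 - p0))
    a = rng.normal(0.0, np.sqrt((1.0 - config.w) * su2 / k0),
                   size=config.m_markers)
    marker_part = counts.astype(float) @ a - 2.0 * (p0 @ a)
    f = ped.f
    d = np.zeros(n)
    founders = (ped.sire == 0) & (ped.dam == 0)
    designated = np.zeros(n, dtype=bool)
    founder_idx = np.nonzero(founders)[0]
    designated[founder_idx[: founder_idx.size // 2]] = True
    shift = config.jfactor_shift * np.sqrt(su2)
    for i in range(n):
        s, dd = ped.sire[i], ped.dam[i]
        if s == 0 and dd == 0:
            d[i] = rng.normal(shift if designated[i] else 0.0,
                              np.sqrt(config.w * su2))
        else:
            pa = 0.0
            fs = f[s - 1] if s else 0.0
            fd = f[dd - 1] if dd else 0.0
            if s:
                pa += 0.5 * d[s - 1]
            if dd:
                pa += 0.5 * d[dd - 1]
            ms_var = config.w * su2 * 0.5 * (1.0 - 0.5 * (fs + fd))
            d[i] = pa + rng.normal(0.0, np.sqrt(ms_var))
    return a, d, marker_part + d


def simulate_phenotypes(ped: Pedigree, generation: np.ndarray,
                        true_u: np.ndarray, candidates: np.ndarray,
                        config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """One record y = mu + u + e per non-candidate animal in the phenotyped
    generations; candidates get no records."""
    is_cand = np.zeros(ped.n + 1, dtype=bool)
    is_cand[candidates] = True
    rows = [i for i in range(ped.n)
            if generation[i] >= config.first_phenotyped_generation
            and not is_cand[i + 1]]
    rows = np.array(rows, dtype=np.int64)
    e = rng.normal(0.0, np.sqrt(config.sigma_e2), size=rows.size)
    return pd.DataFrame(
        {
            "animal": [ped.ids[i] for i in rows],
            "y": config.phenotype_mean + true_u[rows] + e,
        }
    )


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generator under ``config.seed`` (deterministic)."""
    rng = np.random.default_rng(config.seed)
    ped, generation = simulate_pedigree(config, rng)
    h1, h2, p0 = simulate_genotypes(ped, config, rng)
    counts = (h1 + h2).astype(np.int8)
    a, d, true_u = simulate_true_values(ped, counts, p0, config, rng)
    last_gen = config.n_generations - 1
    candidates = np.nonzero(generation == last_gen)[0] + 1
    phen = simulate_phenotypes(ped, generation, true_u, candidates, config, rng)
    non_cand = np.nonzero(
        (generation >= config.first_phenotyped_generation)
        & (generation < last_gen)
    )[0] + 1
    chosen = non_cand[rng.random(non_cand.size)
                      < config.genotyping_rate_parents]
    genotyped_full = np.union1d(chosen, candidates)
    return SimulatedStudy(
        config=config, ped=ped, generation=generation, haplo1=h1, haplo2=h2,
        founder_freq=p0, true_a=a, true_d=d, true_u=true_u, phenotypes=phen,
        genotyped_full=genotyped_full, candidates=candidates,
    )


def genotype_matrix(study: SimulatedStudy, which: str = "full"):
    """Observed genotypes for the full or reduced set.

    Returns ``(GenotypeMatrix, codes)``; allele frequencies are those
    observed in the selected set, so full and reduced centrings differ
    slightly, as they would in consecutive real evaluations.
    """
    if which == "full":
        codes = study.genotyped_full
    elif which == "reduced":
        codes = study.genotyped_reduced
    else:
        raise ValueError(f"unknown genotype set {which!r}")
    counts = study.counts[codes - 1]
    return (
        GenotypeMatrix(
            counts=counts,
            animal_ids=[study.ped.ids[c - 1] for c in codes],
            marker_ids=[f"snp{j + 1}" for j in range(counts.shape[1])],
            allele_freq=allele_frequencies(counts),
        ),
        codes,
    )


def candidate_counts(study: SimulatedStudy) -> np.ndarray:
    return study.counts[study.candidates - 1]


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write pedigree CSV, PLINK trios (full and reduced), phenotype CSV,
    truth TSV and a manifest JSON; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(study.ped, outdir / "pedigree.csv")
    study.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    for which in ("full", "reduced"):
        geno, _ = genotype_matrix(study, which)
        write_plink(geno, outdir / f"genotypes_{which}")
    truth = pd.DataFrame(
        {
            "animal": study.ped.ids,
            "generation": study.generation,
            "true_u": study.true_u,
            "true_d": study.true_d,
            "candidate": np.isin(np.arange(1, study.ped.n + 1),
                                 study.candidates).astype(int),
            "genotyped": np.isin(np.arange(1, study.ped.n + 1),
                                 study.genotyped_full).astype(int),
        }
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cfg = asdict(study.config)
    cfg["founder_freq_range"] = list(cfg["founder_freq_range"])
    manifest = {
        "config": cfg,
        "n_animals": int(study.ped.n),
        "n_genotyped_full": int(study.genotyped_full.size),
        "n_genotyped_reduced": int(study.genotyped_reduced.size),
        "n_candidates": int(study.candidates.size),
        "n_records": int(len(study.phenotypes)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
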