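"""Indirect GEBV prediction for genotyped selection candidates.

A selection candidate is a genotyped animal without own phenotype and
without progeny in the previous evaluation.  Its GEBV can be assembled from
that evaluation's solutions without re-solving the MME, using the
decomposition

    u_c = -1 mu_hat + Z_c g_hat + d_c,

where g_hat are the SNP-effect solutions (backsolved from the breeding
values when the evaluation used the breeding-value formulation), d_c is the
candidate's residual polygenic (RPG) effect, and mu_hat is the J-factor
solution (0 when no J-factor was fitted).

Four predictors are provided:

* ``PA``  — mean of parent GEBV (reference baseline);
* ``DGV`` — direct genomic value Z_c g_hat only;
* ``REG`` — -mu_hat + Z_c g_hat + d~_c with the RPG part approximated by a
  parent average that uses a linear regression of d_g on u_g for
  non-genotyped parents;
* ``GRV`` — -mu_hat + Z_c g_hat + d_c with the exact RPG part
  d_c = A_cg A_gg^-1 d_g.

The exact RPG part is computed without forming A_cg or A_gg^-1: a dense
Cholesky solve against A_gg followed by one Colleau pedigree product
(two-step variant), or equivalently a sparse solve for the non-genotyped
ancestors of the reference animals followed by parent-average propagation
down the candidates' pedigree (ancestor variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse.linalg as spla

from .genomics import GenomicFactor, z_times, zt_times
from .pedigree import Pedigree, a_times_vector, build_a_inverse, prune_to_ancestors

logger = logging.getLogger(__name__)

METHODS = ("PA", "DGV", "REG", "GRV")


@dataclass
class EvaluationSolutions:
    """Converged solutions of one single-step evaluation.

    ``u`` holds the raw additive-genetic solutions in pedigree order;
    ``gebv`` additionally includes the J-factor contribution
    (u_i + J_i mu_hat), which is the published breeding value.  SNP effects
    and genotyped-animal RPG effects are computed lazily on first access.
    """

    ped: Pedigree
    factor: GenomicFactor
    genotyped_codes: np.ndarray  # 1-based pedigree codes, genotype-row order
    u: np.ndarray
    fixed: np.ndarray
    fixed_labels: list[str]
    jfactor_mu: float = 0.0
    jfactor_covariate: np.ndarray | None = None
    marker_ids: list[str] | None = None
    _snp_effects: np.ndarray | None = field(default=None, repr=False)
    _rpg_genotyped: np.ndarray | None = field(default=None, repr=False)

    @property
    def gebv(self) -> np.ndarray:
        if self.jfactor_covariate is None or self.jfactor_mu == 0.0:
            return self.u
        return self.u + self.jfactor_covariate * self.jfactor_mu

    @property
    def u_g(self) -> np.ndarray:
        return self.u[self.genotyped_codes - 1]

    @property
    def snp_effects(self) -> np.ndarray:
        if self._snp_effects is None:
            self._snp_effects = backsolve_snp_effects(self.factor, self.u_g)
        return self._snp_effects

    @snp_effects.setter
    def snp_effects(self, value: np.ndarray) -> None:
        self._snp_effects = np.asarray(value, dtype=float)

    @property
    def rpg_genotyped(self) -> np.ndarray:
        if self._rpg_genotyped is None:
            self._rpg_genotyped = rpg_genotyped(self.u_g, self.factor,
                                                self.snp_effects)
        return self._rpg_genotyped


def backsolve_snp_effects(factor: GenomicFactor, u_g: np.ndarray) -> np.ndarray:
    """SNP effects from genotyped breeding values: g = K^-1 Z' C^-1 u_g.

    Two triangular solves against the cached Cholesky factor of K; equal to
    the dense identity g = B Z' G_C^-1 u_g.
    """
    u_g = np.asarray(u_g, dtype=float)
    if u_g.shape[0] != factor.n:
        raise ValueError("u_g length does not match the genotype matrix")
    return factor.k_solve(zt_times(factor.counts, factor.p,
                                   factor.reg.solve(u_g)))


def rpg_genotyped(u_g: np.ndarray, factor: GenomicFactor,
                  snp_effects: np.ndarray | None = None) -> np.ndarray:
    """RPG effects of the reference genotyped animals: d_g = u_g - Z g."""
    if snp_effects is None:
        snp_effects = backsolve_snp_effects(factor, u_g)
    return np.asarray(u_g, dtype=float) - z_times(factor.counts, factor.p,
                                                  snp_effects)


def rpg_candidates_exact(ped: Pedigree, genotyped_codes: np.ndarray,
                         candidate_codes: np.ndarray, d_g: np.ndarray,
                         agg_factor: np.ndarray) -> np.ndarray:
    """Exact candidate RPG d_c = A_cg A_gg^-1 d_g, two-step.

    Step 1: x = A_gg^-1 d_g by dense Cholesky solve.  Step 2: read d_c off
    the full pedigree product A (0, x, 0)' computed by Colleau's algorithm.
    """
    genotyped_codes = np.asarray(genotyped_codes, dtype=np.int64)
    candidate_codes = np.asarray(candidate_codes, dtype=np.int64)
    if np.intersect1d(genotyped_codes, candidate_codes).size:
        raise ValueError("candidates must be disjoint from the reference "
                         "genotyped set")
    if candidate_codes.size and candidate_codes.max() > ped.n:
        raise ValueError("candidate not in pedigree")
    x = la.cho_solve((agg_factor, True), np.asarray(d_g, dtype=float))
    padded = np.zeros(ped.n)
    padded[genotyped_codes - 1] = x
    full = a_times_vector(ped, padded)
    return full[candidate_codes - 1]


def rpg_candidates_ancestor(ped: Pedigree, genotyped_codes: np.ndarray,
                            candidate_codes: np.ndarray,
                            d_g: np.ndarray) -> np.ndarray:
    """Exact candidate RPG via the ancestor system plus parent averaging.

    Solves the sparse system A^{anc,anc} d_anc = -A^{anc,g} d_g on the
    pedigree pruned to the reference animals and their ancestors, then
    propagates parent averages from the oldest to the youngest animal for
    everyone else (unknown parents contribute 0).  Agrees with
    :func:`rpg_candidates_exact` to solver precision.
    """
    genotyped_codes = np.asarray(genotyped_codes, dtype=np.int64)
    candidate_codes = np.asarray(candidate_codes, dtype=np.int64)
    if np.intersect1d(genotyped_codes, candidate_codes).size:
        raise ValueError("candidates must be disjoint from the reference "
                         "genotyped set")
    pruned, old_codes = prune_to_ancestors(ped, genotyped_codes)
    pos_in_pruned = np.zeros(ped.n + 1, dtype=np.int64)  # 0 = absent
    pos_in_pruned[old_codes] = np.arange(1, old_codes.size + 1)
    g_local = pos_in_pruned[genotyped_codes] - 1
    anc_local = np.setdiff1d(np.arange(pruned.n), g_local)
    known = np.full(ped.n, False)
    values = np.zeros(ped.n)
    values[genotyped_codes - 1] = d_g
    known[genotyped_codes - 1] = True
    if anc_local.size:
        ainv = build_a_inverse(pruned).tocsc()
        a_oo = ainv[np.ix_(anc_local, anc_local)]
        a_og = ainv[np.ix_(anc_local, g_local)]
        d_anc = spla.spsolve(a_oo.tocsc(), -a_og @ np.asarray(d_g, dtype=float))
        d_anc = np.atleast_1d(d_anc)
        anc_codes = old_codes[anc_local]
        values[anc_codes - 1] = d_anc
        known[anc_codes - 1] = True
    for i in range(ped.n):  # topological order: parents already filled
        if known[i]:
            continue
        s, d = ped.sire[i], ped.dam[i]
        acc = 0.0
        if s:
            acc += values[s - 1]
        if d:
            acc += values[d - 1]
        values[i] = 0.5 * acc
    return values[candidate_codes - 1]


def rpg_regression(ped: Pedigree, solutions: EvaluationSolutions,
                   candidate_codes: np.ndarray):
    """Approximate candidate RPG by parent averaging with regressed values.

    Fits d_g = a + b u_g by ordinary least squares over the reference
    genotyped animals; non-genotyped parents contribute d~ = a + b u,
    genotyped parents their exact d_g, unknown parents 0.  Returns
    ``(d_c_approx, a_hat, b_hat)``.
    """
    candidate_codes = np.asarray(candidate_codes, dtype=np.int64)
    u_g = solutions.u_g
    d_g = solutions.rpg_genotyped
    if u_g.size < 2:
        raise ValueError("need at least 2 genotyped animals for the "
                         "regression approach")
    su = np.std(u_g)
    if su == 0.0:
        logger.warning("degenerate RPG regression (constant u_g); using "
                       "a = mean(d_g), b = 0")
        a_hat, b_hat = float(np.mean(d_g)), 0.0
    else:
        b_hat = float(np.cov(u_g, d_g, ddof=0)[0, 1] / np.var(u_g))
        a_hat = float(np.mean(d_g) - b_hat * np.mean(u_g))
    values = a_hat + b_hat * solutions.u
    values[solutions.genotyped_codes - 1] = d_g
    d_c = np.zeros(candidate_codes.size)
    for k, c in enumerate(candidate_codes):
        s, d = ped.sire[c - 1], ped.dam[c - 1]
        acc = 0.0
        if s:
            acc += values[s - 1]
        if d:
            acc += values[d - 1]
        d_c[k] = 0.5 * acc
    return d_c, a_hat, b_hat


@dataclass
class CandidateSet:
    """Genotyped selection candidates to be predicted indirectly.

    ``codes`` are 1-based codes in the evaluation pedigree; ``counts`` their
    allele counts on the evaluation's marker set.  Candidate genotypes are
    centred with the evaluation's allele frequencies (the scale on which the
    SNP effects were estimated).
    """

    codes: np.ndarray
    counts: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.counts.shape[0] != self.codes.size:
            raise ValueError("candidate genotype rows do not match codes")


def parent_status(ped: Pedigree, candidate_codes: np.ndarray,
                  genotyped_codes: np.ndarray) -> np.ndarray:
    """GG / NG / NN per candidate; an unknown parent counts as not genotyped."""
    genotyped = np.zeros(ped.n + 1, dtype=bool)
    genotyped[np.asarray(genotyped_codes, dtype=np.int64)] = True
    genotyped[0] = False
    out = []
    for c in np.asarray(candidate_codes, dtype=np.int64):
        k = int(genotyped[ped.sire[c - 1]]) + int(genotyped[ped.dam[c - 1]])
        out.append(("NN", "NG", "GG")[k])
    return np.array(out)


def predict(candidates: CandidateSet, solutions: EvaluationSolutions,
            method: str) -> pd.DataFrame:
    """Indirect GEBV for the candidates by one of PA, DGV, REG, GRV.

    Returns a table with the prediction and its additive components
    (direct genomic value, RPG part, J-factor part) plus the parent
    genotyping status.  GRV satisfies gebv = j + dgv + rpg exactly.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown indirect method {method!r}")
    ped = solutions.ped
    codes = candidates.codes
    n_c = codes.size
    status = parent_status(ped, codes, solutions.genotyped_codes)
    dgv = np.zeros(n_c)
    rpg = np.zeros(n_c)
    jterm = np.zeros(n_c)
    if method == "PA":
        gebv_all = solutions.gebv
        pred = np.zeros(n_c)
        for k, c in enumerate(codes):
            s, d = ped.sire[c - 1], ped.dam[c - 1]
            acc = 0.0
            if s:
                acc += gebv_all[s - 1]
            if d:
                acc += gebv_all[d - 1]
            pred[k] = 0.5 * acc
    else:
        g_hat = solutions.snp_effects
        dgv = z_times(candidates.counts, solutions.factor.p, g_hat)
        if method == "DGV":
            pred = dgv.copy()
        else:
            if solutions.factor.reg.kind != "w_agg":
                raise ValueError(f"{method} needs the residual-polygenic "
                                 "regularisation C = w A_gg")
            jterm = np.full(n_c, -solutions.jfactor_mu)
            if method == "REG":
                rpg, _, _ = rpg_regression(ped, solutions, codes)
            else:  # GRV
                rpg = rpg_candidates_exact(
                    ped, solutions.genotyped_codes, codes,
                    solutions.rpg_genotyped,
                    solutions.factor.reg.agg_factor,
                )
            pred = jterm + dgv + rpg
    return pd.DataFrame(
        {
            "candidate": candidates.ids,
            "method": method,
            "gebv": pred,
            "dgv_component": dgv,
            "rpg_component": rpg,
            "j_component": jterm,
            "parent_status": status,
        }
    )
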