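"""Comparison metrics and end-to-end study orchestration.

Ties the modules together the way a routine evaluation would run: build the
genomic factor from a genotype set, assemble either MME formulation, solve
by PCG to the convergence target, and post-process solutions into published
breeding values.  The study driver replays the full-versus-reduced design:
solve with all genotypes, solve again without the candidates' genotypes,
predict the candidates indirectly from the reduced solutions, and score the
predictions against the full-data breeding values with three metrics:

* accuracy — Pearson correlation of full-data and indirect GEBV;
* dispersion — slope of the regression of full-data on indirect GEBV
  (ideal 1);
* level bias — mean(indirect - full) in genetic standard deviation units
  (ideal 0),

reported per candidate parent-genotyping group (GG / NG / NN) and overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, MarkerScaling, RegularizationSpec, \
    build_genomic_factor
from .indirect import METHODS, CandidateSet, EvaluationSolutions, \
    parent_status, predict
from .mme import ModelSpec, assemble, build_jfactor_covariate
from .pedigree import Pedigree
from .simulate import SimConfig, SimulatedStudy, candidate_counts, \
    genotype_matrix, simulate_study
from .solver import PCGResult, build_preconditioner, pcg


# ---------------------------------------------------------------------------
# Metrics

def accuracy(full_gebv: np.ndarray, indirect_gebv: np.ndarray) -> float:
    """Pearson correlation between full-data and indirect GEBV."""
    x = np.asarray(full_gebv, dtype=float)
    y = np.asarray(indirect_gebv, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in GEBV vector")
    return float(np.corrcoef(x, y)[0, 1])


def dispersion(full_gebv: np.ndarray, indirect_gebv: np.ndarray) -> float:
    """OLS slope of full-data GEBV regressed on indirect GEBV."""
    x = np.asarray(indirect_gebv, dtype=float)
    y = np.asarray(full_gebv, dtype=float)
    vx = np.var(x)
    if vx == 0.0:
        raise ValueError("zero variance of the indirect GEBV")
    return float(np.cov(x, y, ddof=0)[0, 1] / vx)


def level_bias(full_gebv: np.ndarray, indirect_gebv: np.ndarray,
               sigma_u: float) -> float:
    """Mean (indirect - full) / sigma_u; sign: indirect minus full."""
    if sigma_u <= 0:
        raise ValueError("sigma_u must be positive")
    return float(np.mean(np.asarray(indirect_gebv, dtype=float)
                         - np.asarray(full_gebv, dtype=float)) / sigma_u)


def comparison_report(full_gebv: np.ndarray, predictions: pd.DataFrame,
                      sigma_u: float) -> pd.DataFrame:
    """Per method x parent-status group (plus overall) metric table.

    ``predictions`` is the concatenated output of :func:`ssgblup.indirect
    .predict` for one or more methods; candidate order must match
    ``full_gebv``.
    """
    rows = []
    for method, sub in predictions.groupby("method", sort=False):
        pred = sub["gebv"].to_numpy()
        status = sub["parent_status"].to_numpy()
        groups = {"overall": np.ones(len(sub), dtype=bool)}
        for g in ("GG", "NG", "NN"):
            groups[g] = status == g
        for g, mask in groups.items():
            if mask.sum() < 3:
                continue
            rows.append({
                "method": method,
                "group": g,
                "n": int(mask.sum()),
                "accuracy": accuracy(full_gebv[mask], pred[mask]),
                "slope": dispersion(full_gebv[mask], pred[mask]),
                "level_bias": level_bias(full_gebv[mask], pred[mask],
                                         sigma_u),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Single evaluation

def solve_evaluation(ped: Pedigree, geno: GenotypeMatrix,
                     genotyped_codes: np.ndarray, phenotypes: pd.DataFrame,
                     model: ModelSpec, *, tol: float = 1e-7,
                     maxit: int = 10000, snp_diag_mode: str = "exact",
                     omit_correction_diag: bool = False,
                     ) -> tuple[EvaluationSolutions, PCGResult]:
    """Build, precondition and solve one single-step evaluation.

    Uses the residual-polygenic regularisation C = w A_gg with the
    VanRaden method-1 scaling B = ((1 - w)/k) I, allele frequencies
    observed in the supplied genotype set.
    """
    reg = RegularizationSpec.from_pedigree(model.w, ped, genotyped_codes)
    scaling = MarkerScaling.vanraden(geno.allele_freq, w=model.w)
    with_T = (model.strategy == "original_T"
              or (model.formulation == "ssgtblup"
                  and not omit_correction_diag))
    factor = build_genomic_factor(geno.counts, scaling, reg, with_T=with_T)
    system = assemble(model, ped, factor, phenotypes,
                      genotyped_codes=genotyped_codes,
                      omit_correction_diag=omit_correction_diag)
    precond = build_preconditioner(system, snp_diag_mode=snp_diag_mode,
                                   factor=factor, lambda_=model.lambda_)
    result = pcg(system, precond, tol=tol, maxit=maxit)
    emap = system.map
    fixed = result.solutions[emap.fixed_slice]
    u = result.solutions[emap.animal_slice]
    mu = 0.0
    jvec = None
    if model.jfactor:
        mu = float(fixed[emap.fixed_labels.index("jfactor")])
        jvec = build_jfactor_covariate(ped, genotyped_codes, reg.agg_factor)
    sol = EvaluationSolutions(
        ped=ped, factor=factor, genotyped_codes=np.asarray(genotyped_codes),
        u=u, fixed=fixed, fixed_labels=emap.fixed_labels,
        jfactor_mu=mu, jfactor_covariate=jvec,
        marker_ids=list(geno.marker_ids),
    )
    if model.formulation == "sssnpblup":
        sol.snp_effects = result.solutions[emap.snp_slice]
    return sol, result


# ---------------------------------------------------------------------------
# Full study

@dataclass
class StudyResult:
    """Everything the full-versus-reduced study design produces."""

    study: SimulatedStudy
    sol_full: EvaluationSolutions
    sol_reduced: EvaluationSolutions
    sol_snp: EvaluationSolutions | None
    pcg_full: PCGResult
    pcg_reduced: PCGResult
    pcg_snp: PCGResult | None
    predictions: pd.DataFrame
    report: pd.DataFrame
    formulation_corr: float | None
    formulation_slope: float | None
    reduced_vs_full_corr: float

    def candidate_full_gebv(self) -> np.ndarray:
        return self.sol_full.gebv[self.study.candidates - 1]


def run_study(config: SimConfig, *, tol: float = 1e-7, maxit: int = 10000,
              solve_snpblup: bool = True,
              strategy: str = "component_wise") -> StudyResult:
    """Simulate, solve full + reduced, predict candidates, score.

    ``solve_snpblup`` additionally solves the marker-equation formulation on
    the full data for the formulation-equivalence comparison.
    """
    study = simulate_study(config)
    ped = study.ped
    phen = study.phenotypes
    model = ModelSpec(lambda_=config.lambda_, w=config.w, jfactor=True,
                      formulation="ssgtblup", strategy=strategy)
    geno_full, codes_full = genotype_matrix(study, "full")
    geno_red, codes_red = genotype_matrix(study, "reduced")
    sol_full, pcg_full = solve_evaluation(ped, geno_full, codes_full, phen,
                                          model, tol=tol, maxit=maxit)
    sol_red, pcg_red = solve_evaluation(ped, geno_red, codes_red, phen,
                                        model, tol=tol, maxit=maxit)
    sol_snp = pcg_snp = None
    corr = slope = None
    if solve_snpblup:
        model_snp = ModelSpec(lambda_=config.lambda_, w=config.w,
                              jfactor=True, formulation="sssnpblup")
        sol_snp, pcg_snp = solve_evaluation(ped, geno_full, codes_full, phen,
                                            model_snp, tol=tol, maxit=maxit)
        corr = accuracy(sol_full.gebv, sol_snp.gebv)
        slope = dispersion(sol_snp.gebv, sol_full.gebv)  # snp on gt
    candidates = CandidateSet(
        codes=study.candidates,
        counts=candidate_counts(study),
        ids=[ped.ids[c - 1] for c in study.candidates],
    )
    predictions = pd.concat(
        [predict(candidates, sol_red, m) for m in METHODS],
        ignore_index=True,
    )
    full_cand = sol_full.gebv[study.candidates - 1]
    report = comparison_report(full_cand, predictions,
                               sigma_u=np.sqrt(config.sigma_u2))
    common = np.ones(ped.n, dtype=bool)
    r_rvf = accuracy(sol_full.gebv[common], sol_red.gebv[common])
    return StudyResult(
        study=study, sol_full=sol_full, sol_reduced=sol_red, sol_snp=sol_snp,
        pcg_full=pcg_full, pcg_reduced=pcg_red, pcg_snp=pcg_snp,
        predictions=predictions, report=report,
        formulation_corr=corr, formulation_slope=slope,
        reduced_vs_full_corr=r_rvf,
    )
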