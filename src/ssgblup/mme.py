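"""Matrix-free assembly of the single-step mixed model equations.

A univariate animal model y = X b + W u + e with u ~ N(0, H sigma_u^2) and
e ~ N(0, I sigma_e^2) leads to Henderson's MME.  Two equivalent forms are
assembled here as linear operators:

* ``ssgtblup`` — the breeding-value form: the usual pedigree MME plus the
  genotyped-block correction (G_C^-1 - A_gg^-1) lambda, with G_C^-1 products
  evaluated by the Woodbury identity (component-wise or cached-T strategy).
* ``sssnpblup`` — the extended form with explicit SNP-effect equations: the
  genotyped-block correction becomes (-A_gg^-1 + C^-1) lambda, coupled to the
  SNP block through -C^-1 Z lambda, and the SNP block carries K lambda whose
  action is computed as Z'(C^-1(Z v)) + B^-1 v without forming K.

Both operators act on the same leading blocks (fixed effects, additive
effects of all animals in pedigree order) and share right-hand side
(X'y, W'y, 0), so their solutions agree on those blocks.

The optional J-factor is a fixed covariate absorbing the mean difference
between the pedigree base and the genomic base: value -1 for genotyped
animals and -(A_ng A_gg^-1 1)_i for non-genotyped animal i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .genomics import (
    GenomicFactor,
    dense_gc,
    dense_z,
    gcinv_times,
    z_times,
    zt_times,
)
from .pedigree import Pedigree, a_times_vector, build_a_inverse


@dataclass
class ModelSpec:
    """Model configuration for one univariate single-step evaluation.

    ``fixed_terms`` are (column name, kind) pairs with kind "class" or
    "covariate", applied in order after the intercept; the intercept is
    included only when no class term is present (a class term absorbs the
    mean).  ``lambda_`` is the variance ratio sigma_e^2 / sigma_u^2.
    """

    lambda_: float
    w: float = 0.2
    fixed_terms: list[tuple[str, str]] = field(default_factory=list)
    jfactor: bool = True
    formulation: str = "ssgtblup"  # or "sssnpblup"
    strategy: str = "component_wise"  # or "original_T" (ssgtblup only)
    trait_column: str = "y"

    @classmethod
    def from_variances(cls, sigma_u2: float, sigma_e2: float, **kw) -> "ModelSpec":
        return cls(lambda_=sigma_e2 / sigma_u2, **kw)

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.formulation not in ("ssgtblup", "sssnpblup"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.formulation == "sssnpblup" and self.strategy == "original_T":
            raise ValueError("strategy 'original_T' applies only to ssgtblup")


@dataclass
class EquationMap:
    """Block layout of the solution vector: fixed | animals | (SNPs)."""

    n_fixed: int
    n_animals: int
    n_snp: int
    genotyped_codes: np.ndarray  # 1-based pedigree codes, evaluation order
    fixed_labels: list[str]

    @property
    def n_eq(self) -> int:
        return self.n_fixed + self.n_animals + self.n_snp

    @property
    def fixed_slice(self) -> slice:
        return slice(0, self.n_fixed)

    @property
    def animal_slice(self) -> slice:
        return slice(self.n_fixed, self.n_fixed + self.n_animals)

    @property
    def snp_slice(self) -> slice:
        return slice(self.n_fixed + self.n_animals, self.n_eq)

    @property
    def genotyped_rows(self) -> np.ndarray:
        """0-based positions of the genotyped animals inside the animal block."""
        return self.genotyped_codes - 1


@dataclass
class LinearSystem:
    """Matrix-free MME: coefficient action, right-hand side, exact diagonal."""

    matvec: Callable[[np.ndarray], np.ndarray]
    rhs: np.ndarray
    diag: np.ndarray
    map: EquationMap
    xtx: np.ndarray  # dense X'X for the fixed-block preconditioner


class DesignError(ValueError):
    """Raised for records that cannot be matched to the model or pedigree."""


def build_design(phenotypes, model: ModelSpec, ped: Pedigree):
    """Incidence structures for the fixed effects and the animal effect.

    Returns ``(X, W, y, labels)`` with sparse CSR X (records x fixed levels),
    sparse CSR W (records x animals) and the observation vector.  Class
    levels are indexed in sorted label order so equation numbering is
    deterministic.
    """
    if model.trait_column not in phenotypes.columns:
        raise DesignError(f"phenotype table lacks column {model.trait_column!r}")
    y = phenotypes[model.trait_column].to_numpy(dtype=float)
    n_rec = len(phenotypes)
    codes = ped.index_of(phenotypes["animal"])
    w = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), codes - 1)),
        shape=(n_rec, ped.n),
    )
    columns: list[np.ndarray] = []
    labels: list[str] = []
    has_class = any(kind == "class" for _, kind in model.fixed_terms)
    if not has_class:
        columns.append(np.ones(n_rec))
        labels.append("intercept")
    for name, kind in model.fixed_terms:
        if name not in phenotypes.columns:
            raise DesignError(f"phenotype table lacks fixed-effect column {name!r}")
        col = phenotypes[name]
        if kind == "covariate":
            columns.append(col.to_numpy(dtype=float))
            labels.append(name)
        elif kind == "class":
            levels = sorted(col.astype(str).unique())
            if not levels:
                raise DesignError(f"fixed effect {name!r} has no levels")
            for lev in levels:
                columns.append((col.astype(str) == lev).to_numpy(dtype=float))
                labels.append(f"{name}={lev}")
        else:
            raise DesignError(f"unknown fixed-effect kind {kind!r}")
    x = sp.csr_matrix(np.column_stack(columns))
    return x, w, y, labels


def build_jfactor_covariate(ped: Pedigree, genotyped_codes: np.ndarray,
                            agg_factor: np.ndarray) -> np.ndarray:
    """Per-animal J-factor covariate over the whole pedigree.

    -1 for genotyped animals; -(A_ng A_gg^-1 1)_i for non-genotyped animal i,
    computed as t = A_gg^-1 1 followed by one Colleau product A (0, t, 0)'.
    """
    gi = np.asarray(genotyped_codes, dtype=np.int64) - 1
    t = la.cho_solve((agg_factor, True), np.ones(gi.size))
    padded = np.zeros(ped.n)
    padded[gi] = t
    j = -a_times_vector(ped, padded)
    j[gi] = -1.0  # exact: A_gg t = 1
    return j


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DesignError(msg)


def assemble(model: ModelSpec, ped: Pedigree, factor: GenomicFactor | None,
             phenotypes, *, omit_correction_diag: bool = False,
             genotyped_codes: np.ndarray | None = None) -> LinearSystem:
    """Build the MME linear operator for either formulation.

    ``factor`` may be None (no genotyped animals): both formulations then
    reduce to pedigree BLUP.  ``genotyped_codes`` gives the 1-based pedigree
    codes of the rows of the genotype matrix, in evaluation order.

    ``omit_correction_diag`` drops the rank-m part of the genotyped-block
    diagonal (the behaviour of production component-wise solvers that never
    form T); the default is the exact diagonal.
    """
    lam = model.lambda_
    if factor is None:
        genotyped_codes = np.empty(0, dtype=np.int64)
    else:
        _require(genotyped_codes is not None,
                 "genotyped_codes required when genotypes are present")
        genotyped_codes = np.asarray(genotyped_codes, dtype=np.int64)
        _require(genotyped_codes.size == factor.n,
                 "genotyped_codes does not match genotype matrix rows")
    x, w, y, labels = build_design(phenotypes, model, ped)
    if model.jfactor and factor is not None:
        jvec = build_jfactor_covariate(ped, genotyped_codes,
                                       factor.reg.agg_factor
                                       if factor.reg.kind == "w_agg"
                                       else _agg_factor_fallback(ped, genotyped_codes))
        x = sp.hstack([x, w @ sp.csr_matrix(jvec[:, None])]).tocsr()
        labels = labels + ["jfactor"]
    n_fixed = x.shape[1]
    n_animals = ped.n
    ainv = build_a_inverse(ped)
    n_snp = factor.m if (factor is not None and model.formulation == "sssnpblup") else 0
    emap = EquationMap(n_fixed=n_fixed, n_animals=n_animals, n_snp=n_snp,
                       genotyped_codes=genotyped_codes, fixed_labels=labels)
    grows = emap.genotyped_rows
    xt = x.T.tocsr()
    wt = w.T.tocsr()

    if factor is not None:
        agg_chol = (factor.reg.agg_factor if factor.reg.kind == "w_agg"
                    else _agg_factor_fallback(ped, genotyped_codes))

    def agg_solve(v):
        return la.cho_solve((agg_chol, True), v)

    if model.formulation == "ssgtblup":
        def matvec(s: np.ndarray) -> np.ndarray:
            b = s[emap.fixed_slice]
            u = s[emap.animal_slice]
            e = x @ b + w @ u
            out = np.empty_like(s)
            out[emap.fixed_slice] = xt @ e
            ru = wt @ e + lam * (ainv @ u)
            if factor is not None:
                ug = u[grows]
                corr = gcinv_times(factor, ug, model.strategy) - agg_solve(ug)
                ru[grows] += lam * corr
            out[emap.animal_slice] = ru
            return out
    else:
        def matvec(s: np.ndarray) -> np.ndarray:
            b = s[emap.fixed_slice]
            u = s[emap.animal_slice]
            g = s[emap.snp_slice]
            e = x @ b + w @ u
            out = np.empty_like(s)
            out[emap.fixed_slice] = xt @ e
            ru = wt @ e + lam * (ainv @ u)
            ug = u[grows]
            cinv_ug = factor.reg.solve(ug)
            cinv_zg = factor.reg.solve(z_times(factor.counts, factor.p, g))
            ru[grows] += lam * (cinv_ug - agg_solve(ug) - cinv_zg)
            out[emap.animal_slice] = ru
            # K g computed component-wise: Z'(C^-1(Z g)) + B^-1 g
            kg = zt_times(factor.counts, factor.p, cinv_zg) \
                + g / factor.scaling.b_diag
            out[emap.snp_slice] = lam * (kg - zt_times(factor.counts,
                                                       factor.p, cinv_ug))
            return out

    rhs = np.zeros(emap.n_eq)
    rhs[emap.fixed_slice] = xt @ y
    rhs[emap.animal_slice] = wt @ y

    diag = np.zeros(emap.n_eq)
    xtx = (xt @ x).toarray()
    diag[emap.fixed_slice] = np.diag(xtx)
    du = np.asarray(w.multiply(w).sum(axis=0)).ravel() + lam * ainv.diagonal()
    if factor is not None:
        agg_inv_diag = np.diag(la.cho_solve((agg_chol, True),
                                            np.eye(grows.size)))
        if model.formulation == "ssgtblup":
            du[grows] += lam * (_gcinv_diag(factor, omit_correction_diag,
                                            agg_inv_diag) - agg_inv_diag)
        else:
            du[grows] += lam * (factor.reg.diag_inverse(factor.n) - agg_inv_diag)
            diag[emap.snp_slice] = lam * _k_diag(factor, exact=True)
    diag[emap.animal_slice] = du
    return LinearSystem(matvec=matvec, rhs=rhs, diag=diag, map=emap, xtx=xtx)


def _agg_factor_fallback(ped: Pedigree, genotyped_codes: np.ndarray) -> np.ndarray:
    from .pedigree import a_submatrix

    return la.cholesky(a_submatrix(ped, genotyped_codes), lower=True)


def _gcinv_diag(factor: GenomicFactor, omit_correction: bool,
                agg_inv_diag: np.ndarray) -> np.ndarray:
    """Exact diag(G_C^-1) = diag(C^-1) - colsums(T * T); optionally the
    production shortcut that keeps only the diag(C^-1) part."""
    cinv_diag = (agg_inv_diag / factor.reg.w if factor.reg.kind == "w_agg"
                 else factor.reg.diag_inverse(factor.n))
    if omit_correction:
        return cinv_diag
    if factor.T is not None:
        t = factor.T
    else:
        z = dense_z(factor.counts, factor.p)
        t = la.solve_triangular(factor.L, factor.reg.solve(z).T, lower=True)
    return cinv_diag - np.einsum("ij,ij->j", t, t)


def _k_diag(factor: GenomicFactor, exact: bool) -> np.ndarray:
    """diag(K); the approximate form 2 p q n * scale is used by the solver
    module when requested."""
    if exact:
        return np.diag(factor.K)
    p = factor.p
    scale = (1.0 / factor.reg.w if factor.reg.kind == "w_agg"
             else 1.0 / factor.reg.epsilon)
    return 2.0 * p * (1.0 - p) * factor.n * scale + 1.0 / factor.scaling.b_diag


def k_diag_approx(factor: GenomicFactor) -> np.ndarray:
    """Approximate SNP-equation diagonal: (2 p_i (1-p_i) n) scaled by C^-1
    magnitude, plus B^-1."""
    return _k_diag(factor, exact=False)


def dense_reference(model: ModelSpec, ped: Pedigree,
                    factor: GenomicFactor | None, phenotypes, *,
                    genotyped_codes: np.ndarray | None = None):
    """Explicit dense coefficient matrix and right-hand side (test oracle).

    Built from dense blocks (dense A^-1, numpy inverse of dense G_C, dense Z)
    independently of the matrix-free operator path.  Refuses beyond 5000
    equations.
    """
    lam = model.lambda_
    if factor is None:
        genotyped_codes = np.empty(0, dtype=np.int64)
    else:
        genotyped_codes = np.asarray(genotyped_codes, dtype=np.int64)
    x, w, y, labels = build_design(phenotypes, model, ped)
    if model.jfactor and factor is not None:
        agg = (factor.reg.agg_factor if factor.reg.kind == "w_agg"
               else _agg_factor_fallback(ped, genotyped_codes))
        jvec = build_jfactor_covariate(ped, genotyped_codes, agg)
        x = sp.hstack([x, w @ sp.csr_matrix(jvec[:, None])]).tocsr()
    n_fixed = x.shape[1]
    n = ped.n
    n_snp = factor.m if (factor is not None and model.formulation == "sssnpblup") else 0
    n_eq = n_fixed + n + n_snp
    if n_eq > 5000:
        raise ValueError("dense_reference is a desk-scale oracle (<= 5000 eq)")
    xd = x.toarray()
    wd = w.toarray()
    ainv = build_a_inverse(ped).toarray()
    grows = genotyped_codes - 1
    c = np.zeros((n_eq, n_eq))
    fs = slice(0, n_fixed)
    us = slice(n_fixed, n_fixed + n)
    gs = slice(n_fixed + n, n_eq)
    c[fs, fs] = xd.T @ xd
    c[fs, us] = xd.T @ wd
    c[us, fs] = wd.T @ xd
    c[us, us] = wd.T @ wd + lam * ainv
    if factor is not None:
        from .pedigree import a_submatrix

        agg = a_submatrix(ped, genotyped_codes)
        agg_inv = np.linalg.inv(agg)
        if model.formulation == "ssgtblup":
            gc_inv = np.linalg.inv(dense_gc(factor))
            c[np.ix_(grows + n_fixed, grows + n_fixed)] += lam * (gc_inv - agg_inv)
        else:
            cinv = np.linalg.inv(factor.reg.dense(factor.n))
            z = dense_z(factor.counts, factor.p)
            c[np.ix_(grows + n_fixed, grows + n_fixed)] += lam * (cinv - agg_inv)
            c[np.ix_(grows + n_fixed, range(n_fixed + n, n_eq))] = -lam * (cinv @ z)
            c[np.ix_(range(n_fixed + n, n_eq), grows + n_fixed)] = -lam * (z.T @ cinv)
            c[gs, gs] = lam * factor.K
    rhs = np.concatenate([xd.T @ y, wd.T @ y, np.zeros(n_snp)])
    return c, rhs
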