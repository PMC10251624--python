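"""Preconditioned conjugate gradient solver for the single-step MME.

The preconditioner is block-structured: a dense Cholesky solve with
P_ff = X'X + diag(X'X) * 1e-4 on the fixed-effect block (the diagonal
inflation keeps P_ff positive definite under confounded fixed effects) and a
Jacobi (diagonal) solve on all random-effect equations.  For the SNP block
of the marker-equation formulation the diagonal of K may either be used
exactly (K is formed anyway at desk scale) or approximated per marker by
2 p_i (1 - p_i) n times the C^-1 magnitude, the shortcut used when K is
never formed.

Convergence is monitored by the relative residual of the original system,
C_r = ||C_MME s - r_MME|| / ||r_MME||, and iteration stops at C_r < tol.
The PCG alpha/beta scalars define a Lanczos tridiagonal matrix whose extreme
eigenvalues estimate the effective condition of the preconditioned
coefficient matrix; they are reported as solver diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la

from .genomics import GenomicFactor
from .mme import LinearSystem, k_diag_approx


class SolverError(RuntimeError):
    pass


@dataclass
class PreconditionerSpec:
    """Fixed-block dense factor plus random-block Jacobi diagonal."""

    fixed_factor: np.ndarray  # lower Cholesky factor of P_ff
    random_diag: np.ndarray   # strictly positive, random equations only
    n_fixed: int

    def apply(self, r: np.ndarray) -> np.ndarray:
        out = np.empty_like(r)
        nf = self.n_fixed
        out[:nf] = la.cho_solve((self.fixed_factor, True), r[:nf])
        out[nf:] = r[nf:] / self.random_diag
        return out


def build_preconditioner(system: LinearSystem,
                         snp_diag_mode: str = "exact",
                         factor: GenomicFactor | None = None,
                         lambda_: float | None = None) -> PreconditionerSpec:
    """Assemble the paper-style preconditioner from the system diagonal.

    ``snp_diag_mode`` = "approx_2pqn" replaces the exact SNP-block diagonal
    with the 2 p q n approximation (requires ``factor`` and ``lambda_``).
    """
    nf = system.map.n_fixed
    pff = system.xtx + np.diag(np.diag(system.xtx)) * 1e-4
    try:
        fixed_factor = la.cholesky(pff, lower=True)
    except la.LinAlgError as exc:
        raise SolverError("P_ff is not positive definite; a fixed effect "
                          "has no records") from exc
    rdiag = system.diag[nf:].copy()
    if snp_diag_mode == "approx_2pqn" and system.map.n_snp:
        if factor is None or lambda_ is None:
            raise SolverError("approx_2pqn needs the genomic factor and lambda")
        rdiag[system.map.n_animals:] = lambda_ * k_diag_approx(factor)
    elif snp_diag_mode not in ("exact", "approx_2pqn"):
        raise SolverError(f"unknown snp_diag_mode {snp_diag_mode!r}")
    bad = np.nonzero(rdiag <= 0)[0]
    if bad.size:
        raise SolverError(
            f"nonpositive preconditioner diagonal at equation {nf + bad[0]}"
        )
    return PreconditionerSpec(fixed_factor=fixed_factor, random_diag=rdiag,
                              n_fixed=nf)


def convergence_criterion(system: LinearSystem, s: np.ndarray) -> float:
    """C_r = ||C_MME s - r_MME|| / ||r_MME|| (2-norms)."""
    rhs_norm = np.linalg.norm(system.rhs)
    if rhs_norm == 0.0:
        raise SolverError("zero right-hand side: C_r undefined")
    return float(np.linalg.norm(system.matvec(s) - system.rhs) / rhs_norm)


@dataclass
class PCGResult:
    solutions: np.ndarray
    cr_history: list[float]
    iterations: int
    converged: bool
    alphas: list[float] = field(default_factory=list, repr=False)
    betas: list[float] = field(default_factory=list, repr=False)
    eig_min: float | None = None
    eig_max: float | None = None


def pcg(system: LinearSystem, precond: PreconditionerSpec,
        tol: float = 1e-7, maxit: int = 10000,
        start: np.ndarray | None = None) -> PCGResult:
    """Standard PCG recurrences with per-iteration C_r monitoring.

    The start vector defaults to zero (deterministic).  The residual is
    carried by the recurrence, so C_r per iteration costs no extra matvec;
    it equals the printed formula up to recurrence rounding drift, which is
    far below the stopping tolerance at these problem sizes.
    """
    rhs_norm = np.linalg.norm(system.rhs)
    if rhs_norm == 0.0:
        raise SolverError("zero right-hand side")
    s = np.zeros_like(system.rhs) if start is None else start.astype(float).copy()
    r = system.rhs - system.matvec(s)
    cr_history = [float(np.linalg.norm(r) / rhs_norm)]
    alphas: list[float] = []
    betas: list[float] = []
    if cr_history[0] < tol:
        return PCGResult(solutions=s, cr_history=cr_history, iterations=0,
                         converged=True)
    z = precond.apply(r)
    p = z.copy()
    rz = float(r @ z)
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        ap = system.matvec(p)
        pap = float(p @ ap)
        if not np.isfinite(pap) or pap <= 0.0:
            raise SolverError(f"PCG breakdown at iteration {it}: p'Ap = {pap}")
        alpha = rz / pap
        s += alpha * p
        r -= alpha * ap
        cr = float(np.linalg.norm(r) / rhs_norm)
        if not np.isfinite(cr):
            raise SolverError(f"NaN residual at iteration {it}")
        cr_history.append(cr)
        alphas.append(alpha)
        if cr < tol:
            converged = True
            break
        z = precond.apply(r)
        rz_new = float(r @ z)
        beta = rz_new / rz
        betas.append(beta)
        rz = rz_new
        p = z + beta * p
    eig_min = eig_max = None
    if len(alphas) >= 3:
        eig_min, eig_max = effective_eigenvalues(alphas, betas)
    return PCGResult(solutions=s, cr_history=cr_history, iterations=it,
                     converged=converged, alphas=alphas, betas=betas,
                     eig_min=eig_min, eig_max=eig_max)


def effective_eigenvalues(alphas, betas) -> tuple[float, float]:
    """Extreme eigenvalues of the Lanczos tridiagonal implied by PCG scalars.

    T_kk = 1/alpha_k + beta_{k-1}/alpha_{k-1} (first term only at k = 0);
    off-diagonal T_{k,k+1} = sqrt(beta_k)/alpha_k.  These estimate the
    extreme eigenvalues of the preconditioned coefficient matrix.
    """
    k = len(alphas)
    if k < 3:
        raise SolverError("need at least 3 PCG iterations for eigenvalue "
                          "estimates")
    diag = np.empty(k)
    diag[0] = 1.0 / alphas[0]
    for i in range(1, k):
        diag[i] = 1.0 / alphas[i] + betas[i - 1] / alphas[i - 1]
    off = np.array([np.sqrt(max(betas[i], 0.0)) / alphas[i]
                    for i in range(k - 1)])
    eig = la.eigvalsh_tridiagonal(diag, off)
    return float(eig[0]), float(eig[-1])
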