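"""Genotype I/O and all genomic-relationship-side algebra.

The genomic relationship matrix is assumed to have the low-rank-plus-
regularisation form G_C = Z B Z' + C, where Z = M - 2 1 p' are centred
allele counts, B is a diagonal marker-variance scaling and C is either
eps * I or w * A_gg (the residual-polygenic form).  Products with G_C^-1
are evaluated through the Woodbury identity

    G_C^-1 = C^-1 - C^-1 Z K^-1 Z' C^-1,   K = Z' C^-1 Z + B^-1,

so only the m x m matrix K (and its Cholesky factor L) is ever formed.
Two product strategies are provided: the component-wise one (triangular
solves with L each product) and the original T-matrix one, which caches
T = L^-1 Z' C^-1 and computes (C^-1 - T'T) v.

Genotypes are read and written in the PLINK 1 binary format (.bed/.bim/.fam,
variant-major); the codec lives here because no pre-installed library
provides it and the format is a 2-bit table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as la

from .pedigree import Pedigree, a_submatrix

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit codes (variant-major byte, LSB first): value -> count of allele A1
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)  # 01 = missing
_COUNT_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}


class GenotypeError(ValueError):
    """Raised for malformed PLINK files or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Allele-count matrix with ids and per-marker allele frequencies.

    ``counts`` is n x m int8 with entries in {0, 1, 2} (count of the first
    allele, A1); missing codes are resolved at read time.  ``allele_freq``
    holds the observed frequency of A1 per retained marker.
    """

    counts: np.ndarray
    animal_ids: list[str]
    marker_ids: list[str]
    allele_freq: np.ndarray

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def subset_animals(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        """Row subset; allele frequencies are recomputed on the subset."""
        counts = self.counts[keep_mask]
        ids = [a for a, k in zip(self.animal_ids, keep_mask) if k]
        return GenotypeMatrix(
            counts=counts,
            animal_ids=ids,
            marker_ids=list(self.marker_ids),
            allele_freq=allele_frequencies(counts),
        )


def allele_frequencies(counts: np.ndarray) -> np.ndarray:
    """Observed first-allele frequencies p_i = colsum / (2n)."""
    counts = np.asarray(counts)
    return counts.sum(axis=0, dtype=np.float64) / (2.0 * counts.shape[0])


def scaling_constant(p: np.ndarray) -> float:
    """VanRaden method-1 scaling constant k = 2 sum p_i (1 - p_i)."""
    p = np.asarray(p, dtype=float)
    return float(2.0 * np.sum(p * (1.0 - p)))


def drop_monomorphic(counts, marker_ids):
    """Remove markers fixed in the sample; returns (counts, ids, kept mask)."""
    p = allele_frequencies(counts)
    keep = (p > 0.0) & (p < 1.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic markers", n_dropped)
    ids = [mid for mid, k in zip(marker_ids, keep) if k]
    return counts[:, keep], ids, keep


def read_plink(prefix, missing_policy: str = "mean_impute") -> GenotypeMatrix:
    """Read a PLINK 1 binary trio ``prefix``.bed/.bim/.fam.

    Missing genotypes are mean-imputed per marker (``mean_impute``, with a
    warning) or rejected (``fail``).  Monomorphic markers are dropped with a
    logged count.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      dtype=str)
    animal_ids = fam[1].tolist()
    marker_ids = bim[1].tolist()
    n, m = len(animal_ids), len(marker_ids)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise GenotypeError(f"{prefix}.bed: bad magic bytes")
    if raw[2] == 0x00:
        raise GenotypeError(f"{prefix}.bed: sample-major mode is unsupported")
    if raw[2] != 0x01:
        raise GenotypeError(f"{prefix}.bed: unknown mode byte {raw[2]:#x}")
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise GenotypeError(
            f"{prefix}.bed: expected {expected} bytes for {n} samples x "
            f"{m} variants, found {len(raw)}"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    payload = payload.reshape(m, bytes_per_marker)
    # unpack 2-bit codes, LSB first within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (payload[:, :, None] >> shifts[None, None, :]) & 0b11
    counts = _CODE_TO_COUNT[codes.reshape(m, -1)[:, :n]].T.copy()  # n x m
    missing = counts < 0
    if missing.any():
        if missing_policy == "fail":
            raise GenotypeError(
                f"{prefix}.bed has {int(missing.sum())} missing genotypes "
                "and missing_policy='fail'"
            )
        if missing_policy != "mean_impute":
            raise GenotypeError(f"unknown missing_policy {missing_policy!r}")
        logger.warning(
            "mean-imputing %d missing genotypes (rounded to nearest count)",
            int(missing.sum()),
        )
        counts = counts.astype(np.float64)
        counts[missing] = np.nan
        col_mean = np.nanmean(counts, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.nonzero(missing)
        counts[idx] = np.rint(col_mean[idx[1]])
        counts = counts.astype(np.int8)
    counts, marker_ids, _ = drop_monomorphic(counts, marker_ids)
    return GenotypeMatrix(
        counts=counts,
        animal_ids=animal_ids,
        marker_ids=marker_ids,
        allele_freq=allele_frequencies(counts),
    )


def write_plink(geno: GenotypeMatrix, prefix, *, missing_mask=None) -> None:
    """Write a PLINK 1 binary trio (variant-major).

    ``missing_mask`` (optional boolean n x m) marks cells written with the
    missing code; used to build test fixtures.
    """
    prefix = Path(prefix)
    n, m = geno.counts.shape
    counts = geno.counts.astype(np.int8)
    codes = np.empty((m, n), dtype=np.uint8)
    lut = np.zeros(3, dtype=np.uint8)
    for cnt, code in _COUNT_TO_CODE.items():
        if cnt >= 0:
            lut[cnt] = code
    codes[:] = lut[counts.T]
    if missing_mask is not None:
        codes[np.asarray(missing_mask).T] = _COUNT_TO_CODE[-1]
    bytes_per_marker = (n + 3) // 4
    padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(m, bytes_per_marker, 4) << shifts).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())
    fam = pd.DataFrame(
        {
            0: geno.animal_ids, 1: geno.animal_ids,
            2: "0", 3: "0", 4: "0", 5: "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            0: "1", 1: geno.marker_ids, 2: "0",
            3: [str(i + 1) for i in range(m)], 4: "A", 5: "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Centring, scaling and regularisation


@dataclass
class MarkerScaling:
    """VanRaden method-1 diagonal scaling B = ((1-w)/k) I (or I/k when C = eps I).

    ``p`` are the centring allele frequencies fixed at evaluation build time,
    ``k = 2 sum p(1-p)`` and ``b_diag`` the common diagonal entry of B.
    """

    p: np.ndarray
    k: float
    w: float
    b_diag: float
    kind: str = "vanraden_m1"

    @classmethod
    def vanraden(cls, p: np.ndarray, w: float = 0.0) -> "MarkerScaling":
        p = np.asarray(p, dtype=float)
        k = scaling_constant(p)
        return cls(p=p, k=k, w=w, b_diag=(1.0 - w) / k)


def z_times(counts: np.ndarray, p: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Z v = (M - 2 1 p') v without materialising Z."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != counts.shape[1]:
        raise ValueError("z_times: vector length does not match marker count")
    return counts @ v - 2.0 * (p @ v)


def zt_times(counts: np.ndarray, p: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Z' v = M' v - 2 p (1' v)."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != counts.shape[0]:
        raise ValueError("zt_times: vector length does not match animal count")
    return counts.T @ v - 2.0 * p * v.sum(axis=0)


def dense_z(counts: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Materialised Z (small instances / oracles)."""
    return counts.astype(float) - 2.0 * p[None, :]


@dataclass
class RegularizationSpec:
    """The regularisation matrix C: eps * I or w * A_gg.

    For the RPG form, ``agg_factor`` caches the lower Cholesky factor of
    A_gg (the pedigree relationship among genotyped animals), so C^-1 v is
    a pair of triangular solves scaled by 1/w.
    """

    kind: str  # "epsilon_identity" | "w_agg"
    epsilon: float = 0.0
    w: float = 0.0
    agg: np.ndarray | None = None
    agg_factor: np.ndarray | None = None

    @classmethod
    def epsilon_identity(cls, epsilon: float) -> "RegularizationSpec":
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        return cls(kind="epsilon_identity", epsilon=float(epsilon))

    @classmethod
    def w_agg(cls, w: float, agg: np.ndarray) -> "RegularizationSpec":
        if not 0.0 < w < 1.0:
            raise ValueError("RPG proportion w must be in (0, 1)")
        agg = np.asarray(agg, dtype=float)
        factor = la.cholesky(agg, lower=True)
        return cls(kind="w_agg", w=float(w), agg=agg, agg_factor=factor)

    @classmethod
    def from_pedigree(cls, w: float, ped: Pedigree,
                      genotyped_codes: np.ndarray) -> "RegularizationSpec":
        return cls.w_agg(w, a_submatrix(ped, genotyped_codes))

    def solve(self, v: np.ndarray) -> np.ndarray:
        """C^-1 v (vector or matrix right-hand side)."""
        v = np.asarray(v, dtype=float)
        if self.kind == "epsilon_identity":
            return v / self.epsilon
        x = la.cho_solve((self.agg_factor, True), v)
        return x / self.w

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """C v."""
        v = np.asarray(v, dtype=float)
        if self.kind == "epsilon_identity":
            return self.epsilon * v
        return self.w * (self.agg @ v)

    def diag_inverse(self, n: int) -> np.ndarray:
        """diag(C^-1), exact (dense inverse of A_gg at desk scale)."""
        if self.kind == "epsilon_identity":
            return np.full(n, 1.0 / self.epsilon)
        identity = np.eye(self.agg.shape[0])
        return np.diag(la.cho_solve((self.agg_factor, True), identity)) / self.w

    def dense(self, n: int) -> np.ndarray:
        if self.kind == "epsilon_identity":
            return self.epsilon * np.eye(n)
        return self.w * self.agg


@dataclass
class GenomicFactor:
    """K = Z' C^-1 Z + B^-1, its Cholesky factor L, optionally T = L^-1 Z' C^-1.

    All G_C^-1 products and the marker-effect backsolve run through this
    object; the genotype counts and centring frequencies are carried along so
    Z products never materialise Z.
    """

    counts: np.ndarray
    scaling: MarkerScaling
    reg: RegularizationSpec
    K: np.ndarray
    L: np.ndarray
    T: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    @property
    def p(self) -> np.ndarray:
        return self.scaling.p

    def k_solve(self, v: np.ndarray) -> np.ndarray:
        """K^-1 v = L'^-1 (L^-1 v): forward then backward triangular solve."""
        return la.cho_solve((self.L, True), np.asarray(v, dtype=float))


def build_genomic_factor(geno_counts: np.ndarray, scaling: MarkerScaling,
                         reg: RegularizationSpec,
                         with_T: bool = False) -> GenomicFactor:
    """Assemble K = Z' C^-1 Z + B^-1 and factor it.

    For C = w A_gg the inner solve runs column-block-wise against the cached
    Cholesky factor of A_gg; A_gg^-1 is never formed.
    """
    counts = np.asarray(geno_counts)
    n, m = counts.shape
    p = scaling.p
    z = dense_z(counts, p)
    cinv_z = reg.solve(z)
    K = z.T @ cinv_z
    K[np.diag_indices(m)] += 1.0 / scaling.b_diag
    K = 0.5 * (K + K.T)
    try:
        L = la.cholesky(K, lower=True)
    except la.LinAlgError as exc:
        raise GenotypeError(
            "K = Z'C^-1 Z + B^-1 is not positive definite; check for "
            "duplicated genotypes or increase the regularisation (epsilon/w)"
        ) from exc
    T = None
    if with_T:
        T = la.solve_triangular(L, cinv_z.T, lower=True)
    return GenomicFactor(counts=counts, scaling=scaling, reg=reg, K=K, L=L, T=T)


def gcinv_times(factor: GenomicFactor, v: np.ndarray,
                strategy: str = "component_wise") -> np.ndarray:
    """G_C^-1 v through the Woodbury identity.

    ``component_wise``: C^-1 v - C^-1 (Z (K^-1 (Z' (C^-1 v)))) with K^-1
    applied as two triangular solves against L.  ``original_T``: (C^-1 - T'T) v
    using the cached T.  Both agree to solver precision.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != factor.n:
        raise ValueError("gcinv_times: vector length does not match n")
    cinv_v = factor.reg.solve(v)
    if strategy == "component_wise":
        t = zt_times(factor.counts, factor.p, cinv_v)
        s = factor.k_solve(t)
        return cinv_v - factor.reg.solve(z_times(factor.counts, factor.p, s))
    if strategy == "original_T":
        if factor.T is None:
            raise ValueError("strategy 'original_T' requires a factor built "
                             "with with_T=True")
        return cinv_v - factor.T.T @ (factor.T @ v)
    raise ValueError(f"unknown strategy {strategy!r}")


def dense_gc(factor: GenomicFactor) -> np.ndarray:
    """G_C = Z B Z' + C materialised (test oracle; refuses large n)."""
    if factor.n > 2000:
        raise ValueError("dense_gc is a desk-scale oracle (n <= 2000)")
    z = dense_z(factor.counts, factor.p)
    return factor.scaling.b_diag * (z @ z.T) + factor.reg.dense(factor.n)
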