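"""Pedigree validation and numerator-relationship-matrix algebra.

All downstream single-step computations touch the pedigree only through the
operations here: inbreeding coefficients (Meuwissen & Luo recursion), the
sparse inverse A^-1 (Henderson's rules with inbreeding), matrix-free products
A @ v (Colleau's indirect algorithm), dense submatrices A[S, S] for small
subsets, and ancestor pruning.  The full matrix A is never materialised
except by the tabular oracle used in tests.

Internally animals are numbered 1..N in topological order (parents precede
offspring); 0 denotes an unknown parent.  External identifiers are arbitrary
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``sire`` and ``dam`` are int arrays of length N holding 1-based parent
    codes for animals 1..N (entry ``i`` describes animal ``i + 1``); 0 means
    unknown.  ``ids`` holds the external string label of each animal in the
    same order.  ``inbreeding`` is filled lazily by :func:`compute_inbreeding`.
    """

    sire: np.ndarray
    dam: np.ndarray
    ids: list[str]
    inbreeding: np.ndarray | None = None
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.n
        for name, parent in (("sire", self.sire), ("dam", self.dam)):
            if parent.shape != (n,):
                raise PedigreeError(f"{name} array has wrong length")
            bad = np.nonzero(parent > np.arange(1, n + 1) - 1)[0]
            # parent code must be < own 1-based code (0 = unknown always ok)
            if bad.size:
                raise PedigreeError(
                    f"animal {self.ids[bad[0]]}: {name} does not precede it "
                    "(pedigree not topologically ordered)"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, external_ids) -> np.ndarray:
        """Map external id labels to 1-based internal codes."""
        lookup = {a: i + 1 for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[str(a)] for a in external_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"unknown animal id {exc.args[0]!r}") from exc

    @property
    def f(self) -> np.ndarray:
        if self.inbreeding is None:
            self.inbreeding = compute_inbreeding(self)
        return self.inbreeding


def _toposort(animals: list[str], sires: list[str], dams: list[str],
              unknown: set[str]) -> list[int]:
    """Order rows so parents precede offspring; raise on cycles."""
    index = {a: k for k, a in enumerate(animals)}
    state = np.zeros(len(animals), dtype=np.int8)  # 0 new, 1 open, 2 done
    order: list[int] = []
    for start in range(len(animals)):
        if state[start]:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                raise PedigreeError(
                    f"cycle detected in pedigree at animal {animals[node]!r}"
                )
            state[node] = 1
            stack.append((node, True))
            for p in (sires[node], dams[node]):
                if p in unknown:
                    continue
                k = index[p]
                if state[k] == 1:
                    raise PedigreeError(
                        f"cycle detected in pedigree at animal {animals[k]!r}"
                    )
                if state[k] == 0:
                    stack.append((k, False))
    return order


def read_pedigree(path, *, add_missing_parents: bool = True,
                  id_columns: tuple[str, str, str] = ("animal", "sire", "dam"),
                  ) -> Pedigree:
    """Read an animal/sire/dam CSV into a topologically sorted :class:`Pedigree`.

    Unknown parents are coded ``0`` or left empty.  Parents that appear only
    in a parent column are appended as founders when ``add_missing_parents``
    (the default), otherwise the file is rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    a_col, s_col, d_col = id_columns
    for col in id_columns:
        if col not in df.columns:
            raise PedigreeError(f"pedigree file lacks column {col!r}")
    animals = [a.strip() for a in df[a_col]]
    sires = [s.strip() for s in df[s_col]]
    dams = [d.strip() for d in df[d_col]]
    unknown = {"", "0"}
    seen = set()
    for a in animals:
        if a in unknown:
            raise PedigreeError("animal id may not be 0 or empty")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
    for k, (a, s, d) in enumerate(zip(animals, sires, dams)):
        if a == s or a == d:
            raise PedigreeError(f"animal {a!r} is its own parent")
    missing = [p for p in dict.fromkeys(sires + dams)
               if p not in unknown and p not in seen]
    if missing:
        if not add_missing_parents:
            raise PedigreeError(
                f"parent id {missing[0]!r} has no pedigree row"
            )
        animals = missing + animals
        sires = ["0"] * len(missing) + sires
        dams = ["0"] * len(missing) + dams
        df = pd.concat(
            [pd.DataFrame({a_col: missing, s_col: "0", d_col: "0"}), df],
            ignore_index=True,
        )
    order = _toposort(animals, sires, dams, unknown)
    ids = [animals[k] for k in order]
    code = {a: i + 1 for i, a in enumerate(ids)}
    code.update({u: 0 for u in unknown})
    sire = np.array([code[sires[k]] for k in order], dtype=np.int64)
    dam = np.array([code[dams[k]] for k in order], dtype=np.int64)
    extra_cols = [c for c in df.columns if c not in id_columns]
    extra = df.iloc[order][extra_cols].reset_index(drop=True) if extra_cols else None
    return Pedigree(sire=sire, dam=dam, ids=ids, extra=extra)


def make_pedigree(sire, dam, ids=None) -> Pedigree:
    """Build a Pedigree from 1-based parent code arrays (0 = unknown)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    if ids is None:
        ids = [str(i + 1) for i in range(len(sire))]
    return Pedigree(sire=sire, dam=dam, ids=list(ids))


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo recursion.

    For each animal the within-family segment of the Cholesky factor of A is
    traced over its ancestor list only, giving O(N * ancestor-depth) work
    rather than the O(N^2) tabular method.  F_i = A_ii - 1.
    """
    n = ped.n
    sire = ped.sire
    dam = ped.dam
    f = np.zeros(n + 1)  # f[0] slot: unknown parent, F = -1 convention
    f[0] = -1.0
    # d[i]: Mendelian sampling variance of animal i (1-based)
    d = np.zeros(n + 1)
    point = np.zeros(n + 1, dtype=np.int64)
    l = np.zeros(n + 1)
    for i in range(1, n + 1):
        s, ds = sire[i - 1], dam[i - 1]
        d[i] = 0.5 - 0.25 * (f[s] + f[ds])
        if s == 0 or ds == 0:
            f[i] = 0.0
            continue
        fi = -1.0
        l[i] = 1.0
        j = i
        while j != 0:
            k = j
            r = l[k]
            for p in (sire[k - 1], dam[k - 1]):
                if p == 0:
                    continue
                l[p] += 0.5 * r
                # keep the ancestor list sorted descending; insert p if new
                m = k
                while point[m] > p:
                    m = point[m]
                if point[m] != p:
                    point[p] = point[m]
                    point[m] = p
            fi += r * r * d[k]
            l[k] = 0.0
            nxt = point[k]
            point[k] = 0
            j = nxt
        f[i] = fi
    return f[1:].copy()


def mendelian_variances(ped: Pedigree) -> np.ndarray:
    """Diagonal D of A = T D T': d_i = 0.5 - 0.25 (F_s + F_d), F(unknown) = -1."""
    f = np.concatenate([[-1.0], ped.f])
    return 0.5 - 0.25 * (f[ped.sire] + f[ped.dam])


def build_a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Per animal i with parents s, d the contribution weight is
    b_i = 1 / d_i with d_i the Mendelian sampling variance; unknown parents
    contribute as base animals.
    """
    n = ped.n
    dvec = mendelian_variances(ped)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)
    s = ped.sire - 1  # -1 = unknown
    d = ped.dam - 1
    b = 1.0 / dvec

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(idx, idx, b)
    for p in (s, d):
        known = p >= 0
        add(idx[known], p[known], -0.5 * b[known])
        add(p[known], idx[known], -0.5 * b[known])
        add(p[known], p[known], 0.25 * b[known])
    both = (s >= 0) & (d >= 0)
    add(s[both], d[both], 0.25 * b[both])
    add(d[both], s[both], 0.25 * b[both])
    ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return ainv.tocsr()


def a_times_vector(ped: Pedigree, v: np.ndarray) -> np.ndarray:
    """A @ v via Colleau's indirect algorithm, O(N), without forming A.

    Uses A = T D T' where T is the gene-flow (lower triangular) matrix:
    first w = T' v (youngest to oldest), then x = D w, then r = T x
    (oldest to youngest with r_i = x_i + 0.5 (r_s + r_d)).
    """
    v = np.asarray(v, dtype=float)
    n = ped.n
    if v.shape != (n,):
        raise ValueError(f"vector has length {v.shape}, pedigree has {n} animals")
    sire = ped.sire
    dam = ped.dam
    dvec = mendelian_variances(ped)
    w = v.copy()
    for i in range(n - 1, -1, -1):
        wi = w[i]
        if wi != 0.0:
            s, d = sire[i], dam[i]
            if s:
                w[s - 1] += 0.5 * wi
            if d:
                w[d - 1] += 0.5 * wi
    x = dvec * w
    r = np.empty(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        acc = x[i]
        if s:
            acc += 0.5 * r[s - 1]
        if d:
            acc += 0.5 * r[d - 1]
        r[i] = acc
    return r


def a_times_matrix(ped: Pedigree, v: np.ndarray) -> np.ndarray:
    """Column-wise Colleau products, vectorised over the columns of ``v``."""
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        return a_times_vector(ped, v)
    n = ped.n
    sire = ped.sire
    dam = ped.dam
    dvec = mendelian_variances(ped)
    w = v.copy()
    for i in range(n - 1, -1, -1):
        s, d = sire[i], dam[i]
        if s:
            w[s - 1] += 0.5 * w[i]
        if d:
            w[d - 1] += 0.5 * w[i]
    w *= dvec[:, None]
    r = np.empty_like(w)
    for i in range(n):
        s, d = sire[i], dam[i]
        acc = w[i].copy()
        if s:
            acc += 0.5 * r[s - 1]
        if d:
            acc += 0.5 * r[d - 1]
        r[i] = acc
    return r


def a_submatrix(ped: Pedigree, subset: np.ndarray) -> np.ndarray:
    """Dense A[subset, subset] (1-based subset codes) for desk-scale subsets.

    Computed by |subset| Colleau products against unit vectors; the result is
    exact and symmetric up to floating point, so it is symmetrised.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size and (subset.min() < 1 or subset.max() > ped.n):
        raise ValueError("subset index out of range")
    e = np.zeros((ped.n, subset.size))
    e[subset - 1, np.arange(subset.size)] = 1.0
    cols = a_times_matrix(ped, e)
    out = cols[subset - 1]
    return 0.5 * (out + out.T)


def prune_to_ancestors(ped: Pedigree, keep: np.ndarray):
    """Restrict the pedigree to ``keep`` (1-based) and all their ancestors.

    Returns ``(pruned, old_codes)`` where ``old_codes[i]`` is the original
    1-based code of pruned animal ``i + 1``.  Relationships among kept
    animals are unchanged.
    """
    keep = np.asarray(keep, dtype=np.int64)
    if keep.size and (keep.min() < 1 or keep.max() > ped.n):
        raise ValueError("keep index out of range")
    mark = np.zeros(ped.n + 1, dtype=bool)
    mark[keep] = True
    for i in range(ped.n, 0, -1):  # reverse topological order: one pass
        if mark[i]:
            mark[ped.sire[i - 1]] = True
            mark[ped.dam[i - 1]] = True
    mark[0] = False
    old_codes = np.nonzero(mark)[0]  # ascending = still topological
    new_code = np.zeros(ped.n + 1, dtype=np.int64)
    new_code[old_codes] = np.arange(1, old_codes.size + 1)
    pruned = Pedigree(
        sire=new_code[ped.sire[old_codes - 1]],
        dam=new_code[ped.dam[old_codes - 1]],
        ids=[ped.ids[c - 1] for c in old_codes],
        inbreeding=None if ped.inbreeding is None else ped.inbreeding[old_codes - 1],
    )
    return pruned, old_codes


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (O(N^2) oracle; tests and tiny inputs)."""
    n = ped.n
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i] - 1, ped.dam[i] - 1
        asd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[j, s]
            if d >= 0:
                v += 0.5 * a[j, d]
            a[i, j] = a[j, i] = v
    return a


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the pedigree back to CSV in internal (topological) order."""
    code_to_id = {0: "0", **{i + 1: a for i, a in enumerate(ped.ids)}}
    df = pd.DataFrame(
        {
            "animal": ped.ids,
            "sire": [code_to_id[c] for c in ped.sire],
            "dam": [code_to_id[c] for c in ped.dam],
        }
    )
    if ped.extra is not None:
        for c in ped.extra.columns:
            df[c] = ped.extra[c].values
    df.to_csv(path, index=False)
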