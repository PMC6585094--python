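"""Pedigree and genomic relationship structures.

Builds the numerator relationship matrix A (tabular method), its sparse
inverse (Henderson rules with inbreeding), the VanRaden genomic relationship
G, and the combined single-step inverse H^-1.  Also provides indirect
products A @ x via the pedigree factorisation A = T D T' so that dense
sub-blocks (A22) can be extracted without ever forming the full A, and a
diagonal-plus-low-rank factorisation of A22 for the common cattle design
where phenotyped animals are progeny of founder parents (heavily used AI
sires, essentially unique dams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "KinshipSet",
    "build_A",
    "build_Ainv",
    "build_G",
    "blend_G",
    "build_Hinv",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ordered pedigree: parents always precede offspring.

    ``sire``/``dam`` hold positional indices into ``ids`` (-1 = unknown).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise PedigreeError("ids/sire/dam length mismatch")
        for p in (self.sire, self.dam):
            bad = (p >= np.arange(n)) & (p != UNKNOWN)
            if bad.any():
                raise PedigreeError(
                    "pedigree is not sorted parents-first (or contains a cycle); "
                    f"first offender: {self.ids[np.where(bad)[0][0]]!r}"
                )
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids.tolist())}

    # ------------------------------------------------------------------ io
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from an animal/sire/dam table; 0, '0', NA mean unknown.

        Rows may come in any order; a topological sort is applied.  Parents
        that never appear as animals are added as founders.
        """
        cols = list(df.columns[:3])
        animal = df[cols[0]].astype(str).to_numpy()
        sire = df[cols[1]].astype(str).to_numpy()
        dam = df[cols[2]].astype(str).to_numpy()
        missing = {"0", "", "nan", "NA", "None", "<NA>", "0.0"}
        parents_of = {}
        for a, s, d in zip(animal, sire, dam):
            if a in missing:
                raise PedigreeError("animal id missing")
            if a in parents_of:
                raise PedigreeError(f"duplicate animal id {a!r}")
            parents_of[a] = (None if s in missing else s, None if d in missing else d)
        # implicit founders
        for a in list(parents_of):
            for p in parents_of[a]:
                if p is not None and p not in parents_of:
                    parents_of[p] = (None, None)
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(a: str, stack: list[str]):
            # iterative DFS to avoid recursion limits on deep pedigrees
            stack.append(a)
            while stack:
                x = stack[-1]
                st = state.get(x, 0)
                if st == 2:
                    stack.pop()
                    continue
                if st == 1:
                    state[x] = 2
                    order.append(x)
                    stack.pop()
                    continue
                state[x] = 1
                for p in parents_of[x]:
                    if p is None:
                        continue
                    if state.get(p, 0) == 1:
                        raise PedigreeError(f"pedigree cycle involving {p!r}")
                    if state.get(p, 0) == 0:
                        stack.append(p)

        for a in parents_of:
            if state.get(a, 0) == 0:
                visit(a, [])
        idx = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire_i = np.full(n, UNKNOWN, dtype=np.int64)
        dam_i = np.full(n, UNKNOWN, dtype=np.int64)
        for a, (s, d) in parents_of.items():
            i = idx[a]
            if s is not None:
                sire_i[i] = idx[s]
            if d is not None:
                dam_i[i] = idx[d]
        return cls(np.array(order, dtype=object), sire_i, dam_i, idx)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        def name(p):
            return np.where(p == UNKNOWN, "0", self.ids[np.clip(p, 0, None)])

        return pd.DataFrame(
            {"animal": self.ids, "sire": name(self.sire), "dam": name(self.dam)}
        )

    # ---------------------------------------------------------------- basics
    def __len__(self) -> int:
        return len(self.ids)

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in ids], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"unknown animal {e.args[0]!r}") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    # ----------------------------------------------------------- inbreeding
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen & Luo recursion.

        Uses A_ii = sum_j T_ij^2 D_j (row i of the gene-flow factor T of
        A = T D T'), so F_i = A_ii - 1.  Ancestor path coefficients are
        accumulated in decreasing pedigree order so every ancestor is
        expanded exactly once.
        """
        import heapq

        if "F" in self._cache:
            return self._cache["F"]
        n = len(self)
        F = np.zeros(n)
        D = np.empty(n)
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            if s != UNKNOWN and d != UNKNOWN:
                D[i] = 0.5 - 0.25 * (F[s] + F[d])
            elif s != UNKNOWN or d != UNKNOWN:
                D[i] = 0.75 - 0.25 * F[s if s != UNKNOWN else d]
            else:
                D[i] = 1.0
            if s == UNKNOWN or d == UNKNOWN:
                continue  # F stays 0: inbreeding needs both parental paths
            coeff: dict[int, float] = {i: 1.0}
            heap = [-i]
            in_heap = {i}
            a_ii = 0.0
            while heap:
                j = -heapq.heappop(heap)
                in_heap.discard(j)
                r = coeff.pop(j)
                a_ii += r * r * D[j]
                for p in (sire[j], dam[j]):
                    if p == UNKNOWN:
                        continue
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * r
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
            F[i] = max(a_ii - 1.0, 0.0)
        self._cache["F"] = F
        return F

    # --------------------------------------------------------- A operations
    def a_matmat(self, X: np.ndarray) -> np.ndarray:
        """Return A @ X using A = T D T' (Colleau's indirect method).

        ``X`` is (n, k); cost O(n k) per sweep, no dense A formed.
        """
        X = np.asarray(X, float)
        one_d = X.ndim == 1
        if one_d:
            X = X[:, None]
        n = len(self)
        F = self.inbreeding()
        D = self.mendelian_variances(F)
        # z = T' X : descending accumulation into parents
        Z = X.copy()
        for i in range(n - 1, -1, -1):
            s, d = self.sire[i], self.dam[i]
            if s != UNKNOWN:
                Z[s] += 0.5 * Z[i]
            if d != UNKNOWN:
                Z[d] += 0.5 * Z[i]
        Z *= D[:, None]
        # y = T Z : ascending, child gets half of parents
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s != UNKNOWN:
                Z[i] += 0.5 * Z[s]
            if d != UNKNOWN:
                Z[i] += 0.5 * Z[d]
        return Z[:, 0] if one_d else Z

    def mendelian_variances(self, F: np.ndarray | None = None) -> np.ndarray:
        """Diagonal of D in A = T D T' (accounts for inbreeding)."""
        if F is None:
            F = self.inbreeding()
        n = len(self)
        D = np.empty(n)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s != UNKNOWN and d != UNKNOWN:
                D[i] = 0.5 - 0.25 * (F[s] + F[d])
            elif s != UNKNOWN or d != UNKNOWN:
                p = s if s != UNKNOWN else d
                D[i] = 0.75 - 0.25 * F[p]
            else:
                D[i] = 1.0
        return D

    def a_submatrix(self, ids) -> np.ndarray:
        """Dense relationship block among ``ids`` (A22 for a genotyped or
        phenotyped subset) via multi-RHS indirect products."""
        idx = self.indices(ids)
        E = np.zeros((len(self), len(idx)))
        E[idx, np.arange(len(idx))] = 1.0
        return self.a_matmat(E)[idx, :]

    def factored_submatrix(self, ids):
        """Factor A22 = diag(d0) + F F' for subsets of non-inbred animals
        whose parents are all founders (or unknown).

        F has one column per parent shared by >= 2 subset animals (0.5 at
        each progeny row); parents with a single subset progeny fold into the
        diagonal.  Raises ``PedigreeError`` when the structure does not
        apply; callers then fall back to the dense block.
        """
        idx = self.indices(ids)
        founder = self.is_founder
        for i in idx:
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and not founder[p]:
                    raise PedigreeError("subset animal has a non-founder parent")
        if founder[idx].any():
            raise PedigreeError("subset contains founders")
        m = len(idx)
        counts: dict[int, int] = {}
        for i in idx:
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN:
                    counts[p] = counts.get(p, 0) + 1
        shared = {p: j for j, p in enumerate(sorted(p for p, c in counts.items() if c >= 2))}
        d0 = np.ones(m)
        rows, cols = [], []
        for r, i in enumerate(idx):
            for p in (self.sire[i], self.dam[i]):
                if p == UNKNOWN:
                    continue
                if p in shared:
                    rows.append(r)
                    cols.append(shared[p])
                    d0[r] -= 0.25
        Fmat = sp.csr_matrix(
            (np.full(len(rows), 0.5), (rows, cols)), shape=(m, len(shared))
        )
        return d0, Fmat


# ---------------------------------------------------------------------------
def build_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        acc = np.zeros(i)
        if s != UNKNOWN:
            acc += 0.5 * A[s, :i]
        if d != UNKNOWN:
            acc += 0.5 * A[d, :i]
        A[i, :i] = acc
        A[:i, i] = acc
    return A


def build_Ainv(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding."""
    F = ped.inbreeding()
    D = ped.mendelian_variances(F)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(len(ped)):
        ai = 1.0 / D[i]
        s, d = ped.sire[i], ped.dam[i]
        add(i, i, ai)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * ai)
                add(p, i, -0.5 * ai)
                add(p, p, 0.25 * ai)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, 0.25 * ai)
            add(d, s, 0.25 * ai)
    n = len(ped)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
def allele_frequencies(M: np.ndarray) -> np.ndarray:
    """Allele frequencies of the '2' allele from a 0/1/2 matrix (NaN = missing)."""
    return np.nanmean(np.asarray(M, float), axis=0) / 2.0


def build_G(M: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
    """VanRaden's first-method genomic relationship matrix.

    G = Z Z' / (2 sum p_j (1 - p_j)) with Z = M - 2p.  Monomorphic SNPs are
    rejected: they carry no information and break the scaling.
    """
    M = np.asarray(M, float)
    if p is None:
        p = allele_frequencies(M)
    p = np.asarray(p, float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = int(np.sum((p <= 0.0) | (p >= 1.0)))
        raise ValueError(
            f"{bad} monomorphic SNP(s) present; run QC before building G"
        )
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    return 0.5 * (G + G.T)


def blend_G(G: np.ndarray, A22: np.ndarray, eps: float = 0.05) -> np.ndarray:
    """G_b = (1-eps) G + eps A22; guarantees invertibility for small eps."""
    return (1.0 - eps) * G + eps * A22


@dataclass
class KinshipSet:
    """Bundle of relationship structures used by single-step evaluation."""

    ped: Pedigree
    genotyped_ids: np.ndarray
    Ainv: sp.csr_matrix
    A22: np.ndarray
    G: np.ndarray
    eps: float = 0.05

    @property
    def G_blended(self) -> np.ndarray:
        return blend_G(self.G, self.A22, self.eps)


def build_Hinv(kin: KinshipSet) -> sp.csr_matrix:
    """H^-1 = A^-1 + [0 0; 0 Gb^-1 - A22^-1] on the pedigree ordering."""
    n = len(kin.ped)
    idx = kin.ped.indices(kin.genotyped_ids)
    if len(idx) == 0:
        return kin.Ainv.copy()
    Gb = kin.G_blended
    try:
        Gb_inv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "blended G is singular; increase the blending weight eps"
        ) from e
    corr = Gb_inv - np.linalg.inv(kin.A22)
    C = sp.coo_matrix(
        (corr.ravel(), (np.repeat(idx, len(idx)), np.tile(idx, len(idx)))),
        shape=(n, n),
    )
    H = (kin.Ainv + C.tocsr()).tocsr()
    return 0.5 * (H + H.T)
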