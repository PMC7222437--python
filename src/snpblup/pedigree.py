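"""Pedigree-derived sparse operators.

Builds the inverse pedigree relationship matrix by Henderson's recursive
rules, the ancestor-restricted blocks used to apply the inverse of the
genotyped-animal relationship submatrix and the absorption matrix Q, the
directly-constructed correction matrix Delta, and a stochastic estimator for
the diagonal of the genotyped-submatrix inverse.

Conventions: animals are topologically sorted (parents before offspring),
``sire``/``dam`` hold 1-based parent ids with 0 meaning unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .crs3 import SparseSymCRS3

__all__ = [
    "Pedigree",
    "PedigreeOperators",
    "load_pedigree",
    "build_a_inverse",
    "tabular_relationship",
    "extract_ancestor_blocks",
    "build_delta",
    "q_matmat",
    "agg_inv_matmat",
    "mc_diag_agg_inverse",
    "count_genotyped_parent_links",
]


# ---------------------------------------------------------------------- #
# Pedigree container
# ---------------------------------------------------------------------- #
@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    ``sire[i]``/``dam[i]`` are 1-based ids of the parents of animal ``i``
    (0-based index), with 0 for an unknown parent.  Parents must precede
    their offspring.
    """

    n: int
    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray
    original_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        if self.original_id is None:
            self.original_id = np.arange(1, self.n + 1).astype(str)
        self.validate()

    def validate(self) -> None:
        for name, p in (("sire", self.sire), ("dam", self.dam)):
            if p.shape != (self.n,):
                raise ValueError(f"{name} must have length n")
            if np.any(p < 0) or np.any(p > self.n):
                raise ValueError(f"{name} contains an id out of range")
            # parent id (1-based) must be strictly below own 1-based id
            own = np.arange(1, self.n + 1)
            if np.any(p >= own):
                raise ValueError("pedigree is not topologically sorted (parent does not precede offspring)")
        if self.genotyped.shape != (self.n,):
            raise ValueError("genotyped must have length n")

    @property
    def sire0(self) -> np.ndarray:
        """0-based sire index, -1 for unknown."""
        return self.sire - 1

    @property
    def dam0(self) -> np.ndarray:
        return self.dam - 1

    @property
    def n_genotyped(self) -> int:
        return int(self.genotyped.sum())

    @property
    def genotyped_index(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped)

    @property
    def nongenotyped_index(self) -> np.ndarray:
        return np.flatnonzero(~self.genotyped)


def load_pedigree(path, sep=None, genotyped_ids=None):
    """Load a delimited pedigree file (animal, sire, dam[, genotyped]).

    Unknown parents are coded 0 or NA.  Rows are renumbered to a topological
    order.  Returns ``(Pedigree, id_map)`` where ``id_map`` maps original
    labels to 0-based internal indices.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+|,|\t", engine="python", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs at least 3 columns: animal, sire, dam")
    cols = list(df.columns)
    animal = df[cols[0]].astype(str).to_numpy()
    sire_lab = df[cols[1]].fillna("0").astype(str).to_numpy()
    dam_lab = df[cols[2]].fillna("0").astype(str).to_numpy()
    geno_col = df[cols[3]].astype(str).to_numpy() if df.shape[1] >= 4 else None

    unknown = {"0", "NA", "na", ".", "", "nan"}
    if len(set(animal)) != len(animal):
        raise ValueError("duplicate animal ids in pedigree")
    pos = {a: i for i, a in enumerate(animal)}
    for lab in np.concatenate([sire_lab, dam_lab]):
        if lab not in unknown and lab not in pos:
            raise ValueError(f"parent id {lab!r} not present as an animal")

    # Kahn topological sort on parent -> offspring edges
    n = len(animal)
    parents = [
        [pos[p] for p in (sire_lab[i], dam_lab[i]) if p not in unknown]
        for i in range(n)
    ]
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, ps in enumerate(parents):
        for p in ps:
            children[p].append(i)
            indeg[i] += 1
    order: list[int] = []
    stack = [i for i in range(n) if indeg[i] == 0]
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        raise ValueError("pedigree contains a cycle (an animal is its own ancestor)")

    new_pos = {old: new for new, old in enumerate(order)}
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    geno = np.zeros(n, dtype=bool)
    orig = np.empty(n, dtype=object)
    for old, new in new_pos.items():
        orig[new] = animal[old]
        s, d = sire_lab[old], dam_lab[old]
        sire[new] = 0 if s in unknown else new_pos[pos[s]] + 1
        dam[new] = 0 if d in unknown else new_pos[pos[d]] + 1
        if geno_col is not None:
            geno[new] = geno_col[old] in {"1", "T", "True", "true"}
    if genotyped_ids is not None:
        gset = set(map(str, genotyped_ids))
        for new in range(n):
            if orig[new] in gset:
                geno[new] = True
    ped = Pedigree(n=n, sire=sire, dam=dam, genotyped=geno, original_id=orig.astype(str))
    id_map = {str(a): new_pos[pos[str(a)]] for a in animal}
    return ped, id_map


# ---------------------------------------------------------------------- #
# Henderson's rules
# ---------------------------------------------------------------------- #
def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense relationship matrix A by the tabular recursion (oracle-grade,
    O(n^2) memory; intended for small pedigrees and the inbreeding flag)."""
    n = ped.n
    a = np.zeros((n, n))
    s0, d0 = ped.sire0, ped.dam0
    for i in range(n):
        s, d = s0[i], d0[i]
        if s >= 0 and d >= 0:
            a[i, i] = 1.0 + 0.5 * a[s, d]
        else:
            a[i, i] = 1.0
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * a[s]
        if d >= 0:
            row += 0.5 * a[d]
        a[i, :i] = row[:i]
        a[:i, i] = row[:i]
    return a


def _mendelian_alpha(ped: Pedigree, account_inbreeding: bool) -> np.ndarray:
    """Per-animal Mendelian-sampling precision (1 / sampling variance)."""
    s0, d0 = ped.sire0, ped.dam0
    if not account_inbreeding:
        both = (s0 >= 0) & (d0 >= 0)
        one = (s0 >= 0) ^ (d0 >= 0)
        alpha = np.ones(ped.n)
        alpha[both] = 2.0
        alpha[one] = 4.0 / 3.0
        return alpha
    if ped.n > 20000:
        raise ValueError("inbreeding-aware build uses the dense tabular recursion; pedigree too large")
    f = np.diag(tabular_relationship(ped)) - 1.0
    d = np.empty(ped.n)
    for i in range(ped.n):
        s, dd = s0[i], d0[i]
        if s >= 0 and dd >= 0:
            d[i] = 0.5 - 0.25 * (f[s] + f[dd])
        elif s >= 0 or dd >= 0:
            p = s if s >= 0 else dd
            d[i] = 0.75 - 0.25 * f[p]
        else:
            d[i] = 1.0
    return 1.0 / d


def build_a_inverse(ped: Pedigree, account_inbreeding: bool = False) -> SparseSymCRS3:
    """Inverse of the pedigree relationship matrix in upper-triangular CRS3.

    Per animal at most 3 diagonal and 3 off-diagonal contributions are added,
    so the stored upper triangle holds at most ``4n`` nonzeros.
    """
    ped.validate()
    alpha = _mendelian_alpha(ped, account_inbreeding)
    s0, d0 = ped.sire0, ped.dam0
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(ped.n):
        entries = [(i, 1.0)]
        if s0[i] >= 0:
            entries.append((int(s0[i]), -0.5))
        if d0[i] >= 0:
            entries.append((int(d0[i]), -0.5))
        a = alpha[i]
        for k in range(len(entries)):
            for l in range(k, len(entries)):
                p, cp = entries[k]
                q, cq = entries[l]
                v = a * cp * cq
                # a cross pair between two distinct entries that share an
                # index (sire == dam) lands on the diagonal from both sides
                if k != l and p == q:
                    v *= 2.0
                lo, hi = (p, q) if p <= q else (q, p)
                rows.append(lo)
                cols.append(hi)
                vals.append(v)
    m = SparseSymCRS3.from_coo(ped.n, rows, cols, vals)
    if m.nnz > 4 * ped.n:
        raise AssertionError("CRS3 nonzero bound 4n violated")
    return m


def count_genotyped_parent_links(ped: Pedigree) -> int:
    """Number of (parent, offspring) links whose parent is genotyped.

    An offspring of two genotyped parents contributes two links."""
    g = ped.genotyped
    n_off = 0
    for p in (ped.sire0, ped.dam0):
        known = p >= 0
        n_off += int(g[p[known]].sum())
    return n_off


def count_genotyped_parent_offspring(ped: Pedigree) -> int:
    """Alternative convention: distinct offspring with >=1 genotyped parent."""
    g = ped.genotyped
    s, d = ped.sire0, ped.dam0
    has = ((s >= 0) & g[np.clip(s, 0, None)]) | ((d >= 0) & g[np.clip(d, 0, None)])
    return int(has.sum())


# ---------------------------------------------------------------------- #
# Ancestor-restricted blocks, Delta and Q
# ---------------------------------------------------------------------- #
def _ancestor_mask(ped: Pedigree) -> np.ndarray:
    """Genotyped animals and all their ancestors."""
    mask = ped.genotyped.copy()
    s0, d0 = ped.sire0, ped.dam0
    # reverse pass suffices on a topologically sorted pedigree
    for i in range(ped.n - 1, -1, -1):
        if mask[i]:
            if s0[i] >= 0:
                mask[s0[i]] = True
            if d0[i] >= 0:
                mask[d0[i]] = True
    return mask


def build_delta(ped: Pedigree) -> SparseSymCRS3:
    """Correction matrix over genotyped animals.

    Holds the inverse-relationship contributions, restricted to genotyped x
    genotyped positions, of non-genotyped offspring that are not ancestors of
    any genotyped animal.  Constructed in a single pedigree pass; equals the
    gg block of the full inverse minus the gg block of the ancestor-restricted
    inverse.
    """
    anc = _ancestor_mask(ped)
    g = ped.genotyped
    gpos = -np.ones(ped.n, dtype=np.int64)
    gpos[g] = np.arange(g.sum())
    alpha = _mendelian_alpha(ped, account_inbreeding=False)
    s0, d0 = ped.sire0, ped.dam0
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(ped.n):
        if anc[i]:
            continue  # genotyped or ancestor of a genotyped animal
        parents = [p for p in (int(s0[i]), int(d0[i])) if p >= 0 and g[p]]
        a = alpha[i]
        for k in range(len(parents)):
            for l in range(k, len(parents)):
                p, q = parents[k], parents[l]
                v = a * 0.25
                if k != l and p == q:  # sire == dam, both sides on diagonal
                    v *= 2.0
                lo, hi = (gpos[p], gpos[q]) if gpos[p] <= gpos[q] else (gpos[q], gpos[p])
                rows.append(int(lo))
                cols.append(int(hi))
                vals.append(v)
    n_g = int(g.sum())
    return SparseSymCRS3.from_coo(n_g, rows, cols, vals)


@dataclass
class PedigreeOperators:
    """All pedigree-derived operators needed by the single-step systems."""

    ped: Pedigree
    a_inv_full: SparseSymCRS3
    anc_index: np.ndarray                 # animal indices: genotyped + ancestors
    a_gg_anc: sp.csr_matrix
    a_gn_anc: sp.csr_matrix
    a_nn_anc: sp.csr_matrix | None
    delta: SparseSymCRS3
    solver_nn_anc: object | None = field(default=None, repr=False)
    # blocks of the full-pedigree inverse, partitioned by genotype status
    a_nn: sp.csr_matrix = field(default=None, repr=False)
    a_ng: sp.csr_matrix = field(default=None, repr=False)
    a_gg_blk: sp.csr_matrix = field(default=None, repr=False)
    _solver_nn_full: object | None = field(default=None, repr=False)

    @property
    def n_g(self) -> int:
        return self.ped.n_genotyped

    # -- A_gg^{-1} (inverse of the genotyped submatrix of A) ------------ #
    def agg_inv_matmat(self, v: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(v, dtype=np.float64).T).T
        out = self.a_gg_anc @ v
        if self.a_nn_anc is not None and self.a_nn_anc.shape[0] > 0:
            out = out - self.a_gn_anc @ self.solver_nn_anc(self.a_gn_anc.T @ v)
        return out

    # -- Q = A^{gn}(A^{nn})^{-1}A^{ng} ---------------------------------- #
    def q_matmat(self, v: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(v, dtype=np.float64).T).T
        out = self.delta.matmat(v)
        if self.a_nn_anc is not None and self.a_nn_anc.shape[0] > 0:
            out = out + self.a_gn_anc @ self.solver_nn_anc(self.a_gn_anc.T @ v)
        return out

    # -- helper solves against the full-pedigree nn block --------------- #
    def solve_nn_full(self, rhs: np.ndarray) -> np.ndarray:
        if self._solver_nn_full is None:
            self._solver_nn_full = spla.factorized(self.a_nn.tocsc())
        rhs = np.asarray(rhs, dtype=np.float64)
        if rhs.ndim == 1:
            return self._solver_nn_full(rhs)
        return np.column_stack([self._solver_nn_full(rhs[:, k]) for k in range(rhs.shape[1])])

    def agg_diag(self) -> np.ndarray:
        """Diagonal of the gg block of the full-pedigree inverse."""
        return np.asarray(self.a_gg_blk.diagonal())


def extract_ancestor_blocks(ped: Pedigree, account_inbreeding: bool = False) -> PedigreeOperators:
    """Build every pedigree operator used by the single-step systems.

    The ancestor-restricted inverse is built over genotyped animals and their
    ancestors only, partitioned into gg/gn/nn blocks, and the nn block is
    factorized once for reuse.
    """
    if ped.n_genotyped == 0:
        raise ValueError("no genotyped animals in pedigree")
    a_inv_full = build_a_inverse(ped, account_inbreeding)
    full_sym = a_inv_full.to_symmetric_csr()
    gidx = ped.genotyped_index
    nidx = ped.nongenotyped_index
    a_nn = full_sym[nidx][:, nidx].tocsr()
    a_ng = full_sym[nidx][:, gidx].tocsr()
    a_gg_blk = full_sym[gidx][:, gidx].tocsr()

    anc_mask = _ancestor_mask(ped)
    anc_index = np.flatnonzero(anc_mask)
    # restricted pedigree is closed under parents, and keeps topological order
    remap = -np.ones(ped.n, dtype=np.int64)
    remap[anc_index] = np.arange(len(anc_index))
    s0, d0 = ped.sire0, ped.dam0
    sire_anc = np.where(s0[anc_index] >= 0, remap[np.clip(s0[anc_index], 0, None)] + 1, 0)
    dam_anc = np.where(d0[anc_index] >= 0, remap[np.clip(d0[anc_index], 0, None)] + 1, 0)
    ped_anc = Pedigree(
        n=len(anc_index),
        sire=sire_anc,
        dam=dam_anc,
        genotyped=ped.genotyped[anc_index],
        original_id=ped.original_id[anc_index],
    )
    a_inv_anc = build_a_inverse(ped_anc, account_inbreeding).to_symmetric_csr()
    g_anc = np.flatnonzero(ped_anc.genotyped)
    n_anc = np.flatnonzero(~ped_anc.genotyped)
    a_gg_anc = a_inv_anc[g_anc][:, g_anc].tocsr()
    a_gn_anc = a_inv_anc[g_anc][:, n_anc].tocsr()
    a_nn_anc = a_inv_anc[n_anc][:, n_anc].tocsr() if len(n_anc) else None

    solver = None
    if a_nn_anc is not None and a_nn_anc.shape[0] > 0:
        lu = spla.splu(a_nn_anc.tocsc())

        def solver(rhs, _lu=lu):  # noqa: E731 - small closure
            rhs = np.asarray(rhs, dtype=np.float64)
            return _lu.solve(rhs)

    delta = build_delta(ped)
    return PedigreeOperators(
        ped=ped,
        a_inv_full=a_inv_full,
        anc_index=anc_index,
        a_gg_anc=a_gg_anc,
        a_gn_anc=a_gn_anc,
        a_nn_anc=a_nn_anc,
        delta=delta,
        solver_nn_anc=solver,
        a_nn=a_nn,
        a_ng=a_ng,
        a_gg_blk=a_gg_blk,
    )


def q_matmat(ops: PedigreeOperators, v: np.ndarray) -> np.ndarray:
    return ops.q_matmat(v)


def agg_inv_matmat(ops: PedigreeOperators, v: np.ndarray) -> np.ndarray:
    return ops.agg_inv_matmat(v)


def mc_diag_agg_inverse(ops: PedigreeOperators, n_samples: int = 1000, seed: int = 0) -> np.ndarray:
    """Hutchinson estimate of the diagonal of the genotyped-submatrix inverse.

    Uses Rademacher probes: ``diag ~ (1/s) sum_k (A_gg^{-1} z_k) o z_k``.
    Deterministic for a given seed; exact when n_g = 1.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n_g = ops.n_g
    acc = np.zeros(n_g)
    chunk = 64
    done = 0
    while done < n_samples:
        k = min(chunk, n_samples - done)
        z = rng.integers(0, 2, size=(n_g, k)).astype(np.float64) * 2.0 - 1.0
        acc += np.einsum("ik,ik->i", ops.agg_inv_matmat(z), z)
        done += k
    return acc / n_samples
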