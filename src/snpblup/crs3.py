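"""Three-array compressed-row storage (CRS3) for sparse symmetric matrices.

Only the upper triangle (``j >= i``) is stored.  The three arrays are the
classic CRS triplet: ``IA`` (row pointers, 4-byte integers), ``JA`` (column
indices, 4-byte integers) and ``AA`` (values, 8-byte reals).  The symmetric
matrix-vector product uses every off-diagonal entry twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["SparseSymCRS3", "crs3_bound_bytes"]


def crs3_bound_bytes(n: int) -> int:
    """Upper bound in bytes for storing the upper triangle of a pedigree
    relationship inverse for ``n`` animals in CRS3 form.

    At most ``4n`` nonzeros are stored (``n`` diagonal plus ``3n``
    off-diagonal entries), giving ``4(n+1) + 4*4n + 8*4n = 52n + 4`` bytes.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    return 52 * n + 4


@dataclass
class SparseSymCRS3:
    """Symmetric sparse matrix, upper triangle in 3-array CRS form."""

    n_rows: int
    IA: np.ndarray
    JA: np.ndarray
    AA: np.ndarray
    _sym: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.IA = np.asarray(self.IA, dtype=np.int32)
        self.JA = np.asarray(self.JA, dtype=np.int32)
        self.AA = np.asarray(self.AA, dtype=np.float64)
        if self.IA.shape != (self.n_rows + 1,):
            raise ValueError("IA must have length n_rows + 1")
        if self.IA[0] != 0 or self.IA[-1] != len(self.JA) or len(self.JA) != len(self.AA):
            raise ValueError("inconsistent CRS3 arrays")
        if np.any(np.diff(self.IA) < 0):
            raise ValueError("IA must be non-decreasing")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_coo(cls, n: int, rows, cols, vals) -> "SparseSymCRS3":
        """Build from COO triplets of the upper triangle; duplicates are summed.

        Entries with ``col < row`` are mirrored into the upper triangle.
        """
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals, dtype=np.float64)
        lo = cols < rows
        r = np.where(lo, cols, rows)
        c = np.where(lo, rows, cols)
        m = sp.coo_matrix((vals, (r, c)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        m.eliminate_zeros()
        m.sort_indices()
        return cls(n, m.indptr.astype(np.int32), m.indices.astype(np.int32), m.data)

    @classmethod
    def from_dense(cls, a: np.ndarray, tol: float = 0.0) -> "SparseSymCRS3":
        a = np.asarray(a, dtype=np.float64)
        n = a.shape[0]
        iu, ju = np.triu_indices(n)
        v = a[iu, ju]
        keep = np.abs(v) > tol
        return cls.from_coo(n, iu[keep], ju[keep], v[keep])

    # ------------------------------------------------------------------ #
    @property
    def nnz(self) -> int:
        return int(self.IA[-1])

    def upper_csr(self) -> sp.csr_matrix:
        return sp.csr_matrix((self.AA, self.JA, self.IA), shape=(self.n_rows, self.n_rows))

    def to_symmetric_csr(self) -> sp.csr_matrix:
        if self._sym is None:
            u = self.upper_csr()
            d = sp.diags(u.diagonal())
            self._sym = (u + u.T - d).tocsr()
        return self._sym

    def diagonal(self) -> np.ndarray:
        return self.upper_csr().diagonal()

    def toarray(self) -> np.ndarray:
        return self.to_symmetric_csr().toarray()

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.to_symmetric_csr() @ np.asarray(v)

    def matmat(self, v: np.ndarray) -> np.ndarray:
        return self.to_symmetric_csr() @ np.asarray(v)

    def memory_bytes(self) -> int:
        """Actual CRS3 footprint with 4-byte integers and 8-byte reals."""
        return 4 * len(self.IA) + 4 * self.nnz + 8 * self.nnz
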