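"""Block-diagonal preconditioner, second-level diagonal, PCG, and Lanczos
extreme-eigenvalue estimation from the PCG coefficients.

The preconditioner M has three parts: a plain diagonal for the designated
large fixed effect (f1), small symmetric blocks (one per random-effect
level, coupling the trait/type channels of that level), and a factorized
sparse block with a 1e-4 diagonal ridge for the remaining fixed effects
(f2).  A second-level diagonal D scales the SNP-effect equations by a
constant (default 1e3 for the ms system, 1e2 for the liu system) and leaves
every other equation untouched, so D is constant within each block of M and
``D^{-1} M^{-1}`` stays usable as a symmetric preconditioner.

The genotyped-animal and SNP parts of M use the approximations: the
diagonal of the genotyped-submatrix inverse comes from a Monte-Carlo
estimator, the j-th SNP diagonal of Z'A_gg^{-1}Z is taken as
``2 n_g p_j (1-p_j)`` and that of Z'QZ as ``(2 n_g + n_offspring) p_j
(1-p_j)``; pass ``exact=True`` to replace all three by exact computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .genotypes import z_weighted_sq_colsums
from .model import SsSnpBlupSystem
from .pedigree import count_genotyped_parent_links, mc_diag_agg_inverse

__all__ = [
    "Preconditioner",
    "SecondLevelD",
    "SolveReport",
    "build_preconditioner",
    "apply_two_level",
    "pcg_solve",
    "lanczos_extremes",
]


@dataclass
class Preconditioner:
    """Approximate block-diagonal of the coefficient matrix, factorized."""

    n: int
    f1_slice: slice | None
    diag_f1: np.ndarray | None
    f2_index: np.ndarray | None
    solve_f2: object | None
    block_segments: list = field(default_factory=list)
    # each segment: (slice, inv_blocks) with inv_blocks shape (levels, d, d)
    precision: str = "double"

    def apply(self, r: np.ndarray) -> np.ndarray:
        z = np.zeros_like(r)
        if self.f1_slice is not None:
            z[self.f1_slice] = r[self.f1_slice] / self.diag_f1
        if self.f2_index is not None and len(self.f2_index):
            z[self.f2_index] = self.solve_f2(r[self.f2_index])
        for sl, inv in self.block_segments:
            d = inv.shape[1]
            seg = r[sl].reshape(-1, d)
            z[sl] = np.einsum("lij,lj->li", inv, seg).reshape(-1)
        return z

    def multiply(self, x: np.ndarray) -> np.ndarray:
        """M @ x (inverse of apply; used for verification only)."""
        y = np.zeros_like(x)
        if self.f1_slice is not None:
            y[self.f1_slice] = x[self.f1_slice] * self.diag_f1
        if self.f2_index is not None and len(self.f2_index):
            y[self.f2_index] = self._f2_mat @ x[self.f2_index]
        for sl, inv in self.block_segments:
            d = inv.shape[1]
            blocks = np.linalg.inv(inv)
            seg = x[sl].reshape(-1, d)
            y[sl] = np.einsum("lij,lj->li", blocks, seg).reshape(-1)
        return y


@dataclass
class SecondLevelD:
    """Diagonal second-level preconditioner: a constant on SNP-effect
    equations, one everywhere else."""

    n: int
    snp_slice: slice | None
    d_snp: float = 1.0

    @classmethod
    def for_system(cls, system: SsSnpBlupSystem, d_snp: float | None = None) -> "SecondLevelD":
        if d_snp is None:
            d_snp = 1e3 if system.variant == "ms" else 1e2
        em = system.emap
        return cls(n=em.n_total, snp_slice=slice(em.snp_offset, em.n_total), d_snp=float(d_snp))

    @classmethod
    def identity(cls, n: int) -> "SecondLevelD":
        return cls(n=n, snp_slice=None, d_snp=1.0)

    def apply_inv(self, r: np.ndarray) -> np.ndarray:
        z = r.copy()
        if self.snp_slice is not None and self.d_snp != 1.0:
            z[self.snp_slice] /= self.d_snp
        return z


@dataclass
class SolveReport:
    solution: np.ndarray
    n_iter: int
    rel_residuals: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray
    converged: bool
    rel_residual_true: float = np.nan
    eig_min: float = np.nan
    eig_max: float = np.nan
    cond: float = np.nan


def _invert_blocks(blocks: np.ndarray, what: str) -> np.ndarray:
    try:
        np.linalg.cholesky(blocks)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"non-positive-definite preconditioner block in {what}") from exc
    return np.linalg.inv(blocks)


def build_preconditioner(system: SsSnpBlupSystem, mc_samples: int = 1000, seed: int = 0,
                         exact: bool = False, precision: str = "double") -> Preconditioner:
    """Assemble and factorize M for an assembled system.

    ``exact=True`` computes the genotyped-animal and SNP diagonals exactly
    (dense-cost; intended for small systems and convergence audits).
    """
    spec, em, ops = system.spec, system.emap, system.ped_ops
    t, q = spec.n_traits, spec.q
    w, m = spec.w, system.m
    g0i = system.g0_inv
    dd = system.ls_data_diag()  # LS-domain exact data diagonal

    # -- f1 / f2 split of the fixed block ------------------------------- #
    f1_name = spec.large_fixed_effect
    if f1_name is None and spec.fixed_class_effects:
        f1_name = max(spec.fixed_class_effects, key=lambda e: system.records.n_levels[e])
    f1_slice = None
    diag_f1 = None
    f2_index_parts = []
    for eff in spec.fixed_class_effects:
        o = em.class_offsets[eff]
        size = system.records.n_levels[eff] * t
        if eff == f1_name:
            f1_slice = slice(o, o + size)
        else:
            f2_index_parts.append(np.arange(o, o + size))
    for cov in spec.fixed_covariates:
        o = em.cov_offsets[cov]
        f2_index_parts.append(np.arange(o, o + t))
    if em.j_offset is not None:
        f2_index_parts.append(np.arange(em.j_offset, em.j_offset + q))
    if f1_slice is not None:
        diag_f1 = dd[f1_slice].astype(np.float32 if precision == "single" else np.float64)
        if np.any(diag_f1 <= 0):
            raise ValueError("non-positive diagonal in the f1 fixed-effect block")
    f2_index = np.concatenate(f2_index_parts) if f2_index_parts else np.array([], dtype=np.int64)

    solve_f2 = None
    f2_mat = None
    if len(f2_index):
        c_f2 = system.c_ls[f2_index][:, f2_index].tocsc()
        dg = np.asarray(c_f2.diagonal())
        if np.any(dg <= 0):
            raise ValueError("non-positive diagonal in the f2 fixed-effect block")
        c_f2 = c_f2 + sp.diags(1e-4 * dg)
        lu = spla.splu(c_f2.tocsc())
        solve_f2 = lu.solve
        f2_mat = c_f2

    segments = []

    def data_diag_blocks(sl_ls, n_lev, d):
        """Per-level diagonal data blocks from the LS-domain diagonal."""
        out = np.zeros((n_lev, d, d))
        vals = dd[sl_ls].reshape(n_lev, d)
        idx = np.arange(d)
        out[:, idx, idx] = vals
        return out

    # -- extra random effects (e.g. permanent environment) -------------- #
    for eff, p0inv in system.p0_invs.items():
        n_lev = system.records.n_levels[eff]
        if n_lev == 0:
            continue
        o = em.extra_offsets[eff]
        sl = slice(o, o + n_lev * t)
        blocks = data_diag_blocks(sl, n_lev, t) + p0inv[None]
        segments.append((sl, _invert_blocks(blocks, f"extra effect {eff!r}")))

    # -- non-genotyped animals ------------------------------------------ #
    if em.n_n:
        sl = slice(em.un_offset, em.geno_offset)
        ann_diag = np.asarray(ops.a_nn.diagonal())
        blocks = data_diag_blocks(sl, em.n_n, q) + ann_diag[:, None, None] * g0i[None]
        segments.append((sl, _invert_blocks(blocks, "non-genotyped animal block")))

    # -- genotyped animals ---------------------------------------------- #
    agg_diag = ops.agg_diag()  # gg block of the full-pedigree inverse
    if exact:
        aggi_diag = np.diag(ops.agg_inv_matmat(np.eye(em.n_g)))
    else:
        aggi_diag = mc_diag_agg_inverse(ops, n_samples=mc_samples, seed=seed)
    if em.n_g:
        sl = slice(em.geno_offset, em.snp_offset)
        if system.variant == "ms":
            # (1/w) A^gg + (1 - 1/w) Q, with diag(Q) = diag(A^gg) - diag(A_gg^{-1})
            prior = agg_diag / w + (1.0 - 1.0 / w) * (agg_diag - aggi_diag)
        else:
            prior = agg_diag + (1.0 / w - 1.0) * aggi_diag
        blocks = data_diag_blocks(sl, em.n_g, q) + prior[:, None, None] * g0i[None]
        segments.append((sl, _invert_blocks(blocks, "genotyped animal block")))

    # -- SNP effects ----------------------------------------------------- #
    p = system.centering.p
    pq = p * (1.0 - p)
    if exact:
        dos = system.geno.dosages().astype(np.float64)
        miss = dos < 0
        z_dense = dos - 2.0 * p[None, :]
        z_dense[miss] = 0.0
        if system.variant == "ms":
            core = ops.q_matmat(z_dense)
        else:
            core = ops.agg_inv_matmat(z_dense)
        quad = np.einsum("kj,kj->j", z_dense, core)
    else:
        if system.variant == "ms":
            n_off = count_genotyped_parent_links(ops.ped)
            quad = (2.0 * em.n_g + n_off) * pq
        else:
            quad = 2.0 * em.n_g * pq
    if system.variant == "ms":
        prior_snp = quad + m / (1.0 - w)
    else:
        prior_snp = quad / w + m / (1.0 - w)

    sl = slice(em.snp_offset, em.n_total)
    blocks = prior_snp[:, None, None] * g0i[None]
    if system.variant == "ms":
        # exact data part diag(Z'W_g'R_g^{-1}W_gZ), per channel, blocked pass
        dd_h = dd[em.h_offset:em.n_ls].reshape(em.n_g, q)
        snp_dd = np.column_stack([
            z_weighted_sq_colsums(system.geno, system.centering, dd_h[:, ch])
            for ch in range(q)
        ])
        idx = np.arange(q)
        blocks = blocks.copy()
        blocks[:, idx, idx] += snp_dd
    segments.append((sl, _invert_blocks(blocks, "SNP block")))

    if precision == "single":
        segments = [(sl, inv.astype(np.float32)) for sl, inv in segments]

    pre = Preconditioner(
        n=em.n_total, f1_slice=f1_slice, diag_f1=diag_f1,
        f2_index=f2_index, solve_f2=solve_f2, block_segments=segments,
        precision=precision,
    )
    pre._f2_mat = f2_mat
    return pre


def apply_two_level(m: Preconditioner, d: SecondLevelD, r: np.ndarray) -> np.ndarray:
    """z = D^{-1} M^{-1} r."""
    r = np.asarray(r, dtype=np.float64)
    if r.shape != (m.n,):
        raise ValueError("residual length does not match the preconditioner layout")
    return d.apply_inv(m.apply(r))


class _IdentityPre:
    def apply(self, r):
        return r


def pcg_solve(system, b: np.ndarray | None = None, m: Preconditioner | None = None,
              d: SecondLevelD | None = None, tol: float = 1e-6,
              max_iter: int = 10000, true_res_every: int = 100) -> SolveReport:
    """Preconditioned conjugate gradients with a two-level preconditioner.

    ``system`` is either an assembled system (``b`` defaults to its
    right-hand side) or any object/callable providing a matvec.  Starts from
    x0 = 0; terminates when the recursive residual satisfies
    ``||r_k|| / ||b|| < tol`` (the true residual is recomputed every
    ``true_res_every`` iterations and at termination to guard drift).
    """
    if callable(system) and not hasattr(system, "matvec"):
        matvec = system
    else:
        matvec = system.matvec
        if b is None:
            b = system.b
    b = np.asarray(b, dtype=np.float64)
    n = len(b)
    if m is None:
        m = _IdentityPre()
    if d is None:
        d = SecondLevelD.identity(n)

    def precond(r):
        return d.apply_inv(m.apply(r))

    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return SolveReport(np.zeros(n), 0, np.array([]), np.array([]), np.array([]),
                           converged=True, rel_residual_true=0.0)

    x = np.zeros(n)
    r = b.copy()
    z = precond(r)
    p = z.copy()
    rz = float(r @ z)
    alphas: list[float] = []
    betas: list[float] = []
    rels: list[float] = []
    converged = False
    k = 0
    while k < max_iter:
        q = matvec(p)
        pq = float(p @ q)
        if pq <= 0.0:
            raise RuntimeError(
                f"indefinite preconditioned operator detected at iteration {k} (p'Cp = {pq:g})"
            )
        alpha = rz / pq
        x += alpha * p
        r -= alpha * q
        k += 1
        if true_res_every and k % true_res_every == 0:
            r = b - matvec(x)
        rel = float(np.linalg.norm(r) / bnorm)
        alphas.append(alpha)
        rels.append(rel)
        if rel < tol:
            converged = True
            break
        z = precond(r)
        rz_new = float(r @ z)
        betas.append(rz_new / rz)
        p = z + betas[-1] * p
        rz = rz_new

    true_rel = float(np.linalg.norm(b - matvec(x)) / bnorm)
    report = SolveReport(
        solution=x, n_iter=k, rel_residuals=np.array(rels),
        alphas=np.array(alphas), betas=np.array(betas),
        converged=converged, rel_residual_true=true_rel,
    )
    if k >= 1:
        lanczos_extremes(report)
    return report


def lanczos_extremes(report: SolveReport) -> tuple[float, float, float]:
    """Extreme eigenvalues of the preconditioned operator from the PCG
    coefficients, via the Lanczos tridiagonal

    ``T_kk = 1/alpha_k + beta_{k-1}/alpha_{k-1}`` (with beta_{-1} = 0) and
    ``T_{k,k+1} = sqrt(beta_k)/alpha_k``; the effective spectral condition
    number is their ratio.
    """
    nit = len(report.alphas)
    if nit < 1:
        raise ValueError("Lanczos estimates need at least 1 recorded iteration")
    a = report.alphas
    bt = report.betas
    diag = 1.0 / a
    diag[1:] += bt[: nit - 1] / a[: nit - 1]
    off = np.sqrt(bt[: nit - 1]) / a[: nit - 1]
    eigs = sla.eigh_tridiagonal(diag, off, eigvals_only=True)
    report.eig_min = float(eigs[0])
    report.eig_max = float(eigs[-1])
    report.cond = float(eigs[-1] / eigs[0])
    return report.eig_min, report.eig_max, report.cond
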