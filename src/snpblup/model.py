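"""Assembly of the two single-step SNP-BLUP systems as split operators.

Two equivalent parameterisations are supported:

* ``ms``  — solution vector [fixed | u_n | a_g | g] where a_g are residual
  polygenic effects of genotyped animals, and the coefficient matrix is
  applied as ``T'(C_LS + C_R1)T + C_R2``;
* ``liu`` — solution vector [fixed | u_n | u_g | g] with total genetic
  effects u_g = a_g + Z g, applied as ``C_LS + T'C_R1 T + C_R2``.

``T`` is identity except for the SNP block, which it maps through the
centered genotype matrix Z.  The least-squares part is materialised as an
in-memory sparse matrix; all relationship parts stay matrix-free.

Multi-trait maternal models use ``q = n_traits * n_types`` genetic channels
per level (types direct/maternal, channel order type-major, traits fastest);
every scalar inverse-variance in the univariate description generalises to
the q x q inverse genetic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genotypes import CenteringInfo, PackedGenotypes, z_matmat, zt_matmat
from .pedigree import PedigreeOperators

__all__ = [
    "ModelSpec",
    "RecordSet",
    "EquationMap",
    "SsSnpBlupSystem",
    "assemble_system",
    "j_covariates",
    "solutions_equivalent",
    "load_records",
]

DIRECT = "direct"
MATERNAL = "maternal"


def _check_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim == 0:
        mat = mat.reshape(1, 1)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc
    return mat


@dataclass
class ModelSpec:
    """Model structure and variance components.

    ``G0`` is the q x q genetic covariance across channels (a 1 x 1 array
    holding the additive variance in the univariate case), ``R0`` the
    per-trait residual variance (diagonal use only: each record carries one
    observed trait), ``w`` the residual polygenic fraction, strictly in
    (0, 1).  ``extra_random_effects`` maps effect name -> per-trait
    covariance (e.g. permanent environment).
    """

    traits: tuple
    genetic_effect_types: tuple
    G0: np.ndarray
    R0: np.ndarray
    w: float
    fixed_class_effects: tuple = ()
    large_fixed_effect: str | None = None
    fixed_covariates: tuple = ()
    extra_random_effects: dict = field(default_factory=dict)
    use_j_covariates: bool = True

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.genetic_effect_types = tuple(self.genetic_effect_types)
        if not set(self.genetic_effect_types) <= {DIRECT, MATERNAL}:
            raise ValueError("genetic effect types must be 'direct' and/or 'maternal'")
        if DIRECT not in self.genetic_effect_types:
            raise ValueError("a direct genetic effect is required")
        if not (0.0 < self.w < 1.0):
            raise ValueError("residual polygenic fraction w must be strictly between 0 and 1")
        self.G0 = _check_spd(self.G0, "G0")
        self.R0 = _check_spd(self.R0, "R0")
        q = len(self.traits) * len(self.genetic_effect_types)
        if self.G0.shape != (q, q):
            raise ValueError(f"G0 must be {q} x {q} (channels = types x traits)")
        if self.R0.shape != (len(self.traits),) * 2:
            raise ValueError("R0 must be n_traits x n_traits")
        self.extra_random_effects = {
            k: _check_spd(v, f"covariance of extra effect {k!r}")
            for k, v in self.extra_random_effects.items()
        }

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def q(self) -> int:
        return len(self.traits) * len(self.genetic_effect_types)

    @property
    def channels(self) -> list:
        """(type, trait) pairs, type-major, traits fastest."""
        return [(ty, tr) for ty in self.genetic_effect_types for tr in self.traits]

    def channel_index(self, eff_type: str, trait_idx: int) -> int:
        return self.genetic_effect_types.index(eff_type) * self.n_traits + trait_idx


@dataclass
class RecordSet:
    """Phenotype records.  Each record observes exactly one trait."""

    y: np.ndarray
    trait: np.ndarray                 # index into spec.traits
    animal: np.ndarray                # 0-based pedigree index (direct effect)
    dam: np.ndarray                   # 0-based pedigree index, -1 unknown
    class_levels: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    extra_levels: dict = field(default_factory=dict)
    n_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.trait = np.asarray(self.trait, dtype=np.int64)
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.y)
        for arr in (self.trait, self.animal, self.dam):
            if len(arr) != n:
                raise ValueError("record arrays must share a common length")
        for name, lev in {**self.class_levels, **self.extra_levels}.items():
            lev = np.asarray(lev, dtype=np.int64)
            if name not in self.n_levels:
                self.n_levels[name] = int(lev.max()) + 1 if len(lev) else 0
            if np.any(lev >= self.n_levels[name]) or np.any(lev < -1):
                raise ValueError(f"level code out of range for effect {name!r}")

    @property
    def n_records(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------- #
# Equation layout
# ---------------------------------------------------------------------- #
class EquationMap:
    """Contiguous index blocks [fixed+extra | u_n | a_g-or-u_g | g].

    Genetic levels carry q channels each (channel fastest); fixed class
    effects and extra random effects carry one equation per level per trait.
    """

    def __init__(self, spec: ModelSpec, records: RecordSet, n_n: int, n_g: int, n_snp: int):
        self.spec = spec
        t, q = spec.n_traits, spec.q
        off = 0
        self.class_offsets = {}
        for eff in spec.fixed_class_effects:
            self.class_offsets[eff] = off
            off += records.n_levels[eff] * t
        self.cov_offsets = {}
        for cov in spec.fixed_covariates:
            self.cov_offsets[cov] = off
            off += t
        self.j_offset = None
        if spec.use_j_covariates:
            self.j_offset = off
            off += q
        self.n_fixed = off
        self.extra_offsets = {}
        for eff in spec.extra_random_effects:
            self.extra_offsets[eff] = off
            off += records.n_levels[eff] * t
        self.n_nongenetic = off
        self.un_offset = off
        off += n_n * q
        self.geno_offset = off
        off += n_g * q
        self.snp_offset = off
        off += n_snp * q
        self.n_total = off
        self.n_n, self.n_g, self.n_snp = n_n, n_g, n_snp
        # least-squares domain: [nongenetic | u_n | geno | h], h = Z-mapped block
        self.h_offset = self.snp_offset
        self.n_ls = self.snp_offset + n_g * q

    # block views ------------------------------------------------------- #
    def un_mat(self, x):
        return x[self.un_offset:self.geno_offset].reshape(self.n_n, self.spec.q)

    def geno_mat(self, x):
        return x[self.geno_offset:self.snp_offset].reshape(self.n_g, self.spec.q)

    def snp_mat(self, x):
        return x[self.snp_offset:self.n_total].reshape(self.n_snp, self.spec.q)

    def h_mat(self, v1):
        return v1[self.h_offset:self.n_ls].reshape(self.n_g, self.spec.q)

    def extra_mat(self, x, eff, n_levels):
        o = self.extra_offsets[eff]
        return x[o:o + n_levels * self.spec.n_traits].reshape(n_levels, self.spec.n_traits)


# ---------------------------------------------------------------------- #
# J covariates
# ---------------------------------------------------------------------- #
def j_covariates(ped_ops: PedigreeOperators) -> np.ndarray:
    """Compatibility covariate: -1 on genotyped animals, and the solution of
    ``A^nn j_n = -A^ng j_g`` on non-genotyped animals.  Returns the length-n
    vector over all animals (shared by every genetic channel)."""
    ped = ped_ops.ped
    j = np.zeros(ped.n)
    j[ped.genotyped] = -1.0
    nidx = ped.nongenotyped_index
    if len(nidx):
        rhs = -(ped_ops.a_ng @ j[ped.genotyped_index])
        j[nidx] = ped_ops.solve_nn_full(rhs)
    return j


# ---------------------------------------------------------------------- #
# System
# ---------------------------------------------------------------------- #
@dataclass
class SsSnpBlupSystem:
    """Assembled matrix-free single-step system ``C x = b``."""

    variant: str
    spec: ModelSpec
    records: RecordSet
    emap: EquationMap
    ped_ops: PedigreeOperators
    geno: PackedGenotypes
    centering: CenteringInfo
    c_ls: sp.csr_matrix                 # least-squares part over the LS domain
    b: np.ndarray
    g0_inv: np.ndarray
    p0_invs: dict
    j_values: np.ndarray | None = None

    @property
    def n_equations(self) -> int:
        return self.emap.n_total

    @property
    def m(self) -> float:
        return self.centering.m

    # -- T and T' ------------------------------------------------------- #
    def apply_t(self, x: np.ndarray) -> np.ndarray:
        em = self.emap
        v1 = np.empty(em.n_ls)
        v1[:em.snp_offset] = x[:em.snp_offset]
        h = z_matmat(self.geno, self.centering, em.snp_mat(x))
        v1[em.h_offset:] = h.reshape(-1)
        return v1

    def apply_tt(self, v1: np.ndarray) -> np.ndarray:
        em = self.emap
        y = np.zeros(em.n_total)
        y[:em.snp_offset] = v1[:em.snp_offset]
        y[em.snp_offset:] = zt_matmat(self.geno, self.centering, em.h_mat(v1)).reshape(-1)
        return y

    # -- relationship parts --------------------------------------------- #
    def _r1_ms(self, v1: np.ndarray) -> np.ndarray:
        em, ops, g0i = self.emap, self.ped_ops, self.g0_inv
        w = self.spec.w
        un = em.un_mat(v1)
        ag = em.geno_mat(v1)
        h = em.h_mat(v1)
        qa = ops.q_matmat(ag)       # the only two Q products per matvec
        qh = ops.q_matmat(h)
        out = np.zeros(em.n_ls)
        em.un_mat(out)[:] = (ops.a_ng @ h) @ g0i
        em.geno_mat(out)[:] = ((1.0 - 1.0 / w) * qa + qh) @ g0i
        em.h_mat(out)[:] = (ops.a_ng.T @ un + qa + qh) @ g0i
        return out

    def _r1_liu(self, v1: np.ndarray) -> np.ndarray:
        em, ops, g0i = self.emap, self.ped_ops, self.g0_inv
        w = self.spec.w
        ug = em.geno_mat(v1)
        h = em.h_mat(v1)
        aiu = ops.agg_inv_matmat(ug)   # the only two A_gg^{-1} products
        aih = ops.agg_inv_matmat(h)
        out = np.zeros(em.n_ls)
        em.geno_mat(out)[:] = ((1.0 / w - 1.0) * aiu - aih / w) @ g0i
        em.h_mat(out)[:] = ((aih - aiu) / w) @ g0i
        return out

    def _r2(self, x: np.ndarray) -> np.ndarray:
        em, ops, g0i = self.emap, self.ped_ops, self.g0_inv
        w, m = self.spec.w, self.m
        un = em.un_mat(x)
        ag = em.geno_mat(x)
        g = em.snp_mat(x)
        out = np.zeros(em.n_total)
        em.un_mat(out)[:] = (ops.a_nn @ un + ops.a_ng @ ag) @ g0i
        gg_scale = 1.0 / w if self.variant == "ms" else 1.0
        em.geno_mat(out)[:] = (ops.a_ng.T @ un + gg_scale * (ops.a_gg_blk @ ag)) @ g0i
        em.snp_mat(out)[:] = (m / (1.0 - w)) * (g @ g0i)
        return out

    def _prior_extra(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros(self.emap.n_total)
        for eff, p0inv in self.p0_invs.items():
            n_lev = self.records.n_levels[eff]
            self.emap.extra_mat(out, eff, n_lev)[:] = self.emap.extra_mat(x, eff, n_lev) @ p0inv
        return out

    # -- full operator -------------------------------------------------- #
    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.emap.n_total,):
            raise ValueError(f"x must have length {self.emap.n_total}")
        em = self.emap
        if self.variant == "ms":
            v1 = self.apply_t(x)
            y = self.apply_tt(self.c_ls @ v1 + self._r1_ms(v1))
        else:
            # liu variant: least-squares part acts on the native solution vector
            # (its SNP rows and columns are structurally zero)
            ls_x = np.zeros(em.n_ls)
            ls_x[:em.snp_offset] = x[:em.snp_offset]
            y = np.zeros(em.n_total)
            y[:em.snp_offset] = (self.c_ls @ ls_x)[:em.snp_offset]
            y += self.apply_tt(self._r1_liu(self.apply_t(x)))
        y += self._r2(x) + self._prior_extra(x)
        return y

    def dense(self) -> np.ndarray:
        """Materialise C by applying the operator to identity columns
        (oracle/debug use only)."""
        n = self.emap.n_total
        c = np.empty((n, n))
        e = np.zeros(n)
        for k in range(n):
            e[k] = 1.0
            c[:, k] = self.matvec(e)
            e[k] = 0.0
        return c

    def linear_operator(self):
        import scipy.sparse.linalg as spla

        n = self.emap.n_total
        return spla.LinearOperator((n, n), matvec=self.matvec)

    # -- exact data diagonal (for the preconditioner) ------------------- #
    def ls_data_diag(self) -> np.ndarray:
        """Diagonal of the least-squares part over the LS domain."""
        return np.asarray(self.c_ls.diagonal())


# ---------------------------------------------------------------------- #
# Assembly
# ---------------------------------------------------------------------- #
def assemble_system(spec: ModelSpec, records: RecordSet, ped_ops: PedigreeOperators,
                    geno: PackedGenotypes, centering: CenteringInfo,
                    variant: str = "liu") -> SsSnpBlupSystem:
    """Build the split system for the requested variant ('ms' or 'liu')."""
    if variant not in ("ms", "liu"):
        raise ValueError("variant must be 'ms' or 'liu'")
    ped = ped_ops.ped
    if geno.n_g != ped.n_genotyped:
        raise ValueError("genotype store does not match the number of genotyped animals")
    if np.any(records.animal < 0) or np.any(records.animal >= ped.n):
        raise ValueError("record references an animal absent from the pedigree")
    if np.any(records.dam >= ped.n):
        raise ValueError("record references a dam absent from the pedigree")

    t, q = spec.n_traits, spec.q
    n_n, n_g, n_snp = ped.n - ped.n_genotyped, ped.n_genotyped, geno.n_snp
    emap = EquationMap(spec, records, n_n, n_g, n_snp)

    # positions of each animal inside its block
    npos = -np.ones(ped.n, dtype=np.int64)
    npos[ped.nongenotyped_index] = np.arange(n_n)
    gpos = -np.ones(ped.n, dtype=np.int64)
    gpos[ped.genotyped_index] = np.arange(n_g)

    j_vals = j_covariates(ped_ops) if spec.use_j_covariates else None

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    n_rec = records.n_records
    rec_idx = np.arange(n_rec)
    tr = records.trait

    def add(col_idx, value):
        rows.append(rec_idx)
        cols.append(np.asarray(col_idx, dtype=np.int64))
        vals.append(np.broadcast_to(np.asarray(value, dtype=np.float64), (n_rec,)).copy())

    def add_masked(mask, col_idx, value):
        rows.append(rec_idx[mask])
        cols.append(np.asarray(col_idx, dtype=np.int64)[mask])
        v = np.broadcast_to(np.asarray(value, dtype=np.float64), (n_rec,))[mask]
        vals.append(v.copy())

    for eff in spec.fixed_class_effects:
        # level -1 = reference level (no column), supporting treatment coding
        lev = np.asarray(records.class_levels[eff], dtype=np.int64)
        add_masked(lev >= 0, emap.class_offsets[eff] + np.clip(lev, 0, None) * t + tr, 1.0)
    for cov in spec.fixed_covariates:
        add(emap.cov_offsets[cov] + tr, records.covariates[cov])
    for eff in spec.extra_random_effects:
        lev = np.asarray(records.extra_levels[eff], dtype=np.int64)
        add_masked(lev >= 0, emap.extra_offsets[eff] + np.clip(lev, 0, None) * t + tr, 1.0)

    def genetic_cols(animal_idx, ch):
        """LS-domain column(s) of the genetic incidence for channel ch."""
        is_g = ped.genotyped[animal_idx]
        col = np.where(
            is_g,
            emap.geno_offset + gpos[animal_idx] * q + ch,
            emap.un_offset + npos[np.clip(animal_idx, 0, None)] * q + ch,
        )
        return col, is_g

    dam_known = records.dam >= 0
    for ty in spec.genetic_effect_types:
        carrier = records.animal if ty == DIRECT else records.dam
        mask = np.ones(n_rec, bool) if ty == DIRECT else dam_known
        ch = np.array([spec.channel_index(ty, ti) for ti in range(t)])[tr]
        safe = np.clip(carrier, 0, None)
        col, is_g = genetic_cols(safe, ch)
        add_masked(mask, col, 1.0)
        if variant == "ms":
            # genotyped carrier also loads the Z-mapped block (same incidence)
            hcol = emap.h_offset + gpos[safe] * q + ch
            add_masked(mask & is_g, hcol, 1.0)
        if spec.use_j_covariates:
            jv = j_vals[safe]
            add_masked(mask, emap.j_offset + ch, jv)

    w_ls = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rec, emap.n_ls),
    ).tocsr()
    r_diag = np.diag(spec.R0)
    rinv = 1.0 / r_diag[tr]
    c_ls = (w_ls.T @ sp.diags(rinv) @ w_ls).tocsr()
    b_ls = w_ls.T @ (rinv * records.y)

    b = np.zeros(emap.n_total)
    b[:emap.snp_offset] = b_ls[:emap.snp_offset]
    if variant == "ms":
        h_part = b_ls[emap.h_offset:].reshape(n_g, q)
        b[emap.snp_offset:] = zt_matmat(geno, centering, h_part).reshape(-1)
    # liu variant: SNP block of b is exactly zero

    g0_inv = np.linalg.inv(spec.G0)
    p0_invs = {k: np.linalg.inv(v) for k, v in spec.extra_random_effects.items()}
    return SsSnpBlupSystem(
        variant=variant, spec=spec, records=records, emap=emap, ped_ops=ped_ops,
        geno=geno, centering=centering, c_ls=c_ls, b=b, g0_inv=g0_inv,
        p0_invs=p0_invs, j_values=j_vals,
    )


# ---------------------------------------------------------------------- #
# Cross-variant equivalence
# ---------------------------------------------------------------------- #
def solutions_equivalent(ms_system: SsSnpBlupSystem, ms_x: np.ndarray,
                         liu_system: SsSnpBlupSystem, liu_x: np.ndarray,
                         resid_tol: float = 1e-4) -> dict:
    """Report agreement of the two parameterisations after solving.

    Total genetic effects of genotyped animals satisfy u_g = a_g + Z g in
    the ms system; they are solved for directly in the liu system.
    """
    em = ms_system.emap
    r_ms = float(np.linalg.norm(ms_system.b - ms_system.matvec(ms_x)) / np.linalg.norm(ms_system.b))
    r_liu = float(np.linalg.norm(liu_system.b - liu_system.matvec(liu_x)) / np.linalg.norm(liu_system.b))
    comparable = r_ms < resid_tol and r_liu < resid_tol
    ug_ms = em.geno_mat(ms_x) + z_matmat(ms_system.geno, ms_system.centering, em.snp_mat(ms_x))
    ug_liu = liu_system.emap.geno_mat(liu_x)
    report = {
        "comparable": bool(comparable),
        "resid_ms": r_ms,
        "resid_liu": r_liu,
        "max_abs_diff_ug": float(np.max(np.abs(ug_ms - ug_liu))) if em.n_g else 0.0,
        "max_abs_diff_fixed": float(np.max(np.abs(ms_x[:em.n_fixed] - liu_x[:em.n_fixed]))) if em.n_fixed else 0.0,
        "max_abs_diff_un": float(np.max(np.abs(em.un_mat(ms_x) - em.un_mat(liu_x)))) if em.n_n else 0.0,
        "max_abs_diff_g": float(np.max(np.abs(em.snp_mat(ms_x) - em.snp_mat(liu_x)))),
    }
    if em.n_g and ug_ms.size:
        flat_ms, flat_liu = ug_ms.ravel(), ug_liu.ravel()
        if np.std(flat_ms) > 0 and np.std(flat_liu) > 0:
            report["corr_ug"] = float(np.corrcoef(flat_ms, flat_liu)[0, 1])
    return report


# ---------------------------------------------------------------------- #
# Record loading
# ---------------------------------------------------------------------- #
def load_records(path, spec: ModelSpec, columns: dict, id_map: dict, sep=None) -> RecordSet:
    """Load phenotype records from a delimited file with a header row.

    ``columns`` maps roles to column names: response, trait, animal, dam
    (optional), class effects, covariates and extra random effects.  Records
    with a missing response are dropped.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+|,|\t", engine="python")
    df = df[df[columns["response"]].notna()].reset_index(drop=True)
    trait_of = {t: i for i, t in enumerate(spec.traits)}
    trait = df[columns["trait"]].astype(str).map(trait_of)
    if trait.isna().any():
        raise ValueError("record with unknown trait label")
    animal = df[columns["animal"]].astype(str).map(id_map)
    if animal.isna().any():
        raise ValueError("record references an animal absent from the pedigree")
    if "dam" in columns and columns["dam"] in df.columns:
        dam = df[columns["dam"]].astype(str).map(lambda s: id_map.get(s, -1)).astype(int)
    else:
        dam = np.full(len(df), -1)
    class_levels = {e: df[columns["class"][e]].to_numpy(dtype=np.int64) for e in spec.fixed_class_effects}
    covs = {c: df[columns["covariates"][c]].to_numpy(dtype=np.float64) for c in spec.fixed_covariates}
    extra = {
        e: df[columns["extra"][e]].to_numpy(dtype=np.int64)
        for e in spec.extra_random_effects
    }
    return RecordSet(
        y=df[columns["response"]].to_numpy(dtype=np.float64),
        trait=trait.to_numpy(dtype=np.int64),
        animal=animal.to_numpy(dtype=np.int64),
        dam=np.asarray(dam, dtype=np.int64),
        class_levels=class_levels,
        covariates=covs,
        extra_levels=extra,
    )
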