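"""Independent dense oracles used by the test suite.

Everything here is built from first principles with dense numpy: the
relationship matrix by the tabular recursion, its inverse by dense
inversion, the coefficient matrices of both system variants from their
printed block formulas, and dense design matrices constructed record by
record.  Nothing below calls the package's sparse/packed code paths.
"""

from __future__ import annotations

import numpy as np


def dense_tabular_a(sire0, dam0):
    """Relationship matrix by the tabular recursion (parents precede)."""
    n = len(sire0)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire0[i], dam0[i]
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[s, j]
            if d >= 0:
                v += 0.5 * a[d, j]
            a[i, j] = a[j, i] = v
    return a


def dense_a_inverse(ped):
    """A^{-1} by dense inversion of the tabular A (ignoring-inbreeding
    variant: rebuild A with Mendelian variances matching alpha in
    {2, 4/3, 1})."""
    # The package's default build ignores inbreeding, i.e. it inverts the
    # matrix implied by the recursion u_i = (u_s + u_d)/2 + m_i with
    # var(m_i) = 1 - 0.25*known_parents.  Construct that covariance directly.
    s0, d0 = ped.sire0, ped.dam0
    n = ped.n
    l = np.zeros((n, n))
    dvar = np.zeros(n)
    for i in range(n):
        row = np.zeros(n)
        nk = 0
        if s0[i] >= 0:
            row += 0.5 * l[s0[i]]
            nk += 1
        if d0[i] >= 0:
            row += 0.5 * l[d0[i]]
            nk += 1
        dvar[i] = 1.0 - 0.25 * nk
        row[i] = 1.0
        l[i] = row
    a = (l * dvar) @ l.T
    return np.linalg.inv(a)


def dense_blocks(ped):
    """Blocks of the dense A^{-1} by genotype status, plus Q and A_gg^{-1}."""
    ai = dense_a_inverse(ped)
    g = np.flatnonzero(ped.genotyped)
    n = np.flatnonzero(~ped.genotyped)
    a_nn = ai[np.ix_(n, n)]
    a_ng = ai[np.ix_(n, g)]
    a_gg = ai[np.ix_(g, g)]
    if len(n):
        q = a_ng.T @ np.linalg.solve(a_nn, a_ng)
    else:
        q = np.zeros((len(g), len(g)))
    return {"a_nn": a_nn, "a_ng": a_ng, "a_gg": a_gg, "q": q, "agg_inv": a_gg - q}


def centered_z(dosages, p=None):
    """Dense centered genotype matrix; missing (-1) contributes zero."""
    dosages = np.asarray(dosages, dtype=np.float64)
    miss = dosages < 0
    if p is None:
        obs = np.where(miss, np.nan, dosages)
        p = np.nansum(obs, axis=0) / (2.0 * (~miss).sum(axis=0))
    z = dosages - 2.0 * p[None, :]
    z[miss] = 0.0
    return z, p


def dense_design(spec, records, ped, emap):
    """Dense record-by-record design matrix over the native equation layout
    (SNP columns untouched) plus the per-record residual precision."""
    t, q = spec.n_traits, spec.q
    n_rec = records.n_records
    x = np.zeros((n_rec, emap.n_total))
    gpos = {}
    npos = {}
    for k, i in enumerate(np.flatnonzero(ped.genotyped)):
        gpos[i] = k
    for k, i in enumerate(np.flatnonzero(~ped.genotyped)):
        npos[i] = k
    jvals = None
    if spec.use_j_covariates:
        blocks = dense_blocks(ped)
        jvals = np.zeros(ped.n)
        jvals[ped.genotyped] = -1.0
        nidx = np.flatnonzero(~ped.genotyped)
        if len(nidx):
            jvals[nidx] = np.linalg.solve(blocks["a_nn"], -blocks["a_ng"] @ jvals[ped.genotyped])
    for r in range(n_rec):
        tr = records.trait[r]
        for eff in spec.fixed_class_effects:
            lev = records.class_levels[eff][r]
            if lev >= 0:  # -1 = reference (treatment-coded) level
                x[r, emap.class_offsets[eff] + lev * t + tr] = 1.0
        for cov in spec.fixed_covariates:
            x[r, emap.cov_offsets[cov] + tr] += records.covariates[cov][r]
        for eff in spec.extra_random_effects:
            lev = records.extra_levels[eff][r]
            if lev >= 0:
                x[r, emap.extra_offsets[eff] + lev * t + tr] = 1.0
        for ty in spec.genetic_effect_types:
            animal = records.animal[r] if ty == "direct" else records.dam[r]
            if animal < 0:
                continue
            ch = spec.channel_index(ty, tr)
            if ped.genotyped[animal]:
                x[r, emap.geno_offset + gpos[animal] * q + ch] = 1.0
            else:
                x[r, emap.un_offset + npos[animal] * q + ch] = 1.0
            if spec.use_j_covariates:
                x[r, emap.j_offset + ch] += jvals[animal]
    rinv = 1.0 / np.diag(spec.R0)[records.trait]
    return x, rinv


def dense_system(spec, records, ped, emap, z, m, variant):
    """Coefficient matrix and right-hand side from the printed block
    formulas, over the native equation layout."""
    t, q = spec.n_traits, spec.q
    blocks = dense_blocks(ped)
    g0i = np.linalg.inv(spec.G0)
    n_g, n_snp = z.shape
    w = spec.w

    x, rinv = dense_design(spec, records, ped, emap)
    xz = x.copy()
    if variant == "ms":
        # records on genotyped animals also load the SNP block through Z
        geno_part = x[:, emap.geno_offset:emap.snp_offset].reshape(-1, n_g, q)
        snp_part = np.einsum("rkc,kj->rjc", geno_part, z).reshape(-1, n_snp * q)
        xz[:, emap.snp_offset:] = snp_part
    c = xz.T @ (rinv[:, None] * xz)
    b = xz.T @ (rinv * records.y)

    def put(sl_r, sl_c, struct):
        c[sl_r, sl_c] += np.kron(struct, g0i)

    sl_un = slice(emap.un_offset, emap.geno_offset)
    sl_gn = slice(emap.geno_offset, emap.snp_offset)
    sl_sp = slice(emap.snp_offset, emap.n_total)
    a_nn, a_ng, a_gg, qm, aggi = (blocks[k] for k in ("a_nn", "a_ng", "a_gg", "q", "agg_inv"))
    if variant == "ms":
        s22 = a_gg / w + (1.0 - 1.0 / w) * qm
        put(sl_un, sl_un, a_nn)
        put(sl_un, sl_gn, a_ng)
        put(sl_gn, sl_un, a_ng.T)
        put(sl_un, sl_sp, a_ng @ z)
        put(sl_sp, sl_un, (a_ng @ z).T)
        put(sl_gn, sl_gn, s22)
        put(sl_gn, sl_sp, qm @ z)
        put(sl_sp, sl_gn, (qm @ z).T)
        put(sl_sp, sl_sp, z.T @ qm @ z + (m / (1.0 - w)) * np.eye(n_snp))
    else:
        s22 = a_gg + (1.0 / w - 1.0) * aggi
        put(sl_un, sl_un, a_nn)
        put(sl_un, sl_gn, a_ng)
        put(sl_gn, sl_un, a_ng.T)
        put(sl_gn, sl_gn, s22)
        put(sl_gn, sl_sp, -(aggi @ z) / w)
        put(sl_sp, sl_gn, -(aggi @ z).T / w)
        put(sl_sp, sl_sp, (z.T @ aggi @ z) / w + (m / (1.0 - w)) * np.eye(n_snp))

    for eff, p0 in spec.extra_random_effects.items():
        o = emap.extra_offsets[eff]
        n_lev = records.n_levels[eff]
        sl = slice(o, o + n_lev * t)
        c[sl, sl] += np.kron(np.eye(n_lev), np.linalg.inv(p0))
    return c, b
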