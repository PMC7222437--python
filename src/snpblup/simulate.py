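"""Synthetic pedigree/genotype/phenotype generator.

Produces data with exactly the statistical structure the model assumes:
a multi-generation pedigree with non-overlapping generations and random
mating, gene-dropped genotypes from founder allele frequencies, and
phenotypes from the linear mixed model with fixed effects, direct (and
optionally maternal) polygenic effects carrying the residual polygenic
fraction ``w``, SNP effects, a permanent-environment effect on the dam,
and a residual.  True effect values are retained for recovery tests.
All draws are reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genotypes import PackedGenotypes, pack_dosages, write_bed
from .model import DIRECT, MATERNAL, ModelSpec, RecordSet
from .pedigree import Pedigree

__all__ = ["SimConfig", "SimTruth", "simulate_pedigree", "drop_genotypes",
           "simulate_phenotypes", "simulate_dataset", "write_dataset"]


@dataclass
class SimConfig:
    n_founders: int = 80
    n_generations: int = 3
    offspring_per_generation: int = 150
    genotyping_rate: float | list = 0.3     # scalar or per-generation list
    n_snp: int = 200
    founder_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.0
    traits: tuple = ("t1", "t2")
    genetic_effect_types: tuple = (DIRECT, MATERNAL)
    G0: np.ndarray | None = None
    R0: np.ndarray | None = None
    P0: np.ndarray | None = None            # permanent environment, per trait
    w: float = 0.05
    n_herds: int = 10
    n_seasons: int = 4
    fixed_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.traits)
        q = t * len(self.genetic_effect_types)
        if self.G0 is None:
            base = np.full((q, q), 0.2) + np.eye(q) * 0.8
            self.G0 = base
        if self.R0 is None:
            self.R0 = np.eye(t) * 2.0
        if self.P0 is None:
            self.P0 = np.eye(t) * 0.5
        self.G0 = np.asarray(self.G0, dtype=np.float64)
        self.R0 = np.asarray(self.R0, dtype=np.float64)
        self.P0 = np.asarray(self.P0, dtype=np.float64)
        if not (0.0 < self.w < 1.0):
            raise ValueError("w must be strictly between 0 and 1")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder frequencies must lie in (0, 1)")

    def rate_for_generation(self, gen: int) -> float:
        if np.isscalar(self.genotyping_rate):
            return float(self.genotyping_rate)
        rates = list(self.genotyping_rate)
        return float(rates[min(gen, len(rates) - 1)])

    def model_spec(self, m_obs: float | None = None) -> ModelSpec:
        return ModelSpec(
            traits=self.traits,
            genetic_effect_types=self.genetic_effect_types,
            G0=self.G0,
            R0=self.R0,
            w=self.w,
            fixed_class_effects=("herd", "season"),
            large_fixed_effect="herd",
            extra_random_effects={"pe": self.P0},
        )


@dataclass
class SimTruth:
    """Hidden truth retained for parameter-recovery checks."""

    dosage_all: np.ndarray          # (n, n_snp) true dosages for ALL animals
    founder_freq: np.ndarray
    u: np.ndarray                   # (n, q) total genetic values a + Z_full g
    a: np.ndarray                   # (n, q) polygenic part
    g: np.ndarray                   # (n_snp, q) SNP effects
    pe: np.ndarray                  # (n_pe_levels, t)
    herd_effects: np.ndarray
    season_effects: np.ndarray
    m_used: float
    generation: np.ndarray = field(default=None)


# ---------------------------------------------------------------------- #
def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Non-overlapping generations, random mating, topologically sorted."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sire = [0] * cfg.n_founders
    dam = [0] * cfg.n_founders
    sex = list(rng.integers(0, 2, cfg.n_founders))  # 0 male, 1 female
    gen_of = [0] * cfg.n_founders
    prev = list(range(cfg.n_founders))
    for gen in range(1, cfg.n_generations + 1):
        males = [i for i in prev if sex[i] == 0]
        females = [i for i in prev if sex[i] == 1]
        cur = []
        for _ in range(cfg.offspring_per_generation):
            i = len(sire)
            sire.append(int(rng.choice(males)) + 1 if males else 0)
            dam.append(int(rng.choice(females)) + 1 if females else 0)
            sex.append(int(rng.integers(0, 2)))
            gen_of.append(gen)
            cur.append(i)
        prev = cur
    n = len(sire)
    geno = np.zeros(n, dtype=bool)
    for i in range(n):
        geno[i] = rng.random() < cfg.rate_for_generation(gen_of[i])
    if not geno.any():
        geno[n - 1] = True  # keep at least one genotyped animal
    ped = Pedigree(n=n, sire=np.array(sire), dam=np.array(dam), genotyped=geno)
    ped.generation = np.array(gen_of)
    return ped


def drop_genotypes(ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None):
    """Gene dropping: founder alleles ~ Bernoulli(founder frequency), each
    offspring allele drawn uniformly from the parent's two alleles (an
    unknown parent contributes a fresh population draw).

    Returns ``(PackedGenotypes for the genotyped subset, true dosages for
    all animals, founder frequencies)``.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    lo, hi = cfg.founder_freq_range
    freq = rng.uniform(lo, hi, cfg.n_snp)
    n = ped.n
    alleles = np.zeros((n, 2, cfg.n_snp), dtype=np.int8)
    s0, d0 = ped.sire0, ped.dam0
    for i in range(n):
        for slot, parent in ((0, s0[i]), (1, d0[i])):
            if parent < 0:
                alleles[i, slot] = rng.random(cfg.n_snp) < freq
            else:
                pick = rng.integers(0, 2, cfg.n_snp)
                alleles[i, slot] = alleles[parent, pick, np.arange(cfg.n_snp)]
    dosage_all = alleles.sum(axis=1).astype(np.int8)

    gidx = ped.genotyped_index
    dos_g = dosage_all[gidx].astype(np.int64)
    if cfg.missing_rate > 0:
        mask = rng.random(dos_g.shape) < cfg.missing_rate
        # keep at least one observed call per SNP
        for j in range(cfg.n_snp):
            if mask[:, j].all():
                mask[rng.integers(0, len(gidx)), j] = False
        dos_g = np.where(mask, -1, dos_g)
    pg = pack_dosages(
        dos_g,
        animal_ids=ped.original_id[gidx],
    )
    return pg, dosage_all, freq


def simulate_phenotypes(ped: Pedigree, dosage_all: np.ndarray, cfg: SimConfig,
                        rng: np.random.Generator | None = None):
    """Phenotypes under the assumed mixed model.

    True breeding values are ``u = a + Z_full g`` with SNP effects drawn as
    ``g_j ~ N(0, (1-w) G0 / m)`` (``m`` from the observed full-population
    frequencies, matching the solver prior) and the polygenic part drawn by
    pedigree recursion with variance ``w G0``.  Each animal with a known dam
    yields one record on one trait.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    spec = cfg.model_spec()
    t, q = spec.n_traits, spec.q
    n, n_snp = ped.n, cfg.n_snp

    p_obs = dosage_all.mean(axis=0) / 2.0
    m_used = float(2.0 * np.sum(p_obs * (1.0 - p_obs)))
    g = rng.multivariate_normal(np.zeros(q), (1.0 - cfg.w) * cfg.G0 / m_used, size=n_snp)
    z_full = dosage_all.astype(np.float64) - 2.0 * p_obs[None, :]
    zg = z_full @ g

    # polygenic part by Mendelian-sampling recursion (inbreeding ignored)
    a = np.zeros((n, q))
    chol_base = np.linalg.cholesky(cfg.w * cfg.G0)
    s0, d0 = ped.sire0, ped.dam0
    eps = rng.standard_normal((n, q))
    for i in range(n):
        s, d = s0[i], d0[i]
        n_known = int(s >= 0) + int(d >= 0)
        ms_var = (1.0, 0.75, 0.5)[n_known]
        mean = np.zeros(q)
        if s >= 0:
            mean += 0.5 * a[s]
        if d >= 0:
            mean += 0.5 * a[d]
        a[i] = mean + np.sqrt(ms_var) * (chol_base @ eps[i])
    u = a + zg

    herd_eff = rng.normal(0.0, cfg.fixed_sd, (cfg.n_herds, t))
    season_eff = rng.normal(0.0, cfg.fixed_sd, (cfg.n_seasons, t))

    rec_animal = np.flatnonzero(ped.dam0 >= 0)
    n_rec = len(rec_animal)
    dams = ped.dam0[rec_animal]
    # permanent-environment levels: one per dam appearing in the data
    uniq_dams, pe_level = np.unique(dams, return_inverse=True)
    pe = np.linalg.cholesky(cfg.P0) @ rng.standard_normal((t, len(uniq_dams)))
    pe = pe.T

    trait = rng.integers(0, t, n_rec)
    herd = rng.integers(0, cfg.n_herds, n_rec)
    season = rng.integers(0, cfg.n_seasons, n_rec)
    # guarantee every modelled (level, trait) cell is observed; the season
    # effect is treatment-coded (level 0 is the reference), keeping the
    # fixed-effect design full rank alongside the full herd coding
    if cfg.n_seasons < 2:
        raise ValueError("need at least 2 seasons (level 0 is the reference)")
    need = cfg.n_herds * t + (cfg.n_seasons - 1) * t
    if n_rec < need:
        raise ValueError("too few records to observe every fixed-effect cell")
    k = 0
    for h in range(cfg.n_herds):
        for ti in range(t):
            herd[k], trait[k] = h, ti
            k += 1
    for s in range(1, cfg.n_seasons):
        for ti in range(t):
            season[k], trait[k] = s, ti
            k += 1

    r_sd = np.sqrt(np.diag(cfg.R0))
    y = np.empty(n_rec)
    ch_dir = [spec.channel_index(DIRECT, ti) for ti in range(t)]
    ch_mat = [spec.channel_index(MATERNAL, ti) for ti in range(t)] if MATERNAL in cfg.genetic_effect_types else None
    for r in range(n_rec):
        ti = trait[r]
        val = herd_eff[herd[r], ti] + season_eff[season[r], ti]
        val += u[rec_animal[r], ch_dir[ti]]
        if ch_mat is not None:
            val += u[dams[r], ch_mat[ti]]
        val += pe[pe_level[r], ti]
        val += rng.normal(0.0, r_sd[ti])
        y[r] = val

    records = RecordSet(
        y=y, trait=trait, animal=rec_animal, dam=dams,
        class_levels={"herd": herd, "season": season - 1},
        extra_levels={"pe": pe_level},
        n_levels={"herd": cfg.n_herds, "season": cfg.n_seasons - 1, "pe": len(uniq_dams)},
    )
    truth = SimTruth(
        dosage_all=dosage_all, founder_freq=None, u=u, a=a, g=g, pe=pe,
        herd_effects=herd_eff, season_effects=season_eff, m_used=m_used,
        generation=getattr(ped, "generation", None),
    )
    return records, truth


def bundled_config(seed: int = 1) -> SimConfig:
    """The bundled synthetic benchmark: ~3,000 animals, ~600 genotyped,
    1,000 SNPs, bivariate direct + maternal model."""
    return SimConfig(
        n_founders=200, n_generations=4, offspring_per_generation=700,
        n_snp=1000, genotyping_rate=0.2, seed=seed, n_herds=25, n_seasons=4,
    )


def simulate_dataset(cfg: SimConfig):
    """Full pipeline: pedigree -> genotypes -> phenotypes."""
    ped = simulate_pedigree(cfg)
    pg, dosage_all, freq = drop_genotypes(ped, cfg)
    records, truth = simulate_phenotypes(ped, dosage_all, cfg)
    truth.founder_freq = freq
    return ped, pg, records, truth


# ---------------------------------------------------------------------- #
def write_dataset(outdir, ped: Pedigree, pg: PackedGenotypes, records: RecordSet,
                  cfg: SimConfig, truth: SimTruth | None = None) -> dict:
    """Write pedigree text, PLINK triplet, phenotype file, truth table and a
    ready-to-run solver config.  Round-trips bit-exactly through the loaders."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.txt",
        "bed": outdir / "geno.bed",
        "bim": outdir / "geno.bim",
        "fam": outdir / "geno.fam",
        "phenotypes": outdir / "phenotypes.txt",
        "config": outdir / "config.yaml",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["pedigree"], "w") as fh:
        fh.write("animal sire dam genotyped\n")
        for i in range(ped.n):
            s = ped.original_id[ped.sire0[i]] if ped.sire0[i] >= 0 else "0"
            d = ped.original_id[ped.dam0[i]] if ped.dam0[i] >= 0 else "0"
            fh.write(f"{ped.original_id[i]} {s} {d} {int(ped.genotyped[i])}\n")
    write_bed(pg, paths["bed"], paths["bim"], paths["fam"])
    with open(paths["phenotypes"], "w") as fh:
        fh.write("y trait animal dam herd season pe\n")
        for r in range(records.n_records):
            fh.write(
                f"{records.y[r]:.10g} {cfg.traits[records.trait[r]]} "
                f"{ped.original_id[records.animal[r]]} "
                f"{ped.original_id[records.dam[r]] if records.dam[r] >= 0 else '0'} "
                f"{records.class_levels['herd'][r]} {records.class_levels['season'][r]} "
                f"{records.extra_levels['pe'][r]}\n"
            )
    if truth is not None:
        q = len(cfg.traits) * len(cfg.genetic_effect_types)
        with open(paths["truth"], "w") as fh:
            cols = "\t".join(f"u{c}" for c in range(q))
            fh.write(f"animal\t{cols}\n")
            for i in range(ped.n):
                vals = "\t".join(f"{v:.10g}" for v in truth.u[i])
                fh.write(f"{ped.original_id[i]}\t{vals}\n")
    config = {
        "paths": {k: str(v) for k, v in paths.items() if k in ("pedigree", "bed", "bim", "fam", "phenotypes")},
        "model": {
            "traits": list(cfg.traits),
            "genetic_effect_types": list(cfg.genetic_effect_types),
            "G0": cfg.G0.tolist(),
            "R0": cfg.R0.tolist(),
            "w": cfg.w,
            "fixed_class_effects": ["herd", "season"],
            "large_fixed_effect": "herd",
            "fixed_covariates": [],
            "extra_random_effects": {"pe": cfg.P0.tolist()},
            "use_j_covariates": True,
        },
        "phenotype_columns": {
            "response": "y", "trait": "trait", "animal": "animal", "dam": "dam",
            "class": {"herd": "herd", "season": "season"},
            "covariates": {},
            "extra": {"pe": "pe"},
        },
        "solver": {
            "variant": "liu", "tol": 1.0e-6, "max_iter": 5000,
            "mc_samples": 1000, "seed": cfg.seed, "d_snp": None,
        },
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
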