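from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from snpblup.genotypes import allele_frequencies, pack_dosages
from snpblup.model import ModelSpec, RecordSet
from snpblup.pedigree import Pedigree, extract_ancestor_blocks
from snpblup.simulate import SimConfig, simulate_dataset


def random_pedigree(n, rng, p_geno=0.3, p_founder=0.2):
    """Random topologically sorted pedigree with unknown-parent gaps."""
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        if rng.random() > p_founder:
            if rng.random() > 0.15:
                sire[i] = rng.integers(1, i + 1)
            if rng.random() > 0.15:
                dam[i] = rng.integers(1, i + 1)
    geno = rng.random(n) < p_geno
    if not geno.any():
        geno[n - 1] = True
    return Pedigree(n=n, sire=sire, dam=dam, genotyped=geno)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240921)


@pytest.fixture(scope="session")
def trio_pedigree():
    # sire and dam founders, genotyped offspring
    return Pedigree(n=3, sire=[0, 0, 1], dam=[0, 0, 2], genotyped=[False, False, True])


@pytest.fixture(scope="session")
def tiny_dataset():
    """Tiny bivariate maternal instance with a dense-oracle-friendly size."""
    cfg = SimConfig(
        n_founders=14, n_generations=2, offspring_per_generation=18,
        n_snp=12, genotyping_rate=0.45, seed=11, n_herds=3, n_seasons=2,
    )
    ped, pg, records, truth = simulate_dataset(cfg)
    spec = cfg.model_spec()
    ops = extract_ancestor_blocks(ped)
    cinfo = allele_frequencies(pg)
    return {
        "cfg": cfg, "ped": ped, "pg": pg, "records": records, "truth": truth,
        "spec": spec, "ops": ops, "cinfo": cinfo,
    }


@pytest.fixture(scope="session")
def univariate_dataset():
    """Small univariate direct-only instance."""
    rng = np.random.default_rng(5)
    ped = random_pedigree(40, rng, p_geno=0.4)
    dos = rng.integers(0, 3, size=(ped.n_genotyped, 8))
    pg = pack_dosages(dos)
    cinfo = allele_frequencies(pg)
    ops = extract_ancestor_blocks(ped)
    spec = ModelSpec(
        traits=("t",), genetic_effect_types=("direct",),
        G0=np.array([[1.2]]), R0=np.array([[2.0]]), w=0.1,
        fixed_class_effects=("mu",), large_fixed_effect="mu",
        use_j_covariates=True,
    )
    n_rec = 70
    animal = rng.integers(0, ped.n, n_rec)
    records = RecordSet(
        y=rng.standard_normal(n_rec),
        trait=np.zeros(n_rec, dtype=int),
        animal=animal,
        dam=np.full(n_rec, -1),
        class_levels={"mu": rng.integers(0, 2, n_rec)},
        n_levels={"mu": 2},
    )
    return {"ped": ped, "pg": pg, "cinfo": cinfo, "ops": ops, "spec": spec,
            "records": records, "dosages": dos}
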