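# snpblup

Matrix-free solver for single-step SNP-BLUP genomic evaluations, supporting
the two standard parameterisations of the mixed-model equations:

* **ms** — solution vector `[fixed | u_n | a_g | g]` (residual polygenic
  effects of genotyped animals plus SNP effects);
* **liu** — solution vector `[fixed | u_n | u_g | g]` (total genetic effects
  of genotyped animals; structurally zero SNP block in the data part).

Both coefficient matrices are applied as split operators
(`T'(C_LS + C_R1)T + C_R2` and `C_LS + T'C_R1 T + C_R2`) and are never
materialised:

* the least-squares part `C_LS` is an in-memory sparse matrix built from the
  phenotype records;
* the inverse pedigree relationship matrix is built by Henderson's rules and
  held in a 3-array compressed-row (CRS3) upper-triangular store (at most
  `4n` nonzeros, `52n + 4` bytes);
* the genotype matrix is kept bit-packed in the PLINK 1 binary layout (2
  bits/call, SNP-major) and the centered products `Zv` / `Z'v` decode
  cache-sized panels on the fly;
* the absorption operator `Q` and the genotyped-submatrix inverse
  `A_gg^{-1}` are applied through the ancestor-restricted inverse blocks
  (genotyped animals and their ancestors only) plus a directly-constructed
  correction matrix `Δ`, with a single sparse factorization of the
  non-genotyped ancestor block.

The systems are solved with preconditioned conjugate gradients under a
two-level preconditioner: a block-diagonal `M` (plain diagonal for the
largest fixed effect, per-level trait/type blocks for random effects, a
ridged sparse factorization for the remaining fixed effects) whose
genotyped-animal and SNP diagonals use cheap approximations (Monte-Carlo
`diag(A_gg^{-1})`, `2 n_g p_j(1-p_j)`, `(2 n_g + n_offspring) p_j(1-p_j)`),
and a second-level diagonal `D` that scales the SNP equations (defaults
`10^3` for ms, `10^2` for liu). Extreme eigenvalues of the preconditioned
operator and the effective spectral condition number are estimated by the
Lanczos method from the PCG coefficients.

Uni- and multi-trait models with direct and maternal genetic effects,
permanent-environment effects, and J compatibility covariates are supported;
a synthetic-data module generates pedigrees, gene-dropped genotypes and
phenotypes with exactly the assumed model structure.

## CLI

```sh
# generate a synthetic dataset (pedigree, PLINK triplet, phenotypes, config)
snpblup simulate --outdir data/demo --seed 1

# solve it (variant ms|liu); writes solutions_<variant>.tsv + report_<variant>.json
snpblup solve data/demo/config.yaml --variant liu --tol 1e-6

# analytic storage accounting
snpblup footprint --n-animals 3e7 --n-genotyped 1e6 --n-snp 5e4

# quick oracle-equivalence self-check
snpblup check
```

`solve` exits 0 on convergence, 2 on missing inputs, 3 on non-convergence
(partial outputs are kept). The JSON report carries the residual
trajectory, the Lanczos eigenvalue estimates and condition number, timings
per stage, and the storage-accounting numbers.

## Layout

| module | contents |
| --- | --- |
| `snpblup.crs3` | CRS3 symmetric sparse type and the 52n+4 byte bound |
| `snpblup.pedigree` | pedigree container/loader, Henderson A⁻¹, ancestor blocks, Δ, Q, A_gg⁻¹, Monte-Carlo diagonal |
| `snpblup.genotypes` | PLINK 1 codec, packed store, centered kernels, footprint accounting |
| `snpblup.model` | model/record containers, equation map, system assembly, split matvec, J covariates, variant equivalence |
| `snpblup.solver` | preconditioner, second-level diagonal, PCG, Lanczos |
| `snpblup.simulate` | synthetic pedigree/genotype/phenotype generator and dataset writer |
| `snpblup.cli` | `snpblup` command group |
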