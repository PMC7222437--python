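"""Bit-packed genotype store and cache-blocked centered kernels.

Genotypes are kept in RAM in the PLINK 1 binary layout: SNP-major, 2 bits
per call, four calls per byte.  Code map (bit pairs, little-endian within a
byte): ``00`` -> 0 copies of the counted allele, ``01`` -> missing, ``10`` ->
1 copy, ``11`` -> 2 copies.  The counted allele is the second allele of the
.bim record.

The centered matrix Z (dosage minus twice the observed allele frequency,
zero for missing calls) is never materialised; products with Z and Z' decode
fixed-size blocks into small dense panels and accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PackedGenotypes",
    "CenteringInfo",
    "pack_dosages",
    "read_bed",
    "write_bed",
    "allele_frequencies",
    "z_matmat",
    "zt_matmat",
    "z_weighted_sq_colsums",
    "packed_footprint_bytes",
]

_MAGIC = b"\x6c\x1b"
_MODE_SNP_MAJOR = b"\x01"

# decode lookup tables: byte value -> 4 calls (dosage, missing flag)
_CODE_DOSAGE = np.array([0.0, 0.0, 1.0, 2.0])  # index by 2-bit code; 01 handled via mask
_CODE_MISSING = np.array([False, True, False, False])
_BYTE_CODES = np.zeros((256, 4), dtype=np.uint8)
for _b in range(256):
    for _k in range(4):
        _BYTE_CODES[_b, _k] = (_b >> (2 * _k)) & 0b11
_BYTE_DOSAGE = _CODE_DOSAGE[_BYTE_CODES]        # (256, 4) float
_BYTE_MISSING = _CODE_MISSING[_BYTE_CODES]      # (256, 4) bool
_DOSAGE_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, -1: 0b01}


@dataclass
class PackedGenotypes:
    """SNP-major 2-bit genotype store."""

    n_g: int
    n_snp: int
    codes: np.ndarray          # uint8, shape (n_snp, ceil(n_g / 4))
    snp_ids: np.ndarray | None = None
    animal_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        nb = (self.n_g + 3) // 4
        if self.codes.shape != (self.n_snp, nb):
            raise ValueError("codes array has wrong shape for n_g x n_snp")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j}" for j in range(self.n_snp)])
        if self.animal_ids is None:
            self.animal_ids = np.array([f"ind{k}" for k in range(self.n_g)])

    @property
    def bytes_per_snp(self) -> int:
        return (self.n_g + 3) // 4

    def decode_block(self, snp_lo: int, snp_hi: int, animal_lo: int = 0, animal_hi: int | None = None):
        """Decode SNPs [snp_lo, snp_hi) for animals [animal_lo, animal_hi)
        into dense ``(dosage, missing)`` panels of shape (snps, animals)."""
        if animal_hi is None:
            animal_hi = self.n_g
        b_lo, b_hi = animal_lo // 4, (animal_hi + 3) // 4
        blk = self.codes[snp_lo:snp_hi, b_lo:b_hi]
        dos = _BYTE_DOSAGE[blk].reshape(blk.shape[0], -1)
        mis = _BYTE_MISSING[blk].reshape(blk.shape[0], -1)
        off = animal_lo - 4 * b_lo
        dos = dos[:, off:off + (animal_hi - animal_lo)]
        mis = mis[:, off:off + (animal_hi - animal_lo)]
        return dos, mis

    def dosages(self) -> np.ndarray:
        """Full dense dosage matrix (n_g, n_snp), -1 for missing.  Debug aid."""
        dos, mis = self.decode_block(0, self.n_snp)
        out = dos.astype(np.int8)
        out[mis] = -1
        return out.T


@dataclass
class CenteringInfo:
    """Observed counted-allele frequencies and the scaling constant
    ``m = 2 * sum_j p_j (1 - p_j)``."""

    p: np.ndarray
    m: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")


def pack_dosages(dosages: np.ndarray, snp_ids=None, animal_ids=None) -> PackedGenotypes:
    """Pack an (n_g, n_snp) integer dosage matrix (-1 = missing)."""
    dosages = np.asarray(dosages)
    n_g, n_snp = dosages.shape
    nb = (n_g + 3) // 4
    codes = np.zeros((n_snp, nb), dtype=np.uint8)
    code_of = np.zeros(n_g, dtype=np.uint8)
    for j in range(n_snp):
        col = dosages[:, j]
        for d, c in _DOSAGE_TO_CODE.items():
            code_of[col == d] = c
        if np.any((col < -1) | (col > 2)):
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        padded = np.zeros(nb * 4, dtype=np.uint8)
        padded[:n_g] = code_of
        quads = padded.reshape(nb, 4)
        codes[j] = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    return PackedGenotypes(n_g=n_g, n_snp=n_snp, codes=codes, snp_ids=snp_ids, animal_ids=animal_ids)


# ---------------------------------------------------------------------- #
# PLINK 1 file triplet
# ---------------------------------------------------------------------- #
def read_bed(bed_path, bim_path, fam_path) -> PackedGenotypes:
    """Read a PLINK 1 .bed/.bim/.fam triplet (SNP-major only).

    The packed bytes are stored verbatim; nothing is decoded at load time.
    """
    bim = np.loadtxt(bim_path, dtype=str, ndmin=2)
    fam = np.loadtxt(fam_path, dtype=str, ndmin=2)
    n_snp = bim.shape[0]
    n_g = fam.shape[0]
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if header[:2] != _MAGIC:
            raise ValueError(f"{bed_path}: not a PLINK 1 .bed file (bad magic bytes)")
        if header[2:3] != _MODE_SNP_MAJOR:
            raise ValueError(f"{bed_path}: individual-major .bed files are not supported")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    nb = (n_g + 3) // 4
    if data.size != n_snp * nb:
        raise ValueError(
            f"{bed_path}: size mismatch (expected {n_snp * nb} data bytes for "
            f"{n_g} animals x {n_snp} SNPs, found {data.size})"
        )
    codes = data.reshape(n_snp, nb).copy()
    return PackedGenotypes(
        n_g=n_g, n_snp=n_snp, codes=codes,
        snp_ids=bim[:, 1].copy(), animal_ids=fam[:, 1].copy(),
    )


def write_bed(pg: PackedGenotypes, bed_path, bim_path=None, fam_path=None) -> None:
    """Write the store as a PLINK 1 triplet (bit-exact SNP-major .bed)."""
    with open(bed_path, "wb") as fh:
        fh.write(_MAGIC + _MODE_SNP_MAJOR)
        fh.write(pg.codes.tobytes())
    if bim_path is not None:
        with open(bim_path, "w") as fh:
            for j, sid in enumerate(pg.snp_ids):
                fh.write(f"1\t{sid}\t0\t{j + 1}\tA\tB\n")
    if fam_path is not None:
        with open(fam_path, "w") as fh:
            for aid in pg.animal_ids:
                fh.write(f"0\t{aid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------- #
# Frequencies and kernels
# ---------------------------------------------------------------------- #
def allele_frequencies(pg: PackedGenotypes, snp_block: int = 512) -> CenteringInfo:
    """Observed counted-allele frequency per SNP from non-missing calls only."""
    p = np.empty(pg.n_snp)
    for lo in range(0, pg.n_snp, snp_block):
        hi = min(lo + snp_block, pg.n_snp)
        dos, mis = pg.decode_block(lo, hi)
        n_obs = (~mis).sum(axis=1)
        if np.any(n_obs == 0):
            bad = lo + int(np.flatnonzero(n_obs == 0)[0])
            raise ValueError(f"SNP index {bad} has no non-missing calls")
        dos = np.where(mis, 0.0, dos)
        p[lo:hi] = dos.sum(axis=1) / (2.0 * n_obs)
    m = float(2.0 * np.sum(p * (1.0 - p)))
    return CenteringInfo(p=p, m=m)


def _blocks(n: int, size: int):
    for lo in range(0, n, size):
        yield lo, min(lo + size, n)


def z_matmat(pg: PackedGenotypes, c: CenteringInfo, v: np.ndarray,
             snp_block: int = 32, animal_block: int = 256) -> np.ndarray:
    """Z @ V with Z the centered genotype matrix (missing -> 0).

    V has n_snp rows; the result has n_g rows.  Blocks of the packed store
    are decoded into small dense panels sized to stay cache-resident.
    """
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    v2 = v[:, None] if single else v
    if v2.shape[0] != pg.n_snp:
        raise ValueError(f"V has {v2.shape[0]} rows, expected n_snp = {pg.n_snp}")
    out = np.zeros((pg.n_g, v2.shape[1]))
    for alo, ahi in _blocks(pg.n_g, animal_block):
        for slo, shi in _blocks(pg.n_snp, snp_block):
            dos, mis = pg.decode_block(slo, shi, alo, ahi)
            z = dos - 2.0 * c.p[slo:shi, None]
            z[mis] = 0.0
            out[alo:ahi] += z.T @ v2[slo:shi]
    return out[:, 0] if single else out


def zt_matmat(pg: PackedGenotypes, c: CenteringInfo, v: np.ndarray,
              snp_block: int = 32, animal_block: int = 256) -> np.ndarray:
    """Z' @ V; V has n_g rows, the result has n_snp rows."""
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    v2 = v[:, None] if single else v
    if v2.shape[0] != pg.n_g:
        raise ValueError(f"V has {v2.shape[0]} rows, expected n_g = {pg.n_g}")
    out = np.zeros((pg.n_snp, v2.shape[1]))
    for alo, ahi in _blocks(pg.n_g, animal_block):
        for slo, shi in _blocks(pg.n_snp, snp_block):
            dos, mis = pg.decode_block(slo, shi, alo, ahi)
            z = dos - 2.0 * c.p[slo:shi, None]
            z[mis] = 0.0
            out[slo:shi] += z @ v2[alo:ahi]
    return out[:, 0] if single else out


def z_weighted_sq_colsums(pg: PackedGenotypes, c: CenteringInfo, weights: np.ndarray,
                          snp_block: int = 32, animal_block: int = 256) -> np.ndarray:
    """Per-SNP sums ``sum_k Z_kj^2 * weights_k``; used for the exact data
    part of the SNP-block preconditioner diagonal."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (pg.n_g,):
        raise ValueError("weights must have length n_g")
    out = np.zeros(pg.n_snp)
    for alo, ahi in _blocks(pg.n_g, animal_block):
        for slo, shi in _blocks(pg.n_snp, snp_block):
            dos, mis = pg.decode_block(slo, shi, alo, ahi)
            z = dos - 2.0 * c.p[slo:shi, None]
            z[mis] = 0.0
            out[slo:shi] += (z * z) @ weights[alo:ahi]
    return out


def packed_footprint_bytes(n_g: int, n_snp: int) -> dict:
    """Storage accounting: packed 2-bit store (rounded up per SNP), the same
    matrix as 8-byte reals, and the 8-byte-per-SNP frequency array."""
    if n_g <= 0 or n_snp <= 0:
        raise ValueError("dimensions must be positive")
    return {
        "packed": ((n_g + 3) // 4) * n_snp,
        "dense_double": 8 * n_g * n_snp,
        "freq_array": 8 * n_snp,
    }
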