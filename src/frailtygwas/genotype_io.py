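"""PLINK 1 binary genotype input/output.

Genotypes are kept in the native SNP-major 2-bit packing and decoded one
variant at a time, so the memory needed to test a variant is O(n_samples)
regardless of how many variants the fileset contains.

The 2-bit code table (per the PLINK 1 .bed specification, low bits first
within each byte):

====  =========================================
code  meaning
====  =========================================
00    homozygous allele1 (counted-allele dosage 2)
01    missing
10    heterozygous (dosage 1)
11    homozygous allele2 (dosage 0)
====  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VariantInfo",
    "AlleleStats",
    "GenotypeBlock",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "allele_stats",
    "get_dosage",
]

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit bed code -> counted-allele dosage (-1 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}

# byte -> 4 dosages lookup table, low bits first
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


class PlinkFormatError(ValueError):
    """Raised for malformed .bed/.bim/.fam files."""


@dataclass(frozen=True)
class VariantInfo:
    """Identity of one biallelic variant; ``allele1`` is the counted allele."""

    chrom: str
    pos: int
    id: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if not self.allele1 or not self.allele2:
            raise ValueError("allele strings must be non-empty")


@dataclass(frozen=True)
class AlleleStats:
    """Counted-allele statistics over the non-missing calls of one variant."""

    ac: int
    af: float
    mac: int
    n_missing: int
    n_called: int


@dataclass
class GenotypeBlock:
    """A set of biallelic genotypes in packed 2-bit SNP-major storage.

    ``packed`` has shape (ceil(n_samples/4), n_variants); column j holds the
    bed-encoded bytes of variant j.
    """

    n_samples: int
    n_variants: int
    packed: np.ndarray
    variants: list[VariantInfo]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        nbytes = (self.n_samples + 3) // 4
        if self.packed.shape != (nbytes, self.n_variants):
            raise ValueError(
                f"packed storage shape {self.packed.shape} does not match "
                f"({nbytes}, {self.n_variants})"
            )
        if len(self.variants) != self.n_variants:
            raise ValueError("variant metadata length mismatch")
        if self.sample_ids and len(self.sample_ids) != self.n_samples:
            raise ValueError("sample id length mismatch")

    # -- construction -------------------------------------------------

    @classmethod
    def from_matrix(
        cls,
        calls: np.ndarray,
        variants: Sequence[VariantInfo] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "GenotypeBlock":
        """Pack an (n_samples, n_variants) int matrix of calls in {0,1,2,-1}."""
        calls = np.asarray(calls)
        if calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x variants)")
        n, m = calls.shape
        valid = np.isin(calls, (0, 1, 2, -1))
        if not valid.all():
            raise ValueError("calls must be in {0, 1, 2, -1}")
        if variants is None:
            variants = [
                VariantInfo("1", j + 1, f"snp{j + 1}", "A", "B") for j in range(m)
            ]
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(n)]
        codes = np.empty((n, m), dtype=np.uint8)
        for dosage, code in _DOSAGE_TO_CODE.items():
            codes[calls == dosage] = code
        nbytes = (n + 3) // 4
        padded = np.zeros((nbytes * 4, m), dtype=np.uint8)
        padded[:n] = codes
        packed = np.zeros((nbytes, m), dtype=np.uint8)
        for k in range(4):
            packed |= padded[k::4] << (2 * k)
        return cls(n, m, packed, list(variants), list(sample_ids))

    # -- access -------------------------------------------------------

    def genotypes(self, variant_index: int) -> np.ndarray:
        """Decode variant ``variant_index`` to an int8 vector (-1 = missing)."""
        if not 0 <= variant_index < self.n_variants:
            raise IndexError(variant_index)
        col = self.packed[:, variant_index]
        return _BYTE_LUT[col].reshape(-1)[: self.n_samples]

    def to_matrix(self) -> np.ndarray:
        """Decode everything to an (n_samples, n_variants) int8 matrix."""
        full = _BYTE_LUT[self.packed]  # (nbytes, m, 4)
        return full.transpose(0, 2, 1).reshape(-1, self.n_variants)[: self.n_samples]

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeBlock":
        idx = np.asarray(indices, dtype=int)
        return GenotypeBlock(
            self.n_samples,
            len(idx),
            self.packed[:, idx].copy(),
            [self.variants[j] for j in idx],
            list(self.sample_ids),
        )


# ---------------------------------------------------------------------
# file I/O


def _read_bim(bim_path: Path) -> list[VariantInfo]:
    variants = []
    with open(bim_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(f"bad .bim line: {line!r}")
            chrom, vid, _cm, pos, a1, a2 = parts
            variants.append(VariantInfo(chrom, int(pos), vid, a1, a2))
    return variants


def _read_fam(fam_path: Path) -> list[str]:
    ids = []
    with open(fam_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                raise PlinkFormatError(f"bad .fam line: {line!r}")
            ids.append(parts[1])
    return ids


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeBlock:
    """Read a PLINK 1 fileset into a packed :class:`GenotypeBlock`.

    Row order follows the .fam file, column order the .bim file.  If only
    ``bed_path`` is given, sibling .bim/.fam paths are inferred.
    """
    bed_path = Path(bed_path)
    if bim_path is None:
        bim_path = bed_path.with_suffix(".bim")
    if fam_path is None:
        fam_path = bed_path.with_suffix(".fam")
    variants = _read_bim(Path(bim_path))
    sample_ids = _read_fam(Path(fam_path))
    n, m = len(sample_ids), len(variants)
    nbytes = (n + 3) // 4

    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:3]!r}; expected SNP-major "
            f"PLINK 1 .bed ({_BED_MAGIC!r})"
        )
    expected = 3 + nbytes * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: file has {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} variants"
        )
    packed = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, nbytes).T.copy()
    return GenotypeBlock(n, m, packed, variants, sample_ids)


def write_plink(block: GenotypeBlock, prefix) -> None:
    """Write ``block`` as PLINK 1 ``prefix``.bed/.bim/.fam (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(block.packed.T.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in block.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.allele1}\t{v.allele2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in block.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------
# per-variant statistics


def allele_stats(block: GenotypeBlock, variant_index: int) -> AlleleStats:
    """Counted-allele count/frequency and the polarity-invariant MAC."""
    g = block.genotypes(variant_index)
    called = g >= 0
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError(
            f"variant {variant_index}: all calls missing, allele frequency undefined"
        )
    ac = int(g[called].sum())
    af = ac / (2 * n_called)
    mac = min(ac, 2 * n_called - ac)
    return AlleleStats(ac, af, mac, block.n_samples - n_called, n_called)


def get_dosage(block: GenotypeBlock, variant_index: int, impute: str = "mean") -> np.ndarray:
    """Counted-allele dosage with missing calls mean-imputed to 2*AF."""
    if impute != "mean":
        raise ValueError(f"unknown imputation mode {impute!r}")
    g = block.genotypes(variant_index)
    dosage = g.astype(np.float64)
    miss = g < 0
    if miss.any():
        stats = allele_stats(block, variant_index)
        dosage[miss] = 2.0 * stats.af
    return dosage
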