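"""Lossless 2-bit genotype codec and storage-size arithmetic.

A biallelic genotype has four states — homozygous for allele 1, heterozygous,
no-call, homozygous for allele 2 — so two bits suffice per SNP.  A sample's
whole genotype record on a panel of *n* SNPs packs into ``ceil(n/4)`` bytes:
an 800K array fits in 1,600,000 bits (~196 KB) and one megabyte holds four
million genotypes.  This codec is the storage contract of the whole package:
every genotype ever persisted goes through :func:`pack_codes` and comes back
through :func:`unpack_codes`.

Bit layout (fixed, documented, byte-exact): code *i* occupies bits
``2*(i mod 4)`` .. ``2*(i mod 4)+1`` of byte ``i // 4``, least-significant
bits first; pad bits of the final byte are zero.  Packing ``[0, 1, 2, 3]``
therefore yields the single byte ``0xE4``.

Integer codes:

====  =======================
code  meaning
====  =======================
0     homozygous allele 1
1     heterozygous
2     no-call (missing)
3     homozygous allele 2
====  =======================
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .errors import AlleleMismatchError, DomainError, InvalidCodeError

HOM1: int = 0
HET: int = 1
NOCALL: int = 2
HOM2: int = 3

#: PLINK's missing-genotype token; configurable per call where it matters.
MISSING_TOKEN: str = "0"

#: Placeholder second allele for monomorphic SNPs whose coding had to be
#: inferred from data in which only one allele was ever observed.
MONOMORPHIC_PLACEHOLDER: str = "0"


@dataclass(frozen=True)
class AllelePair:
    """Allele coding of one SNP: which labels map to codes 0 and 3.

    ``allele1`` is the label of the code-0 homozygote, ``allele2`` that of the
    code-3 homozygote.  ``allele2`` may be the ``"0"`` placeholder for a
    monomorphic SNP with inferred coding; encoding a second distinct allele
    for such a SNP is an error, never a silent reassignment.
    """

    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if not self.allele1 or not self.allele2:
            raise DomainError("allele labels must be non-empty")
        if self.allele1 == self.allele2:
            raise DomainError(
                f"allele coding needs two distinct labels, got "
                f"{self.allele1!r} twice"
            )

    @property
    def is_monomorphic_placeholder(self) -> bool:
        return self.allele2 == MONOMORPHIC_PLACEHOLDER


@dataclass(frozen=True)
class PackedGenotypeVector:
    """One sample's genotypes on one panel, 2 bits per SNP.

    ``len(payload) == ceil(n_snps / 4)`` always holds.
    """

    payload: bytes
    n_snps: int

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise DomainError("n_snps must be >= 0")
        if len(self.payload) != packed_size(self.n_snps):
            raise DomainError(
                f"payload of {len(self.payload)} bytes cannot hold "
                f"{self.n_snps} 2-bit genotypes (expected "
                f"{packed_size(self.n_snps)})"
            )

    def __len__(self) -> int:
        return self.n_snps


def packed_size(n_snps: int) -> int:
    """Bytes needed to store ``n_snps`` genotypes at 2 bits each: ceil(n/4)."""
    if n_snps < 0:
        raise DomainError(f"n_snps must be >= 0, got {n_snps}")
    return (int(n_snps) + 3) // 4


def capacity(n_bytes: int) -> int:
    """Number of 2-bit genotypes that fit in ``n_bytes``: 4 per byte."""
    if n_bytes < 0:
        raise DomainError(f"n_bytes must be >= 0, got {n_bytes}")
    return 4 * int(n_bytes)


def selection_size(n_snps: int) -> int:
    """Bytes for a 1-bit-per-SNP selection vector: ceil(n/8).

    An 800K panel needs 100,000 bytes, i.e. ~97.7 KB.
    """
    if n_snps < 0:
        raise DomainError(f"n_snps must be >= 0, got {n_snps}")
    return (int(n_snps) + 7) // 8


def encode_genotype(
    observed: tuple[str, str],
    coding: AllelePair,
    missing: str = MISSING_TOKEN,
) -> int:
    """Map an observed allele pair to its 2-bit integer code.

    Heterozygotes are unordered: ``(B, A)`` and ``(A, B)`` both encode to 1.
    The missing token in either position yields the no-call code 2.

    Raises
    ------
    AlleleMismatchError
        If an observed allele is neither in the coding nor the missing token.
    """
    a, b = observed
    if a == missing or b == missing:
        return NOCALL
    a1, a2 = coding.allele1, coding.allele2
    if a == a1 and b == a1:
        return HOM1
    if a == a2 and b == a2:
        return HOM2
    if (a == a1 and b == a2) or (a == a2 and b == a1):
        return HET
    raise AlleleMismatchError(
        f"observed genotype {a!r}/{b!r} not expressible in coding "
        f"({a1!r}, {a2!r})"
    )


def decode_genotype(
    code: int,
    coding: AllelePair,
    missing: str = MISSING_TOKEN,
) -> tuple[str, str]:
    """Inverse of :func:`encode_genotype` up to heterozygote order.

    Heterozygotes come back in canonical ``(allele1, allele2)`` order; code 2
    yields the missing token twice.
    """
    if code == HOM1:
        return (coding.allele1, coding.allele1)
    if code == HET:
        return (coding.allele1, coding.allele2)
    if code == NOCALL:
        return (missing, missing)
    if code == HOM2:
        return (coding.allele2, coding.allele2)
    raise InvalidCodeError(f"genotype code must be in {{0,1,2,3}}, got {code}")


def _as_code_array(codes: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(codes, dtype=np.uint8)
    if arr.ndim != 1:
        raise DomainError("codes must be one-dimensional")
    if arr.size and int(arr.max()) > 3:
        bad = int(np.argmax(arr > 3))
        raise InvalidCodeError(
            f"code {int(arr[bad])} at position {bad} outside {{0,1,2,3}}"
        )
    return arr


def pack_codes(codes: Sequence[int] | np.ndarray) -> PackedGenotypeVector:
    """Pack a sequence of genotype codes into a 2-bit byte vector."""
    arr = _as_code_array(codes)
    return PackedGenotypeVector(payload=pack_payload(arr), n_snps=arr.size)


def pack_payload(arr: np.ndarray) -> bytes:
    """Pack a validated uint8 code array to raw bytes (no wrapper object)."""
    n = arr.size
    if n == 0:
        return b""
    pad = (-n) % 4
    if pad:
        arr = np.concatenate([arr, np.zeros(pad, dtype=np.uint8)])
    q = arr.reshape(-1, 4)
    out = q[:, 0] | (q[:, 1] << 2) | (q[:, 2] << 4) | (q[:, 3] << 6)
    return out.astype(np.uint8).tobytes()


def unpack_payload(payload: bytes | np.ndarray, n_snps: int) -> np.ndarray:
    """Unpack raw 2-bit payload bytes to a uint8 code array of length n_snps."""
    raw = np.frombuffer(payload, dtype=np.uint8) if isinstance(
        payload, (bytes, bytearray, memoryview)
    ) else np.asarray(payload, dtype=np.uint8)
    if raw.size < packed_size(n_snps):
        raise DomainError(
            f"payload of {raw.size} bytes too short for {n_snps} genotypes"
        )
    out = np.empty((raw.size, 4), dtype=np.uint8)
    out[:, 0] = raw & 3
    out[:, 1] = (raw >> 2) & 3
    out[:, 2] = (raw >> 4) & 3
    out[:, 3] = (raw >> 6) & 3
    return out.reshape(-1)[:n_snps]


def unpack_codes(
    v: PackedGenotypeVector,
    positions: Iterable[int] | None = None,
) -> np.ndarray:
    """Unpack a packed vector to genotype codes.

    Without ``positions`` returns all ``n_snps`` codes in panel order.  With
    ``positions`` (a set of indices) returns the codes at those indices in
    ascending index order.  Trailing pad bits are never exposed.
    """
    codes = unpack_payload(v.payload, v.n_snps)
    if positions is None:
        return codes
    idx = np.asarray(sorted(set(int(p) for p in positions)), dtype=np.int64)
    if idx.size:
        if idx[0] < 0:
            raise DomainError(f"negative SNP index {int(idx[0])}")
        if idx[-1] >= v.n_snps:
            raise DomainError(
                f"SNP index {int(idx[-1])} out of range for a "
                f"{v.n_snps}-SNP vector"
            )
    return codes[idx]


def encode_pair_arrays(
    a: np.ndarray,
    b: np.ndarray,
    allele1: np.ndarray,
    allele2: np.ndarray,
    missing: str = MISSING_TOKEN,
) -> np.ndarray:
    """Vectorized encoder for one sample row across all SNPs of a panel.

    ``a``/``b`` are the observed allele tokens per SNP; ``allele1``/``allele2``
    the per-SNP coding labels.  Returns a uint8 code array.  Raises
    :class:`AlleleMismatchError` naming the first offending SNP position.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    codes = np.full(a.shape, NOCALL, dtype=np.uint8)
    miss = (a == missing) | (b == missing)
    ha = a == allele1
    hb = b == allele1
    ka = a == allele2
    kb = b == allele2
    codes[ha & hb] = HOM1
    codes[ka & kb] = HOM2
    codes[(ha & kb) | (ka & hb)] = HET
    valid = miss | ((ha | ka) & (hb | kb))
    if not valid.all():
        i = int(np.argmin(valid))
        raise AlleleMismatchError(
            f"allele pair {a[i]!r}/{b[i]!r} at SNP position {i} does not "
            f"match coding ({allele1[i]!r}, {allele2[i]!r})"
        )
    return codes
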