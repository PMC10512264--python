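"""2-bit nucleotide encoding and vectorised canonical k-mer extraction.

All k-mer machinery in the package funnels through here: sequences are
mapped to uint8 codes (A=0, C=1, G=2, T=3, anything else 4), k-mers are
packed into int64 words, and the canonical form of a k-mer is the smaller
of its forward and reverse-complement codes.  k must be odd so a k-mer can
never equal its own reverse complement.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def _check_k(k: int) -> None:
    if k % 2 == 0 or not (3 <= k <= 31):
        raise ValueError(f"k must be odd and in [3, 31], got {k}")


def kmer_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward, reverse-complement and validity arrays for every k-mer window.

    Parameters
    ----------
    bases : uint8 array of 2-bit codes (4 marks an invalid base)
    k : k-mer size (odd)

    Returns
    -------
    fwd, rc : int64 arrays of length ``len(bases) - k + 1`` with the packed
        forward and reverse-complement codes of each window
    valid : boolean array, False where the window contains an invalid base
    """
    _check_k(k)
    n = bases.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=bool)

    bad = (bases >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0

    # rolling polynomial by shifted adds: k passes over the array beat an
    # integer matmul (no BLAS path for int64)
    b64 = bases.astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        col = b64[j : j + n]
        fwd |= col << (2 * (k - 1 - j))
        rc |= (3 - col) << (2 * j)
    return fwd, rc, valid


def canonical_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (min of strands) and forward codes plus validity mask."""
    fwd, rc, valid = kmer_codes(bases, k)
    return np.minimum(fwd, rc), fwd, valid


def canonical_set(seqs, k: int, min_count: int = 1) -> np.ndarray:
    """Sorted unique canonical k-mer codes observed >= min_count times.

    ``seqs`` is an iterable of nucleotide strings; k-mers never span
    sequence boundaries.
    """
    _check_k(k)
    joined = "N".join(seqs)
    canon, _, valid = canonical_codes(encode(joined), k)
    canon = canon[valid]
    if canon.size == 0:
        return np.empty(0, dtype=np.int64)
    if min_count <= 1:
        return np.unique(canon)
    codes, counts = np.unique(canon, return_counts=True)
    return codes[counts >= min_count]
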