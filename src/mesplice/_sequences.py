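"""Low-level nucleotide string utilities shared across the package.

Everything here operates on plain Python strings over the {A,C,G,T}
alphabet; reverse-complementing is the only place strand ever enters the
scoring stack.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AmbiguousBaseError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T}."""


class MotifLengthError(ValueError):
    """Raised when a sequence does not match the model's motif length."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_indices(seq: str, length: int | None = None) -> np.ndarray:
    """Validate and encode a nucleotide string as base-4 indices (A=0..T=3).

    Case-insensitive. Raises :class:`MotifLengthError` on a length mismatch
    and :class:`AmbiguousBaseError` on any non-ACGT character (including N).
    """
    if length is not None and len(seq) != length:
        raise MotifLengthError(
            f"expected a {length}-mer, got {len(seq)} nt: {seq!r}"
        )
    up = seq.upper()
    try:
        return np.fromiter((BASE_INDEX[b] for b in up), dtype=np.intp, count=len(up))
    except KeyError as exc:
        raise AmbiguousBaseError(
            f"sequence contains a non-ACGT base {exc.args[0]!r}: {seq!r}"
        ) from None


def indices_to_seq(idx) -> str:
    return "".join(BASES[i] for i in idx)


def has_ambiguous(seq: str) -> bool:
    return any(b not in BASE_INDEX for b in seq.upper())


def kmer_index(seq: str) -> int:
    """Lexicographic rank of a k-mer over ACGT (big-endian base 4)."""
    rank = 0
    for b in seq.upper():
        rank = rank * 4 + BASE_INDEX[b]
    return rank


def index_kmer(rank: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[rank % 4])
        rank //= 4
    return "".join(reversed(out))
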