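"""Small DNA helpers used by several stages.

Sequences are plain upper-case strings over {A, C, G, T, N}. An ``N`` never
matches anything, including another ``N``: the comparison strategy demands
literal base identity, and an ambiguous consensus position cannot certify it.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# any byte that is not an unambiguous base becomes 'N'
_NORMALIZE = bytes(
    c if c in b"ACGT" else ord("N") for c in (bytes([x]).upper()[0] for x in range(256))
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Upper-case and collapse every ambiguous/unknown character to N."""
    return seq.encode("ascii", errors="replace").translate(_NORMALIZE).decode("ascii")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-site substitutions at the given rate.

    A mutated site always receives one of the three *other* bases, so the
    expected pairwise identity to the input is exactly ``1 - rate``.
    ``N`` sites are left untouched.
    """
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    hit &= arr != ord("N")
    idx = np.nonzero(hit)[0]
    if idx.size:
        # pick an offset 1..3 into the base alphabet relative to current base
        cur = np.searchsorted(BASES, arr[idx])
        new = (cur + rng.integers(1, 4, size=idx.size)) % 4
        arr[idx] = BASES[new]
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")
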