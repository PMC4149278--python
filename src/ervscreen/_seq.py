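"""Low-level sequence helpers: random DNA, reverse complement, k-mismatch scan.

All coordinates are 0-based, half-open. Sequences are plain upper-case
strings; numpy uint8 views are used internally for vectorised scans.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(
    b"ACGTRYSWKMBDHVN-", b"TGCAYRSWMKVHDBN-"
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def as_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def mismatch_profile(seq: str, pattern: str) -> np.ndarray:
    """Hamming distance of ``pattern`` against every window of ``seq``.

    Returns an int array of length ``len(seq) - len(pattern) + 1`` (empty if
    the pattern is longer than the sequence). Substitutions only; no indels.
    """
    s = as_u8(seq)
    p = as_u8(pattern)
    n, L = s.size, p.size
    if n < L:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n - L + 1, dtype=np.int64)
    for i in range(L):
        out += s[i : i + n - L + 1] != p[i]
    return out


def mutate_positions(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position with a *different* uniformly chosen base."""
    arr = as_u8(seq).copy()
    for pos in positions:
        old = arr[pos]
        choices = _BASES[_BASES != old]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")
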