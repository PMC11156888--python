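"""Low-level DNA string utilities shared across the package."""

from __future__ import annotations

from typing import Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    N is treated as an ordinary letter: N vs A counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_capped(a: str, b: str, cap: int) -> int:
    """Hamming distance with early exit once ``cap`` is exceeded.

    Returns ``cap + 1`` as soon as the distance is known to exceed the cap.
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def scan_pattern(seq: str, pattern: str, max_mm: int) -> Iterator[tuple[int, int]]:
    """Yield ``(offset, mismatches)`` for every occurrence of ``pattern``
    in ``seq`` at Hamming distance <= ``max_mm``. Offsets ascend."""
    m = len(pattern)
    for off in range(len(seq) - m + 1):
        mm = hamming_capped(seq[off : off + m], pattern, max_mm)
        if mm <= max_mm:
            yield off, mm


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 numpy array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def sliding_mismatches(seq: str, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` against every window of ``seq``.

    Vectorised; returns an int array of length ``len(seq) - len(pattern) + 1``
    (empty when the pattern is longer than the sequence).
    """
    s = encode(seq)
    p = encode(pattern)
    if len(s) < len(p):
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(p))
    return (windows != p).sum(axis=1)


def validate_dna(seq: str, *, what: str = "sequence", allow_n: bool = True) -> str:
    """Uppercase and validate a DNA string against the ACGT(N) alphabet."""
    seq = seq.upper()
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq
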