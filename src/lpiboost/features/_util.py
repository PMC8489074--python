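"""Shared k-mer counting machinery for both sequence alphabets."""

from __future__ import annotations

from itertools import product

import numpy as np


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Integer codes for a sequence over ``alphabet`` (raises on foreign
    symbols — sequences are expected to be normalised upstream)."""
    lookup = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.fromiter((lookup[c] for c in seq), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside alphabet "
                         f"{alphabet!r}") from None


def kmer_indices(codes: np.ndarray, k: int, base: int) -> np.ndarray:
    """Lexicographic index of every length-``k`` window of ``codes``."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    for i in range(k):
        idx = idx * base + codes[i:i + n]
    return idx


def kmer_frequencies(codes: np.ndarray, k: int, base: int) -> np.ndarray:
    """Sliding-window k-mer frequencies (length base**k, sums to 1)."""
    idx = kmer_indices(codes, k, base)
    if idx.size == 0:
        raise ValueError(f"sequence shorter than k={k}")
    counts = np.bincount(idx, minlength=base ** k).astype(float)
    return counts / idx.size


def kmer_names(alphabet: str, k: int) -> list[str]:
    return ["".join(t) for t in product(alphabet, repeat=k)]
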