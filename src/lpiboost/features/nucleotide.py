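"""The 3,051-dimensional lncRNA sequence descriptor.

The descriptor concatenates, in a fixed block order: z-curve (3), GC content
(1), AT/GC ratio (1), cumulative GC/AT skews (2), pseudo k-nucleotide
composition for k = 1..3 (84), and eight families of gapped dinucleotide-
style compositions (monoMono 16, monoDi 256, monoTri 64, diMono 64,
diDi 1024, diTri 256, triMono 256, triDi 1024).

Each gapped family counts patterns L.(gap g).R where L and R are k-mers of
the family's left/right orders; gap distances run over 1..5 restricted to the
family's gap set, enumerated gap-outermost then lexicographically.  Two
family widths (monoTri, diTri) are fixed, historically-printed constants that
do not equal the natural 4^kL*4^kR*|G| pattern count; those families
enumerate the natural |G|=1 pattern set and truncate to the declared width in
lexicographic order (logged once per family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import encode, kmer_indices, kmer_names

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
DESCRIPTOR_LENGTH = 3051
MIN_SEQUENCE_LENGTH = 16  # widest gapped pattern plus margin

#: family -> (left k, right k, gap set, emitted dimension)
GAPPED_FAMILIES: dict[str, tuple[int, int, tuple[int, ...], int]] = {
    "monoMono": (1, 1, (1,), 16),
    "monoDi": (1, 2, (1, 2, 3, 4), 256),
    "monoTri": (1, 3, (1,), 64),    # truncated from 256
    "diMono": (2, 1, (1,), 64),
    "diDi": (2, 2, (1, 2, 3, 4), 1024),
    "diTri": (2, 3, (1,), 256),     # truncated from 1024
    "triMono": (3, 1, (1,), 256),
    "triDi": (3, 2, (1,), 1024),
}

_truncation_logged: set[str] = set()


def _codes(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("empty sequence")
    return encode(seq, ALPHABET)


def _base_counts(seq: str) -> np.ndarray:
    return np.bincount(_codes(seq), minlength=4).astype(float)


def zcurve(seq: str) -> np.ndarray:
    """Raw-count z-curve components (purine/pyrimidine, amino/keto,
    weak/strong)."""
    a, c, g, t = _base_counts(seq)
    return np.array([(a + g) - (c + t),
                     (a + c) - (g + t),
                     (a + t) - (g + c)])


def gc_content(seq: str) -> float:
    a, c, g, t = _base_counts(seq)
    return (g + c) / len(seq)


def atgc_ratio(seq: str) -> float:
    """(A+T)/(G+C); a GC-free sequence yields 0 with a warning."""
    a, c, g, t = _base_counts(seq)
    if g + c == 0:
        logger.warning("atgc_ratio: degenerate input with no G/C, returning 0")
        return 0.0
    return (a + t) / (g + c)


def cumulative_skew(seq: str) -> np.ndarray:
    """GC skew (G-C)/(G+C) and AT skew (A-T)/(A+T); zero denominators
    yield 0."""
    a, c, g, t = _base_counts(seq)
    gc = (g - c) / (g + c) if g + c else 0.0
    at = (a - t) / (a + t) if a + t else 0.0
    return np.array([gc, at])


def pseudo_knc(seq: str, ktuple: int = 3) -> np.ndarray:
    """Concatenated k-mer frequency vectors for k = 1..ktuple (each k-block
    sums to 1); dimension sum(4**k) = 84 for ktuple=3."""
    if ktuple < 1:
        raise ValueError("ktuple must be >= 1")
    if len(seq) < ktuple:
        raise ValueError(f"sequence length {len(seq)} < ktuple {ktuple}")
    codes = _codes(seq)
    blocks = []
    for k in range(1, ktuple + 1):
        idx = kmer_indices(codes, k, 4)
        blocks.append(np.bincount(idx, minlength=4 ** k) / idx.size)
    return np.concatenate(blocks)


def kgap_family(seq: str, family: str) -> np.ndarray:
    """Gapped-pattern composition for one family; each populated gap-block is
    normalised by its window count.  A sequence too short for a gap-block
    yields zeros for that block with a warning."""
    if family not in GAPPED_FAMILIES:
        raise ValueError(f"unknown gapped family {family!r}; expected one of "
                         f"{sorted(GAPPED_FAMILIES)}")
    k_left, k_right, gaps, dim = GAPPED_FAMILIES[family]
    codes = _codes(seq)
    n_patterns = 4 ** k_left * 4 ** k_right
    blocks = []
    for g in gaps:
        width = k_left + g + k_right
        n_win = len(codes) - width + 1
        if n_win <= 0:
            logger.warning("kgap_family(%s): sequence too short for gap %d, "
                           "emitting zeros", family, g)
            blocks.append(np.zeros(n_patterns))
            continue
        left = kmer_indices(codes[:n_win + k_left - 1], k_left, 4)[:n_win]
        right_start = k_left + g
        right = kmer_indices(codes[right_start:], k_right, 4)[:n_win]
        combined = left * 4 ** k_right + right
        blocks.append(np.bincount(combined, minlength=n_patterns) / n_win)
    vec = np.concatenate(blocks)
    if vec.size > dim:
        if family not in _truncation_logged:
            logger.warning(
                "kgap_family(%s): truncating natural %d-pattern enumeration "
                "to the declared width %d (lexicographic order)",
                family, vec.size, dim)
            _truncation_logged.add(family)
        vec = vec[:dim]
    assert vec.size == dim
    return vec


def _block_spec() -> list[tuple[str, int]]:
    spec = [("zcurve", 3), ("gc_content", 1), ("atgc_ratio", 1),
            ("cumulative_skew", 2), ("pseudo_knc", 84)]
    spec += [(f, GAPPED_FAMILIES[f][3]) for f in GAPPED_FAMILIES]
    return spec


@dataclass
class LncRNADescriptor:
    """Fixed-length numeric descriptor with named feature-group blocks."""

    values: np.ndarray
    blocks: dict[str, tuple[int, int]]  # name -> (offset, length)

    def block(self, name: str) -> np.ndarray:
        off, length = self.blocks[name]
        return self.values[off:off + length]


def lncrna_descriptor(seq: str) -> LncRNADescriptor:
    """Full 3,051-dimensional descriptor of a normalised nucleotide
    sequence (length >= 16)."""
    if len(seq) < MIN_SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence length {len(seq)} below minimum "
            f"{MIN_SEQUENCE_LENGTH} for the lncRNA descriptor")
    parts = [zcurve(seq), [gc_content(seq)], [atgc_ratio(seq)],
             cumulative_skew(seq), pseudo_knc(seq, 3)]
    parts += [kgap_family(seq, fam) for fam in GAPPED_FAMILIES]
    values = np.concatenate([np.asarray(p, dtype=float) for p in parts])
    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, length in _block_spec():
        blocks[name] = (offset, length)
        offset += length
    assert offset == DESCRIPTOR_LENGTH == values.size
    return LncRNADescriptor(values=values, blocks=blocks)


def feature_names() -> list[str]:
    """Block-qualified names for all 3,051 descriptor coordinates."""
    names = ["zcurve.x", "zcurve.y", "zcurve.z", "gc_content",
             "atgc_ratio", "skew.gc", "skew.at"]
    for k in (1, 2, 3):
        names += [f"knc.k{k}.{m}" for m in kmer_names(ALPHABET, k)]
    for fam, (kl, kr, gaps, dim) in GAPPED_FAMILIES.items():
        fam_names = []
        for g in gaps:
            for left in kmer_names(ALPHABET, kl):
                for right in kmer_names(ALPHABET, kr):
                    fam_names.append(f"{fam}.g{g}.{left}_{right}")
        names += fam_names[:dim]
    assert len(names) == DESCRIPTOR_LENGTH
    return names


def feature_matrix(records) -> "np.ndarray":
    """Descriptor matrix (n_records x 3,051) from SequenceRecord objects."""
    return np.vstack([lncrna_descriptor(r.sequence).values for r in records])
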