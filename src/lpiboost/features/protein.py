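"""The 9,890-dimensional protein sequence descriptor.

Block order (lengths): amino-acid composition (20), dipeptide composition
(400), tripeptide composition (8000), normalised Moreau-Broto / Moran /
Geary autocorrelation (240 each: 8 physicochemical scales x 30 lags),
composition/transition/distribution over 7 property groupings (21/21/105),
conjoint triad (343), sequence-order coupling numbers (60: 30 lags x 2
residue-distance matrices), quasi-sequence-order (100: 20 + 30 per matrix),
classic pseudo amino-acid composition (50: 20 + lambda 30) and amphiphilic
pseudo amino-acid composition (50: 20 + 2 x lambda 15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tables as T
from ._util import encode, kmer_frequencies, kmer_indices

ALPHABET = T.AA
DESCRIPTOR_LENGTH = 9890
MIN_SEQUENCE_LENGTH = 32  # the binding constraint is the 30-lag statistics

_EPS = 1e-12


def _codes(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("empty sequence")
    return encode(seq, ALPHABET)


def kmer_composition(seq: str, k: int) -> np.ndarray:
    """Sliding-window k-mer frequencies over the 20-letter alphabet
    (lexicographic order, sums to 1)."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    return kmer_frequencies(_codes(seq), k, 20)


_AC_KINDS = ("normalized_moreau_broto", "moran", "geary")


def autocorrelation(seq: str, kind: str, nlag: int = 30) -> np.ndarray:
    """Autocorrelation over 8 standardised property scales and lags
    1..nlag (scale-major order, dimension 8*nlag).

    Moran and Geary statistics have a sequence-variance denominator; a
    sequence whose property values are constant yields 0 for every lag of
    that scale by convention.
    """
    if kind not in _AC_KINDS:
        raise ValueError(f"kind must be one of {_AC_KINDS}")
    n = len(seq)
    if n <= nlag:
        raise ValueError(f"sequence length {n} must exceed nlag={nlag}")
    codes = _codes(seq)
    out = np.empty(8 * nlag)
    for s, scale in enumerate(T.AUTOCORRELATION_SCALES.values()):
        p = T.scale_vector(scale)[codes]
        pbar = p.mean()
        centered = p - pbar
        var_n = float(centered @ centered) / n          # population variance
        var_n1 = float(centered @ centered) / (n - 1) if n > 1 else 0.0
        for d in range(1, nlag + 1):
            a, b = p[:-d], p[d:]
            if kind == "normalized_moreau_broto":
                val = float(a @ b) / (n - d)
            elif kind == "moran":
                if var_n < _EPS:
                    val = 0.0
                else:
                    val = (float((a - pbar) @ (b - pbar)) / (n - d)) / var_n
            else:  # geary
                if var_n1 < _EPS:
                    val = 0.0
                else:
                    val = (float(((a - b) ** 2).sum()) / (2 * (n - d))) / var_n1
            out[s * nlag + d - 1] = val
    return out


def _ctd_classes(seq: str, groups: tuple[str, str, str]) -> np.ndarray:
    lookup = np.zeros(20, dtype=np.int64)
    for cls, members in enumerate(groups):
        for aa in members:
            lookup[T.AA_INDEX[aa]] = cls
    return lookup[_codes(seq)]


def ctd(seq: str) -> np.ndarray:
    """Composition (21), transition (21) and distribution (105) descriptors
    over the 7 canonical physicochemical groupings x 3 classes.

    Distribution reports, per class, the normalised sequence positions of the
    first, 25%, 50%, 75% and last occurrence (1-based position / length); an
    absent class contributes 5 zeros.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("CTD requires sequence length >= 2")
    comp, trans, dist = [], [], []
    for groups in T.CTD_GROUPS.values():
        cls = _ctd_classes(seq, groups)
        counts = np.bincount(cls, minlength=3).astype(float)
        comp.extend(counts / n)
        a, b = cls[:-1], cls[1:]
        for x, y in ((0, 1), (0, 2), (1, 2)):
            t = np.sum(((a == x) & (b == y)) | ((a == y) & (b == x)))
            trans.append(t / (n - 1))
        for c in range(3):
            pos = np.flatnonzero(cls == c) + 1  # 1-based
            if pos.size == 0:
                dist.extend([0.0] * 5)
                continue
            marks = [pos[0]]
            for q in (0.25, 0.50, 0.75, 1.00):
                k = max(1, int(np.ceil(q * pos.size)))
                marks.append(pos[k - 1])
            dist.extend(m / n for m in marks)
    return np.concatenate([comp, trans, dist])


def conjoint_triad(seq: str) -> np.ndarray:
    """Frequencies of 7-class residue triads over sliding windows
    (dimension 343, sums to 1)."""
    if len(seq) < 3:
        raise ValueError("conjoint triad requires sequence length >= 3")
    lookup = np.zeros(20, dtype=np.int64)
    for cls, members in enumerate(T.CONJOINT_CLASSES):
        for aa in members:
            lookup[T.AA_INDEX[aa]] = cls
    cls_codes = lookup[_codes(seq)]
    idx = kmer_indices(cls_codes, 3, 7)
    return np.bincount(idx, minlength=343) / idx.size


def _coupling_numbers(codes: np.ndarray, dist: np.ndarray, maxlag: int
                      ) -> np.ndarray:
    """tau_d = sum_i d(r_i, r_{i+d})^2 for d = 1..maxlag."""
    return np.array([float((dist[codes[:-d], codes[d:]] ** 2).sum())
                     for d in range(1, maxlag + 1)])


def sequence_order(seq: str, maxlag: int = 30, weight: float = 0.1
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sequence-order coupling numbers (2 x maxlag) and quasi-sequence-order
    descriptors (2 x (20 + maxlag)) under two residue-distance matrices
    (a hydrophobicity/hydrophilicity/mass composite, then Grantham)."""
    n = len(seq)
    if n <= maxlag:
        raise ValueError(f"sequence length {n} must exceed maxlag={maxlag}")
    codes = _codes(seq)
    freqs = np.bincount(codes, minlength=20) / n
    socn_parts, qso_parts = [], []
    for dist in (T.physicochemical_distance_matrix(),
                 T.grantham_distance_matrix()):
        tau = _coupling_numbers(codes, dist, maxlag)
        socn_parts.append(tau)
        denom = freqs.sum() + weight * tau.sum()
        qso_parts.append(np.concatenate([freqs / denom,
                                         weight * tau / denom]))
    return np.concatenate(socn_parts), np.concatenate(qso_parts)


_PSEAAC_SCALES = (T.HYDROPHOBICITY, T.HYDROPHILICITY, T.SIDE_CHAIN_MASS)


def pseaac(seq: str, variant: str = "classic", lam: int | None = None,
           weight: float = 0.05) -> np.ndarray:
    """Type-I ("classic", lambda 30) or type-II ("amphiphilic", lambda 15)
    pseudo amino-acid composition; dimension 50, sums to 1.

    Classic correlation factors average squared differences of three
    standardised scales (hydrophobicity, hydrophilicity, side-chain mass);
    amphiphilic factors alternate hydrophobicity and hydrophilicity
    products.
    """
    if variant not in ("classic", "amphiphilic"):
        raise ValueError("variant must be 'classic' or 'amphiphilic'")
    if lam is None:
        lam = 30 if variant == "classic" else 15
    n = len(seq)
    if n <= lam:
        raise ValueError(f"sequence length {n} must exceed lambda={lam} "
                         f"for the {variant} variant")
    codes = _codes(seq)
    freqs = np.bincount(codes, minlength=20) / n
    scales = [T.scale_vector(s)[codes] for s in _PSEAAC_SCALES]
    if variant == "classic":
        theta = np.array([
            float(np.mean([np.mean((s[:-d] - s[d:]) ** 2) for s in scales]))
            for d in range(1, lam + 1)])
    else:
        h1, h2 = scales[0], scales[1]
        theta = np.empty(2 * lam)
        for d in range(1, lam + 1):
            theta[2 * (d - 1)] = float(h1[:-d] @ h1[d:]) / (n - d)
            theta[2 * (d - 1) + 1] = float(h2[:-d] @ h2[d:]) / (n - d)
    denom = freqs.sum() + weight * theta.sum()
    return np.concatenate([freqs / denom, weight * theta / denom])


_BLOCK_SPEC = [
    ("aac", 20), ("dipeptide", 400), ("tripeptide", 8000),
    ("nmb_autocorrelation", 240), ("moran_autocorrelation", 240),
    ("geary_autocorrelation", 240),
    ("ctd_composition", 21), ("ctd_transition", 21),
    ("ctd_distribution", 105),
    ("conjoint_triad", 343),
    ("socn", 60), ("qso", 100),
    ("pseaac", 50), ("apseaac", 50),
]


@dataclass
class ProteinDescriptor:
    """Fixed-length numeric descriptor with named feature-group blocks."""

    values: np.ndarray
    blocks: dict[str, tuple[int, int]]

    def block(self, name: str) -> np.ndarray:
        off, length = self.blocks[name]
        return self.values[off:off + length]


def protein_descriptor(seq: str) -> ProteinDescriptor:
    """Full 9,890-dimensional descriptor of a normalised amino-acid
    sequence (length > 31; the 30-lag autocorrelation/sequence-order
    statistics are the binding constraint)."""
    if len(seq) < MIN_SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence length {len(seq)} below minimum {MIN_SEQUENCE_LENGTH};"
            " the 30-lag autocorrelation and sequence-order blocks require"
            " length > 31")
    ctd_vec = ctd(seq)
    socn, qso = sequence_order(seq)
    parts = [
        kmer_composition(seq, 1), kmer_composition(seq, 2),
        kmer_composition(seq, 3),
        autocorrelation(seq, "normalized_moreau_broto"),
        autocorrelation(seq, "moran"),
        autocorrelation(seq, "geary"),
        ctd_vec[:21], ctd_vec[21:42], ctd_vec[42:],
        conjoint_triad(seq),
        socn, qso,
        pseaac(seq, "classic"), pseaac(seq, "amphiphilic"),
    ]
    values = np.concatenate(parts)
    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, length in _BLOCK_SPEC:
        blocks[name] = (offset, length)
        offset += length
    assert offset == DESCRIPTOR_LENGTH == values.size
    return ProteinDescriptor(values=values, blocks=blocks)


def feature_names() -> list[str]:
    """Block-qualified names for all 9,890 descriptor coordinates."""
    from ._util import kmer_names

    names = [f"aac.{a}" for a in ALPHABET]
    names += [f"dipeptide.{m}" for m in kmer_names(ALPHABET, 2)]
    names += [f"tripeptide.{m}" for m in kmer_names(ALPHABET, 3)]
    for stat in ("nmb", "moran", "geary"):
        for scale in T.AUTOCORRELATION_SCALES:
            names += [f"{stat}.{scale}.lag{d}" for d in range(1, 31)]
    for grp in T.CTD_GROUPS:
        names += [f"ctd_comp.{grp}.c{c}" for c in (1, 2, 3)]
    for grp in T.CTD_GROUPS:
        names += [f"ctd_trans.{grp}.{t}" for t in ("12", "13", "23")]
    for grp in T.CTD_GROUPS:
        for c in (1, 2, 3):
            names += [f"ctd_dist.{grp}.c{c}.{q}"
                      for q in ("first", "q25", "q50", "q75", "last")]
    names += [f"triad.{i}" for i in range(343)]
    for mat in ("physchem", "grantham"):
        names += [f"socn.{mat}.lag{d}" for d in range(1, 31)]
    for mat in ("physchem", "grantham"):
        names += [f"qso.{mat}.{a}" for a in ALPHABET]
        names += [f"qso.{mat}.lag{d}" for d in range(1, 31)]
    names += [f"pseaac.{a}" for a in ALPHABET]
    names += [f"pseaac.lam{d}" for d in range(1, 31)]
    names += [f"apseaac.{a}" for a in ALPHABET]
    names += [f"apseaac.tau{d}" for d in range(1, 31)]
    assert len(names) == DESCRIPTOR_LENGTH
    return names


def feature_matrix(records) -> np.ndarray:
    """Descriptor matrix (n_records x 9,890) from SequenceRecord objects."""
    return np.vstack([protein_descriptor(r.sequence).values for r in records])
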