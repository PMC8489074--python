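"""Sequence and interaction-network I/O.

Two entity kinds are handled: lncRNA nucleotide sequences (normalised to the
{A,C,G,T} alphabet, with RNA ``U`` mapped to ``T``) and protein amino-acid
sequences over the 20 standard residues.  Interactions live in a dense binary
matrix ``Y`` indexed (lncRNA, protein) with ``y_ij = 1`` for a known
interaction, assembled from a tab-separated edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_KINDS = ("lncRNA", "protein")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet."""

    id: str
    sequence: str
    kind: str  # "lncRNA" or "protein"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")


def normalize_sequence(raw: str, kind: str) -> str:
    """Uppercase and restrict a raw sequence to its canonical alphabet.

    Nucleotide sequences have ``U`` mapped to ``T``; symbols outside the
    canonical alphabet (ambiguity codes, the non-standard amino acids
    B/J/O/U/X/Z, gaps...) are removed with a logged count so that composition
    denominators stay well defined downstream.
    """
    seq = raw.upper()
    if kind == "lncRNA":
        seq = seq.replace("U", "T")
        alphabet = NUCLEOTIDE_ALPHABET
    elif kind == "protein":
        alphabet = PROTEIN_ALPHABET
    else:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    kept = [c for c in seq if c in alphabet]
    n_removed = len(seq) - len(kept)
    if n_removed:
        logger.warning("removed %d non-standard symbol(s) from a %s sequence",
                       n_removed, kind)
    return "".join(kept)


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    Records whose sequence is empty after normalisation are dropped with a
    warning.  Malformed input (sequence data before the first header) and
    duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first "
                    f"FASTA header")
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), kind)
        if not seq:
            logger.warning("dropping %r: empty sequence after normalisation",
                           rec.id)
            continue
        records.append(SequenceRecord(id=rec.id, sequence=seq, kind=kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="")
           for r in records]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class InteractionDataset:
    """Entity id lists plus the binary interaction matrix ``Y``.

    ``Y`` has shape ``(len(lncrna_ids), len(protein_ids))`` and entries in
    {0, 1}; row/column order follows the id lists.
    """

    lncrna_ids: list[str]
    protein_ids: list[str]
    Y: np.ndarray
    _lnc_index: dict[str, int] = field(init=False, repr=False)
    _prot_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if self.Y.shape != (len(self.lncrna_ids), len(self.protein_ids)):
            raise ValueError(
                f"Y shape {self.Y.shape} does not match id counts "
                f"({len(self.lncrna_ids)}, {len(self.protein_ids)})")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y entries must be 0 or 1")
        for name, ids in (("lncrna_ids", self.lncrna_ids),
                          ("protein_ids", self.protein_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate entries in {name}")
        self._lnc_index = {i: k for k, i in enumerate(self.lncrna_ids)}
        self._prot_index = {i: k for k, i in enumerate(self.protein_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def lnc_index(self, lnc_id: str) -> int:
        try:
            return self._lnc_index[lnc_id]
        except KeyError:
            raise KeyError(f"unknown lncRNA id {lnc_id!r}") from None

    def prot_index(self, prot_id: str) -> int:
        try:
            return self._prot_index[prot_id]
        except KeyError:
            raise KeyError(f"unknown protein id {prot_id!r}") from None

    def positive_pairs(self) -> np.ndarray:
        """Indices (i, j) of known interactions, row-major order."""
        return np.argwhere(self.Y == 1)


def read_interactions(path: str | Path,
                      lncrna_ids: Sequence[str],
                      protein_ids: Sequence[str]) -> InteractionDataset:
    """Assemble an :class:`InteractionDataset` from a TSV edge list.

    Each line is ``lncrna_id<TAB>protein_id``.  Edges referencing unknown ids
    raise ``ValueError`` listing the offenders; duplicate edges are counted
    once with a warning.
    """
    path = Path(path)
    lncrna_ids = list(lncrna_ids)
    protein_ids = list(protein_ids)
    Y = np.zeros((len(lncrna_ids), len(protein_ids)), dtype=np.int8)
    ds = InteractionDataset(lncrna_ids, protein_ids, Y)
    try:
        edges = pd.read_csv(path, sep="\t", header=None, dtype=str,
                            names=["lncrna", "protein"])
    except pd.errors.EmptyDataError:
        return ds
    unknown: list[str] = []
    for col, index in (("lncrna", ds._lnc_index), ("protein", ds._prot_index)):
        bad = sorted(set(edges[col]) - set(index))
        unknown.extend(f"{col}:{b}" for b in bad)
    if unknown:
        raise ValueError(f"{path}: edges reference unknown ids: "
                         + ", ".join(unknown))
    n_dup = len(edges) - len(edges.drop_duplicates())
    if n_dup:
        logger.warning("%s: %d duplicate edge(s), counted once", path, n_dup)
    rows = edges["lncrna"].map(ds._lnc_index).to_numpy()
    cols = edges["protein"].map(ds._prot_index).to_numpy()
    ds.Y[rows, cols] = 1
    return ds


def write_interactions(ds: InteractionDataset, path: str | Path) -> None:
    """Write the positive edges of a dataset as a two-column TSV."""
    pairs = ds.positive_pairs()
    with open(path, "w") as fh:
        for i, j in pairs:
            fh.write(f"{ds.lncrna_ids[i]}\t{ds.protein_ids[j]}\n")


def read_interaction_matrix(path: str | Path) -> InteractionDataset:
    """Read the dense-matrix TSV dialect (header = protein ids, first
    column = lncRNA ids, cells in {0,1})."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return InteractionDataset(list(df.index.astype(str)),
                              list(df.columns.astype(str)),
                              df.to_numpy())


def write_interaction_matrix(ds: InteractionDataset,
                             path: str | Path) -> None:
    df = pd.DataFrame(ds.Y, index=ds.lncrna_ids, columns=ds.protein_ids)
    df.to_csv(path, sep="\t")


def dataset_summary(ds: InteractionDataset) -> dict[str, int]:
    """Counts (n_lncrna, n_protein, n_positive, n_pairs) for a dataset."""
    n_l, n_p = ds.shape
    return {
        "n_lncrna": n_l,
        "n_protein": n_p,
        "n_positive": int(ds.Y.sum()),
        "n_pairs": n_l * n_p,
    }
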