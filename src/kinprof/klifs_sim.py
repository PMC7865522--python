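"""Pocket-sequence identity and interaction-fingerprint similarity.

Both measures live on the KLIFS 85-residue definition of the kinase
ATP-binding pocket:

* **PocSeqSim** — fraction of identical residues between two kinases
  over the fixed 85-position pocket alignment.  A gap matches nothing,
  including another gap: no residue is present to be identical.
* **IFPSim** — Tanimoto similarity between interaction fingerprints.
  An IFP encodes, for each of the 85 pocket residues, seven interaction
  types with the bound ligand (hydrophobic, aromatic face-to-face and
  edge-to-face, H-bond donor/acceptor both directions, ionic both
  directions) as 85 x 7 = 595 presence bits.  Kinase-level similarity
  is the maximum Tanimoto over all structure pairs; the diagonal is the
  best match between *different* structures of the same kinase.

Structure lists are filtered the way curated fingerprint sets are
built: only structures with orthosteric (ATP-pocket) ligands, and one
entry per PDB structure — the chain/alt-model entry with the highest
KLIFS quality score (0 bad .. 10 flawless), ties broken by smallest
structure key for determinism.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .similarity import SimilarityMatrix

__all__ = [
    "POCKET_LENGTH",
    "IFP_LENGTH",
    "N_INTERACTION_TYPES",
    "PocketSequence",
    "IFPRecord",
    "read_pocket_fasta",
    "read_pocket_tsv",
    "poc_seq_sim",
    "poc_seq_sim_matrix",
    "filter_structures",
    "tanimoto",
    "ifp_sim_matrix",
    "read_ifp_tsv",
    "write_ifp_tsv",
]

logger = logging.getLogger(__name__)

POCKET_LENGTH = 85
N_INTERACTION_TYPES = 7
IFP_LENGTH = POCKET_LENGTH * N_INTERACTION_TYPES  # 595

_POCKET_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX-")
_GAP = "-"
_DFG_STATES = ("in", "out", "out-like")


@dataclass(frozen=True)
class PocketSequence:
    """One kinase's 85-residue pocket sequence from the master MSA."""

    kinase_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != POCKET_LENGTH:
            raise ValueError(
                f"pocket sequence for {self.kinase_id!r} has length "
                f"{len(self.residues)}, expected {POCKET_LENGTH}"
            )
        bad = set(self.residues.upper()) - _POCKET_ALPHABET
        if bad:
            raise ValueError(
                f"invalid residue codes {sorted(bad)} in pocket sequence "
                f"for {self.kinase_id!r}"
            )
        object.__setattr__(self, "residues", self.residues.upper())


@dataclass(frozen=True)
class IFPRecord:
    """One KLIFS-style structure entry with its interaction fingerprint.

    ``structure_key`` is the PDB id plus a chain/alt-model discriminator
    (e.g. ``3poz_A``); the PDB id is the leading alphanumeric token.
    """

    structure_key: str
    kinase_id: str
    bits: tuple[int, ...]
    quality: float
    orthosteric: bool = True
    dfg: str = "in"
    alpha_c: str = "in"

    def __post_init__(self) -> None:
        if len(self.bits) != IFP_LENGTH:
            raise ValueError(
                f"IFP for {self.structure_key!r} has {len(self.bits)} bits, "
                f"expected {IFP_LENGTH}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("IFP bits must be 0/1")
        if not 0.0 <= self.quality <= 10.0:
            raise ValueError(f"quality {self.quality} outside [0, 10]")
        if self.dfg not in _DFG_STATES or self.alpha_c not in _DFG_STATES:
            raise ValueError(f"dfg/alpha_c must be one of {_DFG_STATES}")

    @property
    def pdb_id(self) -> str:
        """Leading alphanumeric token of the structure key."""
        return re.split(r"[^0-9A-Za-z]", self.structure_key, maxsplit=1)[0]

    @property
    def bit_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)


def poc_seq_sim(a: PocketSequence, b: PocketSequence) -> float:
    """Identity fraction over the 85-position pocket alignment.

    Counts positions where both sequences carry the *same non-gap*
    residue, divided by the fixed alignment length 85.
    """
    identical = sum(
        1
        for ra, rb in zip(a.residues, b.residues)
        if ra == rb and ra != _GAP
    )
    return identical / POCKET_LENGTH


def poc_seq_sim_matrix(sequences: Sequence[PocketSequence]) -> SimilarityMatrix:
    """All-pairs PocSeqSim over a panel of pocket sequences."""
    if not sequences:
        raise ValueError("need at least one pocket sequence")
    labels = [s.kinase_id for s in sequences]
    n = len(sequences)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = poc_seq_sim(sequences[i], sequences[j])
    return SimilarityMatrix(
        labels, values, measure_name="PocSeqSim", value_range=(0.0, 1.0)
    )


def read_pocket_fasta(path: str | Path) -> list[PocketSequence]:
    """Read pocket sequences from FASTA (record id = kinase id)."""
    seqs = [
        PocketSequence(kinase_id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def read_pocket_tsv(path: str | Path) -> list[PocketSequence]:
    """Read pocket sequences from a two-column (kinase_id, sequence) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["kinase_id", "residues"],
                     dtype=str)
    return [
        PocketSequence(kinase_id=row.kinase_id, residues=row.residues)
        for row in df.itertuples(index=False)
    ]


def filter_structures(
    records: Iterable[IFPRecord],
    *,
    dfg: str | None = None,
    alpha_c: str | None = None,
) -> list[IFPRecord]:
    """Reduce a structure list to one high-quality entry per PDB structure.

    Non-orthosteric entries are removed; optional DFG/aC conformation
    filters apply next.  Among entries sharing a PDB id the highest
    quality score wins, ties going to the lexicographically smallest
    structure key.  Output is sorted by structure key, so the result is
    invariant to input order.
    """
    kept: dict[str, IFPRecord] = {}
    for rec in records:
        if not rec.orthosteric:
            continue
        if dfg is not None and rec.dfg != dfg:
            continue
        if alpha_c is not None and rec.alpha_c != alpha_c:
            continue
        current = kept.get(rec.pdb_id)
        if (
            current is None
            or rec.quality > current.quality
            or (rec.quality == current.quality
                and rec.structure_key < current.structure_key)
        ):
            kept[rec.pdb_id] = rec
    return sorted(kept.values(), key=lambda r: r.structure_key)


def tanimoto(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary vectors.

    Two all-zero fingerprints share no interactions and score 0 (with a
    warning — filtered data should not contain interaction-free IFPs).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; defined as 0",
                      stacklevel=2)
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def ifp_sim_matrix(
    records: Sequence[IFPRecord],
    kinases: Sequence[str] | None = None,
    *,
    apply_filter: bool = True,
    dfg: str | None = None,
    alpha_c: str | None = None,
) -> SimilarityMatrix:
    """Kinase-level IFPSim: max Tanimoto over structure pairs.

    Off-diagonal entries compare every structure of one kinase with
    every structure of the other; the diagonal compares distinct
    structures of the same kinase and is NaN for single-structure
    kinases.  ``apply_filter`` runs :func:`filter_structures` first;
    pass False for pre-filtered input.
    """
    if apply_filter:
        records = filter_structures(records, dfg=dfg, alpha_c=alpha_c)
    by_kinase: dict[str, list[IFPRecord]] = {}
    for rec in records:
        by_kinase.setdefault(rec.kinase_id, []).append(rec)
    if kinases is None:
        kinases = sorted(by_kinase)
    kinases = list(kinases)
    n = len(kinases)
    values = np.full((n, n), np.nan)
    for i, ka in enumerate(kinases):
        structs_a = by_kinase.get(ka, [])
        if not structs_a:
            warnings.warn(f"kinase {ka} has no structures; NaN row", stacklevel=2)
            continue
        same = [
            tanimoto(ra.bit_array, rb.bit_array)
            for ra, rb in itertools.combinations(structs_a, 2)
        ]
        if same:
            values[i, i] = max(same)
        for j in range(i + 1, n):
            structs_b = by_kinase.get(kinases[j], [])
            cross = [
                tanimoto(ra.bit_array, rb.bit_array)
                for ra in structs_a
                for rb in structs_b
            ]
            if cross:
                values[i, j] = values[j, i] = max(cross)
    return SimilarityMatrix(
        kinases, values, measure_name="IFPSim", value_range=(0.0, 1.0)
    )


_IFP_COLUMNS = ["structure_key", "kinase_id", "quality", "orthosteric",
                "dfg", "alpha_c", "ifp"]


def read_ifp_tsv(path: str | Path) -> list[IFPRecord]:
    """Read IFP records from TSV with columns structure_key, kinase_id,
    quality, orthosteric (0/1), dfg, alpha_c, ifp (595-char 0/1 string).
    Bit ordering is residue-major: residue 1 types 1-7, residue 2 ..."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _IFP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IFP table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            IFPRecord(
                structure_key=str(row.structure_key),
                kinase_id=str(row.kinase_id),
                bits=tuple(int(c) for c in str(row.ifp)),
                quality=float(row.quality),
                orthosteric=str(row.orthosteric).strip() in ("1", "True", "true"),
                dfg=str(row.dfg),
                alpha_c=str(row.alpha_c),
            )
        )
    return records


def write_ifp_tsv(records: Sequence[IFPRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "structure_key": [r.structure_key for r in records],
            "kinase_id": [r.kinase_id for r in records],
            "quality": [r.quality for r in records],
            "orthosteric": [int(r.orthosteric) for r in records],
            "dfg": [r.dfg for r in records],
            "alpha_c": [r.alpha_c for r in records],
            "ifp": ["".join(str(b) for b in r.bits) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
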