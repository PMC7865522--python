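"""Reading docking score tables and deriving deterministic molecule ranks.

A docking run is one structure's scored molecule list (e.g. a DOCK-style
output where lower energy means a better pose).  Downstream scoring only
consumes the 1-based ordinal rank ``r`` of each molecule and the library
size ``m``; this module owns both, including the deterministic tie rule
(equal scores are ordered by molecule identifier) so that re-ranking the
same table always reproduces identical ranks.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pandas as pd
import yaml

__all__ = [
    "MoleculeScore",
    "DockingRun",
    "read_score_table",
    "compute_ranks",
    "scaled_rank",
    "write_ranked_table",
    "read_manifest",
]


@dataclass(frozen=True)
class MoleculeScore:
    """A single (molecule identifier, docking score) pair."""

    molecule_id: str
    score: float

    def __post_init__(self) -> None:
        if not self.molecule_id:
            raise ValueError("molecule_id must be a non-empty string")


@dataclass
class DockingRun:
    """One structure's scored molecule list with derived 1-based ranks.

    Parameters
    ----------
    kinase_id, structure_id
        Labels identifying the protein and the particular structure
        (PDB-style code) the library was docked into.
    entries
        One :class:`MoleculeScore` per distinct molecule.
    ascending
        If True (default) lower scores are better, as for DOCK-style
        energies; set False for scoring functions where higher is better.
    """

    kinase_id: str
    structure_id: str
    entries: list[MoleculeScore]
    ascending: bool = True
    ranks: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        """Number of docked molecules ``m``."""
        return len(self.entries)

    @property
    def is_ranked(self) -> bool:
        return len(self.ranks) == len(self.entries)

    def rank(self, molecule_id: str) -> int:
        """1-based ordinal rank ``r`` of a molecule."""
        try:
            return self.ranks[molecule_id]
        except KeyError:
            raise KeyError(
                f"molecule {molecule_id!r} not docked in structure "
                f"{self.structure_id!r}"
            ) from None

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in self.ranks


def compute_ranks(run: DockingRun) -> DockingRun:
    """Assign ordinal ranks 1..m by score, in place, and return the run.

    Ranks are ordinal (no ties): molecules are sorted by score, best
    first, and equal scores are broken by lexicographic molecule_id so
    the ranking is reproducible across platforms and runs.
    """
    if not run.entries:
        raise ValueError("cannot rank an empty docking run")
    sign = 1.0 if run.ascending else -1.0
    ordered = sorted(run.entries, key=lambda e: (sign * e.score, e.molecule_id))
    run.entries = ordered
    run.ranks = {e.molecule_id: i for i, e in enumerate(ordered, start=1)}
    return run


def scaled_rank(run: DockingRun, molecule_id: str) -> float:
    """Scaled docking rank ``R = r / m`` in (0, 1]."""
    if not run.is_ranked:
        compute_ranks(run)
    return run.rank(molecule_id) / run.size


def read_score_table(
    source: str | Path | TextIO,
    kinase_id: str = "",
    structure_id: str = "",
    *,
    delimiter: str | None = None,
    ascending: bool = True,
) -> DockingRun:
    """Parse a two-column (molecule_id, score) table into a ranked run.

    The delimiter (comma or tab) is auto-detected unless given.  A header
    row is detected by a non-numeric second field.  Duplicate molecule
    rows are collapsed to the best score — the docking analogue of
    keeping a molecule's best pose.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if not text.strip():
        raise ValueError("no molecules: score table is empty")
    if delimiter is None:
        first = text.splitlines()[0]
        delimiter = "\t" if "\t" in first else ","

    df = pd.read_csv(
        io.StringIO(text), sep=delimiter, header=None, dtype=str,
        comment="#", skip_blank_lines=True,
    )
    if df.shape[1] < 2:
        raise ValueError(f"expected 2 columns (molecule_id, score), got {df.shape[1]}")
    df = df.iloc[:, :2]
    df.columns = ["molecule_id", "score"]

    # header row: second field does not parse as a number
    if pd.isna(pd.to_numeric(df.iloc[0]["score"], errors="coerce")):
        df = df.iloc[1:]
        if df.empty:
            raise ValueError("no molecules: score table has only a header")

    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = df.loc[scores.isna()].index[0]
        raise ValueError(
            f"non-numeric score in row {int(bad) + 1}: {df.loc[bad, 'score']!r}"
        )
    df = df.assign(score=scores)
    # duplicates collapse to the best (lowest if ascending) score
    best = df.groupby("molecule_id", sort=False)["score"]
    collapsed = (best.min() if ascending else best.max()).reset_index()

    run = DockingRun(
        kinase_id=kinase_id,
        structure_id=structure_id,
        entries=[
            MoleculeScore(str(r.molecule_id), float(r.score))
            for r in collapsed.itertuples(index=False)
        ],
        ascending=ascending,
    )
    return compute_ranks(run)


def write_ranked_table(run: DockingRun, path: str | Path) -> None:
    """Write a ranked CSV (molecule_id, score, rank)."""
    if not run.is_ranked:
        compute_ranks(run)
    df = pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in run.entries],
            "score": [e.score for e in run.entries],
            "rank": [run.ranks[e.molecule_id] for e in run.entries],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(
    path: str | Path, *, ascending: bool = True
) -> dict[str, list[DockingRun]]:
    """Load a kinase -> structure -> score-file manifest (YAML or JSON).

    The manifest maps each kinase to a mapping of structure ids to score
    table paths, relative to the manifest's directory::

        EGFR:
          1XKK: egfr_1xkk.csv
          3POZ: egfr_3poz.csv

    Returns ranked :class:`DockingRun` lists keyed by kinase.
    """
    path = Path(path)
    text = path.read_text()
    mapping: Mapping = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    if not isinstance(mapping, Mapping) or not mapping:
        raise ValueError(f"manifest {path} is empty or not a mapping")
    runs: dict[str, list[DockingRun]] = {}
    for kinase_id, structures in mapping.items():
        if not isinstance(structures, Mapping) or not structures:
            raise ValueError(f"kinase {kinase_id!r} has no structures in manifest")
        runs[str(kinase_id)] = [
            read_score_table(
                path.parent / str(fname),
                kinase_id=str(kinase_id),
                structure_id=str(sid),
                ascending=ascending,
            )
            for sid, fname in structures.items()
        ]
    return runs
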