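"""Docking-rank similarity (DockRankSim) between structures and kinases.

Two binding sites are considered similar when they are predicted to bind
the same molecules in a similar rank order.  For a pair of docking runs
the top-N molecules of each are intersected, the intersection's ranks
renumbered 1..k preserving each run's order, and the Spearman rank
correlation of the renumbered ranks taken.  Kinase-level similarity is
the maximum over all structure pairs, one structure from each kinase.

The top-N cutoff (default 25,000) restricts the comparison to molecules
the scoring function actually discriminates; rank order deep in a
multi-million-compound library is noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dock_io import DockingRun, compute_ranks
from .similarity import SimilarityMatrix

__all__ = [
    "RankIntersection",
    "top_n_intersection",
    "intersection_correlation",
    "dockrank_sim",
    "kinase_dockrank_matrix",
    "overlap_report",
]

DEFAULT_TOP_N = 25_000


@dataclass
class RankIntersection:
    """Common top-N molecules of two runs with renumbered ranks.

    Molecules are listed in run A's rank order, so ``ranks_a`` is always
    (1, 2, ..., k) and ``ranks_b`` is the permutation giving each
    molecule's renumbered position in run B.
    """

    molecule_ids: list[str]
    ranks_a: np.ndarray
    ranks_b: np.ndarray

    @property
    def k(self) -> int:
        return len(self.molecule_ids)

    def __post_init__(self) -> None:
        self.ranks_a = np.asarray(self.ranks_a, dtype=int)
        self.ranks_b = np.asarray(self.ranks_b, dtype=int)
        expected = np.arange(1, self.k + 1)
        for name, ranks in (("ranks_a", self.ranks_a), ("ranks_b", self.ranks_b)):
            if not np.array_equal(np.sort(ranks), expected):
                raise ValueError(f"{name} is not a permutation of 1..{self.k}")


def top_n_intersection(
    run_a: DockingRun, run_b: DockingRun, n: int = DEFAULT_TOP_N
) -> RankIntersection:
    """Molecules ranked <= n in both runs, ranks renumbered within 1..k."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for run in (run_a, run_b):
        if not run.is_ranked:
            compute_ranks(run)
    top_a = {mol: r for mol, r in run_a.ranks.items() if r <= n}
    top_b = {mol: r for mol, r in run_b.ranks.items() if r <= n}
    common = sorted(top_a.keys() & top_b.keys(), key=top_a.__getitem__)
    # renumber: order within the intersection follows each run's own order
    order_b = {mol: i for i, mol in enumerate(
        sorted(common, key=top_b.__getitem__), start=1)}
    return RankIntersection(
        molecule_ids=common,
        ranks_a=np.arange(1, len(common) + 1),
        ranks_b=np.array([order_b[mol] for mol in common], dtype=int),
    )


def intersection_correlation(intersection: RankIntersection) -> float:
    """Spearman rank correlation of the renumbered ranks; NaN if k < 2.

    The renumbered ranks are tie-free permutations (ordinal ranking
    upstream), so no tie correction applies.
    """
    if intersection.k < 2:
        return float("nan")
    rho = stats.spearmanr(intersection.ranks_a, intersection.ranks_b).statistic
    return float(rho)


def dockrank_sim(
    run_a: DockingRun, run_b: DockingRun, n: int = DEFAULT_TOP_N
) -> float:
    """DockRankSim between two docking runs: Spearman rho of the common
    top-``n`` molecules after renumbering; NaN when fewer than 2 are
    common."""
    return intersection_correlation(top_n_intersection(run_a, run_b, n))


def _nanmax(values: Sequence[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmax(arr))


def kinase_dockrank_matrix(
    runs: Mapping[str, Sequence[DockingRun]], n: int = DEFAULT_TOP_N
) -> SimilarityMatrix:
    """Kinase-level DockRankSim: max over all structure pairs.

    Off-diagonal entries take one structure from each kinase; the
    diagonal takes distinct structure pairs within the kinase and is NaN
    for single-structure kinases (no self-pair exists).
    """
    labels = list(runs)
    for kinase, kinase_runs in runs.items():
        if not kinase_runs:
            raise ValueError(f"kinase {kinase!r} has no docking runs")
    values = np.full((len(labels), len(labels)), np.nan)
    for i, ka in enumerate(labels):
        values[i, i] = _nanmax(
            [dockrank_sim(ra, rb, n)
             for ra, rb in itertools.combinations(runs[ka], 2)]
        )
        for j in range(i + 1, len(labels)):
            kb = labels[j]
            best = _nanmax(
                [dockrank_sim(ra, rb, n)
                 for ra in runs[ka] for rb in runs[kb]]
            )
            values[i, j] = values[j, i] = best
    return SimilarityMatrix(
        labels, values, measure_name="DockRankSim", value_range=(-1.0, 1.0)
    )


def overlap_report(
    runs: Mapping[str, Sequence[DockingRun]], n: int = DEFAULT_TOP_N
) -> pd.DataFrame:
    """Per structure pair: top-N intersection size k and Spearman rho.

    The intersection size is the "common compounds in the top-N"
    bookkeeping; the per-kinase-pair maximum of k over structure pairs is
    the headline overlap number.
    """
    rows = []
    labels = list(runs)
    for i, ka in enumerate(labels):
        for j in range(i, len(labels)):
            kb = labels[j]
            pairs = (
                itertools.combinations(runs[ka], 2)
                if i == j
                else itertools.product(runs[ka], runs[kb])
            )
            for ra, rb in pairs:
                inter = top_n_intersection(ra, rb, n)
                rows.append(
                    {
                        "kinase_a": ka,
                        "structure_a": ra.structure_id,
                        "kinase_b": kb,
                        "structure_b": rb.structure_id,
                        "k": inter.k,
                        "rho": intersection_correlation(inter),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["kinase_a", "structure_a", "kinase_b", "structure_b", "k", "rho"],
    )
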