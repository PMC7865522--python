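"""Labeled symmetric similarity matrices, summaries and cross-comparison."""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SimilarityMatrix", "summarize_similarity", "compare_measures"]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric kinase x kinase similarity matrix with NaN for undefined.

    ``value_range`` declares the admissible interval ([0, 1] for
    fraction-type measures, [-1, 1] for rank correlations); entries
    outside it (other than NaN) are rejected at construction.
    """

    labels: list[str]
    values: np.ndarray
    measure_name: str = "similarity"
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(
            self.values, self.values.T, equal_nan=True, atol=1e-12
        ):
            raise ValueError("similarity matrix must be symmetric")
        lo, hi = self.value_range
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < lo - 1e-12 or finite.max() > hi + 1e-12):
            raise ValueError(
                f"entries outside declared range [{lo}, {hi}] for "
                f"{self.measure_name}"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="kinase")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        measure_name: str = "similarity",
        value_range: tuple[float, float] = (0.0, 1.0),
    ) -> "SimilarityMatrix":
        return cls(
            labels=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            measure_name=measure_name,
            value_range=value_range,
        )

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        measure_name: str = "similarity",
        value_range: tuple[float, float] = (0.0, 1.0),
    ) -> "SimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame, measure_name, value_range)

    def heatmap(self, ax=None, **kwargs):
        """Render the matrix as an annotated heatmap (matplotlib axes)."""
        import seaborn as sns

        kwargs.setdefault("vmin", self.value_range[0])
        kwargs.setdefault("vmax", self.value_range[1])
        kwargs.setdefault("annot", True)
        kwargs.setdefault("fmt", ".2f")
        kwargs.setdefault("cmap", "viridis")
        ax = sns.heatmap(self.to_frame(), ax=ax, **kwargs)
        ax.set_title(self.measure_name)
        return ax


def summarize_similarity(
    matrix: SimilarityMatrix,
    *,
    include_diagonal: bool = True,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-kinase mean and s.d. of similarity to the whole panel.

    By default the kinase's self-similarity (diagonal) is included, so
    the summary reads "mean similarity to all panel kinases including
    itself".  NaN entries (undefined comparisons) are excluded pairwise
    and counted in ``n_undefined``.  ``ddof=1`` gives the sample s.d.;
    pass ``ddof=0`` for the population flavour.
    """
    rows = []
    for i, kinase in enumerate(matrix.labels):
        row = matrix.values[i].copy()
        if not include_diagonal:
            row = np.delete(row, i)
        defined = row[np.isfinite(row)]
        n_undefined = row.size - defined.size
        if n_undefined:
            logger.info(
                "%s: %d undefined entries excluded from %s summary",
                kinase, n_undefined, matrix.measure_name,
            )
        if defined.size == 0:
            warnings.warn(
                f"all-NaN similarity row for {kinase}; summary undefined",
                stacklevel=2,
            )
            mean = sd = float("nan")
        else:
            mean = float(defined.mean())
            sd = float(defined.std(ddof=ddof)) if defined.size > ddof else float("nan")
        rows.append(
            {"kinase": kinase, "mean": mean, "sd": sd,
             "n_used": int(defined.size), "n_undefined": int(n_undefined)}
        )
    return pd.DataFrame(rows).set_index("kinase")


def compare_measures(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    *,
    include_diagonal: bool = False,
) -> tuple[float, float, int]:
    """Pearson correlation between two similarity measures.

    The matrices are reduced to their common label set, vectorised over
    upper-triangle off-diagonal entries (self-similarities mean
    different things per measure and are excluded by default), and
    correlated pairwise-complete.  Returns ``(r, p_value, n_pairs)``;
    fewer than 3 complete pairs yields ``(nan, nan, n)`` with a warning.
    """
    common = [lab for lab in a.labels if lab in b.labels]
    xs, ys = [], []
    offset = 0 if include_diagonal else 1
    for i, j in itertools.combinations_with_replacement(range(len(common)), 2):
        if j - i < offset:
            continue
        va = a.loc(common[i], common[j])
        vb = b.loc(common[i], common[j])
        if np.isfinite(va) and np.isfinite(vb):
            xs.append(va)
            ys.append(vb)
    n = len(xs)
    if n < 3:
        warnings.warn(
            f"only {n} complete pairs between {a.measure_name} and "
            f"{b.measure_name}; correlation undefined",
            stacklevel=2,
        )
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n
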