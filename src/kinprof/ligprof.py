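"""Ligand-profile similarity from ChEMBL-style bioactivity records.

Kinases are compared from the ligand point of view: two kinases are
similar when the compounds tested on both tend to be active on both.
Records are filtered to binding-assay IC50 measurements, deduplicated to
each compound's most potent value, and thresholded (active = IC50
strictly below 500 nM by default).  The pairwise similarity

    LigProfSim(a, b) = |active on both| / |tested on both|

is undefined (NaN) when no compound was tested on both kinases.  The
self-similarity |active| / |tested| is the kinase's *promiscuity* — the
fraction of everything ever tested on it that binds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "ActivityRecord",
    "ActivityMatrix",
    "read_activity_csv",
    "ingest_activities",
    "classify_active",
    "promiscuity",
    "ligprof_sim",
    "ligprof_matrix",
    "DEFAULT_ACTIVITY_THRESHOLD_NM",
]

logger = logging.getLogger(__name__)

DEFAULT_ACTIVITY_THRESHOLD_NM = 500.0

# nM per unit, for optional unit conversion
_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "μm": 1e3, "mm": 1e6, "m": 1e9}


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement of a compound against a kinase."""

    compound_id: str
    kinase_id: str
    assay_id: str
    assay_class: str  # e.g. binding / functional
    activity_type: str  # e.g. IC50
    value_nM: float
    relation: str = "="  # activity qualifier: '=', '<', '>'


@dataclass
class ActivityMatrix:
    """Compound x kinase minimum-IC50 table with a binary activity layer.

    ``values`` is a DataFrame (compounds x kinases) of minimum IC50 in
    nM with NaN for untested pairs; ``active`` is the boolean layer
    values < threshold (all-False until :func:`classify_active` runs).
    """

    values: pd.DataFrame
    threshold_nM: float | None = None
    n_rejected: int = 0

    @property
    def tested(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def active(self) -> pd.DataFrame:
        if self.threshold_nM is None:
            return pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        return self.values < self.threshold_nM

    @property
    def kinases(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def to_records(self) -> list[ActivityRecord]:
        """Render the aggregated matrix back to one record per tested
        pair (synthetic assay id), suitable for re-ingestion."""
        records = []
        stacked = self.values.stack()
        for (compound, kinase), value in stacked.items():
            records.append(
                ActivityRecord(
                    compound_id=str(compound),
                    kinase_id=str(kinase),
                    assay_id="aggregated",
                    assay_class="binding",
                    activity_type="IC50",
                    value_nM=float(value),
                )
            )
        return records


def read_activity_csv(
    path: str | Path, *, column_map: Mapping[str, str] | None = None
) -> list[ActivityRecord]:
    """Read activity records from CSV.

    Expected columns: compound_id, kinase_id, assay_id, assay_class,
    activity_type, value_nM, optionally relation and value_unit (nM
    assumed when absent; unknown units reject the row at ingestion).
    ``column_map`` renames ChEMBL-export column names onto this schema.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["compound_id", "kinase_id", "assay_id", "assay_class",
                "activity_type", "value_nM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        value = pd.to_numeric(getattr(row, "value_nM"), errors="coerce")
        unit = str(getattr(row, "value_unit", "nM") or "nM")
        factor = _UNIT_TO_NM.get(unit.strip().lower())
        records.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                kinase_id=str(row.kinase_id),
                assay_id=str(row.assay_id),
                assay_class=str(row.assay_class),
                activity_type=str(row.activity_type),
                value_nM=float(value) * factor
                if factor is not None and pd.notna(value)
                else float("nan"),
                relation=str(getattr(row, "relation", "=") or "="),
            )
        )
    return records


def _record_ok(rec: ActivityRecord) -> bool:
    if not rec.compound_id or not rec.kinase_id:
        return False
    if not np.isfinite(rec.value_nM) or rec.value_nM <= 0:
        return False
    return True


def ingest_activities(records: Iterable[ActivityRecord]) -> ActivityMatrix:
    """Filter, deduplicate and pivot activity records.

    Keeps binding-assay IC50 records only (case-insensitive match).
    Records with a ``>`` qualifier are dropped — the measurement cannot
    confirm potency; ``<`` and ``=`` are taken at face value.  Within
    one (compound, kinase, assay) the lowest (most active) IC50 is kept,
    and the minimum is taken again across assays of the same pair.
    Malformed records (missing ids, non-positive or non-numeric values)
    are rejected and counted in ``n_rejected``.
    """
    kept = []
    n_rejected = 0
    for rec in records:
        if not _record_ok(rec):
            n_rejected += 1
            continue
        if rec.assay_class.strip().lower() not in ("binding", "b"):
            continue
        if rec.activity_type.strip().lower() != "ic50":
            continue
        if rec.relation.strip().startswith(">"):
            continue
        kept.append(rec)
    if n_rejected:
        logger.info("rejected %d malformed activity records", n_rejected)
    if not kept:
        empty = pd.DataFrame(dtype=float)
        return ActivityMatrix(values=empty, n_rejected=n_rejected)
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in kept],
            "kinase_id": [r.kinase_id for r in kept],
            "assay_id": [r.assay_id for r in kept],
            "value_nM": [r.value_nM for r in kept],
        }
    )
    per_assay = df.groupby(
        ["compound_id", "kinase_id", "assay_id"], sort=True
    )["value_nM"].min()
    per_pair = per_assay.groupby(level=["compound_id", "kinase_id"]).min()
    values = per_pair.unstack("kinase_id")
    return ActivityMatrix(values=values, n_rejected=n_rejected)


def classify_active(
    matrix: ActivityMatrix,
    threshold_nM: float = DEFAULT_ACTIVITY_THRESHOLD_NM,
) -> ActivityMatrix:
    """Attach the binary activity layer: active iff IC50 strictly below
    the threshold (a boundary value is inactive)."""
    if threshold_nM <= 0:
        raise ValueError("threshold must be positive")
    return ActivityMatrix(
        values=matrix.values,
        threshold_nM=threshold_nM,
        n_rejected=matrix.n_rejected,
    )


def promiscuity(matrix: ActivityMatrix, kinase_id: str) -> float:
    """Fraction of compounds tested on a kinase that are active on it."""
    if kinase_id not in matrix.values.columns:
        warnings.warn(f"no compounds tested on {kinase_id}", stacklevel=2)
        return float("nan")
    n_tested = int(matrix.tested[kinase_id].sum())
    if n_tested == 0:
        warnings.warn(f"no compounds tested on {kinase_id}", stacklevel=2)
        return float("nan")
    return int(matrix.active[kinase_id].sum()) / n_tested


def ligprof_sim(matrix: ActivityMatrix, kinase_a: str, kinase_b: str) -> float:
    """Common-active / common-tested ratio; promiscuity on the diagonal;
    NaN when no compound was tested on both kinases."""
    if kinase_a == kinase_b:
        return promiscuity(matrix, kinase_a)
    for k in (kinase_a, kinase_b):
        if k not in matrix.values.columns:
            return float("nan")
    tested = matrix.tested
    active = matrix.active
    both_tested = int((tested[kinase_a] & tested[kinase_b]).sum())
    if both_tested == 0:
        return float("nan")
    both_active = int((active[kinase_a] & active[kinase_b]).sum())
    return both_active / both_tested


def ligprof_matrix(
    matrix: ActivityMatrix, kinases: Sequence[str] | None = None
) -> tuple[SimilarityMatrix, pd.DataFrame, pd.DataFrame]:
    """Full LigProfSim matrix plus companion count tables.

    Returns ``(similarity, kinase_counts, pair_counts)`` where
    ``kinase_counts`` lists actives/tested per kinase and
    ``pair_counts`` lists common-actives/common-tested per pair.
    """
    if kinases is None:
        kinases = matrix.kinases
    kinases = list(kinases)
    if not kinases:
        raise ValueError("need at least one kinase")
    n = len(kinases)
    values = np.full((n, n), np.nan)
    tested, active = matrix.tested, matrix.active
    kin_rows, pair_rows = [], []
    for i, ka in enumerate(kinases):
        has_a = ka in matrix.values.columns
        kin_rows.append(
            {
                "kinase": ka,
                "actives": int(active[ka].sum()) if has_a else 0,
                "tested": int(tested[ka].sum()) if has_a else 0,
            }
        )
        for j in range(i, n):
            kb = kinases[j]
            values[i, j] = values[j, i] = ligprof_sim(matrix, ka, kb)
            if j > i and has_a and kb in matrix.values.columns:
                pair_rows.append(
                    {
                        "kinase_a": ka,
                        "kinase_b": kb,
                        "common_actives": int((active[ka] & active[kb]).sum()),
                        "common_tested": int((tested[ka] & tested[kb]).sum()),
                    }
                )
    sim = SimilarityMatrix(
        kinases, values, measure_name="LigProfSim", value_range=(0.0, 1.0)
    )
    return (
        sim,
        pd.DataFrame(kin_rows, columns=["kinase", "actives", "tested"]),
        pd.DataFrame(
            pair_rows,
            columns=["kinase_a", "kinase_b", "common_actives", "common_tested"],
        ),
    )
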