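"""Profile re-ranking: combine docking ranks over targets and anti-targets.

A *kinase profile* is an ordered set of N kinases, each flagged as a
target (binding wanted) or an anti-target (binding to be designed out),
with one or more docking runs (structures) per kinase.  Each molecule
gets a per-kinase log scaled rank

    target:      P_k = log_b( min_s  r_{k,s} / m_{k,s} )
    anti-target: P_k = log_b( max_s (1 - (r_{k,s} - 1) / m_{k,s}) )

aggregated over the kinase's structures s (a molecule is credited with
its best structure), and the combined profile score

    S = (1/N) * sum_k P_k + (max_k P_k - min_k P_k) / 2

Lower S is better: the mean term rewards good (log-scaled) ranks in all
profile members, and the max-min spread term penalises molecules whose
per-kinase performance is unbalanced.  The anti-target inversion uses
1 - (r-1)/m rather than the naive 1 - r/m so the inverted scaled rank
spans [1/m, 1] exactly like the target case and the logarithm is always
defined; the induced ordering is unchanged.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dock_io import DockingRun

__all__ = [
    "KinaseRole",
    "ProfileSpec",
    "ProfileScoreTable",
    "aggregate_kinase_rank",
    "profile_score",
    "rank_by_profile",
    "expected_profile_hit_rate",
]

logger = logging.getLogger(__name__)


class KinaseRole(enum.Enum):
    """Role of a kinase in a profile: binding wanted (+) or unwanted (-)."""

    TARGET = "target"
    ANTI_TARGET = "anti_target"

    @classmethod
    def parse(cls, value: "KinaseRole | str") -> "KinaseRole":
        if isinstance(value, cls):
            return value
        raw = str(value).strip()
        if raw in ("+", "-"):
            return cls.TARGET if raw == "+" else cls.ANTI_TARGET
        key = raw.lower().replace("-", "_")
        aliases = {
            "target": cls.TARGET,
            "+": cls.TARGET,
            "anti_target": cls.ANTI_TARGET,
            "antitarget": cls.ANTI_TARGET,
            "anti": cls.ANTI_TARGET,
            "-": cls.ANTI_TARGET,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown kinase role {value!r}") from None


@dataclass
class ProfileSpec:
    """Definition of a multi-target/anti-target screening profile.

    Parameters
    ----------
    profile_id
        Free-text label, e.g. ``"+EGFR+ErbB2-BRAF"``.
    members
        Ordered (kinase_id, role) pairs; N = len(members).
    structures
        Structure ids per member kinase (each non-empty).
    log_base
        Base of the logarithm applied to scaled ranks; default 10.
        The molecule ordering by S is invariant to the base.
    """

    profile_id: str
    members: list[tuple[str, KinaseRole]]
    structures: dict[str, list[str]] = field(default_factory=dict)
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a profile needs at least one member kinase")
        self.members = [(k, KinaseRole.parse(r)) for k, r in self.members]
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        for kinase_id, structs in self.structures.items():
            if not structs:
                raise ValueError(f"kinase {kinase_id!r} has an empty structure list")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def kinase_ids(self) -> list[str]:
        return [k for k, _ in self.members]

    def role(self, kinase_id: str) -> KinaseRole:
        for k, r in self.members:
            if k == kinase_id:
                return r
        raise KeyError(f"kinase {kinase_id!r} is not a profile member")

    @classmethod
    def from_file(cls, path: str | Path) -> "ProfileSpec":
        """Load a profile from YAML/JSON with keys profile_id, members
        (list of {kinase, role}), structures, log_base."""
        cfg = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ProfileSpec":
        members = [
            (str(m["kinase"]), KinaseRole.parse(m["role"])) for m in cfg["members"]
        ]
        return cls(
            profile_id=str(cfg.get("profile_id", "profile")),
            members=members,
            structures={
                str(k): [str(s) for s in v]
                for k, v in (cfg.get("structures") or {}).items()
            },
            log_base=float(cfg.get("log_base", 10.0)),
        )


def aggregate_kinase_rank(
    runs: Sequence[DockingRun],
    molecule_id: str,
    role: KinaseRole | str = KinaseRole.TARGET,
    log_base: float = 10.0,
) -> float:
    """Per-kinase log scaled rank P_k, aggregated over structures.

    Targets use the molecule's best (smallest) scaled rank r/m across the
    kinase's structures; anti-targets use the largest inverted scaled
    rank 1 - (r-1)/m, so docking badly to an anti-target in every
    structure is rewarded.  Both aggregates lie in (0, 1], hence P <= 0.
    """
    role = KinaseRole.parse(role)
    scaled: list[float] = []
    for run in runs:
        if molecule_id not in run:
            continue
        r, m = run.rank(molecule_id), run.size
        if role is KinaseRole.TARGET:
            scaled.append(r / m)
        else:
            scaled.append(1.0 - (r - 1) / m)
    if not scaled:
        kinase = runs[0].kinase_id if runs else "?"
        raise KeyError(f"no rank for kinase {kinase!r}: molecule {molecule_id!r} "
                       "absent from all structures")
    best = min(scaled) if role is KinaseRole.TARGET else max(scaled)
    return math.log(best, log_base)


def profile_score(P: Sequence[float]) -> float:
    """Combined profile score S = mean(P) + (max(P) - min(P)) / 2."""
    if len(P) == 0:
        raise ValueError("profile_score needs at least one component")
    arr = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("profile components must be finite")
    # summing in sorted order makes S bitwise permutation-invariant, so
    # molecules with permuted rank multisets tie exactly
    arr = np.sort(arr)
    return float(arr.mean() + (arr[-1] - arr[0]) / 2.0)


@dataclass
class ProfileScoreTable:
    """Re-ranked molecules for one profile.

    ``frame`` is indexed by molecule_id with one ``P_<kinase>`` column per
    profile member, the combined score ``S`` and the 1-based
    ``profile_rank``, sorted ascending by S (ties by molecule_id).
    ``n_dropped`` counts molecules excluded for lacking a rank in at
    least one member kinase.
    """

    profile_id: str
    frame: pd.DataFrame
    n_dropped: int = 0

    def top(self, k: int = 500) -> pd.DataFrame:
        return self.frame.head(k)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="molecule_id")


def rank_by_profile(
    runs_by_kinase: Mapping[str, Sequence[DockingRun]],
    spec: ProfileSpec,
    *,
    missing_as_worst: bool = False,
) -> ProfileScoreTable:
    """Score and re-rank all molecules against a profile.

    By default only molecules with a rank in >= 1 structure of *every*
    member kinase are scored; the rest are dropped and counted (Eq.-style
    scoring needs every P_k, and imputing ranks would invent data).  With
    ``missing_as_worst`` a missing kinase is imputed at rank m+1 in that
    kinase's largest run instead.
    """
    member_runs: dict[str, Sequence[DockingRun]] = {}
    for kinase_id, _ in spec.members:
        runs = runs_by_kinase.get(kinase_id)
        if not runs:
            raise ValueError(f"profile member {kinase_id!r} has no docking runs")
        member_runs[kinase_id] = runs

    universe: set[str] = set()
    for runs in member_runs.values():
        for run in runs:
            universe.update(run.ranks)

    rows: dict[str, list[float]] = {}
    n_dropped = 0
    for mol in universe:
        P: list[float] = []
        ok = True
        for kinase_id, role in spec.members:
            runs = member_runs[kinase_id]
            try:
                P.append(aggregate_kinase_rank(runs, mol, role, spec.log_base))
            except KeyError:
                if missing_as_worst:
                    m = max(run.size for run in runs)
                    R = (m + 1) / m if role is KinaseRole.TARGET else 1.0 / m
                    # imputed worst rank r = m+1 (target R slightly > 1)
                    P.append(math.log(R, spec.log_base))
                else:
                    ok = False
                    break
        if ok:
            rows[mol] = P + [profile_score(P)]
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "profile %s: dropped %d of %d molecules lacking a rank in "
            "at least one member kinase",
            spec.profile_id, n_dropped, len(universe),
        )

    columns = [f"P_{k}" for k in spec.kinase_ids] + ["S"]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    # stable sort: ascending S, ties broken by molecule_id.  S is
    # quantized for ordering only: exact ties (coincidental rank-ratio
    # equalities) land on the id tie-break instead of on float rounding
    # noise, keeping the order identical across log bases.
    frame["_S_key"] = frame["S"].round(12)
    frame = frame.sort_index(kind="mergesort").sort_values("_S_key", kind="mergesort")
    frame = frame.drop(columns="_S_key")
    frame["profile_rank"] = np.arange(1, len(frame) + 1)
    return ProfileScoreTable(spec.profile_id, frame, n_dropped)


def expected_profile_hit_rate(per_kinase_rates: Iterable[float]) -> float:
    """Expected fraction of selected molecules matching a whole profile.

    Multiplies independent per-kinase success probabilities: per-target
    hit rates and per-anti-target avoidance rates.  E.g. two targets at
    a 25% hit rate each and one anti-target avoided with probability
    0.90 give 0.25 * 0.25 * 0.90 = 0.056.
    """
    product = 1.0
    for rate in per_kinase_rates:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate {rate} outside [0, 1]")
        product *= rate
    return product
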