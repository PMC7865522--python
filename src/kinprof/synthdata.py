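"""Synthetic docking runs, bioactivity tables, pocket sequences and IFPs.

Every other module in the package consumes large external artifacts
(multi-million-molecule docking campaigns, ChEMBL bioactivity exports,
KLIFS alignments and fingerprints).  This module generates desk-scale
stand-ins with *controlled* similarity structure, so each measure can be
exercised against known ground truth:

* docking runs — a latent-affinity model: each molecule has a standard
  normal reference affinity; a kinase's latent affinity mixes the
  reference with independent noise at correlation ``rho_lat``; each
  structure adds observation noise on top.  ``rho_lat`` therefore dials
  the expected rank correlation between kinases.
* bioactivity tables — an exact-count mode that places tested/active
  compounds in disjoint blocks so promiscuity and pairwise LigProfSim
  equal the planned ratios exactly, and a stochastic Bernoulli mode.
* pocket sequences — a base 85-mer with an exact number of positions
  mutated per kinase, so identity = (85 - mutations) / 85 by
  construction.
* IFPs — a base bit vector of chosen density with independent per-bit
  flips at a planned rate per structure.

All generators are pure functions of (config, seed).  Random streams
are keyed per kinase/structure, so adding a kinase to a plan does not
perturb the data generated for the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dock_io import DockingRun, MoleculeScore, compute_ranks, write_ranked_table
from .klifs_sim import (
    IFP_LENGTH,
    POCKET_LENGTH,
    IFPRecord,
    PocketSequence,
    write_ifp_tsv,
)
from .ligprof import ActivityRecord

__all__ = [
    "DockingPlan",
    "ActivityPlan",
    "SequencePlan",
    "IFPPlan",
    "SimulationConfig",
    "simulate_docking_runs",
    "simulate_run_pair",
    "simulate_activity_table",
    "simulate_pocket_sequences",
    "simulate_ifps",
    "write_bundle",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-component RNG keyed on (seed, labels)."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(entropy)


@dataclass
class DockingPlan:
    """Per-kinase docking simulation settings."""

    n_structures: int = 2
    rho_lat: float = 0.5  # latent correlation to the shared reference
    noise: float = 0.1  # per-structure observation noise s.d.

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_lat <= 1.0:
            raise ValueError(f"rho_lat {self.rho_lat} outside [-1, 1]")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class ActivityPlan:
    """Bioactivity table plan.

    Exact-count mode (``kinase_counts`` set): per-kinase (actives,
    tested) totals, optionally per-pair (common_actives, common_tested)
    targets, realised exactly via disjoint compound blocks.  Stochastic
    mode (``kinase_counts`` None): each of ``n_compounds`` compounds is
    tested on each kinase with ``test_prob`` and, if tested, active
    with ``active_prob``.
    """

    kinase_counts: dict[str, tuple[int, int]] | None = None
    pair_counts: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    n_compounds: int = 100
    test_prob: dict[str, float] = field(default_factory=dict)
    active_prob: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probs in (self.test_prob, self.active_prob):
            for k, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} for {k} outside [0, 1]")


@dataclass
class SequencePlan:
    """Pocket-sequence plan: base 85-mer plus exact mutation counts."""

    mutations: dict[str, int] = field(default_factory=dict)
    base: str | None = None

    def __post_init__(self) -> None:
        if self.base is not None and len(self.base) != POCKET_LENGTH:
            raise ValueError(f"base sequence must have length {POCKET_LENGTH}")
        for k, count in self.mutations.items():
            if not 0 <= count <= POCKET_LENGTH:
                raise ValueError(
                    f"mutation count {count} for {k} outside 0..{POCKET_LENGTH}"
                )


@dataclass
class IFPPlan:
    """IFP plan: base bit density plus per-structure flip rates."""

    base_density: float = 0.15
    flip_rates: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.base_density < 1.0:
            raise ValueError("base_density must be in (0, 1)")
        for k, rates in self.flip_rates.items():
            for rate in rates:
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"flip rate {rate} for {k} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Complete synthetic study definition; a pure function input."""

    seed: int = 0
    n_molecules: int = 1000
    kinase_plan: dict[str, DockingPlan] = field(default_factory=dict)
    activity_plan: ActivityPlan | None = None
    sequence_plan: SequencePlan | None = None
    ifp_plan: IFPPlan | None = None

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SimulationConfig":
        kinase_plan = {
            str(k): DockingPlan(**v) for k, v in (cfg.get("kinase_plan") or {}).items()
        }
        activity = cfg.get("activity_plan")
        activity_plan = None
        if activity is not None:
            counts = activity.get("kinase_counts")
            pair_counts = {
                tuple(str(p).split("/")): tuple(v)
                for p, v in (activity.get("pair_counts") or {}).items()
            }
            activity_plan = ActivityPlan(
                kinase_counts={k: tuple(v) for k, v in counts.items()}
                if counts
                else None,
                pair_counts=pair_counts,
                n_compounds=int(activity.get("n_compounds", 100)),
                test_prob=dict(activity.get("test_prob") or {}),
                active_prob=dict(activity.get("active_prob") or {}),
            )
        seq = cfg.get("sequence_plan")
        sequence_plan = (
            SequencePlan(
                mutations={k: int(v) for k, v in (seq.get("mutations") or {}).items()},
                base=seq.get("base"),
            )
            if seq is not None
            else None
        )
        ifp = cfg.get("ifp_plan")
        ifp_plan = (
            IFPPlan(
                base_density=float(ifp.get("base_density", 0.15)),
                flip_rates={
                    k: [float(r) for r in v]
                    for k, v in (ifp.get("flip_rates") or {}).items()
                },
            )
            if ifp is not None
            else None
        )
        return cls(
            seed=int(cfg.get("seed", 0)),
            n_molecules=int(cfg.get("n_molecules", 1000)),
            kinase_plan=kinase_plan,
            activity_plan=activity_plan,
            sequence_plan=sequence_plan,
            ifp_plan=ifp_plan,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _molecule_ids(n: int) -> list[str]:
    return [f"MOL{i:06d}" for i in range(1, n + 1)]


def simulate_docking_runs(config: SimulationConfig) -> dict[str, list[DockingRun]]:
    """Generate ranked docking runs under the latent-affinity model."""
    if config.n_molecules < 2:
        raise ValueError("n_molecules must be >= 2")
    if not config.kinase_plan:
        raise ValueError("kinase_plan is empty")
    ids = _molecule_ids(config.n_molecules)
    z_ref = _stream(config.seed, "docking", "reference").standard_normal(
        config.n_molecules
    )
    runs: dict[str, list[DockingRun]] = {}
    for kinase_id, plan in config.kinase_plan.items():
        eps = _stream(config.seed, "docking", "kinase", kinase_id).standard_normal(
            config.n_molecules
        )
        latent = plan.rho_lat * z_ref + np.sqrt(1.0 - plan.rho_lat**2) * eps
        kinase_runs = []
        for s in range(1, plan.n_structures + 1):
            structure_id = f"{kinase_id.lower()}_s{s}"
            eta = _stream(
                config.seed, "docking", "structure", kinase_id, s
            ).standard_normal(config.n_molecules)
            scores = latent + plan.noise * eta
            run = DockingRun(
                kinase_id=kinase_id,
                structure_id=structure_id,
                entries=[
                    MoleculeScore(mol, float(sc)) for mol, sc in zip(ids, scores)
                ],
            )
            kinase_runs.append(compute_ranks(run))
        runs[kinase_id] = kinase_runs
    return runs


def simulate_run_pair(
    n_molecules: int, rho: float, seed: int
) -> tuple[DockingRun, DockingRun]:
    """Two single-structure runs whose latent scores correlate at ``rho``.

    Convenience wrapper used for rank-correlation recovery experiments:
    kinase A carries the reference affinity exactly, kinase B mixes it
    at ``rho``; neither adds structure noise.
    """
    config = SimulationConfig(
        seed=seed,
        n_molecules=n_molecules,
        kinase_plan={
            "KINA": DockingPlan(n_structures=1, rho_lat=1.0, noise=0.0),
            "KINB": DockingPlan(n_structures=1, rho_lat=rho, noise=0.0),
        },
    )
    runs = simulate_docking_runs(config)
    return runs["KINA"][0], runs["KINB"][0]


def _active_value(rng: np.random.Generator) -> float:
    return float(np.round(rng.uniform(10.0, 400.0), 1))


def _inactive_value(rng: np.random.Generator) -> float:
    return float(np.round(rng.uniform(600.0, 10000.0), 1))


def simulate_activity_table(config: SimulationConfig) -> list[ActivityRecord]:
    """Generate bioactivity records per the activity plan.

    Exact-count mode builds disjoint compound blocks: one block per
    kinase pair carrying exactly the planned common-tested compounds
    (of which the planned number is active on both, the rest inactive
    on both), then one block per kinase topping its marginal totals up.
    Infeasible plans (pair actives > pair tested, or pair blocks
    exceeding a kinase's marginal totals) raise before any records are
    emitted.
    """
    plan = config.activity_plan
    if plan is None:
        return []
    if plan.kinase_counts is not None:
        return _exact_activity_records(plan, config.seed)
    return _stochastic_activity_records(plan, config.seed)


def _exact_activity_records(plan: ActivityPlan, seed: int) -> list[ActivityRecord]:
    kinases = list(plan.kinase_counts)
    pair_active_used = {k: 0 for k in kinases}
    pair_tested_used = {k: 0 for k in kinases}
    for (ka, kb), (x_ab, t_ab) in plan.pair_counts.items():
        if ka not in plan.kinase_counts or kb not in plan.kinase_counts:
            raise ValueError(f"pair ({ka}, {kb}) references unplanned kinase")
        if not 0 <= x_ab <= t_ab:
            raise ValueError(
                f"pair ({ka}, {kb}): common actives {x_ab} exceed common "
                f"tested {t_ab}"
            )
        for k in (ka, kb):
            pair_active_used[k] += x_ab
            pair_tested_used[k] += t_ab
    for k, (x_k, t_k) in plan.kinase_counts.items():
        if not 0 <= x_k <= t_k:
            raise ValueError(f"kinase {k}: actives {x_k} exceed tested {t_k}")
        rest_t = t_k - pair_tested_used[k]
        rest_x = x_k - pair_active_used[k]
        if rest_t < 0 or rest_x < 0 or rest_x > rest_t:
            raise ValueError(
                f"kinase {k}: pair blocks ({pair_active_used[k]} active / "
                f"{pair_tested_used[k]} tested) incompatible with marginal "
                f"totals ({x_k} / {t_k})"
            )

    records: list[ActivityRecord] = []
    rng = _stream(seed, "activity", "values")
    counter = 0

    def emit(kinase: str, active: bool, compound: str) -> None:
        value = _active_value(rng) if active else _inactive_value(rng)
        records.append(
            ActivityRecord(
                compound_id=compound,
                kinase_id=kinase,
                assay_id=f"assay_{kinase}",
                assay_class="binding",
                activity_type="IC50",
                value_nM=value,
            )
        )

    for (ka, kb), (x_ab, t_ab) in plan.pair_counts.items():
        for i in range(t_ab):
            counter += 1
            compound = f"CPD{counter:06d}"
            active = i < x_ab
            emit(ka, active, compound)
            emit(kb, active, compound)
    for k, (x_k, t_k) in plan.kinase_counts.items():
        rest_t = t_k - pair_tested_used[k]
        rest_x = x_k - pair_active_used[k]
        for i in range(rest_t):
            counter += 1
            emit(k, i < rest_x, f"CPD{counter:06d}")
    return records


def _stochastic_activity_records(plan: ActivityPlan, seed: int) -> list[ActivityRecord]:
    records: list[ActivityRecord] = []
    kinases = sorted(set(plan.test_prob) | set(plan.active_prob))
    compounds = [f"CPD{i:06d}" for i in range(1, plan.n_compounds + 1)]
    rng_values = _stream(seed, "activity", "values")
    for kinase in kinases:
        rng = _stream(seed, "activity", "kinase", kinase)
        p_test = plan.test_prob.get(kinase, 1.0)
        p_act = plan.active_prob.get(kinase, 0.5)
        tested = rng.random(plan.n_compounds) < p_test
        active = rng.random(plan.n_compounds) < p_act
        for compound, is_tested, is_active in zip(compounds, tested, active):
            if not is_tested:
                continue
            value = (
                _active_value(rng_values) if is_active else _inactive_value(rng_values)
            )
            records.append(
                ActivityRecord(
                    compound_id=compound,
                    kinase_id=kinase,
                    assay_id=f"assay_{kinase}",
                    assay_class="binding",
                    activity_type="IC50",
                    value_nM=value,
                )
            )
    return records


def simulate_pocket_sequences(config: SimulationConfig) -> list[PocketSequence]:
    """Derive kinase pocket sequences from a base 85-mer with exact
    per-kinase mutation counts (mutated residues always differ from the
    base), so pairwise identity to the base is exact by construction."""
    plan = config.sequence_plan
    if plan is None:
        return []
    if plan.base is None:
        rng = _stream(config.seed, "sequence", "base")
        base = "".join(rng.choice(list(_AMINO_ACIDS), size=POCKET_LENGTH))
    else:
        base = plan.base.upper()
    sequences = []
    for kinase_id, count in plan.mutations.items():
        rng = _stream(config.seed, "sequence", "kinase", kinase_id)
        positions = rng.choice(POCKET_LENGTH, size=count, replace=False)
        residues = list(base)
        for pos in positions:
            alternatives = [a for a in _AMINO_ACIDS if a != base[pos]]
            residues[pos] = alternatives[int(rng.integers(len(alternatives)))]
        sequences.append(PocketSequence(kinase_id=kinase_id, residues="".join(residues)))
    return sequences


def simulate_ifps(config: SimulationConfig) -> list[IFPRecord]:
    """Generate per-structure IFPs: a shared base bit vector of the
    planned density, independently bit-flipped at each structure's
    planned rate.  Quality scores are drawn in [6, 10]; all records are
    orthosteric DFG-in unless post-edited by the caller."""
    plan = config.ifp_plan
    if plan is None:
        return []
    base = (
        _stream(config.seed, "ifp", "base").random(IFP_LENGTH) < plan.base_density
    ).astype(int)
    records = []
    for kinase_id, rates in plan.flip_rates.items():
        for s, rate in enumerate(rates, start=1):
            rng = _stream(config.seed, "ifp", "structure", kinase_id, s)
            flips = rng.random(IFP_LENGTH) < rate
            bits = np.where(flips, 1 - base, base)
            quality = float(np.round(rng.uniform(6.0, 10.0), 1))
            records.append(
                IFPRecord(
                    structure_key=f"{kinase_id.lower()}s{s}_A",
                    kinase_id=kinase_id,
                    bits=tuple(int(b) for b in bits),
                    quality=quality,
                )
            )
    return records


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a full synthetic input bundle on disk.

    Writes per-structure score CSVs plus a ``manifest.yaml``, the
    activity table CSV, pocket FASTA and IFP TSV (each only if the
    corresponding plan is present), and returns the paths written.
    Re-running with the same config produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.kinase_plan:
        runs = simulate_docking_runs(config)
        manifest: dict[str, dict[str, str]] = {}
        for kinase_id, kinase_runs in runs.items():
            manifest[kinase_id] = {}
            for run in kinase_runs:
                fname = f"scores_{run.structure_id}.csv"
                write_ranked_table(run, out_dir / fname)
                manifest[kinase_id][run.structure_id] = fname
        manifest_path = out_dir / "manifest.yaml"
        manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
        paths["manifest"] = manifest_path

    if config.activity_plan is not None:
        import pandas as pd

        records = simulate_activity_table(config)
        frame = pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in records],
                "kinase_id": [r.kinase_id for r in records],
                "assay_id": [r.assay_id for r in records],
                "assay_class": [r.assay_class for r in records],
                "activity_type": [r.activity_type for r in records],
                "value_nM": [r.value_nM for r in records],
                "relation": [r.relation for r in records],
            }
        )
        activity_path = out_dir / "activity.csv"
        frame.to_csv(activity_path, index=False)
        paths["activity"] = activity_path

    if config.sequence_plan is not None:
        sequences = simulate_pocket_sequences(config)
        fasta_path = out_dir / "pockets.fasta"
        with open(fasta_path, "w") as fh:
            for seq in sequences:
                fh.write(f">{seq.kinase_id}\n{seq.residues}\n")
        paths["pockets"] = fasta_path

    if config.ifp_plan is not None:
        ifp_path = out_dir / "ifps.tsv"
        write_ifp_tsv(simulate_ifps(config), ifp_path)
        paths["ifps"] = ifp_path

    return paths
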