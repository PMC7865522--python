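import math

import numpy as np
import pytest

from kinprof import (
    ActivityPlan,
    DockingPlan,
    IFPPlan,
    SequencePlan,
    SimulationConfig,
    classify_active,
    dockrank_sim,
    ingest_activities,
    ligprof_sim,
    poc_seq_sim,
    promiscuity,
    read_activity_csv,
    read_ifp_tsv,
    read_manifest,
    read_pocket_fasta,
    simulate_activity_table,
    simulate_docking_runs,
    simulate_ifps,
    simulate_pocket_sequences,
    simulate_run_pair,
    tanimoto,
    write_bundle,
)


class TestDockingSimulation:
    def test_zero_noise_perfect_correlation(self):
        config = SimulationConfig(
            seed=1, n_molecules=200,
            kinase_plan={"K": DockingPlan(n_structures=2, rho_lat=1.0, noise=0.0)},
        )
        runs = simulate_docking_runs(config)["K"]
        assert dockrank_sim(runs[0], runs[1], 200) == pytest.approx(1.0)

    def test_uncorrelated_runs_center_near_zero(self):
        rhos = [
            dockrank_sim(*simulate_run_pair(300, 0.0, seed), 300)
            for seed in range(60)
        ]
        assert abs(float(np.mean(rhos))) < 0.05

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho_lat"):
            DockingPlan(rho_lat=1.5)

    def test_too_few_molecules_rejected(self):
        config = SimulationConfig(seed=1, n_molecules=1,
                                  kinase_plan={"K": DockingPlan()})
        with pytest.raises(ValueError, match="n_molecules"):
            simulate_docking_runs(config)

    def test_fixed_seed_reproduces_runs(self):
        config = SimulationConfig(
            seed=9, n_molecules=100, kinase_plan={"K": DockingPlan()}
        )
        a = simulate_docking_runs(config)["K"][0]
        b = simulate_docking_runs(config)["K"][0]
        assert a.ranks == b.ranks
        assert [e.score for e in a.entries] == [e.score for e in b.entries]

    def test_adding_a_kinase_leaves_others_untouched(self):
        base = SimulationConfig(
            seed=4, n_molecules=100, kinase_plan={"KA": DockingPlan()}
        )
        extended = SimulationConfig(
            seed=4, n_molecules=100,
            kinase_plan={"KA": DockingPlan(), "KB": DockingPlan()},
        )
        assert (
            simulate_docking_runs(base)["KA"][0].ranks
            == simulate_docking_runs(extended)["KA"][0].ranks
        )


class TestActivitySimulation:
    def test_exact_counts_reproduce_promiscuity(self):
        config = SimulationConfig(
            seed=1,
            activity_plan=ActivityPlan(kinase_counts={"EGFR": (3382, 5702)}),
        )
        matrix = classify_active(ingest_activities(simulate_activity_table(config)))
        assert round(promiscuity(matrix, "EGFR"), 2) == 0.59

    def test_exact_pair_counts_reproduce_ligprofsim(self):
        config = SimulationConfig(
            seed=1,
            activity_plan=ActivityPlan(
                kinase_counts={"EGFR": (200, 400), "PI3K": (100, 300)},
                pair_counts={("EGFR", "PI3K"): (13, 180)},
            ),
        )
        matrix = classify_active(ingest_activities(simulate_activity_table(config)))
        assert ligprof_sim(matrix, "EGFR", "PI3K") == pytest.approx(13 / 180)
        assert promiscuity(matrix, "EGFR") == pytest.approx(200 / 400)
        assert promiscuity(matrix, "PI3K") == pytest.approx(100 / 300)

    def test_infeasible_pair_plan_rejected(self):
        config = SimulationConfig(
            seed=1,
            activity_plan=ActivityPlan(
                kinase_counts={"A": (5, 10), "B": (5, 10)},
                pair_counts={("A", "B"): (9, 8)},  # actives > tested
            ),
        )
        with pytest.raises(ValueError, match="exceed"):
            simulate_activity_table(config)

    def test_pair_blocks_exceeding_marginals_rejected(self):
        config = SimulationConfig(
            seed=1,
            activity_plan=ActivityPlan(
                kinase_counts={"A": (5, 10), "B": (5, 10)},
                pair_counts={("A", "B"): (2, 20)},  # 20 tested > marginal 10
            ),
        )
        with pytest.raises(ValueError, match="incompatible"):
            simulate_activity_table(config)

    def test_empty_plan_gives_no_records(self):
        assert simulate_activity_table(SimulationConfig(seed=1)) == []

    def test_stochastic_mode_respects_probabilities(self):
        config = SimulationConfig(
            seed=5,
            activity_plan=ActivityPlan(
                n_compounds=2000,
                test_prob={"K": 0.5},
                active_prob={"K": 0.3},
            ),
        )
        matrix = classify_active(ingest_activities(simulate_activity_table(config)))
        n_tested = int(matrix.tested["K"].sum())
        assert 900 <= n_tested <= 1100
        assert promiscuity(matrix, "K") == pytest.approx(0.3, abs=0.05)


class TestSequenceSimulation:
    def test_exact_mutation_counts(self):
        config = SimulationConfig(
            seed=2,
            sequence_plan=SequencePlan(
                mutations={"base": 0, "m9": 9, "all": 85}
            ),
        )
        seqs = {s.kinase_id: s for s in simulate_pocket_sequences(config)}
        assert poc_seq_sim(seqs["base"], seqs["base"]) == 1.0
        assert poc_seq_sim(seqs["base"], seqs["m9"]) == pytest.approx(76 / 85)
        assert poc_seq_sim(seqs["base"], seqs["all"]) == 0.0

    def test_mutation_count_over_85_rejected(self):
        with pytest.raises(ValueError):
            SequencePlan(mutations={"K": 86})

    def test_explicit_base_sequence_respected(self):
        base = "M" * 85
        config = SimulationConfig(
            seed=2, sequence_plan=SequencePlan(mutations={"K": 3}, base=base)
        )
        (s,) = simulate_pocket_sequences(config)
        diffs = sum(1 for a, b in zip(base, s.residues) if a != b)
        assert diffs == 3


class TestIFPSimulation:
    def test_zero_flip_rate_identical_fingerprints(self):
        config = SimulationConfig(
            seed=3,
            ifp_plan=IFPPlan(base_density=0.2,
                             flip_rates={"KA": [0.0], "KB": [0.0]}),
        )
        a, b = simulate_ifps(config)
        assert tanimoto(a.bit_array, b.bit_array) == 1.0

    def test_tanimoto_decreases_with_flip_rate(self):
        means = []
        for rate in (0.01, 0.1, 0.3):
            sims = []
            for seed in range(30):
                config = SimulationConfig(
                    seed=seed,
                    ifp_plan=IFPPlan(base_density=0.2,
                                     flip_rates={"KA": [0.0], "KB": [rate]}),
                )
                a, b = simulate_ifps(config)
                sims.append(tanimoto(a.bit_array, b.bit_array))
            means.append(float(np.mean(sims)))
        assert means[0] > means[1] > means[2]

    def test_fixed_seed_identical_bits(self):
        config = SimulationConfig(
            seed=6, ifp_plan=IFPPlan(flip_rates={"K": [0.2]})
        )
        assert simulate_ifps(config) == simulate_ifps(config)

    def test_invalid_flip_rate_rejected(self):
        with pytest.raises(ValueError):
            IFPPlan(flip_rates={"K": [1.2]})

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            IFPPlan(base_density=0.0)


def full_config(seed=11):
    return SimulationConfig(
        seed=seed,
        n_molecules=150,
        kinase_plan={
            "EGFR": DockingPlan(n_structures=2, rho_lat=0.9, noise=0.1),
            "BRAF": DockingPlan(n_structures=1, rho_lat=0.3, noise=0.1),
        },
        activity_plan=ActivityPlan(
            kinase_counts={"EGFR": (30, 60), "BRAF": (40, 50)},
            pair_counts={("EGFR", "BRAF"): (10, 20)},
        ),
        sequence_plan=SequencePlan(mutations={"EGFR": 0, "BRAF": 40}),
        ifp_plan=IFPPlan(base_density=0.2,
                         flip_rates={"EGFR": [0.02, 0.05], "BRAF": [0.2]}),
    )


def test_bundle_round_trips_through_readers(tmp_path):
    paths = write_bundle(full_config(), tmp_path)

    runs = read_manifest(paths["manifest"])
    direct = simulate_docking_runs(full_config())
    assert runs["EGFR"][0].ranks == direct["EGFR"][0].ranks

    records = read_activity_csv(paths["activity"])
    matrix = classify_active(ingest_activities(records))
    assert promiscuity(matrix, "BRAF") == pytest.approx(40 / 50)

    seqs = read_pocket_fasta(paths["pockets"])
    assert {s.kinase_id for s in seqs} == {"EGFR", "BRAF"}

    ifps = read_ifp_tsv(paths["ifps"])
    assert ifps == simulate_ifps(full_config())


def test_bundle_is_byte_identical_across_runs(tmp_path):
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    paths_a = write_bundle(full_config(), dir_a)
    paths_b = write_bundle(full_config(), dir_b)
    for key in paths_a:
        assert paths_a[key].read_bytes() == paths_b[key].read_bytes()


def test_config_from_yaml_dict():
    cfg = SimulationConfig.from_dict(
        {
            "seed": 7,
            "n_molecules": 50,
            "kinase_plan": {"EGFR": {"n_structures": 1, "rho_lat": 0.5}},
            "activity_plan": {
                "kinase_counts": {"EGFR": [3, 10]},
                "pair_counts": {},
            },
            "sequence_plan": {"mutations": {"EGFR": 4}},
            "ifp_plan": {"base_density": 0.1, "flip_rates": {"EGFR": [0.1]}},
        }
    )
    assert cfg.kinase_plan["EGFR"].rho_lat == 0.5
    assert cfg.activity_plan.kinase_counts == {"EGFR": (3, 10)}
    assert cfg.sequence_plan.mutations["EGFR"] == 4
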