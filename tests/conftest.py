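import numpy as np
import pytest

from kinprof import DockingRun, MoleculeScore, compute_ranks


def make_run(ordered_ids, kinase_id="KIN", structure_id="s1"):
    """Build a ranked run whose rank order is exactly ``ordered_ids``."""
    entries = [
        MoleculeScore(mol, float(i)) for i, mol in enumerate(ordered_ids, start=1)
    ]
    return compute_ranks(DockingRun(kinase_id, structure_id, entries))


@pytest.fixture
def make_ranked_run():
    return make_run


@pytest.fixture
def full_pipeline_config():
    """Pipeline config exercising every stage on a synthetic bundle."""
    return {
        "simulate": {
            "seed": 21,
            "n_molecules": 120,
            "kinase_plan": {
                "EGFR": {"n_structures": 2, "rho_lat": 0.9, "noise": 0.1},
                "ErbB2": {"n_structures": 1, "rho_lat": 0.8, "noise": 0.1},
                "BRAF": {"n_structures": 2, "rho_lat": 0.2, "noise": 0.1},
            },
            "activity_plan": {
                "kinase_counts": {
                    "EGFR": [30, 60], "ErbB2": [20, 40], "BRAF": [45, 50],
                },
                "pair_counts": {"EGFR/ErbB2": [12, 20], "EGFR/BRAF": [5, 10]},
            },
            "sequence_plan": {
                "mutations": {"EGFR": 0, "ErbB2": 9, "BRAF": 50}
            },
            "ifp_plan": {
                "base_density": 0.2,
                "flip_rates": {
                    "EGFR": [0.02, 0.1], "ErbB2": [0.05], "BRAF": [0.3, 0.3],
                },
            },
        },
        "score_profile": {
            "profile": {
                "profile_id": "p1",
                "members": [
                    {"kinase": "EGFR", "role": "target"},
                    {"kinase": "ErbB2", "role": "target"},
                    {"kinase": "BRAF", "role": "anti_target"},
                ],
            },
            "top_k": 50,
        },
        "docksim": {"top_n": 40},
        "ligprofsim": {},
        "pocseqsim": {},
        "ifpsim": {},
        "summarize": True,
        "compare": True,
    }


@pytest.fixture
def toy_profile_runs():
    """Three kinases, ten molecules, m=10 each, fixed rank tables.

    T2 has two structures so structure aggregation is exercised; ANTI
    is the anti-target.  Rank orders are fixed permutations of the same
    ten molecules.
    """
    mols = [f"m{i}" for i in range(10)]
    rng = np.random.default_rng(42)
    runs = {
        "T1": [make_run(list(rng.permutation(mols)), "T1", "t1_s1")],
        "T2": [
            make_run(list(rng.permutation(mols)), "T2", "t2_s1"),
            make_run(list(rng.permutation(mols)), "T2", "t2_s2"),
        ],
        "ANTI": [make_run(list(rng.permutation(mols)), "ANTI", "anti_s1")],
    }
    return mols, runs
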