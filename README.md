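# kinprof

Multi-target/anti-target docking re-ranking and kinase binding-site
similarity measures.

Selective kinase inhibitors are hard to design because most inhibitors
bind the highly conserved ATP pocket.  When a drug-discovery campaign
needs a ligand that hits several kinases (*targets*) while avoiding
others (*anti-targets*), two questions arise that this package answers
computationally:

1. **Given docking runs of one library against every kinase of a
   profile, which molecules best match the profile?**  `kinprof`
   re-ranks molecules with a combined profile score (see below).
2. **How similar are two kinases in the first place — and hence how
   hard is a given target/anti-target combination?**  `kinprof`
   computes four complementary similarity measures between kinases and
   compares them with each other.

It is aimed at computational chemists running structure-based
virtual-screening campaigns with DOCK-style score lists, ChEMBL-style
bioactivity exports and KLIFS-style pocket alignments/fingerprints.

## The profile score

For a profile of kinases k = 1..N (each a target or an anti-target),
each kinase contributes a log scaled rank per molecule, aggregated over
its structures s:

    target:      P_k = log10( min_s  r_{k,s} / m_{k,s} )
    anti-target: P_k = log10( max_s  (1 - (r_{k,s} - 1) / m_{k,s}) )

where r is the molecule's ordinal docking rank and m the library size.
The combined score is

    S = (1/N) * sum_k P_k  +  ( max_k P_k - min_k P_k ) / 2

Lower S is better.  The mean term rewards good log-scaled ranks
everywhere; the spread term penalises molecules that are good for only
part of the profile.  Anti-targets enter with inverted ranks, so
docking *badly* to them helps.

## The four similarity measures

| Measure | Basis | Value |
|---|---|---|
| LigProfSim | shared ChEMBL ligands | actives-on-both / tested-on-both (IC50 < 500 nM, binding assays) |
| PocSeqSim | KLIFS 85-residue pocket alignment | identical-residue fraction |
| IFPSim | KLIFS interaction fingerprints (85 residues × 7 interaction types = 595 bits) | max Tanimoto over structure pairs |
| DockRankSim | docking runs | Spearman rank correlation of the common top-N molecules, max over structure pairs |

A kinase's *self*-LigProfSim (actives/tested) is its promiscuity.  All
measures produce labeled symmetric matrices with NaN where a
comparison is undefined (e.g. single-structure kinases on the IFPSim
diagonal).

A synthetic-data generator (`kinprof.synthdata`) emulates all four
input kinds with controlled similarity structure — latent-affinity
docking scores with a dialled rank correlation, exact-count activity
tables, pocket sequences with exact mutation counts, and bit-flip IFPs
— so the entire pipeline runs and is tested at desk scale.

## Worked example

```python
import kinprof as kp

config = kp.SimulationConfig(
    seed=7,
    n_molecules=1000,
    kinase_plan={
        "EGFR": kp.DockingPlan(n_structures=2, rho_lat=0.9, noise=0.1),
        "ErbB2": kp.DockingPlan(n_structures=1, rho_lat=0.85, noise=0.1),
        "BRAF": kp.DockingPlan(n_structures=2, rho_lat=0.3, noise=0.1),
    },
)
runs = kp.simulate_docking_runs(config)
spec = kp.ProfileSpec(
    "+EGFR+ErbB2-BRAF",
    [("EGFR", "target"), ("ErbB2", "target"), ("BRAF", "anti_target")],
)
table = kp.rank_by_profile(runs, spec)
print(table.frame.head(5).round(3))
```

```
           P_EGFR  P_ErbB2  P_BRAF      S  profile_rank
MOL000763  -0.996   -1.004  -0.951 -0.957             1
MOL000635  -1.222   -1.119  -0.873 -0.897             2
MOL000278  -0.873   -1.056  -1.000 -0.885             3
MOL000279  -1.699   -1.009  -0.932 -0.830             4
MOL000359  -1.092   -0.759  -1.051 -0.801             5
```

The best-ranked molecule, `MOL000763`, sits around the top 10% of both
target dockings (P ≈ −1, i.e. scaled rank ≈ 0.1) *and* near the bottom
of the anti-target docking (P_BRAF ≈ −0.95 after inversion) — a
balanced profile, which the spread term rewards over, say,
`MOL000279`, whose excellent EGFR rank (P = −1.7) cannot compensate
its imbalance.

Kinase-level docking similarity from the same runs:

```python
print(kp.kinase_dockrank_matrix(runs, n=100).to_frame().round(3))
```

```
        EGFR  ErbB2   BRAF
EGFR   0.861  0.171 -0.024
ErbB2  0.171    NaN  0.049
BRAF  -0.024  0.049  0.921
```

EGFR and ErbB2 were simulated with strongly correlated latent
affinities, and their off-diagonal entry (0.171) is accordingly the
largest; BRAF, nearly uncorrelated with both, sits around 0.  The
diagonal compares different structures of the same kinase; ErbB2 has a
single structure, hence NaN.

The same pipeline is available from the shell:

```sh
kinprof simulate --config sim.yaml --out-dir inputs/
kinprof score-profile --manifest inputs/manifest.yaml --profile profile.yaml --out-dir out/
kinprof docksim --manifest inputs/manifest.yaml --top-n 25000 --out-dir out/
kinprof ligprofsim --activity chembl_export.csv --out-dir out/
kinprof pocseqsim --fasta pockets.fasta --out-dir out/
kinprof ifpsim --ifps klifs_ifps.tsv --out-dir out/
kinprof summarize --matrix out/ligprofsim.csv --measure LigProfSim
kinprof compare --matrix-a out/ifpsim.csv --matrix-b out/pocseqsim.csv
kinprof run --config pipeline.yaml --out-dir out/   # all stages at once
```

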