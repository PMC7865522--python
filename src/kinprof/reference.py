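"""Reference nine-kinase panel counts from the ChEMBL v27 kinase subset.

Per-kinase numbers of compounds with binding-assay IC50 measurements
(``tested``) and of those with IC50 below 500 nM (``actives``), for the
nine-kinase panel used throughout the worked examples: EGFR, ErbB2,
PI3K, VEGFR2, BRAF, CDK2, LCK, MET and p38a.  These counts are the
published inputs to the promiscuity calculation; they are data, not
expected outputs.
"""

from __future__ import annotations

__all__ = ["KINASE_PANEL_COUNTS", "panel_activity_plan"]

# kinase -> (actives, tested)
KINASE_PANEL_COUNTS: dict[str, tuple[int, int]] = {
    "EGFR": (3382, 5702),
    "ErbB2": (1048, 1690),
    "PI3K": (2706, 4150),
    "VEGFR2": (5197, 7426),
    "BRAF": (2968, 3625),
    "CDK2": (837, 1520),
    "LCK": (976, 1552),
    "MET": (2248, 2851),
    "p38a": (2753, 3581),
}


def panel_activity_plan():
    """Exact-count activity plan reproducing the panel's per-kinase
    actives/tested totals (no pairwise constraints)."""
    from .synthdata import ActivityPlan

    return ActivityPlan(kinase_counts=dict(KINASE_PANEL_COUNTS))
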