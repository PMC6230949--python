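"""Shared fixtures: small deterministic simulations reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from radmap import linkage, sim


@pytest.fixture(scope="session")
def small_cross():
    """3 chromosomes x 5 Mb, error-free, with one hotspot and one coldspot."""
    genome = sim.simulate_genome(3, 15_000_000, seed=11)
    land = sim.plant_landscape(
        genome,
        5.5,
        hotspots=[("chr01", 1_000_000, 1_100_000, 100.0)],
        coldspots=[("chr02", 1_500_000, 3_500_000)],
    )
    scaffolds = sim.fragment_scaffolds(genome, 1_000_000, seed=12)
    design = sim.CrossDesign(n_progeny=184, error_rate=0.0, missing_rate=0.0, seed=13)
    gm, pileup, truth = sim.simulate_cross(
        genome, land, 30.0, design, scaffolds=scaffolds, decoys_per_mb=2.0
    )
    return {
        "genome": genome,
        "landscape": land,
        "scaffolds": scaffolds,
        "gm": gm,
        "pileup": pileup,
        "truth": truth,
        "design": design,
    }


@pytest.fixture(scope="session")
def small_map(small_cross):
    """Linkage map built from the small error-free cross."""
    gm = small_cross["gm"]
    lmap, pairs, groups, singletons, n_masked = linkage.construct_map(gm.calls)
    return {"lmap": lmap, "pairs": pairs, "groups": groups, "singletons": singletons}


def make_calls(columns: list[str]) -> np.ndarray:
    """Build a call matrix from strings like '0011-' (one string per marker)."""
    trans = {"0": 0, "1": 1, "-": linkage.MISSING}
    return np.array([[trans[c] for c in col] for col in columns], dtype=np.int8)
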