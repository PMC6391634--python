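from __future__ import annotations

from itertools import combinations

import pytest

from acmine.chem_io import Compound, Status
from acmine.fragmentation import (
    DEFAULT_RETRO_RULES,
    MMP,
    enumerate_retrosynthetic_cuts,
    enumerate_single_cuts,
)
from acmine.synthetic_data import GeneratorConfig, generate_target_set


def brute_force_pairs(compounds, family=MMP, rules=DEFAULT_RETRO_RULES):
    """O(n^2) oracle: exhaustively intersect the fragmentation cores of every
    compound pair, keeping the largest shared core with differing
    substituents.  Returns {(id_a, id_b, core, sub_a, sub_b)}."""
    frags = {}
    for c in compounds:
        if family == MMP:
            frags[c.compound_id] = enumerate_single_cuts(c.smiles, c.compound_id)
        else:
            frags[c.compound_id] = enumerate_retrosynthetic_cuts(
                c.smiles, rules, c.compound_id
            )
    out = set()
    ids = sorted(frags)
    for a, b in combinations(ids, 2):
        best = None
        for fa in frags[a]:
            for fb in frags[b]:
                if fa.core_smiles != fb.core_smiles:
                    continue
                if fa.substituent_smiles == fb.substituent_smiles:
                    continue
                cand = (
                    -fa.core_heavy_atoms,
                    fa.core_smiles,
                    fa.substituent_smiles,
                    fb.substituent_smiles,
                )
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out.add((a, b, best[1], best[2], best[3]))
    return out


def active(cid: str, smiles: str, pki: float) -> Compound:
    return Compound(cid, smiles, Status.ACTIVE, pki)


def inactive(cid: str, smiles: str) -> Compound:
    return Compound(cid, smiles, Status.INACTIVE)


@pytest.fixture(scope="session")
def small_synthetic_set():
    """One modest analog-series set with inactives and planted cliffs."""
    cfg = GeneratorConfig(
        n_series=3,
        series_size=6,
        potency_sigma=0.7,
        planted_cliff_fraction=0.05,
        inactive_fraction=0.2,
        seed=11,
    )
    ts, truth = generate_target_set(cfg)
    return ts, truth, cfg
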