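"""Synthetic analog-series target sets with planted cliffs and inactive
analogs.

Each series is one scaffold with distinct R-groups substituted at a single
fixed attachment position, so within-series pairs form transformation
size-restricted matched pairs by construction.  Potencies are Gaussian with
configurable spread, clamped to the plausible [3, 12] pK_i range; a chosen
fraction of within-series active pairs is planted with an exact potency gap,
and a fraction of analogs is emitted as confirmed inactives.  Everything is
driven by a single seed: identical (config, seed) gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import Compound, Source, Status, TargetSet
from .errors import ConfigurationError

PKI_MIN, PKI_MAX = 3.0, 12.0

# Scaffolds with a single [*:1] attachment point, 10-15 heavy atoms each so
# that the shared core dominates any default R-group (tsr by construction).
# Attachment bonds are mixed: some match retrosynthetic rules (amide, ether,
# aromatic C-C, sulfonamide, amine), some are plain sp3 C-C cuts that only
# random fragmentation finds.
DEFAULT_CORE_LIBRARY: tuple[str, ...] = (
    "O=C(Nc1ccc(F)cc1)[*:1]",            # anilide, amide-rule cut
    "O=S(=O)(N[*:1])c1ccc(C)cc1",        # sulfonamide-rule cut
    "[*:1]OCc1ccc2ccccc2c1",             # ether-rule cut (naphthylmethyl)
    "[*:1]Oc1ccc(-c2ccccc2)cc1",         # ether-rule cut (biphenylol)
    "[*:1]N1CCN(c2ccccn2)CC1",           # amine-rule cut (piperazine)
    "[*:1]CC1CCc2ccccc2C1",              # plain sp3 C-C cut (no retro rule)
    "O=C(N1CCCC1)c1ccc([*:1])cc1",       # aryl attachment on benzamide
    "[*:1]CN1C(=O)c2ccccc2C1=O",         # sp3 C-C cut (phthalimide methyl)
)

DEFAULT_RGROUP_LIBRARY: tuple[str, ...] = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]C(C)C", "[*:1]CCCC",
    "[*:1]C(C)(C)C", "[*:1]OC", "[*:1]OCC", "[*:1]F", "[*:1]Cl",
    "[*:1]Br", "[*:1]O", "[*:1]N", "[*:1]C#N", "[*:1]C(=O)C",
    "[*:1]C(=O)OC", "[*:1]CO", "[*:1]CCO", "[*:1]C1CC1", "[*:1]C1CCC1",
    "[*:1]CF", "[*:1]C(F)(F)F", "[*:1]CCN", "[*:1]COC",
)

# Structurally unrelated screening compounds used as "diverse" inactives.
DIVERSE_INACTIVE_LIBRARY: tuple[str, ...] = (
    "CCOC(=O)C1=CC=CC=C1N",
    "CC(=O)OC1=CC=CC=C1C(=O)O",
    "C1=CC=C(C=C1)C2=NN=C(O2)S",
    "CCN(CC)CCNC(=O)C1=CC=C(N)C=C1",
    "OC1CCCCC1N2CCOCC2",
    "CC1=CC(=O)N(N1C)C2=CC=CC=C2",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_series: int = 5
    series_size: int = 8
    core_library: tuple[str, ...] = DEFAULT_CORE_LIBRARY
    rgroup_library: tuple[str, ...] = DEFAULT_RGROUP_LIBRARY
    potency_mean: float = 7.0
    potency_sigma: float = 1.0  # within-series pK_i spread
    series_mean_sigma: float = 1.2  # spread of per-series mean potencies
    planted_cliff_fraction: float = 0.0
    planted_delta: float = 3.2
    inactive_fraction: float = 0.0
    diverse_inactive_fraction: float = 0.0
    seed: int = 0
    target_id: str = "T1"
    target_name: str = "synthetic target"

    def validate(self) -> None:
        if not self.core_library or not self.rgroup_library:
            raise ConfigurationError("core and R-group libraries must be non-empty")
        if self.series_size < 2:
            raise ConfigurationError("series_size must be >= 2")
        if self.series_size > len(self.rgroup_library):
            raise ConfigurationError(
                f"series_size {self.series_size} exceeds R-group library size "
                f"{len(self.rgroup_library)}"
            )
        if not (0.0 <= self.inactive_fraction <= 1.0):
            raise ConfigurationError("inactive_fraction must be in [0, 1]")
        if self.planted_delta <= 0:
            raise ConfigurationError("planted_delta must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    series_of: dict[str, int] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    inactive_ids: list[str] = field(default_factory=list)
    inactive_analog_pairs: list[tuple[str, str]] = field(default_factory=list)
    diverse_inactive_ids: list[str] = field(default_factory=list)


def _join(core: str, rgroup: str) -> str:
    mol = Chem.molzip(Chem.MolFromSmiles(core), Chem.MolFromSmiles(rgroup))
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_target_set(cfg: GeneratorConfig) -> tuple[TargetSet, GroundTruth]:
    """Build one synthetic target set plus its ground truth.

    Guarantees: every molecule parses; at least one active per series; planted
    pairs have an exact |dpKi| of ``planted_delta``; same config implies
    byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    actives: list[Compound] = []
    inactives: list[Compound] = []
    plant_quota = 0.0  # fractional planted-pair budget carried across series

    for s in range(cfg.n_series):
        core = cfg.core_library[s % len(cfg.core_library)]
        rgroups = rng.choice(
            len(cfg.rgroup_library), size=cfg.series_size, replace=False
        )
        smiles = [_join(core, cfg.rgroup_library[i]) for i in rgroups]
        ids = [f"{cfg.target_id}-S{s:02d}-{k:03d}" for k in range(cfg.series_size)]
        for cid in ids:
            truth.series_of[cid] = s

        # inactive subset: never the whole series
        n_inactive = min(
            int(round(cfg.inactive_fraction * cfg.series_size)), cfg.series_size - 1
        )
        inactive_idx = set(
            rng.choice(cfg.series_size, size=n_inactive, replace=False).tolist()
        )
        active_idx = [k for k in range(cfg.series_size) if k not in inactive_idx]

        # each series sits at its own potency level: the between-series
        # spread drives set-level qualification while the (smaller)
        # within-series spread shapes the pair-delta distribution
        series_mean = cfg.potency_mean + float(
            rng.normal(0.0, cfg.series_mean_sigma)
        )
        pkis = np.clip(
            rng.normal(series_mean, cfg.potency_sigma, size=cfg.series_size),
            PKI_MIN,
            PKI_MAX,
        )

        # plant exact-gap pairs on disjoint active pairs of this series;
        # the fractional budget carries over so small fractions still plant
        n_active_pairs = len(active_idx) * (len(active_idx) - 1) // 2
        plant_quota += cfg.planted_cliff_fraction * n_active_pairs
        n_planted = min(int(plant_quota), len(active_idx) // 2)
        plant_quota -= n_planted
        if n_planted > 0:
            delta = min(cfg.planted_delta, PKI_MAX - PKI_MIN - 0.5)
            order = rng.permutation(len(active_idx))
            for j in range(n_planted):
                lo = active_idx[order[2 * j]]
                hi = active_idx[order[2 * j + 1]]
                # straddle the series mean so planted compounds are not
                # outliers that inflate the realized mean+2*sigma threshold
                center = rng.normal(series_mean, 0.25 * cfg.potency_sigma)
                base = float(
                    np.clip(center - delta / 2.0, PKI_MIN, PKI_MAX - delta)
                )
                pkis[lo] = base
                pkis[hi] = base + delta
                truth.planted_pairs.append(tuple(sorted((ids[lo], ids[hi]))))

        for k in range(cfg.series_size):
            if k in inactive_idx:
                inactives.append(
                    Compound(ids[k], smiles[k], Status.INACTIVE, None, Source.SYNTHETIC)
                )
                truth.inactive_ids.append(ids[k])
                for a in active_idx:
                    truth.inactive_analog_pairs.append((ids[a], ids[k]))
            else:
                actives.append(
                    Compound(
                        ids[k], smiles[k], Status.ACTIVE, float(pkis[k]), Source.SYNTHETIC
                    )
                )

    n_diverse = int(round(cfg.diverse_inactive_fraction * len(inactives)))
    for j in range(min(n_diverse, len(DIVERSE_INACTIVE_LIBRARY))):
        cid = f"{cfg.target_id}-DIV-{j:03d}"
        smi = Chem.MolToSmiles(Chem.MolFromSmiles(DIVERSE_INACTIVE_LIBRARY[j]))
        inactives.append(Compound(cid, smi, Status.INACTIVE, None, Source.SYNTHETIC))
        truth.inactive_ids.append(cid)
        truth.diverse_inactive_ids.append(cid)

    ts = TargetSet(cfg.target_id, cfg.target_name, actives, inactives)
    truth.planted_pairs.sort()
    truth.inactive_analog_pairs.sort()
    return ts, truth


def generate_benchmark_suite(
    n_sets: int = 10,
    seed: int = 7,
    base: GeneratorConfig = GeneratorConfig(n_series=8, series_size=10),
) -> list[tuple[TargetSet, GroundTruth, GeneratorConfig]]:
    """Deterministic panel of sets spanning flat and high-variance potency
    distributions, with and without inactives.

    Set 0 is always flat (near-zero within- and between-series sigma) so
    qualification rejects it; the remaining sets cycle through within-series
    sigmas of 0.35-0.8 log units on top of a ~1 log-unit between-series
    spread, tuned so realized set-dependent thresholds land in the 0.9-2.7
    range while the sets still qualify as having significant potency
    variation.
    """
    if n_sets < 1:
        raise ConfigurationError("n_sets must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_sets)]
    # mean+2*sigma of |dpKi| ~ 2.83 * potency_sigma for Gaussian pK_i, so
    # sigmas of 0.35-0.95 keep realized thresholds near the 0.9-2.7 window
    sigmas = [0.35, 0.5, 0.65, 0.8]
    suite = []
    for i in range(n_sets):
        if i == 0:
            sigma, between, inact, planted = 0.01, 0.0, 0.0, 0.0
        else:
            sigma = sigmas[(i - 1) % len(sigmas)]
            between = base.series_mean_sigma
            inact = 0.15 if i % 2 == 1 else 0.0
            planted = 0.02 if i % 3 != 0 else 0.0
        cfg = replace(
            base,
            potency_sigma=sigma,
            series_mean_sigma=between,
            inactive_fraction=inact,
            planted_cliff_fraction=planted,
            seed=child_seeds[i],
            target_id=f"T{i:03d}",
            target_name=f"synthetic target {i}",
        )
        ts, truth = generate_target_set(cfg)
        suite.append((ts, truth, cfg))
    return suite


# ---------------------------------------------------------------------------
# Table emission in the dialects chem_io reads.
# ---------------------------------------------------------------------------


def write_activity_table(sets: Sequence[TargetSet], path: str | Path) -> None:
    lines = ["compound_id\ttarget_id\ttarget_name\tsmiles\tpki"]
    for ts in sets:
        for c in ts.actives:
            lines.append(
                f"{c.compound_id}\t{ts.target_id}\t{ts.target_name}\t{c.smiles}\t{c.pki!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_inactives_table(sets: Sequence[TargetSet], path: str | Path) -> None:
    lines = ["compound_id\ttarget_id\tsmiles"]
    for ts in sets:
        for c in ts.inactives:
            lines.append(f"{c.compound_id}\t{ts.target_id}\t{c.smiles}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_ground_truth(
    truths: Sequence[tuple[str, GroundTruth]], path: str | Path
) -> None:
    """Planted pairs and inactive-analog pairs as a labelled TSV."""
    lines = ["target_id\tkind\tcompound_a\tcompound_b"]
    for tid, truth in truths:
        for a, b in truth.planted_pairs:
            lines.append(f"{tid}\tplanted_cliff\t{a}\t{b}")
        for a, b in truth.inactive_analog_pairs:
            lines.append(f"{tid}\tinactive_analog\t{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
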