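"""Target-set qualification, set-dependent thresholds and cliff calling.

Three cliff flavors are produced from transformation-size-restricted matched
pairs:

* ``original`` — constant threshold, |dpKi| >= 2.0 (100-fold potency gap);
* ``sd``       — set-dependent, |dpKi| >= mean + 2*sigma of the set's full
                 pair-delta distribution; active/active only;
* ``isd``      — an AC-relevant-potency (ACRP) active paired with a confirmed
                 inactive analog; carries no potency difference.

All cliff boundaries are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .chem_io import Compound, Status, TargetSet
from .errors import EmptyDistributionError
from .fragmentation import (
    DEFAULT_RETRO_RULES,
    MatchedPair,
    RetroRule,
    TsrParams,
    find_matched_pairs,
    tsr_pairs,
)

ORIGINAL_DELTA = 2.0  # two orders of magnitude in K_i

CLIFF_ORIGINAL = "original"
CLIFF_SD = "sd"
CLIFF_ISD = "isd"


@dataclass(frozen=True)
class SetThreshold:
    """Set-dependent potency-difference threshold: mean + 2*sigma of |dpKi|
    over ALL tsr pairs of the set (sample standard deviation)."""

    target_id: str
    family: str
    n_pairs: int
    mean_delta: float
    sigma_delta: float

    @property
    def threshold(self) -> float:
        return self.mean_delta + 2.0 * self.sigma_delta


@dataclass(frozen=True)
class Cliff:
    pair: MatchedPair
    cliff_type: str
    family: str
    potent_partner: str
    other_partner: str
    delta_pki: float | None = None  # absent for isd cliffs

    @property
    def ids(self) -> tuple[str, str]:
        return self.pair.ids


@dataclass(frozen=True)
class ACRPResult:
    """AC-relevant-potency selection: the threshold is the median pK_i of the
    unique highly potent sd-cliff partners; every set active at or above it is
    an ACRP compound (not only cliff partners)."""

    target_id: str
    family: str
    acrp_threshold: float
    acrp_compound_ids: frozenset[str]


@dataclass(frozen=True)
class QualificationCriterion:
    """Proxy for 'statistically significant potency variation': enough actives
    and enough spread.  Pluggable via ``predicate``."""

    min_compounds: int = 50
    min_sigma: float = 1.0
    predicate: Callable[[TargetSet], bool] | None = None


def qualify_target_set(
    target_set: TargetSet, criterion: QualificationCriterion = QualificationCriterion()
) -> bool:
    """True iff the set is large enough and its pK_i spread wide enough for
    set-dependent cliff analysis (flat sets are excluded)."""
    if criterion.predicate is not None:
        return bool(criterion.predicate(target_set))
    pkis = [c.pki for c in target_set.actives]
    if len(pkis) < criterion.min_compounds:
        return False
    sigma = float(np.std(pkis, ddof=1)) if len(pkis) > 1 else 0.0
    return sigma >= criterion.min_sigma


def pair_deltas(
    pairs: Sequence[MatchedPair], pki: Mapping[str, float]
) -> np.ndarray:
    return np.array(
        [abs(pki[p.compound_a] - pki[p.compound_b]) for p in pairs], dtype=float
    )


def compute_set_threshold(
    pairs: Sequence[MatchedPair],
    pki: Mapping[str, float],
    target_id: str,
    family: str,
) -> SetThreshold:
    """Mean + 2*(sample sigma) of |dpKi| over all tsr pairs of one set."""
    deltas = pair_deltas(pairs, pki)
    if deltas.size == 0:
        raise EmptyDistributionError(
            f"no tsr pairs for target {target_id} ({family})"
        )
    mean = float(np.mean(deltas))
    sigma = float(np.std(deltas, ddof=1)) if deltas.size > 1 else 0.0
    return SetThreshold(target_id, family, int(deltas.size), mean, sigma)


def _active_cliffs(
    pairs: Iterable[MatchedPair],
    pki: Mapping[str, float],
    cutoff: float,
    cliff_type: str,
    family: str,
) -> list[Cliff]:
    out = []
    for p in pairs:
        delta = abs(pki[p.compound_a] - pki[p.compound_b])
        if delta >= cutoff:
            potent, other = (
                (p.compound_a, p.compound_b)
                if pki[p.compound_a] >= pki[p.compound_b]
                else (p.compound_b, p.compound_a)
            )
            out.append(Cliff(p, cliff_type, family, potent, other, delta))
    return out


def call_sd_cliffs(
    pairs: Sequence[MatchedPair],
    pki: Mapping[str, float],
    threshold: SetThreshold,
) -> list[Cliff]:
    """All tsr pairs whose |dpKi| reaches the set threshold (inclusive)."""
    return _active_cliffs(pairs, pki, threshold.threshold, CLIFF_SD, threshold.family)


def call_original_cliffs(
    pairs: Sequence[MatchedPair],
    pki: Mapping[str, float],
    family: str,
    delta: float = ORIGINAL_DELTA,
) -> list[Cliff]:
    """Constant-threshold cliffs: |dpKi| >= 2.0."""
    return _active_cliffs(pairs, pki, delta, CLIFF_ORIGINAL, family)


def determine_acrp_compounds(
    sd_cliffs: Sequence[Cliff], target_set: TargetSet
) -> ACRPResult | None:
    """Select AC-relevant-potency compounds from sd cliffs.

    Returns None when the set yielded no sd cliffs (no-ACRP condition: the
    set can produce no isd cliffs).
    """
    if not sd_cliffs:
        return None
    pki = target_set.pki_map
    family = sd_cliffs[0].family
    unique_potent = sorted({c.potent_partner for c in sd_cliffs})
    acrp_threshold = float(np.median([pki[cid] for cid in unique_potent]))
    acrp_ids = frozenset(
        c.compound_id for c in target_set.actives if c.pki >= acrp_threshold
    )
    return ACRPResult(target_set.target_id, family, acrp_threshold, acrp_ids)


def call_isd_cliffs(
    acrp: ACRPResult,
    target_set: TargetSet,
    family: str,
    rules: Sequence[RetroRule] = DEFAULT_RETRO_RULES,
    tsr: TsrParams = TsrParams(),
) -> list[Cliff]:
    """tsr pairs between ACRP actives and confirmed inactives of the set.

    Pair finding runs over the union of ACRP actives and inactives with the
    same family restriction as the rest of the run; active/active and
    inactive/inactive pairs are discarded and isd cliffs carry no dpKi.
    """
    if not target_set.inactives:
        return []
    acrp_actives = [
        c for c in target_set.actives if c.compound_id in acrp.acrp_compound_ids
    ]
    pool: list[Compound] = acrp_actives + list(target_set.inactives)
    status = {c.compound_id: c.status for c in pool}
    cliffs = []
    for p in tsr_pairs(find_matched_pairs(pool, family, rules), tsr):
        sa, sb = status[p.compound_a], status[p.compound_b]
        if sa is sb:
            continue
        active_id, inactive_id = (
            (p.compound_a, p.compound_b)
            if sa is Status.ACTIVE
            else (p.compound_b, p.compound_a)
        )
        if active_id not in acrp.acrp_compound_ids:
            continue
        cliffs.append(Cliff(p, CLIFF_ISD, family, active_id, inactive_id, None))
    return cliffs
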