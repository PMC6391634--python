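"""Single-cut fragmentation, fragment-and-index matched-pair generation and
transformation-size restrictions.

A fragmentation cuts one exocyclic single bond between two heavy atoms and
yields a core (the larger fragment) and a substituent, each carrying exactly
one unlabeled attachment-point dummy atom.  Matched molecular pairs (MMPs)
are found by indexing compounds on their canonical core SMILES; retrosynthetic
MMPs (RMMPs) restrict the cuts to bonds matching a configurable rule set and
are therefore always a subset of the MMPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .chem_io import Compound
from .errors import ConfigurationError, StructureError

MMP = "MMP"
RMMP = "RMMP"
RANDOM_CUT = "random-cut"


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut of a molecule into core + substituent."""

    compound_id: str
    core_smiles: str
    substituent_smiles: str
    core_heavy_atoms: int
    substituent_heavy_atoms: int
    rule_id: str = RANDOM_CUT


@dataclass(frozen=True)
class MatchedPair:
    """Two compounds sharing a core and exchanging a pair of substituents.

    ``compound_a < compound_b`` lexicographically; ``sub_a_smiles`` belongs to
    ``compound_a``.  Exactly one pair is kept per unordered compound pair and
    family: the one with the largest shared core (smallest transformation).
    """

    compound_a: str
    compound_b: str
    core_smiles: str
    sub_a_smiles: str
    sub_b_smiles: str
    family: str
    core_heavy_atoms: int
    sub_a_heavy_atoms: int
    sub_b_heavy_atoms: int

    @property
    def ids(self) -> tuple[str, str]:
        return (self.compound_a, self.compound_b)

    @property
    def size_stats(self) -> tuple[int, int, int]:
        return (self.core_heavy_atoms, self.sub_a_heavy_atoms, self.sub_b_heavy_atoms)


@dataclass(frozen=True)
class RetroRule:
    """A retrosynthetic cut rule: a SMARTS whose atoms mapped :1 and :2 flank
    the bond to cut."""

    rule_id: str
    smarts: str


# RECAP-style stand-in rule set (the published retrosynthetic inventory is not
# reproduced here; patterns are configurable via load_rules).
DEFAULT_RETRO_RULES: tuple[RetroRule, ...] = (
    RetroRule("amide", "[C:1](=O)-[N:2]"),
    RetroRule("ester", "[C:1](=O)-[O;D2:2]"),
    RetroRule("sulfonamide", "[S:1](=O)(=O)-[N:2]"),
    RetroRule("amine", "[N;X3;!$(N~[!#6]);!$(N-C=[O,S,N]):1]-[C;!$(C=*):2]"),
    RetroRule("ether", "[O;D2;!$(O-C=O):1]-[C,c:2]"),
    RetroRule("aromatic_cc", "[c:1]-[c:2]"),
    RetroRule("aromatic_n_aliphatic_c", "[n:1]-[C:2]"),
    RetroRule("olefin_adjacent", "[C;$(C=C):1]-[C;X4:2]"),
)


def load_rules(path: str | Path) -> tuple[RetroRule, ...]:
    """Load a rules file: one ``rule_id<TAB>SMARTS`` per line, '#' comments."""
    rules: list[RetroRule] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'rule_id<TAB>SMARTS', got {line!r}"
            )
        if Chem.MolFromSmarts(parts[1]) is None:
            raise ConfigurationError(f"{path}:{lineno}: invalid SMARTS {parts[1]!r}")
        rules.append(RetroRule(parts[0], parts[1]))
    if not rules:
        raise ConfigurationError(f"{path}: empty rule set")
    return tuple(rules)


def _parse_single_molecule(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureError(f"expected a single connected molecule: {smiles!r}")
    return mol


def heavy_atom_count(fragment_smiles: str) -> int:
    """Heavy atoms in a fragment SMILES, excluding the attachment dummy."""
    mol = Chem.MolFromSmiles(fragment_smiles)
    if mol is None:
        raise StructureError(f"unparseable fragment: {fragment_smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of exocyclic single bonds between two heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() is not Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _fragment_at_bond(
    mol: Chem.Mol, bond_idx: int, compound_id: str, rule_id: str
) -> Fragmentation | None:
    frag = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    try:
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    except Exception:
        return None
    if len(pieces) != 2:  # defensive; acyclic cut always gives two pieces
        return None
    smis = [Chem.MolToSmiles(p) for p in pieces]
    sizes = [sum(1 for a in p.GetAtoms() if a.GetAtomicNum() > 1) for p in pieces]
    # core = larger fragment; ties broken by lexicographically smaller SMILES
    order = sorted(range(2), key=lambda i: (-sizes[i], smis[i]))
    ci, si = order
    return Fragmentation(
        compound_id=compound_id,
        core_smiles=smis[ci],
        substituent_smiles=smis[si],
        core_heavy_atoms=sizes[ci],
        substituent_heavy_atoms=sizes[si],
        rule_id=rule_id,
    )


def enumerate_single_cuts(
    smiles: str, compound_id: str = ""
) -> list[Fragmentation]:
    """All single-cut fragmentations of a molecule.

    One fragmentation per acyclic single bond between heavy atoms; bonds to
    hydrogen and ring bonds are never cut.
    """
    mol = _parse_single_molecule(smiles)
    frags = []
    for bidx in _cuttable_bonds(mol):
        f = _fragment_at_bond(mol, bidx, compound_id, RANDOM_CUT)
        if f is not None:
            frags.append(f)
    return frags


def enumerate_retrosynthetic_cuts(
    smiles: str,
    rules: Sequence[RetroRule] = DEFAULT_RETRO_RULES,
    compound_id: str = "",
) -> list[Fragmentation]:
    """Single cuts restricted to bonds matching >=1 retrosynthetic rule.

    The result is always a subset of :func:`enumerate_single_cuts`; the first
    matching rule (in rule order) is recorded as provenance.
    """
    if not rules:
        raise ConfigurationError("retrosynthetic rule set must not be empty")
    mol = _parse_single_molecule(smiles)
    eligible = set(_cuttable_bonds(mol))
    bond_rule: dict[int, str] = {}
    for rule in rules:
        patt = Chem.MolFromSmarts(rule.smarts)
        if patt is None:
            raise ConfigurationError(f"invalid SMARTS for rule {rule.rule_id!r}")
        maps = {a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum()}
        if 1 not in maps or 2 not in maps:
            raise ConfigurationError(
                f"rule {rule.rule_id!r} must map the cut atoms as :1 and :2"
            )
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[maps[1]], match[maps[2]])
            if bond is None:
                continue
            bidx = bond.GetIdx()
            if bidx in eligible and bidx not in bond_rule:
                bond_rule[bidx] = rule.rule_id
    frags = []
    for bidx in sorted(bond_rule):
        f = _fragment_at_bond(mol, bidx, compound_id, bond_rule[bidx])
        if f is not None:
            frags.append(f)
    return frags


def fragment_compound(
    compound: Compound,
    family: str = MMP,
    rules: Sequence[RetroRule] = DEFAULT_RETRO_RULES,
) -> list[Fragmentation]:
    if family == MMP:
        return enumerate_single_cuts(compound.smiles, compound.compound_id)
    if family == RMMP:
        return enumerate_retrosynthetic_cuts(compound.smiles, rules, compound.compound_id)
    raise ConfigurationError(f"unknown family {family!r}")


def find_matched_pairs(
    compounds: Iterable[Compound],
    family: str = MMP,
    rules: Sequence[RetroRule] = DEFAULT_RETRO_RULES,
    fragment_cache: Mapping[str, Sequence[Fragmentation]] | None = None,
) -> list[MatchedPair]:
    """Fragment-and-index matched-pair generation.

    Compounds are fragmented once; fragmentations are indexed by canonical
    core SMILES.  Two compounds under the same core with different
    substituents form a candidate pair; per unordered compound pair the
    candidate with the largest core is kept.  The result is order-independent
    and deduplicated, sorted for deterministic output.

    ``fragment_cache`` (compound_id -> fragmentations) lets callers reuse
    fragmentations across families.
    """
    index: dict[str, dict[str, set[tuple[str, int, int]]]] = {}
    for c in compounds:
        if fragment_cache is not None and c.compound_id in fragment_cache:
            frags = fragment_cache[c.compound_id]
        else:
            frags = fragment_compound(c, family, rules)
        for f in frags:
            per_cpd = index.setdefault(f.core_smiles, {})
            per_cpd.setdefault(c.compound_id, set()).add(
                (f.substituent_smiles, f.substituent_heavy_atoms, f.core_heavy_atoms)
            )

    # candidate with max core size wins; deterministic tie-break on SMILES
    best: dict[tuple[str, str], tuple] = {}
    for core, per_cpd in index.items():
        if len(per_cpd) < 2:
            continue
        ids = sorted(per_cpd)
        for a, b in combinations(ids, 2):
            for sub_a, ha_a, core_ha in per_cpd[a]:
                for sub_b, ha_b, _ in per_cpd[b]:
                    if sub_a == sub_b:
                        continue
                    key = (a, b)
                    cand = (-core_ha, core, sub_a, sub_b, ha_a, ha_b)
                    if key not in best or cand < best[key]:
                        best[key] = cand
    pairs = []
    for (a, b) in sorted(best):
        neg_core_ha, core, sub_a, sub_b, ha_a, ha_b = best[(a, b)]
        pairs.append(
            MatchedPair(
                compound_a=a,
                compound_b=b,
                core_smiles=core,
                sub_a_smiles=sub_a,
                sub_b_smiles=sub_b,
                family=family,
                core_heavy_atoms=-neg_core_ha,
                sub_a_heavy_atoms=ha_a,
                sub_b_heavy_atoms=ha_b,
            )
        )
    return pairs


@dataclass(frozen=True)
class TsrParams:
    """Transformation-size restrictions: core >= factor x each substituent,
    substituent size difference <= max_size_diff, each substituent
    <= max_sub_size heavy atoms."""

    core_factor: float = 2.0
    max_size_diff: int = 8
    max_sub_size: int = 13


def apply_tsr_filter(pair: MatchedPair, params: TsrParams = TsrParams()) -> bool:
    core, sa, sb = pair.size_stats
    return (
        core >= params.core_factor * sa
        and core >= params.core_factor * sb
        and abs(sa - sb) <= params.max_size_diff
        and sa <= params.max_sub_size
        and sb <= params.max_sub_size
    )


def tsr_pairs(
    pairs: Iterable[MatchedPair], params: TsrParams = TsrParams()
) -> list[MatchedPair]:
    return [p for p in pairs if apply_tsr_filter(p, params)]
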