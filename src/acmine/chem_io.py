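"""Compound/target-set data model, table readers, potency curation and the
deposition text format.

Potency is handled as pK_i = -log10(K_i in mol/L) throughout.  Input tables
reporting K_i in nM can be converted by the reader when the dialect declares
``ki_nm=True`` (pki = 9 - log10(Ki_nM)).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    ConfigurationError,
    DepositionFormatError,
    FormatError,
    StructureError,
)

RDLogger.DisableLog("rdApp.*")


class Status(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class Source(str, Enum):
    MEDCHEM = "medchem"
    SCREENING = "screening"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class Compound:
    """One molecule with identity, structure and (for actives) a potency.

    Invariants: an active compound carries a finite pK_i; an inactive one
    carries none.
    """

    compound_id: str
    smiles: str
    status: Status
    pki: float | None = None
    source: Source = Source.MEDCHEM

    def __post_init__(self) -> None:
        if self.status is Status.ACTIVE:
            if self.pki is None or not math.isfinite(self.pki):
                raise ValueError(
                    f"active compound {self.compound_id!r} requires a finite pki"
                )
        else:
            if self.pki is not None:
                raise ValueError(
                    f"inactive compound {self.compound_id!r} must not carry a pki"
                )

    def shifted(self, delta: float) -> "Compound":
        """Return a copy with pK_i shifted by ``delta`` (actives only)."""
        if self.status is not Status.ACTIVE:
            return self
        return replace(self, pki=self.pki + delta)


@dataclass(frozen=True)
class ActivityMeasurement:
    """A single numeric pK_i reading for one compound against one target."""

    compound_id: str
    target_id: str
    pki_value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pki_value):
            raise ValueError("pki_value must be finite")


@dataclass
class TargetSet:
    """All curated actives for one target plus its pool of confirmed inactives."""

    target_id: str
    target_name: str = ""
    actives: list[Compound] = field(default_factory=list)
    inactives: list[Compound] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        overlap = {c.compound_id for c in self.actives} & {
            c.compound_id for c in self.inactives
        }
        if overlap:
            raise ValueError(
                f"target {self.target_id}: ids in both actives and inactives: "
                f"{sorted(overlap)}"
            )

    @property
    def active_ids(self) -> set[str]:
        return {c.compound_id for c in self.actives}

    @property
    def pki_map(self) -> dict[str, float]:
        return {c.compound_id: c.pki for c in self.actives}

    @property
    def compounds(self) -> dict[str, Compound]:
        out = {c.compound_id: c for c in self.actives}
        out.update({c.compound_id: c for c in self.inactives})
        return out

    def add_inactive(self, compound: Compound) -> None:
        if compound.status is not Status.INACTIVE:
            raise ValueError("add_inactive requires an inactive compound")
        if compound.compound_id in self.active_ids:
            raise ValueError(
                f"{compound.compound_id} already active in {self.target_id}"
            )
        self.inactives.append(compound)

    def shifted(self, delta: float) -> "TargetSet":
        """Copy of the set with every active pK_i shifted by ``delta``."""
        return TargetSet(
            target_id=self.target_id,
            target_name=self.target_name,
            actives=[c.shifted(delta) for c in self.actives],
            inactives=list(self.inactives),
        )


@dataclass(frozen=True)
class TableDialect:
    """Column naming / separator conventions of a delimited activity table."""

    sep: str = "\t"
    compound_id_col: str = "compound_id"
    target_id_col: str = "target_id"
    smiles_col: str = "smiles"
    pki_col: str = "pki"
    target_name_col: str | None = "target_name"
    ki_nm: bool = False  # pki column actually holds K_i in nM


@dataclass
class ReadSummary:
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_missing_pki: int = 0
    n_dropped_bad_structure: int = 0
    n_conflicts: int = 0
    n_unknown_targets: int = 0


def curate_smiles(smiles: str) -> str:
    """Canonicalize a SMILES, keeping the largest organic fragment.

    Salts/solvents are stripped by retaining the fragment with the most heavy
    atoms (carbon-containing fragments preferred).  Raises
    :class:`StructureError` when nothing parses.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        def key(m):
            has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
            return (has_c, m.GetNumHeavyAtoms(), Chem.MolToSmiles(m))

        mol = max(frags, key=key)
    if mol.GetNumHeavyAtoms() == 0:
        raise StructureError(f"no heavy atoms after curation: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _load_table(path: str | Path, dialect: TableDialect, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=dialect.sep, dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_activity_table(
    path: str | Path, dialect: TableDialect = TableDialect()
) -> tuple[list[ActivityMeasurement], dict[str, str], dict[str, str], ReadSummary]:
    """Read an activity table into measurements.

    Returns ``(measurements, smiles_by_compound, target_names, summary)``.
    Rows with a missing or non-numeric potency are dropped and counted in the
    summary, never silently.
    """
    d = dialect
    df = _load_table(path, d, [d.compound_id_col, d.target_id_col, d.smiles_col, d.pki_col])
    summary = ReadSummary(n_rows=len(df))
    measurements: list[ActivityMeasurement] = []
    smiles: dict[str, str] = {}
    target_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        raw = rec[d.pki_col]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            summary.n_dropped_missing_pki += 1
            continue
        if not math.isfinite(value):
            summary.n_dropped_missing_pki += 1
            continue
        if d.ki_nm:
            if value <= 0:
                summary.n_dropped_missing_pki += 1
                continue
            value = 9.0 - math.log10(value)
        cid = str(rec[d.compound_id_col])
        tid = str(rec[d.target_id_col])
        measurements.append(ActivityMeasurement(cid, tid, value))
        smiles[cid] = str(rec[d.smiles_col])
        if d.target_name_col and d.target_name_col in rec:
            name = rec[d.target_name_col]
            if isinstance(name, str) and name:
                target_names[tid] = name
        summary.n_kept += 1
    return measurements, smiles, target_names, summary


def aggregate_potency(
    measurements: Iterable[ActivityMeasurement],
    smiles: Mapping[str, str],
    target_names: Mapping[str, str] | None = None,
    max_spread: float = 1.0,
    source: Source = Source.MEDCHEM,
) -> tuple[dict[str, TargetSet], ReadSummary]:
    """Aggregate replicate readings into one Compound per (compound, target).

    Replicates are reconciled by the arithmetic mean of their pK_i values; a
    compound whose readings span more than ``max_spread`` log units for a
    target is discarded for that target.  The resulting mean always lies
    within [min, max] of the readings.
    """
    target_names = target_names or {}
    summary = ReadSummary()
    grouped: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for m in measurements:
        grouped[m.target_id][m.compound_id].append(m.pki_value)
        summary.n_rows += 1
    sets: dict[str, TargetSet] = {}
    for tid in sorted(grouped):
        actives: list[Compound] = []
        for cid in sorted(grouped[tid]):
            values = grouped[tid][cid]
            if max(values) - min(values) > max_spread:
                summary.n_dropped_missing_pki += 1
                continue
            try:
                smi = curate_smiles(smiles[cid])
            except (KeyError, StructureError):
                summary.n_dropped_bad_structure += 1
                continue
            actives.append(
                Compound(cid, smi, Status.ACTIVE, sum(values) / len(values), source)
            )
            summary.n_kept += 1
        if actives:
            sets[tid] = TargetSet(tid, target_names.get(tid, ""), actives)
    return sets, summary


def read_inactives(
    path: str | Path,
    target_sets: Mapping[str, TargetSet],
    dialect: TableDialect = TableDialect(),
    source: Source = Source.SCREENING,
) -> ReadSummary:
    """Attach inactive compounds from a table to existing target sets.

    Inactives for unknown targets are skipped and counted; an inactive whose
    id already exists among a set's actives is rejected as a conflict so the
    active/inactive disjointness invariant always holds.
    """
    d = dialect
    df = _load_table(path, d, [d.compound_id_col, d.target_id_col, d.smiles_col])
    summary = ReadSummary(n_rows=len(df))
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        tid = str(rec[d.target_id_col])
        cid = str(rec[d.compound_id_col])
        ts = target_sets.get(tid)
        if ts is None:
            summary.n_unknown_targets += 1
            continue
        if cid in ts.active_ids or cid in {c.compound_id for c in ts.inactives}:
            summary.n_conflicts += 1
            continue
        try:
            smi = curate_smiles(str(rec[d.smiles_col]))
        except StructureError:
            summary.n_dropped_bad_structure += 1
            continue
        ts.add_inactive(Compound(cid, smi, Status.INACTIVE, None, source))
        summary.n_kept += 1
    return summary


# ---------------------------------------------------------------------------
# Deposition format
#
# UTF-8, tab separated.  Per-target header lines are '#'-prefixed:
#   #TARGET <target_id> <target_name> <assay_ids ';'-joined or NA> \
#           <acrp_threshold or NA> <family>
# followed by one cliff record per line:
#   <cliff_type> <active_id> <active_smiles> <active_pki> \
#                <partner_id> <partner_smiles> <partner_pki|NA> <delta_pki|NA>
# isd records carry a potency only for the active partner.
# ---------------------------------------------------------------------------

_NA = "NA"


@dataclass(frozen=True)
class DepositionRecord:
    """One cliff as it appears in the deposition files."""

    cliff_type: str  # "original" | "sd" | "isd"
    active_id: str
    active_smiles: str
    active_pki: float
    partner_id: str
    partner_smiles: str
    partner_pki: float | None  # None for isd records
    delta_pki: float | None  # None for isd records


@dataclass
class TargetCliffBlock:
    """Per-target cliff results of one family, as deposited."""

    target_id: str
    target_name: str
    family: str  # "MMP" | "RMMP"
    assay_ids: tuple[str, ...] = ()
    acrp_threshold: float | None = None
    records: list[DepositionRecord] = field(default_factory=list)


def _fmt(x: float | None) -> str:
    return _NA if x is None else repr(float(x))


def _parse_opt_float(token: str, lineno: int) -> float | None:
    if token == _NA:
        return None
    try:
        return float(token)
    except ValueError:
        raise DepositionFormatError(f"bad numeric field {token!r}", lineno)


def write_deposition(
    blocks_by_family: Mapping[str, Sequence[TargetCliffBlock]],
    out_paths: Mapping[str, str | Path],
) -> None:
    """Write one deposition text file per family ("MMP", "RMMP").

    Output is byte-stable for a fixed input order: floats are serialized with
    ``repr`` so the write/read round trip is exact.
    """
    for family, path in out_paths.items():
        blocks = blocks_by_family.get(family, [])
        lines: list[str] = []
        for blk in blocks:
            assays = ";".join(blk.assay_ids) if blk.assay_ids else _NA
            lines.append(
                "\t".join(
                    [
                        "#TARGET",
                        blk.target_id,
                        blk.target_name or _NA,
                        assays,
                        _fmt(blk.acrp_threshold),
                        blk.family,
                    ]
                )
            )
            for r in blk.records:
                lines.append(
                    "\t".join(
                        [
                            r.cliff_type,
                            r.active_id,
                            r.active_smiles,
                            _fmt(r.active_pki),
                            r.partner_id,
                            r.partner_smiles,
                            _fmt(r.partner_pki),
                            _fmt(r.delta_pki),
                        ]
                    )
                )
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_deposition(
    paths: Mapping[str, str | Path]
) -> dict[str, list[TargetCliffBlock]]:
    """Exact inverse of :func:`write_deposition` on files it wrote."""
    out: dict[str, list[TargetCliffBlock]] = {}
    for family, path in paths.items():
        blocks: list[TargetCliffBlock] = []
        current: TargetCliffBlock | None = None
        text = Path(path).read_text(encoding="utf-8")
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "#TARGET":
                if len(fields) != 6:
                    raise DepositionFormatError(
                        f"header needs 6 fields, got {len(fields)}", lineno
                    )
                current = TargetCliffBlock(
                    target_id=fields[1],
                    target_name="" if fields[2] == _NA else fields[2],
                    assay_ids=tuple(fields[3].split(";")) if fields[3] != _NA else (),
                    acrp_threshold=_parse_opt_float(fields[4], lineno),
                    family=fields[5],
                )
                blocks.append(current)
                continue
            if current is None:
                raise DepositionFormatError("record before any #TARGET header", lineno)
            if len(fields) != 8:
                raise DepositionFormatError(
                    f"record needs 8 fields, got {len(fields)}", lineno
                )
            active_pki = _parse_opt_float(fields[3], lineno)
            if active_pki is None:
                raise DepositionFormatError("active partner must carry a pki", lineno)
            current.records.append(
                DepositionRecord(
                    cliff_type=fields[0],
                    active_id=fields[1],
                    active_smiles=fields[2],
                    active_pki=active_pki,
                    partner_id=fields[4],
                    partner_smiles=fields[5],
                    partner_pki=_parse_opt_float(fields[6], lineno),
                    delta_pki=_parse_opt_float(fields[7], lineno),
                )
            )
        out[family] = blocks
    return out
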