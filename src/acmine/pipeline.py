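"""End-to-end orchestration of the five-stage cliff identification protocol.

Stages per family (MMP and/or RMMP):

1. qualify target sets (size + potency spread);
2. generate tsr matched pairs among actives and, for sets reaching
   ``min_pairs``, compute the set-dependent threshold and call sd cliffs
   (original constant-threshold cliffs are called alongside for comparison);
3. determine AC-relevant-potency (ACRP) compounds from the sd cliffs;
4. search tsr pairs between ACRP compounds and confirmed inactives
   (isd cliffs) for sets that have inactives;
5. report sets yielding isd cliffs, build sd and combined networks and
   compare their cluster structure.

sd cliffs are computed for all qualifying sets; the availability of
inactives gates only the isd stage.  All outputs are deterministic for a
fixed input order and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from . import chem_io
from .chem_io import (
    DepositionRecord,
    TableDialect,
    TargetCliffBlock,
    TargetSet,
)
from .cliff_calling import (
    ACRPResult,
    Cliff,
    QualificationCriterion,
    SetThreshold,
    call_isd_cliffs,
    call_original_cliffs,
    call_sd_cliffs,
    compute_set_threshold,
    determine_acrp_compounds,
    qualify_target_set,
)
from .errors import AcmineError
from .fragmentation import (
    DEFAULT_RETRO_RULES,
    MMP,
    RMMP,
    RetroRule,
    TsrParams,
    find_matched_pairs,
    load_rules,
    tsr_pairs,
)
from .network import NetworkComparison, build_network, compare_networks, export_graph

_NA = "NA"


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults reproduce the stated
    protocol constants (min 50 compounds / sigma 1.0, min 100 pairs,
    tsr 2x / diff 8 / size 13)."""

    out_dir: str | Path = "acmine_out"
    activity_path: str | Path | None = None
    inactives_path: str | Path | None = None
    family: str = "both"  # "MMP" | "RMMP" | "both"
    min_compounds: int = 50
    min_sigma: float = 1.0
    min_pairs: int = 100
    tsr: TsrParams = field(default_factory=TsrParams)
    rules_path: str | Path | None = None
    dialect: TableDialect = field(default_factory=TableDialect)
    max_spread: float = 1.0
    seed: int = 0
    export_networks: bool = True

    @property
    def families(self) -> tuple[str, ...]:
        if self.family == "both":
            return (MMP, RMMP)
        if self.family in (MMP, RMMP):
            return (self.family,)
        raise AcmineError(f"unknown family {self.family!r}")

    def retro_rules(self) -> tuple[RetroRule, ...]:
        if self.rules_path is None:
            return DEFAULT_RETRO_RULES
        return load_rules(self.rules_path)


@dataclass
class SetResult:
    """Everything computed for one target set under one family."""

    target_set: TargetSet
    family: str
    qualified: bool = False
    n_tsr_pairs: int = 0
    threshold: SetThreshold | None = None
    sd_cliffs: list[Cliff] = field(default_factory=list)
    original_cliffs: list[Cliff] = field(default_factory=list)
    acrp: ACRPResult | None = None
    isd_cliffs: list[Cliff] = field(default_factory=list)
    sd_network: nx.Graph | None = None
    combined_network: nx.Graph | None = None
    comparison: NetworkComparison | None = None

    @property
    def target_id(self) -> str:
        return self.target_set.target_id


@dataclass
class FamilySummary:
    """Filter-cascade counts mirroring the per-family result table: each row
    is non-increasing in the order listed."""

    family: str
    n_total_sets: int = 0
    n_qualifying_sets: int = 0
    n_min_pairs_sets: int = 0
    n_with_inactives_sets: int = 0
    n_with_isd_sets: int = 0
    n_acrp_compounds: int = 0
    n_inactive_compounds: int = 0
    n_sd_cliffs: int = 0
    n_isd_cliffs: int = 0
    n_original_cliffs: int = 0


@dataclass
class PipelineResult:
    config: RunConfig
    set_results: dict[str, list[SetResult]]  # family -> per-set results
    summaries: dict[str, FamilySummary]


def analyze_target_set(
    target_set: TargetSet,
    family: str,
    cfg: RunConfig,
    rules: Sequence[RetroRule],
) -> SetResult:
    """Run stages 1-5 for one set and one family."""
    res = SetResult(target_set=target_set, family=family)
    criterion = QualificationCriterion(cfg.min_compounds, cfg.min_sigma)
    res.qualified = qualify_target_set(target_set, criterion)
    if not res.qualified:
        return res

    pairs = tsr_pairs(
        find_matched_pairs(target_set.actives, family, rules), cfg.tsr
    )
    res.n_tsr_pairs = len(pairs)
    if res.n_tsr_pairs < cfg.min_pairs:
        return res

    pki = target_set.pki_map
    res.threshold = compute_set_threshold(pairs, pki, target_set.target_id, family)
    res.sd_cliffs = call_sd_cliffs(pairs, pki, res.threshold)
    res.original_cliffs = call_original_cliffs(pairs, pki, family)
    res.acrp = determine_acrp_compounds(res.sd_cliffs, target_set)
    if res.acrp is not None and target_set.inactives:
        res.isd_cliffs = call_isd_cliffs(
            res.acrp, target_set, family, rules, cfg.tsr
        )

    acrp_ids = res.acrp.acrp_compound_ids if res.acrp else frozenset()
    compounds = target_set.compounds
    res.sd_network = build_network(res.sd_cliffs, compounds, acrp_ids)
    res.combined_network = build_network(
        res.sd_cliffs + res.isd_cliffs, compounds, acrp_ids
    )
    res.comparison = compare_networks(res.sd_network, res.combined_network)
    return res


def summarize(family: str, results: Sequence[SetResult]) -> FamilySummary:
    s = FamilySummary(family=family)
    acrp_ids: set[str] = set()
    inactive_ids: set[str] = set()
    for r in results:
        s.n_total_sets += 1
        if not r.qualified:
            continue
        s.n_qualifying_sets += 1
        if r.threshold is None:
            continue
        s.n_min_pairs_sets += 1
        s.n_sd_cliffs += len(r.sd_cliffs)
        s.n_original_cliffs += len(r.original_cliffs)
        if r.acrp is not None:
            acrp_ids.update(r.acrp.acrp_compound_ids)
        if r.target_set.inactives:
            s.n_with_inactives_sets += 1
            inactive_ids.update(c.compound_id for c in r.target_set.inactives)
        if r.isd_cliffs:
            s.n_with_isd_sets += 1
            s.n_isd_cliffs += len(r.isd_cliffs)
    s.n_acrp_compounds = len(acrp_ids)
    s.n_inactive_compounds = len(inactive_ids)
    return s


def run_on_sets(
    sets: Sequence[TargetSet], cfg: RunConfig
) -> PipelineResult:
    """Run the full protocol on in-memory target sets and write all outputs."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rules = cfg.retro_rules()
    ordered = sorted(sets, key=lambda t: t.target_id)
    set_results: dict[str, list[SetResult]] = {}
    summaries: dict[str, FamilySummary] = {}
    try:
        for family in cfg.families:
            results = [analyze_target_set(ts, family, cfg, rules) for ts in ordered]
            set_results[family] = results
            summaries[family] = summarize(family, results)
        result = PipelineResult(cfg, set_results, summaries)
        _write_outputs(result, out_dir)
    except Exception as exc:
        (out_dir / "FAILED.txt").write_text(
            f"pipeline aborted: {type(exc).__name__}: {exc}\n"
        )
        raise
    return result


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Load inputs from the configured tables and run the protocol."""
    if cfg.activity_path is None:
        raise AcmineError("RunConfig.activity_path is required for run_pipeline")
    measurements, smiles, names, _ = chem_io.read_activity_table(
        cfg.activity_path, cfg.dialect
    )
    sets, _ = chem_io.aggregate_potency(
        measurements, smiles, names, max_spread=cfg.max_spread
    )
    if cfg.inactives_path is not None:
        chem_io.read_inactives(cfg.inactives_path, sets, cfg.dialect)
    return run_on_sets(list(sets.values()), cfg)


# ---------------------------------------------------------------------------
# Output writing (all delimited text; deterministic for fixed inputs)
# ---------------------------------------------------------------------------


def _fmt(x: float | None) -> str:
    return _NA if x is None else repr(float(x))


def _cliff_rows(r: SetResult) -> list[str]:
    rows = []
    compounds = r.target_set.compounds
    for cliff in r.original_cliffs + r.sd_cliffs + r.isd_cliffs:
        potent = compounds[cliff.potent_partner]
        other = compounds[cliff.other_partner]
        rows.append(
            "\t".join(
                [
                    r.target_id,
                    cliff.family,
                    cliff.cliff_type,
                    potent.compound_id,
                    potent.smiles,
                    _fmt(potent.pki),
                    other.compound_id,
                    other.smiles,
                    _fmt(other.pki),
                    _fmt(cliff.delta_pki),
                    cliff.pair.core_smiles,
                    cliff.pair.sub_a_smiles,
                    cliff.pair.sub_b_smiles,
                ]
            )
        )
    return rows


CLIFF_TABLE_HEADER = "\t".join(
    [
        "target_id", "family", "cliff_type",
        "potent_id", "potent_smiles", "potent_pki",
        "other_id", "other_smiles", "other_pki",
        "delta_pki", "core_smiles", "sub_a_smiles", "sub_b_smiles",
    ]
)


def deposition_blocks(results: Sequence[SetResult]) -> list[TargetCliffBlock]:
    """sd + isd cliffs of one family in deposition layout."""
    blocks = []
    for r in results:
        if not r.sd_cliffs and not r.isd_cliffs:
            continue
        compounds = r.target_set.compounds
        block = TargetCliffBlock(
            target_id=r.target_id,
            target_name=r.target_set.target_name,
            family=r.family,
            acrp_threshold=r.acrp.acrp_threshold if r.acrp else None,
        )
        for cliff in r.sd_cliffs + r.isd_cliffs:
            potent = compounds[cliff.potent_partner]
            other = compounds[cliff.other_partner]
            block.records.append(
                DepositionRecord(
                    cliff_type=cliff.cliff_type,
                    active_id=potent.compound_id,
                    active_smiles=potent.smiles,
                    active_pki=potent.pki,
                    partner_id=other.compound_id,
                    partner_smiles=other.smiles,
                    partner_pki=other.pki,
                    delta_pki=cliff.delta_pki,
                )
            )
        blocks.append(block)
    return blocks


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    cfg = result.config

    # per-family cliff tables
    for family, results in result.set_results.items():
        lines = [CLIFF_TABLE_HEADER]
        for r in results:
            lines.extend(_cliff_rows(r))
        (out_dir / f"cliffs_{family.lower()}.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    # deposition files (sd + isd cliffs)
    blocks = {
        family: deposition_blocks(results)
        for family, results in result.set_results.items()
    }
    paths = {
        family: out_dir / f"deposition_{family.lower()}.txt" for family in blocks
    }
    chem_io.write_deposition(blocks, paths)

    # summary table (filter cascade, Table-2-like row structure)
    lines = [
        "\t".join(
            [
                "family", "total_sets", "qualifying_sets", "min_pairs_sets",
                "with_inactives_sets", "with_isd_sets", "acrp_compounds",
                "inactive_compounds", "sd_cliffs", "isd_cliffs",
                "original_cliffs", "seed",
            ]
        )
    ]
    for family in sorted(result.summaries):
        s = result.summaries[family]
        lines.append(
            "\t".join(
                str(v)
                for v in [
                    s.family, s.n_total_sets, s.n_qualifying_sets,
                    s.n_min_pairs_sets, s.n_with_inactives_sets,
                    s.n_with_isd_sets, s.n_acrp_compounds,
                    s.n_inactive_compounds, s.n_sd_cliffs, s.n_isd_cliffs,
                    s.n_original_cliffs, cfg.seed,
                ]
            )
        )
    (out_dir / "summary.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    # per-set threshold/ACRP table
    lines = [
        "\t".join(
            [
                "target_id", "family", "qualified", "n_tsr_pairs",
                "mean_delta", "sigma_delta", "threshold", "acrp_threshold",
                "n_acrp_compounds", "n_sd_cliffs", "n_isd_cliffs",
            ]
        )
    ]
    for family in sorted(result.set_results):
        for r in result.set_results[family]:
            t = r.threshold
            lines.append(
                "\t".join(
                    [
                        r.target_id, family, str(int(r.qualified)),
                        str(r.n_tsr_pairs),
                        _fmt(t.mean_delta if t else None),
                        _fmt(t.sigma_delta if t else None),
                        _fmt(t.threshold if t else None),
                        _fmt(r.acrp.acrp_threshold if r.acrp else None),
                        str(len(r.acrp.acrp_compound_ids) if r.acrp else 0),
                        str(len(r.sd_cliffs)),
                        str(len(r.isd_cliffs)),
                    ]
                )
            )
    (out_dir / "set_stats.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    # network comparison report
    lines = [
        "\t".join(
            [
                "target_id", "family", "new_clusters", "extended_clusters",
                "merged_clusters", "unchanged_components", "new_isolated_pairs",
            ]
        )
    ]
    for family in sorted(result.set_results):
        for r in result.set_results[family]:
            if r.comparison is None or not r.isd_cliffs:
                continue
            c = r.comparison
            lines.append(
                "\t".join(
                    str(v)
                    for v in [
                        r.target_id, family, c.n_new_clusters,
                        c.n_extended_clusters, c.n_merged_clusters,
                        c.n_unchanged_components, c.n_new_isolated_pairs,
                    ]
                )
            )
    (out_dir / "network_comparison.tsv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )

    # graph exports for sets that produced cliffs
    if cfg.export_networks:
        net_dir = out_dir / "networks"
        for family in sorted(result.set_results):
            for r in result.set_results[family]:
                if r.sd_network is None or r.sd_network.number_of_nodes() == 0:
                    continue
                prefix = net_dir / f"{r.target_id}_{family.lower()}_sd"
                export_graph(r.sd_network, prefix)
                if r.isd_cliffs:
                    export_graph(
                        r.combined_network,
                        net_dir / f"{r.target_id}_{family.lower()}_combined",
                    )
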