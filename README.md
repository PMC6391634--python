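# acmine

Target set-dependent activity-cliff mining with matched molecular pairs.

`acmine` implements an end-to-end pipeline for finding second-generation
activity cliffs in compound activity classes:

1. **MMP/RMMP generation** — single-cut fragmentation of exocyclic single
   bonds (fragment-and-index), optionally restricted to retrosynthetic
   (RECAP-style) bond rules, with transformation-size restrictions
   (core ≥ 2× each exchanged substituent, substituent size difference ≤ 8
   heavy atoms, each substituent ≤ 13 heavy atoms).
2. **Set-dependent thresholds** — for each qualifying target set (enough
   actives, enough potency spread), the cliff threshold is the mean plus two
   sample standard deviations of the |ΔpK_i| distribution over *all* size-
   restricted pairs of the set; pairs at or above it are **sd cliffs**.
   Constant-threshold (ΔpK_i ≥ 2) "original" cliffs are called alongside.
3. **ACRP selection** — the median pK_i of the unique highly potent sd-cliff
   partners defines the AC-relevant potency threshold; every set active at or
   above it is an ACRP compound.
4. **Inactive-analog cliffs (isd)** — size-restricted pairs between ACRP
   compounds and confirmed-inactive analogs; these carry no ΔpK_i.
5. **Network analysis** — cliff networks (nodes = cliff compounds, edges =
   cliffs), clusters (components with > 2 nodes), and a comparison of
   sd-only vs sd+isd networks (new / extended / merged clusters).

A synthetic-data module generates analog-series target sets with controlled
potency structure, planted cliffs, and inactive analogs, so the entire
pipeline is testable without any external database.

## CLI

```bash
# generate a synthetic benchmark suite (activity / inactivity / truth tables)
acmine simulate --n-sets 10 --seed 7 --out-dir sim/

# individual stages
acmine fragment --activity sim/activity.tsv --family MMP --out pairs.tsv
acmine cliffs   --activity sim/activity.tsv --out cliffs.tsv
acmine acrp     --activity sim/activity.tsv --out acrp.tsv
acmine isd      --activity sim/activity.tsv --inactives sim/inactives.tsv --out isd.tsv
acmine network  --cliff-table cliffs.tsv --target T001 --out-prefix nets/T001

# full five-stage protocol (reads tables, or simulates its own inputs)
acmine run-all --activity sim/activity.tsv --inactives sim/inactives.tsv --out-dir out/
acmine run-all --simulate-sets 10 --seed 7 --out-dir out/
```

`run-all` writes per-family cliff tables, two deposition text files
(sd + isd cliffs with per-target headers and ACRP thresholds), per-set
statistics, a filter-cascade summary, network node/edge tables + GraphML
exports, and a cluster-comparison report. All outputs are deterministic
for a fixed seed. Defaults (≥ 50 actives, σ ≥ 1.0, ≥ 100 pairs, tsr
2×/8/13, Δ ≥ 2 for original cliffs) can be overridden on the command line
or via `--config config.yaml` whose keys mirror `pipeline.RunConfig`.

Retrosynthetic rules are configurable: see `rules/default_rules.tsv`
(`rule_id<TAB>SMARTS`, cut bond between atoms mapped `:1`/`:2`). The
shipped set is a RECAP-style stand-in and can be replaced wholesale with
`--rules`.

## Library use

```python
from acmine import synthetic_data
from acmine.pipeline import RunConfig, run_on_sets

suite = synthetic_data.generate_benchmark_suite(n_sets=10, seed=7)
result = run_on_sets([ts for ts, _, _ in suite], RunConfig(out_dir="out"))
print(result.summaries["MMP"])
```

Modules: `chem_io` (data model, table readers, potency curation, the
deposition format), `fragmentation` (single cuts, retro rules, pair
finding, tsr filter), `cliff_calling` (qualification, thresholds,
sd/original/isd cliffs, ACRP), `network` (build/cluster/compare/export),
`synthetic_data` (generator + benchmark suite), `pipeline` + `cli`
(orchestration).

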