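# trialnet

Weighted country co-participation networks from clinical-trial registry
records, with the connectivity, regional, temporal, and condition-stratified
statistics derived from them.

Each registry record carries a study id, a start date, a list of
participating countries, and a list of studied conditions. After
normalization and deduplication, every multinational study (more than one
distinct country) contributes one connection per unordered pair of its
countries; pooling all connections and collapsing multiplicities yields a
weighted edge list in which an edge's weight is the number of studies its
two countries shared. Node sizes are weighted totals of incident
connections. On top of that network the package computes totals and shares
per country and per region, the cross-region share, strongest edges,
regional participation proportions, annual multinational-study series with
growth rates and peak detection, and region-stratified top-k condition
tables.

## Layout

- `trialnet.registry_io` — TSV / registry-XML readers, country-name
  normalization (alias table), six-region assignment, deduplication,
  single-nation vs multinational classification.
- `trialnet.network_builder` — pair extraction, master list, edge
  weighting, network assembly; CSV / GEXF / GraphML exports.
- `trialnet.metrics` — connectivity totals, country and region shares,
  cross-region share, top edges, participation report.
- `trialnet.trends` — per-year series, year-over-year growth, annualized
  growth (`mean_yoy` or `cagr`), peak year.
- `trialnet.conditions` — region-stratified top-k condition tables.
- `trialnet.synthetic_data` — seeded synthetic registry generator with
  recorded ground truth and an analytic expected-edge-weight hook.
- `trialnet.cli` — `trialnet` command-line front end.

## CLI

```sh
# generate a seeded synthetic registry (TSV + ground-truth JSON + region map)
trialnet simulate --n-studies 5000 --seed 7 --out scratch/sim

# full pipeline: ingest -> network -> metrics + trends + conditions
trialnet run --input scratch/sim/registry.tsv \
             --region-map scratch/sim/region_map.yaml \
             --out scratch/analysis

# individual stages
trialnet ingest --input registry.tsv --out out/
trialnet build-network --input registry.tsv --out out/
trialnet metrics --input registry.tsv --policy endpoint_half --out out/
trialnet trends --input registry.tsv --growth-window 1990 2009 --out out/
trialnet conditions --input registry.tsv --top-k 5 --out out/
```

Inputs are TSV (columns `study_id`, `start_date`, `countries`,
`conditions`; multi-values pipe-separated) or registry XML
(`--format ctgov_xml`). Region maps and alias tables are YAML key-value
files; shipped defaults live in `src/trialnet/data/` and are overridable
with `--region-map` / `--aliases`. `--strict` makes malformed records and
unmapped countries fatal; the default lenient mode logs and continues.
All writers are sorted and timestamp-free, so reruns on identical inputs
are byte-identical.

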