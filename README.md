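# mzgroupnet

Mass-difference transformation networks and pathway inference for
time-series LC-MS metabolomics.

Given per-time-point tables of high-mass-accuracy m/z features — each with a
ranked list of candidate sum formulas — `mzgroupnet`:

1. detects pairwise chemical/biochemical transformations by comparing exact
   integer elemental differences between candidate formulas against an
   editable rules file (56 default transformations, e.g. methylation
   `+1C+2H`, hexosylation `+6C+10H+5O`);
2. assembles the matches into a directed network whose edges respect the
   chronological order of first appearance (a feature first seen on day 2
   cannot be the precursor of one first seen on day 1);
3. extracts non-redundant pathways (maximal simple paths; any path contained
   contiguously in a longer one is dropped);
4. ranks how often each rule fired, and mines recurrent composition
   differences **not** in the rules file as suggestions for novel
   modifications;
5. projects chosen formulas onto van Krevelen (O/C vs H/C) coordinates and
   finds CH2/O "rhombus" motifs.

Because matching is by exact composition arithmetic rather than mass
tolerance, a shared transformation can pick the correct sum formula out of
an ambiguous candidate list even when it is not the top ppm hit.

## Command line

```bash
# generate the synthetic time-series fixture (7-member planted chain + decoys)
mzgroupnet synth --out fixture/ --seed 1

# run the full pipeline
mzgroupnet run \
    --inputs fixture/t0_day00.csv --inputs fixture/t1_day02.csv \
    --inputs fixture/t2_day04.csv --inputs fixture/t3_day08.csv \
    --inputs fixture/t4_day14.csv --inputs fixture/t5_day20.csv \
    --out results/ --ppm 1.0 --max-candidates 10 --bounds C100,H200,O50,N10

# validate a user-edited rules file / list the default rules
mzgroupnet rules --validate my_rules.csv
mzgroupnet rules
```

Input tables are CSV/TSV with columns `id` (optional), `mz`, optional
`rt`/`intensity`, then `formula_1,ppm_1,formula_2,ppm_2,…`; one file per
time point, given in chronological order. Features are merged across time
points by m/z proximity (`--merge-ppm`, default 2 ppm). Features lacking
candidate columns get formulas generated exhaustively within `--ppm` of the
observed m/z under the `--bounds` element limits.

A run writes into `--out`:

| file | content |
| --- | --- |
| `transformations.csv` | all rule-matched edges with formulas, m/z, times |
| `rule_frequency.csv`  | edges per rule, most frequent first |
| `unlisted_differences.csv` | recurrent deltas absent from the rules file |
| `mzstructure.json`    | bundle of features, rules, edges, pathways, counts |
| `network.net`         | Pajek file for network visualization |
| `pathways.csv`        | non-redundant pathways (nodes, rules, m/z sequence) |
| `vankrevelen.csv`     | O/C and H/C coordinates per feature |

## Rules file format

CSV with header `name,delta,note`. Deltas use signed element tokens
(`+1C+2H`, `-2H+1O`) or plain formulas (`C1H2`). Names must be unique and
deltas nonzero; rules are directed (list a reverse reaction explicitly).

## Library example

```python
from mzgroupnet import (FixtureSpec, generate_fixture, default_rules,
                        detect_transformations, build_network, enumerate_pathways)

features, tables = generate_fixture(FixtureSpec(seed=1))
edges = detect_transformations(features, default_rules())
paths = enumerate_pathways(build_network(edges, features))
print(paths[0].nodes)   # ('M287', 'M449', 'M595', 'M727', 'M889', 'M975', 'M1121')
print(paths[0].rules)   # ('hexosylation', 'coumaroylation', 'pentosylation',
                        #  'hexosylation', 'malonylation', 'coumaroylation')
```
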