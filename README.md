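# haplogeo

Haplotype phylogeography from aligned chloroplast-DNA matrices: a tested,
reusable re-implementation of a classic cpDNA pipeline — from an aligned
multi-FASTA and per-population haplotype counts to

* **haplotyping** — binary indel coding, haplotype collapsing, polymorphic-site
  accounting and inter-haplotype step distances;
* **diversity / differentiation** — unordered (`h_S`, `h_T`, `G_ST`) and
  ordered (`v_S`, `v_T`, `N_ST`) estimators with equal population weights and
  the permutation test for phylogeographic structure (`N_ST > G_ST`);
* **AMOVA** — three-level analysis of molecular variance with Φ-statistics,
  the three standard permutation schemes, and pairwise population `F_ST`
  (distance-kernel Φ_ST or identity-kernel);
* **statistical-parsimony network** — probability-of-parsimony connection
  limit, minimum-spanning construction retaining tied alternatives (loops),
  frequency → interiority → geography loop resolution, and the deep-split
  lineage bipartition;
* **isolation by distance** — great-circle distance matrices, simple Mantel
  tests, Nei's standard genetic distance, and gene-flow/drift regime
  classification from distance scatterplots;
* **molecular-clock dating** — net between-lineage divergence
  `d_A = d_XY − (d_X + d_Y)/2` and `T = d_A / 2μ`;
* **synthetic data** — a two-lineage simulator (star-like northern lineage,
  isolation-by-distance southern lineage) with exact planted truth.

Two packaged fixtures (`table1`: 47 populations × 16 haplotype counts with
coordinates and morphotype columns; `table2`: 16 haplotypes × 23 coded
characters) make the whole analysis runnable offline.

## Command-line use

```sh
# Full analysis on the packaged fixtures (defaults reproduce the reference
# settings: 1000 / 1023 / 999 permutations, mu = 1.01e-9, alpha = 0.05):
haplogeo run --output-dir out/

# From a TOML config:
haplogeo run --config cfg.toml

# Useful overrides:
haplogeo run --fixed-limit 15 --no-loop-resolution --fst-kernel identity --mu 2e-9

# Simulate a two-lineage dataset and write pipeline-ready inputs
# (populations.csv, coded_matrix.csv, individuals.fasta, truth.json):
haplogeo simulate --seed 1 --split-steps 11 --out sim/

# Export a packaged fixture:
haplogeo fixtures --name table1 --out table1.csv
```

`run` writes `report.json` (deterministic for a given config + seed),
`diversity.csv`, `amova.csv`, `fst_km.tsv` (scatterplot data), and the
haplotype network as GML + edge-list TSV.

Config keys (TOML) mirror `haplogeo.cli_pipeline.PipelineConfig`:
`population_table`, `coded_matrix` (paths or `fixture:table1` /
`fixture:table2`), `n_perm_diversity`, `n_perm_amova`, `n_perm_mantel`,
`seed`, `mu`, `alpha`, `fixed_limit`, `fst_kernel`, `loop_resolution`,
`groupings`, `output_dir`.

## Python API

```python
import haplogeo as hg

table = hg.load_fixture("table1")          # PopulationTable
matrix = hg.load_fixture("table2")         # CodedMatrix
steps = hg.pairwise_step_distances(matrix)

res = hg.diversity_analysis(table, steps)  # h_S, h_T, G_ST, N_ST, p-value
net = hg.resolve_loops(hg.build_network(matrix, populations=table), table)
lineages = hg.lineage_bipartition(net)
```

## Layout

```
src/haplogeo/
  io_model.py            domain types, readers/writers, DMS parsing, fixtures
  haplotyping.py         indel coding, collapsing, step distances
  popgen_diversity.py    h_S/h_T/G_ST, v_S/v_T/N_ST, permutation test
  amova.py               nested AMOVA, pairwise F_ST
  parsimony_network.py   connection limit, network, loop resolution, lineages
  ibd_geo.py             km matrices, Mantel, Nei distance, regime calls
  divergence_dating.py   d_A and clock dating
  synthetic_data.py      two-lineage simulator with planted truth
  cli_pipeline.py        orchestration + `haplogeo` CLI
tests/                   pytest suite (unit, property, acceptance)
scripts/acceptance.py    acceptance report generator
```
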