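# coproscope

Multiproxy analysis of herbivore coprolites: pollen-assemblage summaries and
clustering, an environmental-prevalence-index (EPI) diet signal, short-amplicon
ancient-DNA assignment, radiocarbon calibration with 95.4% highest-density
ranges, and deposition-event / minimum-number-of-individuals (MNI) inference.
A synthetic-data generator with full ground truth makes every stage testable
without any external download.

## Modules

| module | what it does |
| --- | --- |
| `coproscope.tables` | `PollenMatrix` / `TaxonRegistry` data model, TSV I/O, percent-of-pollen-sum, occurrence percentages (half-up, 1 dp), spike-based concentrations, loss-on-ignition, proxy Venn cells, habitat tallies |
| `coproscope.epi` | EPI factor products (mode 1/3 × production 1–3 × dispersal 1–3), tie-averaged abundance ranks, cumulative-frequency null ranks, over/neutral/under calls |
| `coproscope.clustering` | uncentered-Pearson distances, deterministic average-linkage agglomeration, threshold cut into "highly similar" groups, Newick export |
| `coproscope.adna` | 31 bp control-region species/haplotype calls (diagnostic site 25, C↔T damage flag), semi-global rbcL clone assignment with a >96% identity threshold and internal-stop-codon screening, clone deduplication |
| `coproscope.radiocarbon` | `.14c` curve parsing, Gaussian calibration on a 1-yr grid, 95.4% HPD ranges, range-overlap tests |
| `coproscope.events` | three-evidence joining (assemblage group ∧ haplotype ∧ age overlap) into deposition events, haplotype+age linking into probable individuals, MNI |
| `coproscope.simulate` | seeded generator: Dirichlet diets per individual, EPI-weighted pollen rain, multinomial counts, clone libraries with dropout and C→T damage, noisy radiocarbon ages, `SimTruth` ground truth |
| `coproscope.fixtures` | packaged occurrence / dated-sample tables used by the acceptance tests |
| `coproscope.cli` / `coproscope.pipeline` | `coproscope` command with subcommands and end-to-end orchestration |

## CLI

```sh
coproscope simulate --seed 1 --out-dir demo
coproscope summarize --counts demo/pollen_counts.tsv
coproscope epi --registry demo/taxon_registry.tsv --percents pct.tsv
coproscope cluster --percents pct.tsv --out-tree tree.nwk --out-groups groups.tsv
coproscope assign --clones demo/rbcl_clones.fasta --refs demo/rbcl_refs.fasta \
    --sidecar demo/rbcl_refs.tsv
coproscope calibrate --curve shcal04.14c --cra 694 --sigma 30
coproscope report --in-dir demo --out-dir results --curve shcal04.14c
```

`report` runs the full pipeline (percentages → EPI → clustering → assignment →
calibration → events) and writes TSV outputs plus `report.yaml` / `report.txt`
with the event grouping and MNI. Re-running with the same inputs produces
byte-identical outputs.

## File formats

- **Pollen counts TSV** — first line `# spike_total=N`; then a header row with
  `coprolite`, one column per taxon, plus `spike_observed` and
  `sample_mass_g`. Counts are raw integers.
- **Taxon registry TSV** — columns `taxon`, `family`, `growth_form`,
  `detected_by` (comma-joined subset of `DNA,pollen,macrofossil`),
  `macrofossil_kind`, `habitats` (comma-joined), `epi_mode`,
  `epi_production`, `epi_dispersal`, `epi_include`, `in_pollen_sum`.
- **Calibration curve** — standard `.14c` layout: cal BP, 14C age BP, 1σ error
  (comma- or whitespace-delimited, `#` comments). No curve ships with the
  package; supply SHCal04 (or any curve) yourself and point to it with
  `--curve` or the `COPROSCOPE_CURVE` environment variable.
- **Ages TSV** — `coprolite`, `cra`, `error`.
- Reference sets are FASTA with an optional sidecar TSV (`id`, `taxon`,
  `frame_offset`).

## Conventions

- Percentages are reported half-up at one decimal place.
- The pollen sum includes terrestrial pollen and fern/lycophyte spores; the
  exotic *Lycopodium* spike and coprophilous *Sporormiella* spores are
  excluded from the denominator.
- The EPI null line is operationalised as the tie-averaged expected rank of
  taxa ordered by descending EPI; taxa whose observed abundance rank beats it
  are called over-represented (candidate dietary items).
- Clustering defaults: uncentered Pearson, average linkage, "highly similar"
  cut at distance 0.1 (correlation ≥ 0.9); all overridable.
- HPD interval endpoints are integer cal BP, accumulated by descending
  density to ≥ 95.4% mass.
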