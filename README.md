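# commkit

Desk-scale pathway/genome databases and community metabolic analysis for
microbiomes.

Given a set of annotated metagenome-assembled genomes (MAGs) — one GenBank
or GFF3+FASTA file per organism, with product names and optional EC
numbers — and a reference database of compounds, reactions (with
pre-computed atom mappings), and pathways, commkit builds a lightweight
pathway/genome database per organism and analyses the community:

* **Import** — parse annotations, predict each organism's reactome from
  EC numbers and enzyme names, infer transport reactions from transporter
  names, and predict operons from strand and intergenic distance.
* **Pathway prediction** — score each reference pathway by its completion
  ratio (fraction of reactions with enzyme evidence), gated by key
  reactions and taxonomic range; a completion-ratio-only baseline mode is
  included for comparison, and pathway holes are reported.
* **Comparative analysis** — multi-organism searches and tables: summary
  statistics, shared/unique reactions, pathways and compounds, EC and
  pathway-ontology breakdowns with drill-downs, transporter substrate
  tables, genes-per-transcription-unit distributions.
* **Omics overlay** — map per-organism gene values onto reactions and
  render the community as a grid of metabolic panels, reactions colored
  orange/red for up-regulation and blue/purple for down-regulation.
* **Route search** — exact minimal-cost linear routes from a start to a
  goal metabolite across the union of the community's reaction networks,
  scoring length, heavy-atom conservation through composed atom mappings,
  and organism switches:

  `cost = w_len·n_steps + w_atom·(heavy_atoms(start) − conserved) + w_switch·n_switches`

  A switch is charged wherever no single organism spans consecutive
  reactions (minimal segmentation of the per-reaction organism sets).

A synthetic generator produces self-consistent fixtures — reference DB
with valid atom mappings, communities with known pathway/operon truth in
both annotation formats, omics tables with known perturbations — so the
whole pipeline runs and is tested without any downloads.

Audience: microbiome researchers who want transparent, scriptable
reconstructions of community members and their joint metabolic
capabilities, at the scale of tens of organisms.

## Worked example

```sh
commkit synth --seed 17 --out fixtures
# synth: 40 reactions, 11 pathways, 8 organisms -> fixtures

commkit import --refdb fixtures/refdb.json --input fixtures/mags --out community
# INFO commkit: imported org01: 34 genes, 30 reactions, 3 transport records, 14 TUs
# ...
# imported 8 organisms -> community

commkit predict-pathways --refdb fixtures/refdb.json --community community --out pred
# INFO commkit: org01: 7 pathways present (of 9 scored)
```

`pred/org01.pathways.tsv` then begins:

```
pathway_id  name                                 score   present  missing_keys  holes
DECOY001    decoy pathway 1                      0.8333  no       RXN0034       RXN0034
PWY001      pathway 1 (amino acid biosynthesis)  1.0000  yes
```

The decoy scores a completion ratio of 0.83 — above any reasonable
threshold — but stays absent because its key reaction RXN0034 has no
enzyme evidence; with `--baseline` (completion ratio only) it would be
called present. That is the false-positive mode the gates exist to
suppress.

```sh
commkit route --refdb fixtures/refdb.json --community pred/community \
        --start C0001 --goal C0005 --out routes.json
# route 1: 4 steps, 4 atoms conserved, 0 switches, cost 8.00
```

Four reactions transform metabolite C0001 into C0005; 4 of C0001's 8
heavy atoms survive the composed atom mappings, so the cost is 4·1.0 for
length + 4·1.0 for the four lost atoms, and one organism carries the
whole route, so no switch cost is incurred.

```sh
commkit compare --refdb fixtures/refdb.json --community pred/community --out report
commkit overlay --refdb fixtures/refdb.json --community pred/community \
        --omics fixtures/omics --out overview.svg
```

`report/` holds the comparison tables as TSV; `overview.svg` is the
community map (one panel per organism) and `overview.svg.tsv` the
per-reaction display values and color classes behind it.

See `docs/methods.md` for the models and their assumptions and
`docs/refdb_schema.md` for the reference-database format.

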