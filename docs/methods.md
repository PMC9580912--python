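# Methods

commkit reconstructs the metabolism of a microbial community from annotated
metagenome-assembled genomes (MAGs) at desk scale: per-organism
pathway/genome databases, comparative tables, an omics-colored community
map, and minimal-cost metabolic route search across the union of the
members' reaction networks. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic test substrate
does and does not show.

## Import pipeline

Each MAG must arrive already annotated (gene coordinates, product names,
optional EC numbers) as GenBank or GFF3+FASTA; ORF calling and function
prediction are upstream of this toolkit. Import runs four inferences per
organism:

1. **Parsing.** One `Gene` per CDS feature; coordinates are 1-based
   inclusive throughout (the native convention of both formats), strand
   from `complement()` in GenBank or column 7 in GFF3. The GFF3 attribute
   reader treats `=`-less tokens as continuation values of the preceding
   key, so `ec_number=1.1.1.1;2.7.1.40` parses as two EC numbers; standard
   comma-separated multi-values are also accepted. A CDS without a product
   is retained with an empty name and logged.
2. **Reactome prediction.** Each gene contributes the union of reactions
   matched by its EC numbers (exact and prefix lookup against the
   reference EC index) and by its normalized product name (lowercase,
   punctuation stripped, whitespace collapsed). EC and name evidence are
   never arbitrated: both are recorded, and names matching several
   reactions contribute all of them, with the multi-mapping noted in the
   build report. Prediction is monotone — adding a gene can only add
   reactions.
3. **Transport inference.** Product names are matched against an editable
   pattern table (`<substrate> uptake/efflux (system|protein)`,
   `<substrate> (ABC )transporter`, `<substrate> permease`; first match
   wins). Permeases are treated as uptake, bare transporters as direction
   unknown. The captured substrate resolves against compound names;
   unresolved substrates are kept, flagged, and logged rather than
   dropped.
4. **Operon prediction.** Genes are coordinate-sorted per replicon;
   consecutive genes join one transcription unit when they share a strand
   and the intergenic gap (`next.start − prev.end − 1`) is ≤ `max_gap`
   (default 50 bp). Singletons are single-gene units. The distance/strand
   heuristic is the transparent baseline for prokaryotic operon structure;
   `max_gap` is a configuration knob. The result is independent of input
   gene order.

The build is fully deterministic: collections iterate in sorted id order
and nothing draws random numbers.

## Pathway prediction

The score of a pathway for an organism is its **completion ratio** — the
fraction of the pathway's reactions with enzyme evidence in the organism's
reactome. A pathway is called present when

* score ≥ threshold (default 0.5), and
* every **key reaction** (reactions diagnostic for the pathway) has
  enzyme evidence, and
* the organism's taxon lineage intersects the pathway's **taxonomic
  range** (an empty range is unrestricted).

`baseline_mode` disables both gates and tests the completion ratio alone,
reproducing module-completion-ratio predictors. On collections where
pathways share reactions this over-predicts by construction — a decoy
pathway borrowing most of its reactions from a genuinely present pathway
clears any completion threshold below the borrowed fraction — which is
exactly the failure mode the gates suppress. Gated predictions are always
a subset of baseline predictions at equal threshold.

Reactions of predicted-present pathways that lack enzyme evidence are
merged into the organism as *pathway-imported*, a separate evidence class,
so comparative statistics can distinguish observed from inferred
reactions. These evidence-free reactions inside present pathways are the
pathway **holes** reported per organism.

Superpathways are scored on their flat reaction set like any other
pathway; they inherit no evidence from contained base pathways (the
alternative — inheriting component evidence — would make a superpathway
present whenever its parts are, which is a display convention, not an
inference). The 0.5 default threshold is this package's choice; it sits
halfway between "any evidence" and "complete" and is exposed as a
parameter.

## Comparative operations

All comparisons are set algebra over per-member sets (reactomes including
pathway-imported reactions, present pathways, participating compounds,
transport records, transcription units), rendered as tables with members
in community order and rows sorted by label, so output is diffable.
Specifics worth recording:

* A compound "belongs to" an organism when it participates in any reaction
  of its reactome — membership is defined through the reactome, not
  through pathway membership.
* The pathway-class rollup counts each present pathway once per *ancestor*
  class on its ontology path, so parent rows are supersets of child rows;
  drill-down on a class lists every reference pathway under it with an
  explicit empty cell for members lacking it (absence is a result).
* EC breakdown uses top-level categories 1–7 (translocases included);
  reactions without a classifiable EC are binned `unclassified`. A
  reaction with ECs in several categories counts once per category.
* Reversible reactions count their participants once as reactant and once
  as product in the role-frequency table.
* Protein molecular weight, when searched, is approximated as
  (codons − 1) × 110 Da since MAG inputs carry no protein sequences; the
  approximation is good to a few percent for typical proteins and is
  documented at the query surface.

## Route search

A route is a simple (no compound revisited) sequence of oriented reactions
from a start to a goal compound, linked through non-blocked compounds.
The searched network is the union of all members' reactions; each reaction
carries the exact set of members containing it. Blocked compounds default
to the reference currency list — linking through water or ATP would
produce biologically meaningless shortcuts.

**Cost.** `cost = w_len·steps + w_atom·(heavy(start) − conserved) +
w_switch·switches`, defaults 1.0 / 1.0 / 2.0. The three terms cover route
length, atom economy and organism switching; all weights are exposed. The
2.0 switch default makes one inter-organism transfer as expensive as two
extra reactions, a deliberate mild penalty.

**Atom conservation** is tracked as explicit atom-index sets composed
through each reaction's pre-computed atom mapping (restricted to the
linking compounds; when a compound fills several slot instances the first
instance on each side is used). Sets only shrink, so conservation is exact
even when alternative routes keep different atom subsets. Hydrogens are
never tracked.

**Switches.** A segment is a maximal run of consecutive reactions whose
organism sets share at least one member; switches = segments − 1. The
greedy rule (extend while the running intersection is nonempty) achieves
the minimum number of segments — any segmentation must cut wherever the
greedy one does. Note the literal pairwise rule ("adjacent sets disjoint")
*undercounts*: three sets may pairwise overlap yet share no common
organism ({X,Y},{Y,Z},{Z,X} needs one switch). Both counts are reported;
the cost uses the minimal segmentation.

**Search.** Best-first expansion on the accumulated bound
`w_len·steps + w_atom·lost-so-far + w_switch·switches-so-far`. Every term
is non-decreasing under extension (steps and committed switches grow, atom
sets shrink), so the first k goal states popped are exactly the k
minimal-cost routes; ties break on the lexicographic reaction-id sequence
for deterministic output. Reversible reactions contribute both
orientations, but one route may not use both orientations of the same
reaction (prevents trivial shuttling). `enumerate_all_routes` is the
guarded exhaustive oracle (refuses past 10⁶ partial paths) used to verify
exactness on random networks.

## Omics overlay

Per-organism tab-delimited files (identifier, value; extra columns
ignored; header auto-detected) attach gene values to reactions through
enzyme-evidence links, keeping every value per reaction. One display value
per reaction is chosen by an aggregation rule — default `max-magnitude`
(the most extreme response wins the paint), with `mean` and `median`
available; the rule is recorded in the SVG metadata because discordant
genes on one reaction have no canonical color.

Display values are binned on the log2-ratio scale at −2 / −0.5 / 0.5 / 2
into purple / blue / neutral / orange / red (down-regulation cold,
up-regulation warm). Ratio data are log2-transformed; absolute data are
rank-transformed within the organism onto [−3, 3] so within-organism
extremes reach the extreme bins — absolute intensities have no natural
zero, so quantiles are the honest default. Thresholds are configurable.

The rendering is a static SVG: one panel per member in a near-square grid;
within a panel, pathway glyph columns ordered biosynthesis → energy →
degradation by ontology branch, a grid of pathway-unassigned reactions on
the right, transport records on the membrane border (single border by
default, double via a flag), tooltips as SVG `<title>` elements. Every
reactome reaction appears exactly once per panel; a reaction in several
pathways is drawn under the first by sorted pathway id, with full
membership still queryable. Interactivity (zoom, mouse-over) is out of
scope; the analytical content — mapping, aggregation, binning, layout
partition — is what the TSV companion file exposes for testing.

## Synthetic test substrate

The generator builds, from one integer seed: a reference database whose
atom mappings are constructed by partitioning reactant atoms among
products (valid by construction, never post-hoc matched); pathways as
reaction chains of length 3–5 with 1–2 key reactions and occasional
taxonomic restriction to one of two phyla; decoy pathways that borrow a
donor pathway's reactions plus one never-evidenced key reaction; one
superpathway per pair of designated base pathways; a community of 8
organisms (a realistic model-community size) receiving each eligible
pathway with probability 0.6; gene runs laid out with 20 bp intra-operon
and 400 bp inter-unit gaps; and omics tables in which ~30% of each
organism's pathways are perturbed by ±2 log2 units over Gaussian noise
(sd 0.3). Annotation noise (probability that a gene loses its EC and name)
defaults to 0 so recovery is exact; it is a parameter of the generator,
not of any test after the fact.

Fixed seed ⇒ byte-identical files. Truth labels live in a separate JSON,
never in the annotation files.

What passing on this substrate shows — and does not. The generator
emulates the *structure* of annotated MAGs (formats, coordinates, EC/name
annotations, operon-like spacing, pathway/decoy logic), so the tests
demonstrate that every inference is implemented exactly as specified and
that the route search is exact for its cost function. It does not emulate
annotation error modes of real pipelines (wrong ECs rather than missing
ones), sequencing incompleteness of real MAGs, promiscuous enzymes, or
realistic network topology; quantitative results on real communities
depend on annotation quality and reference-database coverage in ways no
synthetic fixture can certify.

## Problem sizes and verification

The verification suite runs the complete pipeline on the 8-organism
synthetic community, checks the route search against exhaustive
enumeration on 20 random networks of 28 reactions over 3 organisms, and
checks the switch count against a dynamic-programming minimum on all
137,256 organism-set sequences of length ≤ 6 over 3 organisms. These sizes
make every check exact and exhaustive where exhaustiveness is the point;
`scripts/acceptance.py` recomputes the same quantities from scratch.

## Known limitations

* Pathway scoring is the gated completion ratio; no probabilistic
  calibration, no enzyme-level weighting.
* Pathway holes are reported, never filled.
* Transport inference is name-pattern-based; transporters with
  uninformative names are invisible.
* Route search models inter-organism transfer as free apart from the
  switch cost — no transporter requirement on segment boundaries, no
  thermodynamics, linear routes only.
* Operon prediction is the distance/strand heuristic; no promoter or
  terminator signals.
* Flux-balance analysis, taxonomic binning of reads, and regulatory
  network content beyond transcription-unit sizes are out of scope.
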