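# Methods

This note documents the models and procedures implemented by `c4recon`,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## The gene-centric reconstruction

The core data structure is the gene-enzyme-reaction association table: one
row links one gene to one reaction in one compartment (and optionally one
leaf cell type). This "gene-centric" organization, standard for C4
genome-scale frameworks, makes homology transfer trivial — annotations
move with genes — at the cost of redundancy: a reaction catalyzed by *k*
isozymes appears *k* times.

**Collapsing.** Entries sharing the key *(reaction_id, compartment,
cell_type)* collapse to one reaction. The GPR becomes the OR over the
entries' genes; entries sharing a nonempty `complex_group` label form one
AND conjunction (enzyme complex). The collapse rule itself never invents
conjunctions — complexes must be declared in the input. Stoichiometry and
reversibility must agree within a group; a disagreement is a hard
`ConflictError` naming both rows rather than a silent first-wins, because
silent resolution makes the collapse untestable.

**Localization.** Compartments are a fixed six-value vocabulary (cytosol,
plastid, mitochondrion, peroxisome, vacuole, extracellular); *glyoxysome*
is accepted as an input alias for peroxisome since both names are used for
the same isoform locations in the literature. Cell types (mesophyll,
bundle sheath) are optional: the default is a single `generic` pool,
because tissue-level omics measure the total pool of both cell types;
two-cell models are expressed the same way with cell-typed entries.
Transporter entries override compartment/cell per stoichiometric term
(`mal@plastid`, `pep@cytosol/mesophyll`), and every transporter must move
a metabolite between two distinct locations — a validated invariant.

**The stoichiometric matrix.** S has one row per metabolite key
participating in at least one reaction and one column per collapsed
reaction, both orderings lexicographic, zeros never stored. Every
non-transporter column carries at least one negative and one positive
coefficient (mass flows somewhere); transporter columns are exempt when
the same species id appears on both sides. No flux-balance machinery is
attached: there is no objective, no bounds semantics beyond
reversibility, and no mass/charge balancing — the reconstruction is an
annotation and mapping platform, not a model ready for FBA.

**Six-field summary.** `reconstruction_stats` reports association-entry
count and unique-gene count from the *uncollapsed* table, the number of
distinct localized metabolites, and reaction counts per transporter class
(extracellular, plasmodesmata, interorganelle) from the collapsed network.

## Homology lift

Target genomes are mapped onto the reference through a standard 12-column
alignment hit table. Per query, rows pass when e-value ≤ `max_evalue`
(default 1e-10), identity ≥ `min_identity` (30%), and query coverage ≥
`min_coverage` (50%); among passing rows the lowest e-value wins, ties
broken by bitscore then lexicographic subject id, so the map is a function
of the row multiset and never of file order. The defaults are conventional
for plant ortholog transfer; no specific aligner parameters are assumed,
and all thresholds are recorded in the output provenance.

Coverage needs a query length that the 12-column format does not carry:
lengths can be supplied explicitly, otherwise the per-query maximum `qend`
stands in (exact whenever coordinates span the full query, as the
synthetic tables guarantee).

Mapping is one-way best hit (target → reference) because annotation
transfer needs exactly one reference per target; a reciprocal-best-hit
mode is available for stricter orthology. Entries whose reference gene
attracted no hit are dropped *and counted* — the shrinkage of a lifted
model relative to its reference (fewer genes in a smaller genome) is a
first-class, explainable output rather than a silent loss.

`normalize_gene_id` strips transcript-model suffixes (a trailing `m`
after the numeric locus body, and `.N` version tags) so transcript-level
and gene-level tables join on the same locus id. It is idempotent.

## Differential contrasts

All contrasts are mature vs immature tissue, mature in the numerator.

* **Transcripts** (FPKM, non-negative): log2FC =
  log2((mean_mature + c) / (mean_immature + c)) with pseudocount c = 1
  FPKM to avoid log(0) for silent genes; the two-group test runs on
  log2(FPKM + 1), respecting the roughly multiplicative noise of
  abundance data. A DE-caller export with precomputed
  `log2fc`/`p_value`/`q_value` columns is accepted as-is and flagged
  `external_stats`; when only p is present, BH is recomputed in-repo.
* **Proteins** (log2 isobaric-channel ratios): already on log scale, so
  the fold change is a difference of group means and no pseudocount
  applies. Default test is the moderated contrast (below), matching how
  low-replicate proteome panels are conventionally analyzed.
* **Metabolites** (concentrations): fold change is reported on the
  *linear* scale (concentration ratio), as metabolite panels
  conventionally display it; the test runs on log2 concentrations.

**Tests.** The default is Welch's unequal-variance t-test. The
`moderated` mode implements a deliberately simple empirical-Bayes
variance shrinkage: the per-feature pooled variance is shrunk toward a
prior (the mean of all per-feature pooled variances, plugged in for the
prior) with `prior_df` = 4 prior degrees of freedom, and the t statistic
is referred to a t distribution with residual + prior df. This captures
the essential behavior of moderated linear-model contrasts — stabilized
variances and extra df at low replication — without reimplementing a full
linear-model pipeline. Degenerate inputs follow fixed conventions: zero
variance with equal means gives p = 1; zero variance with unequal means
gives p = 0 (infinite separation).

**Multiple testing.** Benjamini–Hochberg step-up within one omics layer
(never pooled across layers, matching per-platform analysis); the
implementation delegates to `statsmodels.multipletests(method="fdr_bh")`
and is verified against a brute-force step-up oracle in the test suite.

## The overlay and its color rule

A reaction inherits the transcript records of its GPR genes and the
protein records of those genes' products. A contributor is *significant*
when adjusted p < α (default 0.05) **and** |log2FC| > the display
threshold (default 0.5); the display flag is set when any contributor in
either layer exceeds the fold-change threshold. Colors:

* no significant contributor → **gray**;
* all significant contributors positive → **green** (up in mature);
* all negative → **red**;
* both signs present → **yellow** (isoforms regulated oppositely).

Transcript and protein evidence are pooled into one contributor set: a
reaction is green if the union of its significant contributors is
all-positive, since a pathway display shows a step whenever either layer
moved. Measured metabolites are colored green/red by linear fold change
above/below 1 with q < α — significance is required even though pathway
displays do not always state how metabolite significance was assessed;
requiring it is the conservative choice. Both thresholds are CLI-exposed.

The rule has clean symmetries used as tests: invariance under contributor
relabeling, green↔red exchange under a global sign flip, and monotone
escape from gray as α relaxes.

**Coverage statistics.** Percentages are integers computed by
round-half-up in exact integer arithmetic: pct = ⌊(200·num + den) /
(2·den)⌋. Denominators are documented and fixed: the genome's
protein-coding gene count for "expressed"; expressed genes for
"differentially expressed" and for both "mapped" statistics; identified
proteins and measured metabolites for their own layers. A gene counts as
expressed when any FPKM replicate is positive (externally computed records
without replicate values count unconditionally). Zero denominators report
an absent percentage, never NaN.

**Pathway panels** are data, not code: a YAML file lists numbered enzyme
steps per panel (the generator ships NADP-ME and NAD-ME C4-subtype panels
matching its backbone reactions). Every referenced reaction is validated
against the reconstruction, and the report emits ordered step rows plus
per-panel color counts.

**Transcript–protein correlation** is Pearson r and Spearman ρ over
gene-matched (transcript log2FC, protein log2FC) pairs, requiring ≥ 3
pairs.

## The synthetic-data generator

The generator starts at the abundance/hit-table level — no reads, no
spectra — and plants a complete answer sheet.

* **Core models**: a canonical C4 carbon-shuttle backbone (PEPC, NADP-MDH,
  NADP-ME, PPDK, Rubisco, NAD-MDH, NAD-ME, aminotransferases) plus generic
  linear chains, with configurable transporter-class counts and an isozyme
  rate adding redundant entries. The ledger records the six summary
  statistics by independent bookkeeping at generation time.
* **Hit tables**: each target gene derives from one reference gene with
  simulated identity 100·(1 − mutation_rate) plus per-target Gaussian
  noise (sd 3 identity points). The noise is drawn from the seed *before*
  the mutation rate applies (common random numbers) and the e-value is a
  deterministic monotone function of identity, so recall vs divergence is
  exactly monotone within a seed family. Decoy rows are spurious
  cross-hits with 15–28% identity and e-values above 1e-8, which exercise
  the filters without polluting the best-hit map.
* **Omics tables**: FPKM and concentration replicates are log-normal
  around planted means (log2-scale sd σ = 0.25 by default, a realistic
  replicate variability for pooled tissue samples); isobaric log-ratios
  get additive Gaussian noise (sd 0.2). DE features (default fraction
  0.3) receive log2 effects drawn from ±Uniform(0.75, 3) — strictly above
  the 0.5 display threshold by a 0.25 margin so planted truth colors are
  unambiguous; boundary behavior is tested separately with hand-built
  contributors. Transcriptome uses 3, proteome 4 replicates per condition,
  mirroring the respective platforms. Proteins exist for a subset of
  network genes and agree in sign with their transcript with probability
  `concordance`; a discordant DE protein flips sign, which is what plants
  yellow reactions. The metabolite panel defaults to every network
  metabolite with a planted DE fraction of 0.67 in the presets.
* **Presets**: `small` (20 reactions, 14 reference genes, 90 expressed
  genes) for fast tests; `fullscale` (300 reactions with an 18/11/83
  transporter-class split, ~2,000 expressed genes) echoing realistic
  proportions at desk scale.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequence-level alignment artifacts
(paralogy, domain shuffling, split/merged gene models), count-based
mean–variance relationships of RNA-seq at low expression, ratio
compression in isobaric labeling, batch effects, and missing-not-at-random
proteome coverage. Recovery results on synthetic universes bound what the
pipeline can do under its own assumptions; they do not certify calibration
on any real platform.

## Numerical and determinism conventions

Every ordering is lexicographic; no hash-order dependence anywhere.
Floats are serialized with fixed formats (`%g` for coefficients, 4
decimals for abundances); JSON is written with sorted keys. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; two runs of simulate + reconstruct + overlay
+ report with the same seed are byte-identical except the single
`timestamp` field of `report.json`. SBML export (via cobra, SBML L3 with
no objective) flattens cell types into `_M`/`_BS` compartment suffixes
and round-trips all fields through reaction/species notes.

## Problem sizes used in the checks

The automated checks run at sizes chosen to make every statistical
assertion sharp at desk scale: the truth-table equivalence enumerates all
≤ 3-contributor patterns (~44,000 cases); BH calibration uses 200
complete-null datasets of 2,000 features at 3 vs 3; homology recovery
uses 50 reference genes × 500 targets over a mutation-rate grid; DE-
fraction recovery uses 2,000 genes at 3 vs 3 with effects in (1.5, 3);
color recovery uses a 40-reaction model in the separation regime
(|log2FC| ≥ 2, σ = 0.1, 4 replicates), where classification accuracy is
exactly 1.0 because measured effects sit many standard errors from both
the significance and display thresholds.

## Known limitations

* The moderated test uses a plug-in prior (mean of pooled variances, df
  4) rather than estimating prior scale and df by marginal likelihood; at
  very low replication its p-values are approximate.
* GPR conjunctions (complexes) are carried through collapsing and SBML but
  the overlay treats each gene of a complex as an independent contributor;
  no min/max-style AND aggregation of evidence is attempted.
* Metabolite matching is by bare metabolite id across compartments — a
  measured pool cannot be assigned to one compartment, which mirrors how
  tissue-level metabolomics works but loses localization.
* `n_coding_genes` defaults to the number of genes in the expression
  table when not supplied, which makes "expressed" 100% by construction;
  supply the genome's annotated coding-gene count for meaningful coverage.
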