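# Methods

This note documents the models and rules the package implements, the
parameters that matter, what the synthetic benchmark does and does not
emulate, and the design decisions taken where the underlying screening
protocol is genuinely open.

## Multiheme cytochrome detection

*c*-type cytochromes bind heme covalently at CXXCH motifs. The detector
counts distinct motif start positions (`C`, a gap of `x` residues, `C`,
`H`); overlapping motifs all count, and a start position that matches at
more than one gap width counts once.

Parameters (`MotifSpec`):

| parameter | default | meaning |
|---|---|---|
| `gap_min`/`gap_max` | 2/2 | intervening residues; widen to 2–4 to admit CX₃CH/CX₄CH variants |
| `min_hemes_multiheme` | 3 | motifs needed to call a protein multiheme |

The canonical CXXCH motif is the standard proxy for covalent heme binding;
the threshold of 3 excludes mono- and di-heme housekeeping cytochromes
(e.g. *c*₁, *c*₅₅₀) while keeping genuine EET-associated multihemes, which
typically carry ≥ 4. Both are exposed in configuration because the
screening literature does not fix them. Subcellular localization is
consumed as an input label from an upstream predictor (vocabulary:
extracellular, outer_membrane, periplasmic, cytoplasmic, inner_membrane,
unknown); the package deliberately does not predict localization.

## EET system typing

Per MAG, a single call is made by a decision ladder (homologous system >
pcc-like > mto-like > none); all clusters remain available in the evidence
output.

1. **Homologous systems.** Protein homology hits against reference
   component sets (Geobacter pcc, Shewanella mtrABC, cyc2, mtoABCD,
   foxEZY, pioABC) are filtered at e-value ≤ 1e-5, identity ≥ 30%, query
   coverage ≥ 50% (defaults; the literature rarely states cutoffs), keeping
   the best hit per (query, component) by bitscore, then e-value, then
   input order. A system is called when every *required* component has a
   passing hit and the hit genes co-locate on one contig within the gene
   window; the call is `complete` if optional components are also present,
   `partial` otherwise. The gsu1999-analog periplasmic cytochrome is the
   one optional component of the Geobacter system: genomes lacking it
   (e.g. *Melioribacter*) still reduce Fe(III), so its absence downgrades
   rather than rejects.
2. **pcc-like.** A porin gene (identified by an annotation label in a
   configurable porin vocabulary *or* a passing hit to any reference porin
   component) with ≥ 1 periplasmic and ≥ 1 extracellular multiheme
   cytochrome within the window.
3. **mto-like.** A porin with periplasmic but no extracellular multiheme
   cytochrome in the cluster. This is a negative-evidence label — the
   extracellular cytochrome may simply have failed to assemble or bin — so
   mto-like calls carry completeness `partial`.
4. **none.** Genes localized `unknown` satisfy neither the periplasmic nor
   the extracellular requirement.

The neighborhood window defaults to 5 gene-index units (operon scale).
Distances are measured in gene ranks rather than base pairs so the rule is
robust to gene length variation; gene ranks are computed per contig by
ascending start, ties by end then gene id.

Classification is monotone in evidence: adding genes or hits never lowers
the category rank, and tightening hit thresholds never creates a
homologous call that looser thresholds lacked. Both properties are tested.

## CO₂-fixation pathway completeness

Four pathways are screened: CBB, rTCA, Wood–Ljungdahl (WL) and the
3-hydroxypropionate (3HP) bicycle. A pathway is `complete` only when every
role in its definition is evidenced by an annotation label, `absent` when
no role is present, `partial` otherwise. Role tables ship as editable YAML
(`data/pathway_definitions.yaml`); they are curated stand-ins — compact
role lists with KO/EC/product labels — not a transcription of any
particular study's supplementary gene lists, and deployments screening real
annotations should extend them.

Key markers: CBB — RuBisCO large subunit and phosphoribulokinase (an
archaeal variant definition adds thiazole-adenylate synthase and
sedoheptulose-1,7-bisphosphatase); WL — CODH (acsA); 3HP — malonyl-CoA
reductase (EC:1.2.1.17). rTCA implements the conservative rule: the
citrate-cleavage step is an alternative-marker slot satisfied by aclAB *or*
citryl-CoA synthetase + citryl-CoA lyase, and 2-oxoglutarate synthase is
additionally required — aclAB alone is never sufficient. The
3-hydroxypropionate/4-hydroxybutyrate and dicarboxylate/4-hydroxybutyrate
pathways are not screened by default (they are restricted to thermophilic
archaea from far hotter systems) but can be added to a copy of the YAML.

Directionality is not inferred: a complete WL call carries a caveat that
the same gene complement supports the oxidative acetyl-CoA route for
acetate assimilation; the status itself is unchanged.

Phototrophy: `oxygenic` requires photosystem II and I hits; pufL + pufM +
puhA give `anoxygenic_typeII`; a type-I reaction center without PS-II gives
`anoxygenic_typeI`. Trophic cross-tabulation: `eet_and_cfix` (both),
`eet_only`, `phototroph_cfix` (complete pathway + phototrophy, no EET),
`cfix_only`, `none`.

## Abundance profiles and OTU summaries

Per-MAG, per-sample coverage is the length-weighted mean of contig depths.
Cross-sample normalization multiplies each sample's depths by
(min over samples of total mapped reads) / (sample total), so a
single-sample run is the identity — chosen over per-million scaling
precisely for that property, since the upstream normalization formulas in
field studies are usually unstated. A MAG is **abundant** when its
normalized coverage strictly exceeds the arithmetic mean over the sample's
MAGs; a MAG exactly at the mean is not abundant. Contigs with coverage but
no bin pool into an `unbinned` pseudo-MAG that contributes to sample read
totals but not to the mean or the flags.

Category breakdowns report, per sample, MAG counts and summed
mapped-read percentages for abundant MAGs split by trophic category, with
non-abundant MAGs pooled as `below_average` regardless of content;
`phototroph_cfix` folds into `cfix_only` (it is a CO₂-fixing MAG without an
EET system) so the five buckets partition the MAG set. Percentages are
rounded half-away-from-zero to one decimal in tables and to the nearest
integer in prose-style summaries, so bucket sums can deviate from the total
mapped percentage by at most 0.05 per bucket.

OTU tables are collapsed at a chosen rank by truncating each OTU's
six-slot, rank-prefixed lineage (`k__;p__;c__;o__;f__;g__`; unassigned
ranks are empty tokens, never omitted, making the collapse deterministic).
Per-taxon percent is computed per sample and averaged unweighted across
samples; rows strictly above the threshold (default 1%) are retained and
the cumulative percentage is the sum of their *unrounded* values, reported
at one decimal. Because the filter compares unrounded means, a published
row printed at exactly the cutoff is treated as above it — the
`magscreen.datasets` reconstructions of the two published hot-spring
profiles therefore use a slightly sub-nominal read total so rows printed at
1.0% sit strictly above 1%, and the recomputed cumulative (61.1%) sits
between the sum of the printed values (61.0%) and the pre-rounding total
printed in the original table (61.2%) — all agreeing at integer precision.

## Consensus taxonomy

Lineages are fixed six-slot vectors with prefix structure. The
lowest common ancestor (LCA) of a lineage set is the longest common rank
prefix. A MAG's consensus is the top-down majority vote over per-gene
lineage labels — at each rank the most common token (restricted to
lineages consistent with the accepted prefix) wins if its share of
non-empty votes at that rank is ≥ `min_support` (default 0.5; empty votes
excluded from denominators) — reconciled with the placement lineage by
LCA. Majority-then-LCA is the most conservative reading of a "consensus"
between two classifiers; the report flags when the reconciliation truncated
either input. Consensus depth is non-increasing in `min_support` (tested).

## 16S–MAG linking

Global pairwise alignment with affine gaps (match 1, mismatch −1, gap open
−2, gap extend −0.5; configurable), identity = matches / alignment columns.
Because co-optimal alignments can disagree on the match count, the pair is
aligned in a canonical orientation (lexicographically smaller sequence
first), making the reported identity symmetric. A link is accepted at
≥ 97% identity over ≥ 200 aligned nt — the conventional OTU radius;
reported study links run 98.8–100%, comfortably inside it. Global rather
than local alignment is the default because amplicon and MAG-derived
fragments cover the same region in the benchmark; a local mode is available
for real partial fragments. Each OTU's best accepted link (highest
identity, ties by MAG id) is flagged.

## The synthetic benchmark

`default_community()` builds a 20-MAG, 3-sample community whose composition
mirrors an Fe-cycling hot-spring screen: complete and gsu1999-partial
Geobacter-type conduits (3 MAGs), pcc-like (4) and mto-like (2) clusters, a
cyc2-type Fe(II)-oxidizer homolog with a complete CBB cycle, complete WL
(3) and rTCA (1) pathways, partial rTCA in green-sulfur-type anoxygenic
phototrophs and a partial 3HP bicycle in a filamentous-anoxygenic-type MAG,
an oxygenic cyanobacterial phototroph, and 10 MAGs with no planted system —
including the decoys: an orphan porin with no nearby cytochrome, a
cytoplasmic multiheme cytochrome, and a porin adjacent to a 2-heme
(sub-threshold) periplasmic cytochrome, each of which must classify `none`.

Generator mechanics and deliberate simplifications:

* Protein backgrounds are drawn from a near-uniform amino-acid model with
  cysteine down-weighted (weight 0.3), then scrubbed so that no unintended
  protein reaches the multiheme threshold while single spurious motifs
  survive — the near-boundary negatives the threshold must reject. Planted
  multiheme cytochromes carry 5–12 motifs inserted at spaced positions and
  are verified by recount at generation time.
* Contig nucleotide sequences are random plumbing: proteins are generated
  directly rather than translated from the contig DNA. Coordinates, contig
  lengths and coverage tables are mutually consistent.
* Coverage noise is multiplicative log-normal (σ configurable, default 0 =
  noise-free, the condition under which recovery must be exact); depths are
  strictly positive by construction. Mapped reads are depth × length /
  read length.
* 16S divergence is an independent per-site substitution model (a hit site
  changes to one of the other three bases), so expected identity is
  analytically 1 − rate; the default rate is 0 so every planted OTU must
  link at 100%. OTU counts are Poisson around 20× the MAG's coverage level.
* The truth manifest is computed in the generator by direct arithmetic on
  the emitted records (not by calling the pipeline), including the expected
  abundant flags under smallest-library scaling.
* Not emulated: real gene sequences, assembly or binning artifacts,
  chimeras, strain heterogeneity, FASTQ-level reads. Passing the
  planted-truth tests therefore demonstrates the correctness of the
  decision rules, not robustness to annotation noise in real data.

## Numerical and degenerate-input choices

* All coordinates are 1-based inclusive (GFF3 convention); only CDS rows
  of the GFF3 subset are consumed, everything else is logged and skipped —
  parsers never silently drop rows.
* BLAST tabular input is the fixed 12-column layout; extra columns are
  ignored with a warning; coverages are recomputed from coordinates
  normalized so start ≤ end.
* Ties: gene ranks (start, end, id); best hit (bitscore, e-value, input
  order); rank-abundance (coverage desc, MAG id); consensus votes (count,
  token text); best link (identity, MAG id). Every tie-break is
  deterministic, giving byte-identical reruns.
* Degenerate inputs raise: empty sequences, zero-length MAGs, samples with
  no mapped reads, empty lineage-vote lists, `min_support` outside (0, 1].

## Known limitations

* Presence of an EET gene complement is metabolic *potential*, not
  activity; mto-like in particular may be an assembly artifact.
* Pathway role tables are compact curated defaults; real-data screens
  should review and extend them.
* One EET call per MAG (the highest-ranked category) matches per-MAG
  reporting conventions; a MAG carrying two distinct systems surfaces only
  through the evidence output.
* The acceptance script's problem sizes (20 MAGs × 3 samples, 1000-protein
  and 1000-subset oracle batches, ≤ 300-nt alignment pairs) were chosen as
  the package's own desk-scale benchmark; the statistics they produce are
  exact agreements, not sampled estimates, at any scale.
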