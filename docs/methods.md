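# Methods

## Scope and model

The package reconstructs RNA-motif regulons by genome-context
reasoning, not by sequence search: covariance-model hits are consumed
as tabular input, and functional roles of genes are input annotations.
The chain of inference is

    sites ⟶ operons ⟶ regulated operons ⟶ regulons (per genome)
          ⟶ CRONs (per lineage) ⟶ regulogs ⟶ categories & statistics

All coordinates are 1-based inclusive (GFF3 convention), with
`start ≤ end` and strand stored separately; minus-strand tblout rows
(seq-from > seq-to) are normalised on input.

## Operon inference

Adjacent genes on one contig merge into an operon when they share a
strand and the intergenic gap — defined as `next.start − prev.end − 1`,
i.e. the number of nucleotides strictly between coding regions — is at
most `max_gap` (default 200 nt), or when the coding regions overlap and
the overlap option is on (default). The strict-between definition makes
the 200 nt bound inclusive and testable at the boundary: a 200 nt gap
merges, 201 breaks. A gene nested inside another on the same strand is
treated as a coding overlap. The gap is measured to the running
rightmost coding end of the growing operon, so nesting cannot
artificially split a run. Genes are ordered 5′→3′ in transcription
direction within each operon; the leader (first gene in transcription
direction) carries the start codon used by site assignment.

## Site assignment

The "position" of a site is its gene-proximal end — the site end on
plus-strand operons, the site start on minus-strand operons — because
riboswitch aptamers abut the ORF they regulate; the choice of which
site coordinate must fall in the window is otherwise underdetermined.
A site is assignable to an operon when strands match and the signed
distance from the proximal end to the leader start codon lies in
[−upstream, +downstream] (defaults −500, +100; negative = upstream).
Before assignment, overlapping same-family hits in one genome are
reduced greedily by descending bit score (ties: leftmost start, then
site id). A site qualifying for several operons goes to the nearer
start codon; an exact distance tie is reported as ambiguous and left
unassigned rather than guessed — mirroring what a curator would flag.
Sites claimed by no operon are orphans; assigned + ambiguous + orphans
always equals the deduplicated site count. Two or more same-family
sites on one operon form a single regulated operon with `tandem=True`;
tandem sites count individually in site totals but their operon counts
once everywhere.

## CRON clustering and acceptance

Within one motif family and one taxonomic group, regulated operons are
first grouped by the ortholog group of their leader gene (operons with
an unmapped leader seed singletons). Groups then merge into one CRON
when the Jaccard index of their member operons' ortholog-group sets is
≥ 0.5, applied transitively as connected components (networkx); a
brute-force fixed-point merger serves as the test oracle for this step.
The interactive clustering this replaces has no published algorithmic
form, so anchor-first + Jaccard is declared configuration
(`merge_jaccard`), as are all acceptance thresholds.

Conservation is (genomes with a regulated member) / (genomes of the
group bearing the anchor ortholog group), so gene absence — e.g. an
auxotroph that lost the pathway — does not count against regulatory
conservation. Because Jaccard merging can pull in operons whose leaders
sit outside the primary anchor group (the most common leader group,
ties lexicographic), regulated genomes are unioned into the
denominator; this preserves the 0–1 bound and the property that adding
a regulated member never lowers conservation. A CRON is accepted when
conservation ≥ `min_conservation` (0.5) in ≥ `min_genomes` (2)
regulated genomes, or via the rescue path: a single-genome CRON whose
best site score reaches the family's high-confidence threshold (a
registry column; the per-family filtering thresholds stand in for the
Rfam noise cutoffs, which are model metadata rather than printed
values). Accepted operons are extended iteratively: the next same-strand
downstream gene is appended when its gap is ≤ `extension_cap` (300 nt)
and its ortholog group occurs in ≥ 50% of the other member operons.

## T-box specificity

Specifier codons are located by reference anchoring: one alignment row
is declared the reference with its codon's three 1-based ungapped
positions, and the corresponding alignment columns are read for every
row — the reproducible equivalent of calling codons visually on an
alignment. Codons with gaps, ambiguity characters or stop translations
are "unresolved" and excluded rather than imputed. Translation uses the
standard genetic code on the RNA alphabet (Biopython); the specificity
group defaults to the amino acid's three-letter code, with optional
configured merges, so the observed group inventory (e.g. 18 groups in
real T-box collections, where some amino acids never appear) is data,
not a hard-coded list. Splitting a lineage-level T-box regulog
preserves CRON structure (per-specificity sub-CRONs) and conserves
sites: specificity regulogs + the unassigned bucket account for every
original site.

## Functional classification

Role → SFC → OFC matching is exact after case/whitespace
normalisation; fuzzy matching would silently reclassify genes, whereas
unmapped roles surface visibly under "Other or unknown functional
roles" / "Miscellaneous". The 45-SFC/10-OFC table ships as an editable
TSV (`data/functional_categories.tsv`) because the scheme is data, not
code. A gene is counted once per motif family regardless of how many
operons of that family contain it; OFC counts are exactly the SFC
counts aggregated through the map. OFC proportion tables exclude only
the unknown-role SFC (not the whole Miscellaneous OFC, whose other
SFCs are genuine functions); scopes with no classified gene are "N/A".

## Statistics and reporting conventions

Distribution classes: ribosomal leaders, amino acid leaders and
T-boxes are fixed to D/E/F by mechanism; riboswitch-like motifs are A
when present in strictly more than 75% of lineages, C when present in
at most three, else B. Per-genome ratios print as integers at ≥ 10
(half-up) and with one decimal below 10, matching the mixed formatting
of published regulog tables. Two grand-average conventions coexist and
are labelled explicitly in the output metadata: grand sites-per-genome
is weighted (total sites / total genomes), grand genes-per-genome is
the unweighted mean of lineage ratios — the convention pair that
reproduces the published reference table, whose TOTAL row is not
internally consistent under any single convention (its sites column
sums to 5194 against a printed 5204; the regulog column sums to 394
while the accounting arithmetic 310 − 9 + 92 gives 393; both numbers
are exposed rather than reconciled).

## Synthetic communities

The generator emulates exactly the structure the pipeline relies on:
per-lineage gene-order templates shared by all genomes of a group
(orthology by template position), operon blocks with geometric sizes
(mean 2.5 genes, capped at 6), intra-operon gaps U(20, 150) nt versus
inter-operon gaps U(300, 600) nt, gene lengths U(300, 1500) nt, and
per-genome gene dropout (presence 0.9; planted operons exempt so their
anchors are unambiguous). True sites are placed with their proximal end
uniformly in [−400, −20] of the planted leader's start codon — strictly
inside the assignment window — with bit scores N(60, 8) over a
threshold of 30; tandem pairs occupy disjoint strata ([−150, −20] and
[−400, −310]) so they never overlap. Spurious sites score N(45, 6)
(above threshold, so they must be rejected structurally, not by the
score filter) and are rejection-sampled so the whole site avoids, on
its own strand, the padded window of every operon leader; ground truth
is therefore unambiguous by construction. T-box rows are generated from
a fixed 90-nt template with the specifier codon substituted per planted
specificity, ~3% background mutation and occasional single-base
deletions away from the anchor, plus all-gap columns inserted outside
the anchor region.

The default study conditions (`default_config`) are two lineages of
four genomes, ~60 genes per genome, three planted regulons per lineage
(a three-gene cobalamin-like operon, a two-gene glycine-like operon
with tandem probability 0.8, a two-gene T-box operon with a fixed
specificity), conservation 0.8, and one spurious site per genome
(≈ 20% of true sites). These sizes keep a full 20-replicate recovery
experiment in the low seconds while exercising every stage.

What passing on synthetic data does **not** show: real genomes have
operon structures that violate the distance heuristic (long 5′ UTRs,
internal promoters), hits near the score threshold where filtering and
deduplication genuinely interact, orthology errors, and regulatory
sites whose window membership is marginal — the generator plants
cleanly inside/outside the window by design, so recovery metrics here
validate the machinery, not the biology of edge cases.

## Numerical choices and degenerate inputs

Ties in deduplication and assignment are deterministic (score, then
leftmost, then lexicographic id). Empty genomes yield empty operon
lists; a lineage with no regulogs reports zeros without division
errors; motifs with zero sites report NA ratios flagged undefined;
conservation with an empty denominator is 0 with a warning. All
randomness in the simulator flows from a single `numpy` Generator
seeded from the config, making bundles byte-identical across reruns.

## Known limitations

- CRON merging is quadratic in the number of anchor groups per
  (motif, lineage) cell — fine at curated-collection scale, not tuned
  for thousands of anchors.
- Operon extension trusts the orthology map; paralog confusion there
  propagates into extended operons.
- The assignment window is a hard cutoff; sites just outside it are
  orphans rather than soft candidates.
- The GFF3 reader ingests `gene`/`CDS` features only and expects
  ID-bearing attributes; exotic dialects should be converted to the
  gene TSV.
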