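# Methods

This note documents the models, conventions and numerical choices behind
`splicecons`, and what the synthetic-data tests do and do not demonstrate.

## Alignment map

The reference-anchored alignment is the partial function `w(k, g_t)` from
reference positions to (contig, position, strand) triples in each target
genome, populated by walking MAF columns: every non-gap reference column
paired with a non-gap target row contributes one entry. Coordinates are
0-based half-open everywhere in memory; GTF (1-based closed) and VCF
(1-based) are converted on ingestion. Minus-strand MAF rows are normalised
to forward-strand target coordinates via `srcSize`; the strand is kept so
that base comparisons complement the fetched target base, which is
equivalent to comparing the aligned column characters.

Conventions that the MAF format leaves open:

* **Overlapping blocks.** When two blocks map the same reference position
  for the same target, the first block encountered wins and a warning is
  logged. This keeps `w` single-valued; the alternative (last-wins or
  splitting) would be equally arbitrary.
* **Unknown contigs.** `map_position` raises on a contig or target the
  alignment has never seen. The exon-level queries (`W(e,g)`, `A(e)`,
  `r(e)`) instead treat an absent reference contig as fully unaligned, so
  that completeness tables can include strata from contigs excluded from
  the alignment (unplaced patches, chrY-like contigs).

The map is stored densely per (reference contig, target) as numpy arrays —
position, contig index, strand, provenance — sized by the reference contig.
This favours speed and simplicity over memory; at human scale with hundreds
of targets a block-interval representation would be preferable, and the
container isolates that choice behind `map_position` / `map_arrays`.

## Synteny realignment

An exon with no aligned position in a target, but with aligned exons both
up- and downstream on the same reference contig whose aligned positions fall
on one common target contig, is *syntenic*: its homolog, if present, should
lie in the target segment `u = [max A(e_a)+1, min A(e_b)−1]`. The nearest
qualifying flank on each side is chosen (the free choice minimises segment
length; a bounded outward scan of 5 exons per side resolves flanks whose
positions straddle target contigs). Segments longer than 100,000 bp
(configurable) are skipped as too expensive and too likely spurious.

Placement is an infix alignment: the exon is consumed in full, the segment's
flanks are free, unit costs. It is computed by a row-vectorised dynamic
program (the within-row gap dependency is resolved with a prefix-minimum
scan), with deterministic tie-breaking: the leftmost optimal end column is
chosen, and the traceback prefers match/mismatch over exon-gap over
segment-gap, maximising mapped positions among cost-equal paths at each
step. Determinism matters because recovered mappings feed every downstream
count; the test suite checks the implementation column-for-column against an
independent quadratic dynamic program with the same conventions, and checks
the optimal distance against the edlib library's infix mode. Ambiguous
(non-ACGT) bases never match, including against themselves.

A realignment of exon `e` is accepted only when `r'(e) > mean(R_t) − sd(R_t)`
(strict), where `R_t` holds the scores of originally aligned exons of that
target; `sd` is the population standard deviation (ddof=0, configurable).
The baseline is computed once from the original alignment — not updated as
recoveries accumulate — and recovered exons never enter it. If fewer than
two exons are originally aligned the baseline is undefined and all
candidates for that target are rejected with a reason. Merging never
overwrites an existing mapping and tags recovered positions with
`recovered` provenance, so conservation scoring can exclude them if desired
(by default they are included: realignment precedes scoring).

## Sites, shifts and strand

A splice site is keyed by (contig, strand, kind, origin), where the origin
is the reference coordinate of the first canonical-dinucleotide base *in
transcript orientation*: for a plus-strand intron `[s, e)` the donor origin
is `s` and the acceptor origin `e−2`; on the minus strand, `e−1` and `s+1`.
Shifts count along the transcript — the reference position of shift `l` is
`origin + l` on the plus strand and `origin − l` on the minus strand — which
makes donor and acceptor profiles strand-symmetric. Every downstream number
(conservation vectors, SNP shifts, clinical overlap) uses this convention.

The conservation indicator `C(s, l, t)` is 1 iff the position is aligned and
the bases match, case-insensitively; unaligned positions and Ns count 0
rather than missing, matching the count-of-species framing of the features.
A species conserves the canonical dinucleotide *jointly* only when both
shift-0 and shift-1 positions are aligned and matching. Window positions
truncated by a contig edge count 0.

Canonical classes (GT-AG, GC-AG, AT-AC, other) are assigned from the
donor/acceptor dinucleotide pair of the intron; non-canonical sites are
retained and flow through all operations.

## Gene-type dialects and exclusions

GENCODE and MANE carry the transcript's `transcript_type`; CHESS carries
`gene_type`; RefSeq requires the conjunction of the gene's `gene_biotype`
(`protein_coding` / `lncRNA`) with the transcript's `transcript_biotype`
(`mRNA` / `lnc_RNA`). A transcript failing its dialect's rule is typed
`other` (retained but flagged); a missing attribute warns. MANE subtraction
removes from a catalog exactly the coding sites whose key appears in MANE;
lncRNA sites are untouched since the consensus catalog has no non-coding
entries. Exclusions drop single-exon transcripts, configurable contigs
(default chrY) and, when an alignment is supplied, contigs absent from it.

## Random (neutral) annotation

Negative training examples are two-exon transcripts placed uniformly inside
consensus-catalog introns, at least 35 bp away from every annotated site
origin of every loaded catalog — far enough that the whole feature window
(shifts −30..31) avoids real splicing motifs. Defaults: exon 80–120 bp,
internal intron 100–200 bp, radius 35 bp; all configurable, and chosen as
plausible stand-ins since only the "inside introns, outside motifs"
requirements are fixed by the design. Generated loci are not required to
carry GT/AG reference dinucleotides (they model neutral *positions*, not
splice sites); a flag restricts to GT/AG loci when desired. Placement is
rejection-sampled to keep all origins distinct and is deterministic under
the seed.

## Classifier

Separate donor and acceptor models; features are the joint-dinucleotide
species count plus the sixty positional counts (61 features), or the joint
count alone for the dinucleotide-only variant. Fitting uses scikit-learn's
logistic regression with its standard ridge (`C = 1.0`, recorded and
configurable). A nominally unregularised fit (`C → ∞`) was rejected after
it measurably hurt the full model: with linearly separable training data
the optimiser inflates coefficients along noise directions and the
61-feature model generalised *worse* than the single-feature one, inverting
the expected relationship between the two; the mild ridge leaves the
informative directions essentially untouched while suppressing that
pathology. The train/test split is stratified by class and seeded; the 20%
held-out fraction provides the ROC, AUROC and F-score. Labels use
probability ≥ 0.5 as well-supported (the boundary itself is measure-zero;
the convention is stated here because the comparison is `>=`).

Aggregations: a transcript (≥ 1 intron) is well-supported when every site is
MANE-shared or labelled well; MANE-shared sites are accepted by membership
without being run through the model. Introns fall into 4 categories by which
of their two sites are well-supported (1 neither, 2 donor only, 3 acceptor
only, 4 both). A site is "inside a MANE exon" iff its origin overlaps any
MANE exon interval. The conservation-score correlation uses, per site, the
minimum of the two per-base scores at the canonical dinucleotide against the
model probability (Pearson).

## Population and expression summaries

SNP rates are per-shift fractions of sites carrying ≥ 1 single-nucleotide
variant with at least one homozygous-alternate sample (the `nhomalt`-style
key and the `AF`-style key are configurable, since population databases
disagree on INFO names). Multi-allelic records are split per allele before
filtering; each site counts at most once per shift. The default profile
window is −4..+7 in transcript orientation. Clinical overlap counts sites
with a pathogenic or likely-pathogenic variant (case-insensitive substring,
conflicting-interpretation records excluded) on either canonical position.
Junction coverage integrates tissues by the per-intron maximum and
summarises medians/IQR/±1.5·IQR whiskers per intron category; junction
matching is exact on (contig, start, end, strand).

## Synthetic world

The generator emulates the statistical structure the analyses rely on, not
mammalian genome biology:

* **Star phylogeny.** Each target genome is an independent per-position
  substitution of the reference with probability `d_t × multiplier(class)`,
  where classes are conserved motif (windows ±31 around intended-well site
  origins, multiplier 0.02), exon interior (0.3) and neutral background
  (1.0). The classifier consumes only per-species counts, so tree-correlated
  substitutions would change nothing it can see; this is a deliberate
  simplification of a real multi-species alignment.
* **Divergence ladder.** `d_t` is evenly spaced over 0.02–0.7 across the
  default 25 species. The low end guarantees near species (≤ 5% divergence)
  for realignment stress-tests; the spread makes the joint-count
  distribution of neutral sites broad (mode ≈ 11 of 25) while conserved
  sites stay near 25 — a bimodal separation ≥ m/2.
* **MAF structure.** Blocks follow gene regions (±100 bp flanks), split at
  exon boundaries plus one random split per exon. Exon sub-blocks are
  dropped per species at rate 0.05 (giving the score baseline `R_t` a
  realistic spread below 1.0), and a configured fraction (default 5%) of
  internal (exon, species) pairs is withheld entirely — rows removed from
  the MAF while the sequence stays in the target FASTA — with flanking
  exons kept intact so the pairs are recoverable by synteny. An optional
  deletion knob introduces target-side gap columns to stress the MAF
  walker; it is off by default.
* **Catalogs.** The MANE-like catalog holds one transcript per coding gene;
  the superset catalog adds every gene (including lncRNA-typed ones) plus up
  to three extra isoforms per gene whose novel sites shift one intron
  boundary to a planted motif — alternating conserved-class ("well" intent)
  and neutral ("less") — or shift both boundaries to neutral novel sites,
  yielding introns whose sites are all less-supported (category-1 material).
* **Variants and coverage.** Homozygous SNVs are planted per site and shift:
  canonical shifts at 4% (well-intent) vs 24% (less-intent), other shifts at
  10%; allele frequencies are drawn from 0.0005–0.005 (well) vs 0.005–0.05
  (less); 300 background variants carry `nhomalt=0` to exercise the filter.
  Clinical variants are planted at canonical positions (6% well, 2% less,
  plus benign records). Junction counts are negative-binomial with means
  8/16/16/80 for categories 1–4 (size 20), so category-4 introns dominate
  the coverage summaries by design.
* **chrY-like contig.** A small extra contig carries catalog genes but no
  alignment, exercising the exclusion paths.

Everything derives from a single seed (sub-generators use fixed small
offsets of it), and outputs are byte-identical across runs. The ground
truth — withheld pairs, per-site intents, planted variants, intron-category
intents, class intervals — is serialised next to the outputs, and
`truth_check` verifies the world's structural invariants.

**What passing tests show.** On this world the pipeline recovers ≥ 90% of
withheld low-divergence pairs, separates the classes with held-out AUROC
≥ 0.95, and reproduces the planted SNP-rate and coverage orderings. What it
does not show: robustness to indel-rich alignments, paralogous placements,
tree-correlated conservation, alignment error, or motif-composition effects
— none of which the generator models.

## Problem sizes

Defaults are sized for routine complete runs on one CPU: a 2 Mb reference,
50 genes, 25 target species and 1,000 random sites, which the full pipeline
(load → realign → score → train → label) processes in well under a minute.
Unit tests use smaller worlds (≈ 300 kb, 8 species). All sizes are plain
configuration fields; nothing in the code depends on these particular
values.

## Known limitations

* The dense per-contig mapping arrays trade memory for simplicity (see
  above); very large references with many targets need chunking or an
  interval representation.
* `find_syntenic_unaligned` requires each flank to hit exactly one target
  contig; exons whose aligned positions straddle contigs are skipped rather
  than arbitrated.
* The classifier is intentionally shallow — per-position counts with a
  linear model — and does not see sequence content, so it cannot separate
  two sites with identical conservation patterns.
* Junction matching is exact; fuzzy junction coordinates (e.g. from noisy
  aligners) are reported as unmatched rather than merged.
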