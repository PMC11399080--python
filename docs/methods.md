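# Methods

This note documents the models and conventions implemented in `orftag`, the
reasoning behind parameter defaults, what the synthetic-data generator does
and does not emulate, and the numerical edge-case choices. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and annotation model

All internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted on parse, BED output needs no conversion. A transcript is
"protein-coding" if its transcript biotype says so, falling back to the gene
biotype when the transcript-level attribute is absent (GENCODE dialect
drift). CDS frames are taken from the GTF frame column when present and
recomputed by cumulative-length arithmetic when absent, so minimal GTFs
without frames still work.

**Splice-acceptor index.** Only non-first exons of protein-coding transcripts
carry usable splice acceptors: the first exon has no acceptor, non-coding
transcripts cannot host a productive tag fusion, and intronless genes have no
non-first exons at all, so they drop out of the index by construction.
Identical (acceptor position, gene) pairs contributed by several isoforms
collapse to one entry — downstream counting is per gene, so isoform
multiplicity must not multiply counts. The acceptor coordinate of a `+` exon
is its start; of a `-` exon its half-open end. Under genome reflection
(x → L − x with strands flipped) these two conventions exchange exactly,
which is what makes the whole pipeline strand-symmetric (and is tested as
such). The acceptor "position" is the exon's first base; the intron/exon
junction base itself would differ by 1 nt, with no effect on any decision
made at 200 kb scale.

## Exon phase and its upstream correction

Phase follows the GTF frame convention for CDS features: the number of bases
at the feature start still belonging to the previous codon, i.e. how many
bases to skip to reach the first complete codon. For an exon whose acceptor
boundary lies *upstream* of the transcript's start codon, the effective phase
of a tag fusion is set by the spliced-transcript distance d from the boundary
to the ATG: phase = d mod 3 (2 nt upstream → phase 2; exactly at the ATG or
3 nt upstream → phase 0). Exons entirely downstream of the stop codon have
undefined phase (a `None` sentinel, never an exception), and undefined phase
is never "in frame".

## Cassette frames and the frame→phase map

The three cassette variants differ by 0, 1 or 2 nucleotides between the last
complete tag codon (AAG) and the splice donor: tails `AAG-CAG-GT`,
`AAG-G-CAG-GT`, `AAG-GC-CAG-GT` (frames 1–3; GT is intronic). Which cassette
frame splices in-frame onto which exon phase is stored as an explicit
bijection `FramePhaseMap`, **not** derived from sequence arithmetic. The
screen's published mapping {frame 1 → phase 2, frame 2 → phase 1,
frame 3 → phase 0} is the default. Naive codon arithmetic from the printed
donor tails under the GTF frame convention instead yields the rotated map
{1 → 0, 2 → 2, 3 → 1}; the two cannot be reconciled from the printed
material alone (the resolution would require the exact processed donor/
acceptor junction sequence). Rather than guess, both maps ship
(`PAPER_FRAME_PHASE_MAP`, `CODON_ARITHMETIC_FRAME_PHASE_MAP`) and every
frame-aware function takes the map as a parameter, defaulting to the
published one.

**Read classification.** Cassette-derived RNA-seq reads start with a 6-nt
degenerate prefix (random-hexamer priming) followed by a frame-identifying
constant region ending in the tag's last codons (`…GACGATGACGATAAGCAG` /
`…AAGGCAG` / `…AAGGCCAG`). Classification compares the read's constant
region to each anchor by Hamming distance (an `N` counts as a mismatch —
conservative), accepts at most `max_mismatches` (default 1), takes the anchor
with fewer mismatches when several fit, and discards exact ties rather than
guessing: a mislabelled frame is worse than a lost read. The trimmed
remainder is the first bases of the spliced acceptor exon.

## Insertion extraction and assignment

From alignments, one candidate site per retained read: first mates only (the
second mate of an inverse-PCR pair does not mark the junction), primary
alignments only, mapping quality > 30 (i.e. mapq ≤ 30 discarded). The
insertion coordinate is the read's 5′ end in genome coordinates, and cassette
orientation equals read orientation; `--flip-strand` covers libraries with
the opposite junction geometry. Which genomic base the junction maps to
(junction base vs first genomic base) is not re-derivable from the protocol
description, so one convention is fixed and shared with the simulator —
internal consistency is what the analysis actually needs. Sites deduplicate
by (contig, position, strand); all counting downstream is in unique
insertions, never reads.

Assignment: nearest same-strand acceptor downstream of the insertion
(increasing coordinate for `+`, decreasing for `-`), at most 200,000 nt away
— the bound read inclusively. Equidistant candidates can only share a
coordinate (the search is one-sided); ties go to the lexicographically
smallest gene_id and are counted. Insertions inside an exon assign to the
next downstream acceptor: the cassette's donor splices over whatever exonic
sequence follows it.

**Reversed-integration flag.** Genes with strand-symmetric insertion pileups
can be artefacts (or two adjacent antisense hits). All insertion strands are
flipped, assignment re-run, and the identical Fisher/FDR/threshold machinery
applied; forward hits whose flipped counts also qualify get the comment
`Enriched for reversed integrations` rather than being dropped — the flag is
a caution, not a filter.

## Hit calling

Per gene, the 2×2 table contrasts its unique sorted insertions against the
merged background, with margins equal to the *assigned* unique insertions per
sample. (Using all mapped insertions instead would shrink both rates by the
same unassigned mass; assigned-only is implemented, and the totals are
overridable arguments.) The test is the one-tailed Fisher exact test
(alternative = greater), i.e. the upper hypergeometric tail P(X ≥ n_sorted).
Genes with fewer than 3 unique sorted insertions are removed *before*
multiple-testing correction — the wording "only genes with at least three
unique insertions … were considered" reads as a pre-filter, and a smaller BH
family is also the statistically coherent choice. Benjamini–Hochberg step-up
adjustment (via statsmodels) and the thresholds FDR < 0.001, log₂OR ≥ 1
define hits.

The odds ratio is the sample (unconditional) estimator a·d / (b·c) with
Haldane–Anscombe 0.5 pseudo-counts added to all four cells only when a zero
cell exists; this keeps log₂OR finite without perturbing non-degenerate
tables. The conditional MLE would differ slightly; the published tables do
not specify the estimator, and the sample OR is the common practice the
package follows.

## Bias metrics

The normalized ratio for a gene subset S and a stratum t of reference
universe R is (|S∩t|/|S|) / (|R∩t|/|R|): 1 means the subset mirrors the
reference, and Σ_t (|R∩t|/|R|) · ratio(t) = 1 holds algebraically for any
subset (tested exactly). CDS-length strata on the gene's shortest CDS:
< 2500 nt, [2500, 5000] nt, > 5000 nt — the boundaries are stated only as
"<2.5, 2.5–5, >5 kb", so both edges of the middle stratum are taken
inclusive; at genome scale the choice moves single genes. Expression classes:
inactive (mean TPM = 0) plus nearest-rank quartiles of the active genes, with
boundary ties to the lower class. Genes missing a CDS or an expression value
are excluded and counted, never silently zeroed.

Gene-set over-representation uses the same one-tailed Fisher machinery
against an explicit background universe (typically all intronic
protein-coding genes), dropping categories with fewer than 5 genes or fewer
than 3 hit members before testing, BH-FDR, significance at FDR < 0.05.

**Multi-transduction.** With a measured transduced fraction r, the per-cell
cassette count is modelled Poisson with λ = r, giving
P(≥2) = 1 − e^(−λ)(1 + λ). Two candidate conventions were evaluated against
the six published rate/percentage pairs before implementation: λ = r
reproduces all six to the printed 2 decimals; λ = −ln(1 − r) (exact under
"fraction with ≥1 integration = r") does not, and conditioning on
transduction, P(≥2 | ≥1), does not either. The unconditional form with λ = r
is therefore implemented; strictly it treats the transduced fraction as the
Poisson mean, a first-order approximation that is excellent at r ≲ 0.2 and
increasingly rough toward r = 1 (a warning fires at r ≥ 1).

## The synthetic screen

The generator emulates the *statistical structure* the analysis relies on,
not the biology of integration-site selection:

- **Genome/annotation**: one contig (~18 Mb at defaults), 2,000
  non-overlapping genes on both strands; 5.9% intronless and 45.6% noncoding
  first exons (the genome-wide values for mouse protein-coding genes);
  3–10 exons of 80–300 nt, introns 200–1,800 nt, intergenic gaps 1–5 kb —
  desk-scale stand-ins that keep every distance regime (intra-exon,
  intra-gene, intergenic) represented. CDS placement is arithmetic-first, so
  emitted GTF frames are consistent with the CDS by construction (and
  checked against an independent oracle).
- **Insertions**: a mixture of a TSS-proximal component (exponential decay,
  length 1,000 nt, upstream/downstream with equal probability, sense strand
  with probability 0.8) and a uniform genomic component; mixture weight 0.75
  toward the TSS component. The decay length and mixture weight are chosen
  to give the pronounced-but-not-exclusive TSS clustering retroviral vectors
  show; the sense-strand probability is a declared parameter (lowering it to
  0.5 produces the strand-symmetric pileups the reversed flag exists for).
- **Selection**: the sorted sample keeps the library size fixed and
  *reallocates* insertion mass: each planted gene's weight in the TSS
  component is multiplied by the enrichment factor (default 8×), and the
  reallocated fraction is placed on the gene's sense strand within its
  tagging window (downstream of the previous gene, upstream of its last
  acceptor) — emulating FACS selection of cells whose fusion tags the
  regulator, which by definition requires a productive sense-strand
  insertion upstream of an acceptor.
- **Reads**: 6 random nt + the true frame's anchor + real acceptor-exon
  sequence from the toy genome, with an optional per-base substitution rate.

Defaults (2,000 genes; 50 planted hits; 40,000 background and 15,000 sorted
insertions; 8×; seed 42) are the package's stated test conditions — roughly
a tenth of the real screens' gene count and a hundredth of their sequencing
depth. All randomness flows from a single seed through named independent
`numpy` bit-generator streams, so each artefact is byte-reproducible and
independent of which other artefacts are generated.

What the generator does **not** emulate — and hence what a green test does
not establish: sequence preferences of retroviral integration, chromatin
accessibility, overlapping and nested genes, alternative isoform complexity
(one transcript per gene), PCR/sequencing noise in site recovery, and
selection acting through anything but the planted weights. A ≥90% planted-hit
recall on synthetic data validates the statistical machinery, not the assay.

## Numerical and degenerate-input choices

- Undefined quantities (phase beyond the stop codon, correlation with < 2
  informative bins, median of an empty set, ratio with an empty reference
  stratum) return `None` / NaN sentinels, never exceptions or silent zeros.
- Malformed GTF/BED records raise with the 1-based line number.
- The BH family is exactly the tested genes (post-prefilter); adjusted
  values are monotone and order-preserving, and `fdr ≥ p` always holds.
- Output ordering is total and deterministic: FDR ascending, log₂OR
  descending, then gene_id.
- Unassigned insertions are a value (dropped from counts, reported in QC),
  not an error.
- Percent reporting rounds half-up to 2 decimals, matching how the published
  percentages are printed.

## Known limitations

- One transcript per synthetic gene; isoform-collapse logic is exercised
  only by hand-built fixtures.
- The frame→phase map discrepancy described above is documented and
  configurable, not resolved.
- `first_exon_statistics`' domain coverage uses genomic interval overlap
  with domain annotations, not protein-space alignment; for domains split
  across exons the genomic ≥10% criterion is an approximation.
- The gene-set engine expects pre-made category files; ortholog mapping and
  category curation are out of scope.
- Genome-scale spliced alignment of cassette reads is out of scope; read
  remainders are located by exact prefix lookup against the toy genome.
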