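# Methods

## Scope and model

cypmine analyses a plant multigene family (the cytochrome P450 superfamily
is the motivating case) at the level of a genome annotation: protein
sequences, gene models, promoters and expression tables. The homology search
that produces candidate proteins, the multiple sequence alignment, and
maximum-likelihood tree inference are treated as external inputs — the
package starts from a candidate protein set (or whole proteome) and an
aligned FASTA, and owns everything downstream.

## Family mining

A protein is called a family member when all four P450 signature motifs
match and the ungapped length lies in [450, 600] aa. The default patterns
are deliberately minimal degenerate consensi: heme `FxxGxRxCxG` (the
cysteine that ligates the heme iron is invariant), I-helix `[AG]GxDT`,
K-helix `ExxR`, and `PER[FW]`. Published logos show conservation gradients,
not regular expressions, so the patterns are config-overridable
(`SignatureProfile`); matching is exact per-position set membership, and a
regex-free sliding scan keeps the semantics obvious. Redundancy removal
collapses exact sequence duplicates only — near-duplicates (alleles,
recent paralogs) are retained because no identity cutoff for "redundant" is
universally agreed.

## Alignment statistics and trees

Percent identity between two aligned rows is 100 × matches / comparable
columns, where a column is comparable when neither row has a gap; pairs with
zero comparable columns are flagged undefined rather than silently zeroed.
Column conservation is the sequence-logo quantity: information = log2(20) −
Shannon entropy of the gap-excluded residue distribution.

Distances are the p-distance (mismatch fraction) and its Poisson correction
−ln(1−p), flagged infinite at saturation. A rate-matrix (Dayhoff/PAM)
maximum-likelihood distance is intentionally not implemented: neighbor
joining consumes any additive distance, and the package's tree claims are
about NJ itself, not about a substitution model. The distance model used is
recorded in output metadata.

Neighbor joining follows Saitou–Nei: join the pair minimising
Q(i,j) = (n−2)d(i,j) − r_i − r_j, with branch lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)). Ties in Q break by lexicographic
label order (internal nodes are keyed by their smallest descendant leaf), so
results are deterministic. Negative branch lengths are clamped to zero with
the deficit moved to the sibling branch, preserving the pairwise sum. The
returned tree is unrooted with a trifurcating root. On additive matrices
this recovers the generating tree exactly (verified on random 4–8 leaf
trees and cross-checked against an independent NJ implementation).

Bootstrap support resamples alignment columns with replacement B times
(default 1000), rebuilds the NJ tree per replicate, and scores each internal
edge of the original tree by the percentage of replicates containing the
same leaf bipartition. Bipartitions are canonicalised so a split compares
equal from either side.

Family/subfamily assignment is single-linkage clustering of the percent
identity matrix at 40% (family) and 55% (subfamily), the P450 nomenclature
committee convention; subfamilies are clustered within each family's member
set, which guarantees the subfamily partition refines the family partition
regardless of the cut values. Clusters are numbered by decreasing size then
smallest member, for stable labels.

## Intron evolution

For an intron after k coding nucleotides (cumulative CDS length 5′ of the
junction, strand-aware), the codon index is floor(k/3)+1 (1-based) and the
phase is k mod 3. This one formula covers all phases; the convention —
"the codon containing or immediately following the intron" — matters only
when comparing against coordinates produced under another convention, so it
is stated here explicitly. Introns lying entirely in UTR contribute no CDS
junction and are excluded by construction.

Insertion sites are built per phase class (the conservation definition
requires phase identity, and cross-phase merging would create sites that can
never be called conserved): amino-acid positions are single-linkage
clustered with link threshold = window, which in one dimension reduces to
splitting the sorted positions at gaps larger than the window. Sites are
numbered I1..In by ascending mean position across all phases. A site is a
conserved intron when every member lies within the window of the site mean,
members share one phase, and at least `min_genes` (default 2) distinct genes
carry it. The window is one parameter W (default 45 aa, the upper end of the
40–45 range used in practice), exposed on the CLI.

The census uses the classes {0,1,2,3,4,5+} with percentages rounded half-up
to two decimals; raw counts are always emitted so any rounding convention
can be audited. The gain/loss matrix marks a family × site cell 1 when any
gene of the family carries an intron at the site.

## Promoter enrichment

Promoters are up to L = 2000 nt upstream of the TSS: on the + strand
genome[max(0, tss−L), tss), on the − strand the reverse complement of
genome[tss+1, tss+1+L) clipped at the contig end. Clipped promoters are
flagged; zero-length ones are excluded with a warning. BED6 rows are emitted
for audit.

Motif scanning expands IUPAC letters to per-position base sets; an N in the
genome is unknown sequence and matches only the motif letter N. Overlapping
matches all count. With both-strand scanning (the default — motif databases
are written strand-specifically but regulatory elements act from either
strand), the reverse-complement pattern's matches are added; a palindromic
consensus is scanned once so it is not double-counted, which makes the
presence matrix invariant under reverse-complementing every promoter. The
scanner compiles each motif to a lookahead regex; a position-by-position
brute-force matcher and an independent vectorised matcher serve as oracles
in the tests.

Enrichment is a one-sample test of binomial proportions on presence/absence
(not counts, though counts are reported): p₀ is the empirical fraction of
background promoters (all protein-coding genes) carrying the motif, and the
group's success count x out of n is scored with the exact upper tail
p = Σ_{k≥x} C(n,k) p₀ᵏ (1−p₀)ⁿ⁻ᵏ. The exact tail is used instead of a
normal approximation because tissue groups can have as few as 3 genes.
Degenerate backgrounds are handled analytically: p₀ = 0 with x > 0 is
flagged "background-absent" (p set to 0), p₀ = 1 gives p = 1. The default
alternative is one-sided "greater" (the question is overrepresentation).
Benjamini–Hochberg adjustment is computed alongside the raw p-values; the
significance flag follows the raw p at α = 0.05 so that both conventions are
available downstream. Comparing against the empirical genome background is
also what controls for the random occurrence of short motifs: a motif common
by composition alone has a high p₀ and is not called enriched.

## Expression profiling

A gene is expressed when its maximum FPKM across tissues reaches T (default
2.0, just below the smallest expression value typically reported for
family members). Tissue specificity is s = max FPKM / total FPKM ∈
[1/n_tissues, 1] (0 for an all-zero row); a gene is tissue-specific when it
is expressed and s ≥ s* (default 0.5). No published criterion pins these
two knobs, so both are CLI-exposed and written to output metadata; s is
scale-invariant, so FPKM renormalisation does not move the calls. Heatmap
preparation mirrors ClustVis defaults — ln(x+1) then per-row mean-centering
and unit-variance scaling (ddof = 1) — with constant rows centered to zero
and flagged. Clustering itself is out of scope.

qPCR fold changes follow Livak: ΔCt = Ct_target − Ct_reference,
ΔΔCt = ΔCt(tissue) − ΔCt(calibrator), fold = 2^−ΔΔCt. Technical replicates
are averaged before differencing (the input Ct table carries one row per
biological replicate); ΔΔCt is matched within biological replicate when the
calibrator was measured in that replicate, otherwise against the
calibrator's mean ΔCt, and the per-tissue mean ± sd of the fold over
biological replicates is reported. The method assumes ~100% PCR efficiency
for both target and reference; no efficiency correction is modelled.

## Synthetic data: what it emulates and what it does not

All generators are driven by one `SimulationConfig`; the seed fully
determines every output, and each generator returns a ground-truth table.

- **Gene models.** 300 genes (233 designated family members), protein
  lengths uniform in [450, 600] aa, intron counts drawn from the class
  weights {0: 23/233, 1: 108/233, 2: 37/233, 3: 4/233, 4: 30/233,
  5+: 31/233} (5+ extends uniformly up to 14), i.e. concentrated at one or
  two introns with a 0–14 range. Introns are placed at a catalog of
  insertion sites: two configured conserved sites (defaults at 120 aa and
  280 aa, both phase 1 — two shared same-phase sites, one carried by ~84%
  of intron-bearing genes and the other by the rest) plus background sites
  whose same-phase means are kept more than window + 2·jitter apart, with
  per-site jitter 10 aa ≤ window/2. That separation makes single-linkage
  recovery of the planted sites exact, which is what the recovery tests
  assert. The cost of exactness is realism: every synthetic multi-gene site
  is tightly clustered, so on synthetic data the conserved flag separates
  multi-gene sites from singletons only — real data additionally breaks
  conservation through positional spread and phase heterogeneity, which the
  generator does not emulate.
- **Proteins.** Family members get one concrete instantiation of each
  signature planted at non-overlapping positions; decoys alternate between
  a protein scrubbed of one motif (accidental matches are mutated away and
  the other three motifs re-verified) and a length violator (300 or 700
  aa). Filtering on this set is exactly separable by construction, so the
  mining tests assert sensitivity = specificity = 1; they say nothing about
  borderline real proteins with degenerate motifs.
- **Promoters.** Background composition is i.i.d. uniform A/C/G/T — chosen
  so the analytic random-occurrence probability of a motif is computable as
  a test oracle, not because real promoters are uniform. Planted
  occurrences are inserted at uniform positions/strands with overlap
  rejection, keeping the planted truth exact; planting rates default to
  p₀ = 0.1 / p₁ = 0.9 for one catalog motif with a group of 10 genes.
- **Expression.** FPKM is log-normal(μ = −1.33, σ = 0.6) i.i.d. per tissue
  over 19 tissues, with 31% of genes tissue-specific (one designated tissue
  × fold 100). The parameters were derived, before any testing, from the
  study conditions they must reproduce jointly: a ~31% expressed fraction
  at T = 2.0 (the specific genes are the expressed population; background
  genes clear T in ≥1 of 19 tissues with probability ≈ 0.007) and reliable
  recovery of fold-100 plantings (P[fold·X ≥ Σ others] ≈ 0.99 at these
  parameters). Real FPKM has inter-tissue correlation and heavier tails;
  the generator has neither, so the recovery numbers bound only the
  statistical machinery, not real-data performance.
- **Alignments.** Sequences evolve down a tree under the simplest
  exchangeable model: per branch of length t each site substitutes with
  probability 1 − exp(−t) to a uniformly chosen different residue. NJ
  consistency needs additivity, not realism, and the model's pairwise
  expectation has a closed form used in the tests.

## Numerical choices

- Coordinates are 0-based half-open internally everywhere; GFF3 (1-based
  inclusive) and BED are converted only at file boundaries. One mRNA per
  gene; extra mRNAs are dropped with a warning.
- Percentages are rounded half-up (Decimal, two decimals); published
  census tables mix rounding and truncation, so raw counts accompany every
  percentage.
- All tie-breaks (NJ joins, top-tissue argmax, cluster numbering, report
  ordering) are lexicographic or by explicit sort keys; every stochastic
  routine takes a seed. The exact binomial tail is computed by the
  regularised incomplete beta (scipy's survival function), verified against
  direct summation with exact coefficients to 1e-12.
- Undefined quantities (no comparable alignment columns, saturated Poisson
  distances, all-gap columns, constant heatmap rows) are flagged and
  propagated, never silently replaced.

## Problem sizes used in the checks

The acceptance script and test suite run at desk scale: 1,000-triple
binomial grids, 1,000 null motifs against a 2,000-gene background, 200
power replicates, 100 random additive matrices (5–8 leaves), 100 seeded
30-gene genomes for conserved-site recovery, and a 1,000 × 50
promoter-by-motif scan equivalence check. These sizes give stable
percentages (binomial 99% intervals are accounted for where a rate is
asserted) while each stage remains a few seconds to a couple of minutes.

## Known limitations

- No rate-matrix (PAM/LG) distances or ML tree inference; NJ topology
  quality on real alignments depends on the distance model chosen.
- Redundancy removal is exact-duplicate only.
- No ancestral-state reconstruction of intron gain/loss on the tree; the
  gain/loss matrix reports presence patterns, not events.
- Promoter analysis does no PWM scoring or de novo discovery; consensus
  matching treats all matches equally.
- The 2^−ΔΔCt computation assumes equal amplification efficiencies.
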