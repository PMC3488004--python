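# Methods

`cisfootprint` analyses the regulatory architecture of NF-κB-dependent
genes: how many NF-κB-family binding sites a promoter carries, whether
those sites lie in evolutionarily conserved regions, how many AU-rich
elements (AREs) the 3′UTR carries, and whether these features separate
genes by the timing of their transcriptional response (Early / Middle /
Late). Because the package is exercised on synthetic sequences with
planted ground truth, every claim its tests make is about recovery of a
known signal, not about any particular genome.

## Binding-site model

A transcription-factor binding motif is a position count matrix
`C ∈ ℝ^{4×L}` over the alphabet A,C,G,T. Counts are converted to
log-odds weights against a background composition `b` (uniform by
default) with a pseudocount `p` distributed proportionally to the
background:

    w[i,j] = log( (C[i,j] + p·b[i]) / (colsum_j + p) ) − log b[i]

A window `x` of length `L` scores `S(x) = Σ_j w[x_j, j]`, reported as
the **relative score**

    rel(x) = (S(x) − S_min) / (S_max − S_min) ∈ [0, 1],

where `S_min`/`S_max` are the column-wise minimal/maximal attainable
sums, so the consensus scores exactly 1. Both strands are scanned and a
window is a hit when `rel ≥ θ`; the default threshold is θ = 0.80, the
conventional compromise between sensitivity and specificity for this
family. Windows containing ambiguity codes are skipped and counted in a
debug log rather than scored.

Hits are summarised per promoter two ways: **all** sites (every hit,
overlaps included) and **distinct** sites (connected components of
interval overlap pooled over all four matrices and both strands). The
distinct/all contrast is the operational definition of "multiple and
overlapping" site architecture: a promoter with 71 hits piled on one
locus has 1 distinct site.

The bundled matrix set (`data/nfkb_family_synthetic.jaspar`) contains
four synthetic 10-nt matrices labelled NFKB, REL, p50 and p65. They are
constructed stand-ins sharing the family's hallmark GGG-opening and
C-rich tail, not database entries; any JASPAR-format file can be
substituted.

Defaults: pseudocount 0.8, uniform background, θ = 0.80. A palindromic
window meeting the threshold on both strands yields two hits.

## Phylogenetic footprinting

Orthologous promoter pairs are aligned globally (Needleman–Wunsch,
affine gaps; match +1, mismatch −1, gap open −5, gap extend −1; a gap of
length k costs `open + (k−1)·extend`). The aligner's first co-optimal
alignment is used, which is deterministic for fixed inputs. Per
alignment column, percent identity is computed over a centred window
(default 50 nt, truncated at the ends; gap columns count as
mismatches), and maximal runs of columns with identity ≥ 40% are the
conserved regions. Both window and cutoff are the conventional settings
for promoter-scale footprinting of mammalian orthologs.

A binding site counts as **conserved** when (a) at least 50% of its
aligned columns fall inside a conserved region in both species, (b) the
two hits come from the same matrix and strand, and (c) their alignment
start columns differ by at most 3 (absorbing alignment jitter without
merging neighbouring sites). Pairing is greedy by smallest offset, then
leftmost; each hit joins at most one pair. The cross-species matrix
reports, for template species M against species N, the percentage of
M's hits that paired; the denominator is the template's hit count, so
the matrix is only approximately symmetric, and cells with zero
template hits are undefined (NaN), never 0.

## ARE classes

On DNA alphabet (RNA transcoded U→T on input):

* **Class I** — every occurrence of the core pentamer ATTTA, overlaps
  included. A strict-region mode (count T-rich regions *containing*
  dispersed pentamers) is available behind a flag; motif counting is
  the default because per-gene counts in the tens are only consistent
  with counting individual motifs.
* **Class II** — maximal chains of the destabilising nonamer
  TTATTTA(T/A)(T/A) in which consecutive nonamer starts differ by < 9
  (i.e. the copies overlap). Chains of ≥ 2 nonamers count once each.
* **Class III** — T-rich stretches with no ATTTA. Operational rule:
  every 50-nt window with T fraction ≥ 0.60 and no ATTTA marks its
  positions; coverage is split at any ATTTA (merged coverage can
  straddle a pentamer that no single window contains); maximal marked
  runs of length ≥ 50 count once each. Window length, T fraction, and
  an A+T ("AU") counting mode are configurable — the class III
  definition in the literature is verbal, so this rule is a documented
  operationalisation.
* **Core** — every ATTT occurrence, the most permissive signal.

Counting is per sequence, without alignment. Invariants: core ≥ class I
(every ATTTA contains ATTT); each nonamer embeds a pentamer at offset
2, so class II chains inflate the class I count by ≥ 2 per chain.

## Statistics

* **Abundance**: two-sided Wilcoxon rank-sum comparing distinct-site
  counts of a gene group against background sequences. Exact null
  distribution when the smaller sample is ≤ 10 without ties, otherwise
  normal approximation with tie and continuity correction. The suite
  verifies type-I error calibration at 5% ± 1% over 10 000 Poisson-null
  replicates.
* **ARE counts**: one-way ANOVA across Early/Middle/Late, returning F,
  p, group means and t-based 95% CI half-widths. A Kruskal–Wallis
  variant is exposed for count data that violates normality; it is off
  by default.
* **Clustering**: per-gene feature vectors (expression group, distinct
  sites, all sites, dispersion, ARE I/II/III counts) are clustered by
  UPGMA. The default distance is **percent disagreement**: numeric
  features are discretised into dataset-wide tertiles and the distance
  is the fraction of features (including the group label) on which two
  genes differ. Euclidean distance on raw numeric features is the
  alternative used for the Middle-gene sub-clustering. UPGMA merge
  height is the average inter-cluster distance; ties break by the
  smallest cluster ids; cutting at k withholds the k−1 final merges.
* **Dispersion**: coefficient of variation of the gaps between
  consecutive distinct-locus starts (0 when fewer than 3 loci). This
  is a documented stand-in for "site scatter" — regularly spaced or
  clustered sites score low, irregular placement scores high.

The published per-gene "TFBS index" has no recoverable definition; the
implemented `tfbs_index` is a labelled surrogate (mean distinct-site
count per gene, or mean all-hit count on request) and is not claimed to
reproduce published index values.

## Synthetic data: what it emulates and what it does not

The generator provides every input with known ground truth:

* **Promoters** (default 1000 nt, i.i.d. background at a requested GC
  content) carry planted consensus sites: *clustered* mode packs all
  sites into one window (default 250 nt), emulating the dense,
  overlapping site architecture of rapidly induced genes; *scattered*
  mode spaces sites ≥ 100 nt apart, emulating late-responding genes.
* **Orthologs** evolve by per-site Bernoulli substitution at a neutral
  rate outside and a slower rate inside conserved blocks; a substituted
  base is always replaced by a *different* base, so the expected
  mismatch fraction equals the rate exactly — the simplest model with
  closed-form expectations. Single-base indels occur outside conserved
  blocks only, so a zero conserved rate guarantees planted sites
  survive verbatim. Pipeline defaults emulate chimp-, mouse- and
  cattle-like divergence with neutral rates 0.03, 0.25, 0.30 and a
  conserved-block rate of 0.02 for Early-like genes (Late-like genes
  get no protection).
* **3′UTRs** (pipeline default 4000 nt) carry planted AREs with
  group-dependent mean counts — Early (8, 3, 10) for classes I, II,
  III; Middle early-like (5, 1, 8); Middle late-like (2, 0, 4); Late
  (1.5, 0, 2) — Poisson-drawn and truncated at twice the mean so every
  draw is placeable. Elements are flanked by C/G guards, separated by
  ≥ 60 nt (more than the class III window, so coverage cannot bridge
  elements), and accidental background ATTTAs are scrubbed; the
  detector therefore recovers planted class II/III counts exactly.
* **Backgrounds** are i.i.d. uniform-composition sequences (50 × 1000
  nt by default) — the composition of the original random-sequence
  generator is unrecorded, so uniform is the configurable default —
  plus exact letter-permutations (mononucleotide shuffles) of each
  promoter.
* **Feature vectors** for clustering tests use two deterministic
  Middle archetypes and noisy Early/Late profiles with margins wide
  enough that dataset tertile edges fall between profiles, making
  recovery tests reproducible rather than knife-edge.

What passing tests therefore show: the scanner, footprinter, detectors
and statistics recover planted signal of the stated effect sizes under
an i.i.d. background and a memoryless substitution model. What they do
not show: performance on real promoters (repeats, CpG islands,
composition heterogeneity), real indel structure, alignment ambiguity
at high divergence, or the false-positive behaviour of PWM scanning on
genomic DNA.

## Numerical and scale choices

* Coordinates are 0-based half-open on the forward strand everywhere;
  reverse-strand hits are reported in forward coordinates.
* Touching intervals (end == start) do not overlap and stay distinct.
* All randomness flows from explicit integer seeds; the pipeline
  derives every stage seed from one master seed, and reruns are
  byte-identical.
* Scan equivalence is verified against exhaustive-window oracles for
  sequences ≤ 200 nt and matrices with L ≤ 8; alignment scores against
  exponential enumeration for lengths ≤ 8; UPGMA against an
  independent average-linkage implementation on 8-leaf problems.
* Test problem sizes (100 scan instances, 100 seeded recall promoters,
  30 footprint-recovery seeds, a 20-rate × 10-replicate degradation
  grid, 1000 ARE oracle sequences, 10 000 calibration replicates, 200
  power runs with 14 genes per arm) were chosen so the full suite runs
  in well under a minute of statistical simulation while keeping every
  Monte-Carlo bound comfortably away from its pass/fail boundary.

## Known limitations

* The aligner replaces the original interactive footprinting tool with
  a standard global affine-gap alignment; on real, rearranged promoters
  a local or chained aligner would be more appropriate.
* Class III AREs and the dispersion statistic are operational
  definitions; published counts based on unspecified rules should not
  be expected to match exactly.
* The Wilcoxon exact path is limited to small samples without ties;
  count data with heavy ties always takes the corrected normal
  approximation.
* Percent-disagreement clustering depends on the binning; tertiles are
  computed over the dataset at hand, so cluster assignments are not
  comparable across datasets.
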