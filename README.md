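# cisfootprint

Regulatory-sequence analysis of NF-κB-dependent genes: position-weight-
matrix (PWM) scanning for NF-κB-family binding sites in promoters,
phylogenetic footprinting of orthologous promoter pairs, AU-rich-element
(ARE) detection in 3′UTRs, background enrichment statistics, and
hierarchical clustering of per-gene features — together with a
synthetic-data generator that produces ground-truthed inputs for all of
it.

## Who this is for

NF-κB-dependent genes respond to nuclear NF-κB translocation with
different kinetics (Early ≈ 30–60 min, Middle ≈ 3 h, Late up to 6 h).
Two sequence-level correlates of that timing are (1) the number and
packing of NF-κB-family binding sites in the promoter, especially sites
lying in evolutionarily conserved regions, and (2) the number of
mRNA-destabilising AREs in the 3′UTR. This package implements the full
computational chain needed to measure both and to test whether they
separate the timing groups — for anyone studying promoter architecture
and cross-species conservation of cis-regulatory sites, or who needs a
tested, seeded reference implementation of these classic operations.

## The core operations

* **Scanning** — counts `C` become log-odds weights
  `w[i,j] = log((C[i,j] + p·b_i)/(colsum_j + p)) − log b_i`; a window
  scores `S = Σ_j w[x_j, j]`, rescaled to the relative score
  `(S − S_min)/(S_max − S_min)`; hits are windows ≥ 0.80 on either
  strand. Overlap-merged hits give the *distinct* site count, raw hits
  the *all* count.
* **Footprinting** — global affine-gap alignment of ortholog pairs,
  windowed percent identity (50 nt), conserved regions at ≥ 40%
  identity, and greedy pairing of same-matrix hits whose aligned starts
  agree within 3 columns. Reported as the percentage of the template
  species' sites conserved against each other species.
* **ARE detection** — class I: every ATTTA; class II: maximal chains of
  ≥ 2 overlapping TTATTTA(T/A)(T/A) nonamers; class III: T-rich
  (≥ 60%) ATTTA-free stretches ≥ 50 nt; core: every ATTT.
* **Statistics** — Wilcoxon rank-sum for site abundance vs background,
  one-way ANOVA for ARE counts across groups, and UPGMA clustering of
  gene feature vectors under percent-disagreement (tertile-binned) or
  Euclidean distance.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Run the whole pipeline on its default synthetic study (43 genes: 14
Early, 18 Middle, 11 Late; 4 species; 50 random backgrounds):

```
cisfootprint run --seed 1 --outdir run1
```

which prints (abridged):

```json
{
  "n_genes": 43,
  "avg_distinct_per_gene": 13.49,
  "avg_distinct_per_background": 1.74,
  "abundance_p_values": {
    "Early": 7.2e-09, "Middle": 1.03e-08, "Late": 1.71e-04
  },
  "are_anova_p_values": {
    "I": 2.74e-12, "II": 1.38e-08, "III": 1.37e-09
  },
  "mean_pct_conserved_by_group": {
    "Early": 84.9, "Middle": 62.5, "Late": 37.7
  }
}
```

Reading these numbers: genes average 13.5 distinct family sites per
promoter against 1.7 in random backgrounds, and every timing group is
significantly enriched (Wilcoxon vs the 50 backgrounds). ARE counts of
all three classes differ significantly across timing groups (ANOVA).
Cross-species conservation of binding sites falls from 85% in Early-like
promoters (planted sites in slowly evolving blocks) to 38% in Late-like
promoters (unprotected sites) — the qualitative Early > Middle > Late
gradient the analysis is designed to expose. The run directory holds
every intermediate artifact: FASTA inputs, hit BED files, the
participation table, conserved-fraction tables, per-gene ARE reports,
and Newick dendrograms with the k=4 cluster table.

Individual stages are available as subcommands (`simulate`, `scan`,
`footprint`, `are`, `stats`) and as library functions:

```python
import cisfootprint as cf

pwms = cf.bundled_nfkb_pwms()
seq, truth = cf.generate_promoter(
    cf.PromoterSpec(length=1000, n_planted_sites=3, seed=5), pwms)
hits = cf.scan_sequence(seq, pwms, threshold=0.80)
report = cf.summarize_hits(hits, pwms)
print(report.distinct_total, report.all_total)   # 6 14
```

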