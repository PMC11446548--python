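# imprintseq

Analysis toolkit for **co-transcriptional mRNA imprinting**: detecting where
an RNA-binding transcription factor loads onto nascent transcripts, and
linking that binding to transcription and decay kinetics.

The motivating biology is a budding-yeast transcription factor that, after
being recruited to promoters, travels with RNA polymerase II, increases Pol
II backtracking, and transfers onto a subset of nascent mRNAs near their 3'
ends ("imprinting"), stabilizing those mRNAs in the cytoplasm. The toolkit
implements the quantitative pipeline such a study needs:

- **Bound-transcript classification** — from a per-base cross-linking (CRAC/
  CLIP-style) coverage track: select the top-N transcripts by read count,
  cluster their polyadenylation-site (pA)-anchored profiles with k-means,
  and call the clusters whose signal concentrates in the 250 bp upstream of
  the pA as bound ("CRAC+"); report a per-gene binding propensity
  (**CRAC index** = cross-linking RPKM / mRNA level).
- **Motif positional analysis** — scan sense-strand transcript sequence for
  maximal contiguous (GCT)n repeats (n ≥ 2), summarize distances upstream of
  the pA, and test presence enrichment between gene sets.
- **Steady-state kinetics** — per-gene half-lives from run-on data under the
  steady-state identity **HL = RA / SR** (abundance over synthesis rate),
  between-condition ratio tables, and log-linear half-life fits of
  reference-normalized decay time courses.
- **Backtracking index** — **BI = Rpb3-ChIP / GRO** per gene from 250 bp
  5'/3' end tiles (a backtracked polymerase is ChIP-visible but cannot
  elongate in a run-on), with median-centred z-scoring.
- **Rpb4/Rpb3 stoichiometry** — ratio profiles over −100..+250 of the TSS
  and −250..+100 of the pA, normalized to the TSS −100 position, plus
  per-gene body averages and a Pearson/Spearman correlation ledger across
  quantities and gene-set strata.
- **Gene-set statistics** — exact hypergeometric inclusion/exclusion tests,
  Venn accounting, and Holm–Bonferroni-adjusted term enrichment.
- **Synthetic data** — a first-class generator that plants all of the above
  structure (peaks ~150 bp upstream of pA in a minority class, (GCT)n
  motifs, RA = SR × HL, backtrack fractions b with GRO ∝ 1 − b, linear
  Rpb4 decline) with a truth table, so every stage is testable end to end
  without downloads.

Inputs are plain standard formats: BED6/BED12 or GFF3 annotations, bedGraph
coverage tracks (strand-resolved), FASTA genomes, and TSV per-gene tables.
All coordinates are 0-based half-open; windows are always oriented 5'→3' in
transcript sense, and out-of-chromosome positions are masked, not
zero-filled.

## Worked example

```python
from imprintseq import synthetic_data as sd, crac_classify as cc
from imprintseq.motif_positional import hits_near_pa, positional_summary

sim = sd.generate_genome(n_genes=600, seed=1)
track = sd.plant_crac_track(sim, seed=2)      # 262/600 bound, peaks ~150 bp upstream of pA
sd.plant_motifs(sim, seed=3)                  # (GCT)n in ~65% of the bound class

report = cc.classify_pipeline(track, sim.annotations, seed=4)
truth = set(sim.crac_positive_ids())
called = set(report.crac_positive.members)
tp = len(called & truth)
print(f"called {len(called)} bound genes "
      f"(recall {tp/len(truth):.3f}, precision {tp/len(called):.3f})")
print(f"clusters called positive: {report.clusters.crac_positive_clusters}; "
      f"{report.positive_read_fraction:.1%} of reads in positive clusters")

hits = hits_near_pa(sim.annotations, sim.sequences, window_upstream=250)
s = positional_summary(hits)
print(f"{s['n']} genes with a (GCT)n motif, "
      f"mean {s['mean']:.1f} bp upstream of the pA site (median {s['median']:.1f})")
```

prints

```
called 262 bound genes (recall 1.000, precision 1.000)
clusters called positive: [1, 2, 3]; 94.6% of reads in positive clusters
169 genes with a (GCT)n motif, mean 151.7 bp upstream of the pA site (median 151.0)
```

i.e. the classifier recovers the planted 262-gene bound class exactly: the
k-means step yields three pA-proximal clusters holding ~95% of the
cross-linking reads plus one flat background cluster, and the motif scanner
locates the planted repeats ~150 bp upstream of the pA sites.

The same analyses are available from the shell via one executable with
subcommands (`imprintseq simulate | metagene | classify | motif | kinetics |
backtrack | stoich | overlap`); each reads/writes TSV plus a JSON run
manifest. `imprintseq simulate --outdir study/` emits a complete synthetic
study (FASTA, BED, bedGraphs, expression tables, truth table) to analyse.

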