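# Methods

This note documents the models implemented in `imprintseq`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Coordinate and signal conventions

All coordinates are 0-based, half-open (BED-native). A transcription unit
is (chromosome, strand, TSS, pA); the pA site is the exclusive end of the
transcript in transcript sense, so "x bp upstream of the pA" means
transcript-sense offset −x from the anchor. On the − strand, transcript
position j maps to genomic `tss − 1 − j`; every extracted window reads
5'→3' in transcript sense so upstream/downstream have the same meaning for
both strands.

Coverage tracks are per-base, strand-resolved, non-negative vectors
(bedGraph on disk; overlapping intervals sum). Window cells that fall off a
chromosome are **masked**, never zero-filled: zero-filling would bias edge
columns of metagene averages downward, whereas masked cells simply reduce
the per-column valid count `n_valid` used in every mean.

## Metagene profiles

`anchored_matrix` builds genes × positions matrices anchored on the TSS,
the pA site, or a per-gene motif center. `scaled_metagene` produces the
hybrid-scale profile: flanks at real bp scale, gene body resampled onto a
fixed number of percent bins. Body resampling uses **mean within bin**
rather than interpolation so total signal mass is conserved up to binning —
the natural choice for read-density signals. Genes shorter than the bin
count are skipped and logged.

`robust_filter` removes the rows with the most extreme mean coverage before
averaging: the extreme fraction f (default 0.05) is split evenly between
tails, removing ⌈f/2·n⌉ rows from each. The even split is a convention
choice (the filtering idea comes from standard metagene practice where only
the total extreme fraction is specified); it is recorded in output
metadata. Replicate tracks are combined by summing before scaling — a
profile-correlation helper (`profile_correlation`) makes the
replicate-similarity check reproducible.

## Bound-transcript classification

Pipeline: per-gene read counts → top-N selection (default N = 600, ties
broken lexicographically and recorded) → pA-anchored matrix (default
−500..+100, 10 bp bins) → scaling → k-means (default k = 4, fixed seed,
`n_init` = 10) → cluster-level call: clusters whose mean-profile mass
fraction inside [−250, 0) of the pA exceeds the threshold (default 0.6) are
bound; the called set is the union of their genes.

**Scaling.** The default scales the whole matrix by its mean row mass
("global" scaling). We deliberately did not default to per-row unit-mass
scaling: with a few hundred genes where unbound transcripts carry only a
handful of background reads, row scaling makes a two-read row whose reads
happen to fall upstream indistinguishable from a genuine peak, and the
cluster-level call then inherits shot noise (measured precision drops to
~0.85 on the default simulation). Global scaling keeps between-gene
amplitude — a bound gene's ~50-read pile separates cleanly from sparse
background — while remaining invariant to multiplying the track by any
positive constant. On the default simulation it yields three pA-proximal
clusters plus one flat cluster holding only a few percent of the reads,
which is also the structure one expects when the negative class is
signal-poor. Row scaling stays available (`scaling="row"`) for data where
all selected genes are read-rich and shape is the only discriminant.

Cluster labels are renumbered so cluster 1 is the most pA-proximal
(largest upstream mass fraction). The report includes read-mass accounting
per cluster (summing to the matrix total) and the fraction of reads in the
called-positive clusters. The mass threshold is a first-class parameter
with a sensitivity sweep (`threshold_sweep`), and a silhouette sweep over
k ∈ 2..8 is provided, because both choices are analysis decisions rather
than facts about the data. A uniform profile over the default −500..+100
window has upstream mass fraction 250/600 ≈ 0.417, comfortably below the
0.6 default.

The **CRAC index** is cross-linking RPKM divided by mRNA level (RPKM =
count / (length/1e3) / (library/1e6)); zero denominators are flagged, not
dropped. An alternative normalization by a ChIP signal is provided for
cross-checking.

## Motif scanning

`scan_unit_repeats` reports maximal, non-overlapping runs of ≥ 2 contiguous
copies of a trinucleotide unit (default GCT) on the sense strand; a run is
never split into overlapping sub-hits, and any N breaks a run because it
cannot match the unit. The scanner is verified in tests against a greedy
regex oracle, exhaustively for all strings of length ≤ 9 and on random
200-mers. Distances to the pA are measured to the **run midpoint**; start
vs center is an arbitrary convention at the ±3 bp level and is recorded in
output metadata. `hits_near_pa` scans a window upstream of each pA
(default 160 bp, clipped at the TSS) and keeps the hit nearest the pA per
gene. Presence enrichment between gene sets delegates to the
hypergeometric machinery below. De novo motif discovery is out of scope;
the unit and minimum repeat count are parameters so other short repeats can
be scanned.

## Steady-state kinetics and decay fitting

Under steady state, synthesis and decay balance, so HL = RA/SR in arbitrary
units; SR = 0 genes are flagged rather than raising. Condition ratios
(mutant/WT or post/pre-depletion) are elementwise over the shared gene
universe, optionally log2. Depletion analyses are summarized as per-set
median ratio shifts rather than per-gene significance calls, matching the
distributional (scatter/density) way such data are usually presented.

Decay time courses are normalized to a stable reference transcript (e.g.
the Pol III transcript SCR1) and rescaled so t = 0 is 100%. Half-lives come
from least squares on ln(percent) vs time: on 3–5-point courses a
log-linear fit is far more robust than a nonlinear exponential fit, and it
is exact on noiseless exponential data (the (100, 50, 25) @ (0, 10, 20) min
course gives HL = 10 exactly). Points at 0% are excluded with a warning;
non-negative slopes are flagged "no decay" instead of being converted to a
meaningless half-life.

## Backtracking index and stoichiometry

Per-gene signals are means over 250 bp tiles at the transcript 5' and 3'
ends (shorter genes use the whole transcript, flagged). **BI** combines
the two tiles as the mean of the tile means for both ChIP and GRO — the
tile-combination rule is not dictated by the ratio definition, so per-tile
indices (BI5, BI3) are also reported. With the default pseudocount 0,
genes with zero run-on signal are flagged undefined. `zscore_median`
implements the median-centred z-score ((x − median)/SD with sample SD about
the mean); MAD-based scaling is available behind `zscore_mad` for heavier
tails. Median centring with mean-based SD means the transformed vector has
median exactly 0 and SD exactly 1, which tests assert.

Rpb4/Rpb3 **ratio profiles** cover −100..+250 of the TSS and −250..+100 of
the pA and are normalized to the TSS −100 position (a promoter-side
reference where the ratio should reflect freshly recruited polymerase).
The profile uses the **ratio of mean signals** across the gene set per
position — robust to per-gene zeros — while the per-gene **body ratio**
(TSS..+250 and −250..pA) uses the mean of per-position ratios, which is
the natural per-gene summary. Both accept a pseudocount; the default is 0
so noiseless data are recovered exactly, with zero-denominator positions
flagged NaN (on real, noisy tracks a pseudocount of ~1% of the positive
signal median is a reasonable setting).

The **correlation ledger** computes Pearson and Spearman r, two-sided
p-values and n for requested quantity pairs (e.g. BI_ratio vs HL_ratio),
stratified by gene set, on pairwise-complete observations. No
multiple-testing correction is applied inside the ledger (correlations are
reported per panel, not screened); this is stated in the output.

## Gene-set statistics

Hypergeometric tails are exact: enrichment is P(X ≥ k) (upper tail
including the observed overlap — conventions differ between tools, so this
is stated in output), depletion P(X ≤ k). The universe must be passed
explicitly; silently defaulting to the union of the sets would change the
test, and legitimate universes differ between analyses. Venn region counts
cover 2–3 sets with an outside-universe check. Term enrichment applies
Holm–Bonferroni step-down adjustment (monotone, clipped at 1); the
annotation database itself is caller-supplied.

## Synthetic-data generator

The generator is the package's test bed and defines its default study
conditions:

| quantity | default | rationale |
|---|---|---|
| genes | 600 on 2 chromosomes, both strands | size of the top-N analysis universe |
| transcript length | uniform 800–2500 bp | typical mRNA lengths; long enough for 250 bp end tiles and a 600 bp pA window |
| bound fraction | 262/600 | the bound-class share of the analysis universe |
| peak offset | Gaussian, mean 150 bp upstream of pA, sd 20 | 3'-proximal binding site location |
| pile shape | Gaussian, sd 30 bp | cross-link pile width |
| reads per bound gene | Poisson(50) | specific signal |
| background | Poisson, 5 reads/kb, uniform over transcript | nonspecific signal on all genes |
| motif fraction | 73/113 ≈ 0.65 of bound genes | motif-bearing share of the peak clusters |
| motif offset | Gaussian, mean 150 bp, sd 25, ≥ 2 GCT units | motif placement upstream of pA |
| SR, HL | log-uniform 0.5–20, 4–60 (arb. units) | broad realistic dynamic range |
| RA | SR × HL × lognormal(cv) | steady-state identity with multiplicative noise |
| backtrack fraction b | U(0.3, 0.7) bound / U(0.05, 0.4) rest | bound genes backtrack more |
| mutant condition | b and HL of bound genes halved; optional coupling HL_ratio ∝ BI_ratio | loss of the stabilizing factor acts on the bound class |
| Rpb4 decline | ratio = max(ε, 1 − slope·d/1000), slope per kb, flat in flanks | linear stoichiometry loss along the body |

Poisson reads plus lognormal multiplicative noise is the simplest
generative model consistent with count tracks and array-style ratios; all
parameters are exposed. Same seed ⇒ byte-identical outputs; planted read
mass equals track mass (asserted in tests).

When motifs are planted, chance (GCT)≥2 runs in the scanned window are
purged (one base of the second unit mutated) and guard bases prevent
chance units from extending a planted run, so recovered positions equal
planted positions exactly — tests rely on this.

What the generator does **not** emulate: UTR structure and splicing, read
sequences (FASTQ), mappability and GC bias, array probe effects,
between-replicate variance structure, or any dependence of background on
expression level. Passing tests therefore demonstrate that the algorithms
recover the planted statistical structure at realistic sizes and noise —
not that any particular biological dataset would yield the same numbers.

## Problem sizes and determinism

Tests and the acceptance script run on 120–600-gene simulations — large
enough for stable rank statistics (SEM of a Spearman rho at n = 600 is
~0.04) and small enough to iterate quickly. Every stochastic step takes an
explicit seed (`numpy.random.default_rng`); k-means uses a fixed
`random_state` and `n_init`, so all reported numbers are exactly
reproducible given the seed.

## Known limitations

- The bound/unbound call is cluster-level, as in the underlying heatmap
  methodology; per-gene posterior probabilities are not computed.
- The mass threshold (0.6) and k (4) are conventions, not estimates; the
  sweeps exist so their influence can be inspected per dataset.
- bedGraph is the only track format read natively (text, diffable); bigWig
  input would need conversion.
- GFF3 reading uses top-level `gene` features only; transcript isoforms
  are not modeled (one TSS/pA pair per gene).
- The decay fitter assumes single-exponential decay; biphasic courses will
  be summarized by an effective slope.
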