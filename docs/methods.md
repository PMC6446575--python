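# Methods

## Scope and data model

`cislink` analyses interval-shaped genomics data downstream of
alignment.  All coordinates are 0-based half-open (BED convention);
bedGraph uses the same convention; GTF input (1-based) is converted on
read.  Genes are reduced to a strand-aware transcription start site
(TSS): the annotated start for `+` genes, the annotated end − 1 for `-`
genes.  Distance from a point (a TSS) to an interval (an enhancer) is 0
inside the interval and otherwise the gap to the nearer edge base; edge
rather than center distance keeps "within 100 kb" monotone in enhancer
width (a center mode is not provided).  Nearest-gene ties break to the
lexicographically smallest gene id, and every set-valued output is
emitted sorted by (chrom, start, end), so all results are deterministic.

## Peak calling

A deliberately small local-Poisson model in the MACS2 mold, applied to
fragment intervals rather than reads.  Fragment midpoints (not full
overlaps) define window membership, echoing the shifted-cut convention
of ATAC processing and avoiding double counting.  Windows of
`window_size` = 177 bp advance by `step` = 88 bp; replicates of a
condition are pooled before calling.  Each window's count k is tested
against

λ = max( λ_1kb, λ_10kb, λ_genome ),

where each local rate is estimated from a window-centered background
span **excluding the focal window** and rescaled to window size.  The
exclusion matters: a genuinely enriched window otherwise contributes
~20–40% of its own background estimate at the 1 kb scale and roughly
halves detection power for planted 8× windows; with exclusion the
planted-window benchmark recovers ≈ 0.97 (detection Jaccard) while null
calibration is unchanged (no significant windows over 20 seeded
homogeneous-Poisson simulations).  P-values are the Poisson upper tail
P(X ≥ k | λ); BH adjustment runs across all windows genome-wide, and
windows with q ≤ 0.001 merge into peaks when separated by at most
`merge_gap` (= window size), each peak carrying its minimum window q.

Recovery is reported as a detection-level Jaccard:
recovered-truth / (n-truth + false-positive peaks).  A base-pair Jaccard
is structurally capped near 0.5 for a windowed caller (called peaks are
unions of 177-bp windows at 88-bp step, ≈ 2× wider than a planted
177-bp region) and would measure discretization, not detection.

## Differential accessibility

Two classification modes per contrast (A, B), e.g. (vehicle, T0):

- **presence** (default): *closed* = enhancer overlaps a peak in A but
  none in B; *opened* = converse; *stable* = overlaps a peak in either.
  This mirrors per-condition peak calling followed by set overlap, and
  is exactly antisymmetric under swapping the contrast.
- **counts**: per-enhancer fragment-midpoint counts per sample are
  tested with the negative-binomial Wald machinery below; *closed* =
  q < 0.05 and log2FC < 0 (B vs A).

Presence mode is faithful to peak-level bookkeeping but insensitive to
partial closure (a 2.8× drop on a strong enhancer still yields a peak);
count mode is the powered alternative and is what the planted-truth
benchmarks exercise (sensitivity ≥ 0.98, empirical FDR ≈ 0.06–0.08 at
the design point: 500/5,000 enhancers at log2FC −1.5, n = 4, dispersion
0.05).

## Differential expression

A compact stand-in for a DESeq2-class engine — deliberately without
dispersion shrinkage, outlier filtering, or fold-change shrinkage, since
the package's contribution is the integration, not the DE engine:

- size factors by median of ratios to the per-feature geometric mean
  (features nonzero in all samples); a CPM fallback is available when no
  such feature exists;
- group means m_A, m_B of normalized counts with pseudo-count 0.5;
  log2FC = log2(m_B / m_A);
- per-feature NB dispersion α by method of moments on normalized counts,
  averaged over the two groups and floored at 1e-8;
- delta-method variance of the log2 fold change,
  Var = [ (1/m_A + α)/n_A + (1/m_B + α)/n_B ] / ln(2)²,
  Wald z, two-sided normal p, BH across features.

Calibration at the simulated depths: all-null runs call ≈ 1–2% of
features at q < 0.05 (mean over 20 seeds; the moment dispersion estimate
with 3–4 replicates is noisy, which costs some calibration relative to
a shrunken estimator but stays well under control).  Median estimated
log2FC over genes planted at −1.5 (200 of 2,000 genes, mean 200, n = 3)
is ≈ −1.41: a small attenuation arising because planted down-shifts move
the normalization median of affected samples, which is why the recovery
benchmark plants the effect in a 10% minority — planting it in *all*
features would be absorbed entirely by size factors.

Gene classification: repressed/induced at q < 0.05 (optionally with a
linear fold-change filter); LPS-inducibility is the same rule applied to
a second contrast (vehicle vs LPS).  The default "T0 effect" contrast is
(LPS, T0+LPS) — the T0 effect on an LPS background — with (vehicle, T0)
equally available; every contrast is explicit in the configuration, none
is silently chosen.

## Signal tracks, metaprofiles, correlation

Coverage tracks accumulate fragment-base coverage per fixed-width bin
(default 25 bp); RPGC normalization rescales by genome length / total
fragment bases so the base-pair-weighted genome mean is exactly 1.
bedGraph records are materialized onto the bin grid by base-pair
weighted mean and written back run-length merged (zero runs omitted).

Metaprofiles sample the track in offset bins (default ±2 kb flank,
25 bp bins — not dictated by anything upstream; chosen to resolve a
177-bp feature comfortably) around region centers floor((start+end)/2),
strand-agnostically (enhancer sets carry no orientation).  Regions whose
window crosses a chromosome end are dropped and counted, not
zero-padded, to avoid edge bias.  The heat-map matrix uses the same
sampling path, so its column means equal the metaprofile exactly (bit
exact before row sorting).  Track–track correlation is the Pearson r of
per-region mean signals (≥ 3 regions, defined variance required).

## Linkage analysis

For each (gene set × enhancer set) cell: the fraction of genes whose
nearest enhancer lies within the window (default 100 kb) of the TSS, the
per-gene distance sample, and a size-matched random gene set drawn
uniformly without replacement from the gene universe (one draw by
default, as the analysis is usually displayed; more draws give a null
band).  Random sets are *not* expression-matched; this is a known
limitation.  Genes with no same-chromosome enhancer have infinite
distance: counted as unlinked in fractions, excluded from rank tests
(count reported).

Distance distributions are compared by Kruskal–Wallis with tie
correction (H defined 0 and p = 1 when all values tie) and Dunn post hoc
z-tests on pooled ranks with tie correction, Holm-adjusted (the
adjustment is configurable).  Both match independent implementations to
1e-10 on randomized small samples; under equal planted link
probabilities the Kruskal–Wallis rejection rate at α = 0.05 is ≈ 0.02–
0.04 over 50 seeds.

## Motif scanning and enrichment

PWMs are position probability matrices (rows sum to 1) scored as
log2-odds against a background composition (uniform default) after a
1e-3 pseudo-count.  Both strands are scanned (reverse-complemented
matrix on forward coordinates); windows containing N are skipped.  A
sequence hits a motif when any window reaches `threshold_frac` (default
0.8) of the motif's maximum achievable score — a simple deterministic
rule; exact score-distribution thresholds would be a natural extension.
Set enrichment compares the fraction of target vs background enhancers
with ≥ 1 hit: fold = rate ratio (0/0 undefined, x/0 infinite), one-sided
Fisher exact p, BH across motifs.  The bundled matrices are
consensus-built (strong base 0.91, IUPAC degeneracy split evenly), not
database-fitted: DR4/LXRE (AGGTCAnnnnAGGTCA), NR half-site (AGGTCA),
NF-κB (GGGRNNYYCC), AP-1 (TGASTCA).  Note the enrichment design uses the
full enhancer set as background, so a target that is a subset of the
background dilutes its own fold (planted 30% vs 2% yields fold ≈ 5–6,
not 15).

## The synthetic study

The generator emulates a four-condition macrophage design — vehicle, T0,
LPS, T0+LPS — with 4 ATAC and 3 RNA replicates per condition.  Defaults
(one set of study conditions, fixed):

| parameter | default | meaning |
|---|---|---|
| genome | 4 × 10 Mb | uniform-random sequence |
| n_enhancers / enhancer_length | 300 / 500 bp | non-overlapping placements |
| decoy_frac | 0.3 | accessible regions outside the marked set (capture ≈ 0.7) |
| marked_extra_frac | 0.2 | marked regions with no accessibility |
| frac_closed / frac_opened | 0.20 / 0.10 | T0-affected enhancer fractions |
| lfc_access | −1.5 | log2 effect on closed enhancers (opened get +1.5) |
| mean_fragments_per_enhancer | 100 | NB mean per sample |
| background_fragment_rate | 5e-5 /bp | scattered fragments per sample |
| nb_dispersion | 0.05 | NB dispersion (ATAC and RNA) |
| chip_enrichment_fold / halfwidth | 8 / 500 bp | triangular bump at ChIP+ enhancers |
| chip_background_rate | 0.02 | ChIP+ rate among non-closed enhancers |
| n_genes / rna_mean / lfc_expr | 1000 / 200 / 1.5 | expression design |
| frac_repressed / frac_induced | 0.15 / 0.15 | planted DE fractions |
| lps_inducible_frac | 0.6 | repressed genes also LPS-inducible |
| link_prob_target / background | 0.8 / 0.2 | TSS-within-100-kb plant probabilities |
| motif_plant_rate_target / background | 0.30 / 0.02 | DR4 plants in closed vs other enhancers |

Gene placement makes the link probabilities exact by construction: a
"linked" gene's TSS is uniform within 100 kb of a uniformly chosen
target enhancer; an "unlinked" gene is rejection-sampled until it is
more than 100 kb from *every* affected enhancer.  The 4 × 10 Mb genome
keeps that rejection step feasible (affected windows cover ≈ 30% of the
genome).  One global seed drives everything through fixed per-stream
sub-generators, so outputs are byte-identical across runs and each stage
is independently reproducible.

What the generator does **not** model — and hence what passing tests do
not establish about real data: sequencing error and GC bias,
fragment-length distributions (fixed 100 bp), genome composition and
repeats, dispersion trends with expression level, correlated enhancer
modules, expression-matched null gene sets, trans effects, and any
batch structure.  The benchmarks demonstrate that each algorithm
recovers what was planted under its own model assumptions, not that the
model captures real chromatin biology.

## Numerical and design notes

- Empty-set conventions: capture/overlap fractions of an empty set are
  NaN (reported as undefined, never silently 0); empty fragment sets
  yield empty peak sets without error.
- BH is a step-up with monotonization, applied genome-wide per pooled
  window set (peaks) or per feature set (DE, motifs).
- Benchmarks and the acceptance script share one code path
  (`cislink.benchmarks`), and all of their randomness derives from the
  caller's seed; reduced problem sizes (2 × 3 Mb, 60 enhancers,
  120 genes) are used for the end-to-end determinism check, full default
  sizes for recovery checks.
- The run summary JSON embeds the resolved configuration and SHA-256
  hashes of every declared input; deterministic serialization makes
  re-runs byte-comparable.
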