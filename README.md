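# cislink

Integration toolkit for chromatin accessibility and gene expression in a
multi-condition stimulation design, built around the question of *cis*
regulation by a nuclear receptor: when a ligand (here the LXR agonist
T0901317, "T0") closes or opens enhancers, are the genes it represses or
induces sitting next to those enhancers?

The package implements, as a tested and reusable pipeline:

- **Peak calling** on ATAC-style fragment intervals with a local-Poisson
  sliding-window model: fragment midpoints are counted in 177-bp windows
  (88-bp step), scored against λ = max of 1 kb / 10 kb / genome-wide
  background rates (focal window excluded), with Benjamini–Hochberg
  control at q ≤ 0.001 and merging of significant windows.
- **Enhancer filtering**: restriction of peaks to histone-marked
  (H3K27ac/H3K4me2-style) enhancer annotations, with the capture
  fraction reported.
- **Differential accessibility classification** of enhancers into
  *closed* / *opened* / *stable* per condition contrast, in two modes:
  peak presence/absence, or a negative-binomial count test.
- **Signal tracks and metaprofiles**: RPGC-normalized (1× coverage)
  tracks, bedGraph I/O, ChIP signal histograms and heat-map matrices
  centered on enhancer sets, and track–track correlation.
- **Differential expression**: a compact negative-binomial Wald test
  (median-of-ratios size factors, method-of-moments dispersion, BH
  adjustment) with gene classification at 5% FDR.
- **Enhancer–gene linkage**: for each gene set, the fraction of genes
  with an enhancer of a given class within 100 kb of the TSS, compared
  against size-matched random gene sets; nearest-enhancer distance
  distributions compared by tie-corrected Kruskal–Wallis with Dunn post
  hoc (Holm-adjusted).
- **Motif enrichment**: log-odds PWM scanning (both strands) and
  target-vs-background hit-rate enrichment by one-sided Fisher exact
  test; bundled consensus matrices for the DR4 response element
  (AGGTCAnnnnAGGTCA), the AGGTCA half-site, NF-κB and AP-1.
- **A synthetic-data generator** that plants all of the above — enhancer
  closure/opening, coincident ChIP bumps, DE genes preferentially placed
  within 100 kb of affected enhancers, motif instances in affected
  enhancer sequences — under one seed, so every stage can be scored
  against known truth.

## Worked example

Simulate a reduced study (2 × 3 Mb genome, 60 enhancers, 120 genes;
four conditions — vehicle, T0, LPS, T0+LPS — with 4 ATAC and 3 RNA
replicates), run the pipeline in count mode, and score it against the
planted truth:

```bash
cat > sim.yaml <<EOF
genome: [[chr1, 3000000], [chr2, 3000000]]
n_enhancers: 60
n_genes: 120
seed: 11
EOF
cislink simulate --config sim.yaml --outdir simdata

python - <<EOF
import yaml
from cislink.pipeline import config_for_dataset
cfg = config_for_dataset("simdata", "out", seed=11, mode="counts")
yaml.safe_dump(cfg.to_dict(), open("run.yaml", "w"))
EOF
cislink run --config run.yaml
cislink score --run-dir out --truth simdata/ground_truth.json
```

The score report (abridged) reads:

```json
{
 "closed_enhancers": {"n_predicted": 11, "n_true": 12,
                      "sensitivity": 0.917, "fdr": 0.0},
 "repressed_genes":  {"n_predicted": 21, "n_true": 18,
                      "sensitivity": 1.0, "fdr": 0.143},
 "linkage": {
  "repressed|closed":        {"observed": 0.667, "planted": 0.8},
  "random_repressed|closed": {"observed": 0.381, "planted": 0.2}
 }
}
```

11 of the 12 planted closed enhancers are recalled with no false calls;
all 18 planted repressed genes are found (3 extra calls at q < 0.05).
Two-thirds of repressed genes have a closed enhancer within 100 kb of
their TSS versus ~0.38 of a size-matched random gene set — at this small
size (18–21 genes per set) the binomial noise around the planted 0.8 /
0.2 probabilities is large; the default study size (300 enhancers, 1,000
genes on 4 × 10 Mb) recovers both within a few points.  The run summary
(`out/summary.json`) also records that the simulated ChIP metaprofile
over called-closed enhancers peaks at 7.81× baseline at the central bin,
and that 62% of repressed genes are LPS-inducible (0.6 planted).

`cislink run` works equally on real data: fragments as BED, enhancer
annotations as BED, ChIP as bedGraph, expression as a counts TSV plus
sample sheet, TSS as TSV, motifs in a plain PWM text format.

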