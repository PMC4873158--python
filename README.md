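# pathconcord

Cross-cohort analysis of immune-pathway transcription in blood: are the same
pathways dysregulated, in the same direction, across related diseases?

`pathconcord` is a tested, reusable implementation of the analysis chain used
to compare peripheral-blood expression profiles of the Toll-like receptor
(TLR), T-cell receptor (TCR) and B-cell receptor (BCR) signaling pathways
across atherosclerosis-spectrum cohorts (asymptomatic atherosclerosis,
ischemic stroke, and a paired two-timepoint myocardial-infarction study),
together with the DNMT1 regulator analysis. It works on any combination of
unpaired case/control and paired two-timepoint expression studies with any
gene sets, and it ships a synthetic multi-cohort generator with planted
ground truth so every stage is testable without external data.

## What it computes

Given per-study expression matrices (TSV or GEO series-matrix text), sample
annotations and gene sets (GMT):

1. **Ingestion** — quantile normalization (every sample is forced onto the
   mean order-statistic distribution) and probe→gene collapsing that keeps,
   for each gene, the probe with the most significant differential
   expression.
2. **Differential expression** — per-gene Welch *t* (case − control) or
   paired *t* on within-subject late − early differences.
3. **Permutation pathway enrichment** — for each gene set, the count *k* of
   mapped members with *p* < α, against a null built by permuting group
   labels (or sign-flipping paired differences) and recomputing every
   per-gene test; `perm_p = (1 + #{k_null ≥ k_obs}) / (B + 1)`.
4. **Cross-study concordance** — Pearson correlation of per-gene *t*
   statistics between study pairs within each set, with the analytic
   *p* from `t = r·√((n−2)/(1−r²))`.
5. **Co-expression networks** — soft-thresholded adjacency
   `a_ij = |cor(x_i, x_j)|^β` (β chosen by scale-free fit), topological
   overlap

   `TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(K_i, K_j) + 1 − a_ij)`,

   per-gene TOM connectivity `k_i = Σ_{j≠i} TOM_ij` (the hub statistic),
   edge calling by top-quantile and/or permutation FDR
   (Benjamini–Hochberg on pooled empirical *p*), and the correlation of
   connectivity with −log₁₀ *p* of differential expression.
6. **Regulator analysis** — Pearson correlation of a designated regulator
   transcript (e.g. DNMT1) with every pathway gene, per-set sign summaries,
   and the regulator's own differential expression.

## Worked example

Simulate the built-in three-cohort design (two unpaired cohorts, one paired
18-subject cohort; TLR-like set planted up, TCR/BCR-like sets planted down;
a DNMT1-like regulator planted down and factor-coupled −/+/+ to the three
sets) and run the full pipeline:

```bash
pathconcord simulate --seed 7 --out data/
cat > run.yaml <<EOF
studies:
  - {name: atherosclerosis, expr: data/atherosclerosis.expr.tsv, samples: data/atherosclerosis.samples.tsv}
  - {name: stroke,          expr: data/stroke.expr.tsv,          samples: data/stroke.samples.tsv}
  - {name: mi,              expr: data/mi.expr.tsv,              samples: data/mi.samples.tsv}
gmt: data/genesets.gmt
out_dir: out
seed: 7
regulator: DNMT1
EOF
pathconcord run --config run.yaml
```

`out/report.json` from this exact run contains (abridged):

```
enrichment grid        atherosclerosis   stroke           mi
  TLR                  65/106 (61%)      64/106 (60%)     24/106 (23%)
  TCR                  68/104 (65%)      58/104 (56%)     27/104 (26%)
  BCR                  51/72 (71%)       51/72 (71%)      46/72 (64%)
concordance r ranges   TLR 0.50–0.74   TCR 0.66–0.76   BCR 0.61–0.83
connectivity vs -log10(p)   athero r=0.76   stroke r=0.75   mi r=0.57
DNMT1                  decreased in all three (p = 2.9e-4, 1.1e-4, 5.5e-2)
```

Reading this: each enrichment cell is *k/m* — significant over mapped set
genes — with its permutation *p* in the TSV outputs; the concordance ranges
say the per-gene *t* statistics of each pathway agree strongly across all
three cohorts (the planted truth); the connectivity–significance
correlations show that hub genes of the co-expression network are also the
most differentially expressed; and the planted down-regulated regulator is
recovered in all cohorts (weakest in the 18-pair study, as expected from
its size).

Per-study TSVs (`de.tsv`, `edges.tsv`, `nodes.tsv`, `regulator.tsv`,
scatter tables for every concordance panel) land next to the report.

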