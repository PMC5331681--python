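# occutarget

Call direct targets of a transcriptional corepressor by integrating
replicated ChIP-seq peak calls with differential-expression data.

Corepressors such as Groucho/TLE do not bind DNA themselves: they are
recruited by sequence-specific repressors and can act over long distances,
so their ChIP-seq peaks sit upstream of, inside, and sometimes far from the
genes they silence.  Differential expression after perturbing the
corepressor is equally ambiguous on its own, because severe developmental
perturbations produce large numbers of indirect expression changes.
`occutarget` combines the two: binding evidence is converted into a
per-gene **occupancy score** with a shallow logistic distance decay (so
distal sites still count), and the score is calibrated against the
expression response to separate direct targets from bystanders.

It is intended for genomicists analyzing factor-perturbation studies —
peak calls per timepoint and replicate (BED6/narrowPeak), gene models
(GTF/BED12), DESeq2-style DE tables (TSV), and stranded bedGraph coverage
of chromatin-associated RNA.

## The model

**Occupancy score.**  For gene *g* and peak *P*, every basepair *x* of the
peak contributes

```
s(x) = 1                                   if x lies inside the gene span
s(x) = 1 / (1 + exp(k (d(x) - d_half)))    otherwise
```

where *d(x)* is the distance from *x* to the nearest end of the gene,
*k* = 5×10⁻⁴ per bp and *d_half* = 15 bp.  The peak's score is the mean of
its per-base contributions, and the gene's occupancy score is the sum over
nearby peaks.  The decay is deliberately shallow: a base 2 kb away still
contributes ≈ 0.27, encoding long-range corepressor action.

**Target calling.**  Genes are ranked by score, and for a progressively
relaxing score cutoff the number of genes that are also down-regulated upon
corepressor overexpression (|log₂FC| ≥ 0.5, padj < 0.05) is traced out — a
*response curve*.  The same curve on 100 random gene sets of matched size
gives the chance baseline.  A continuous two-segment piecewise-linear fit
locates the change of slope; where it is clearly evident (≥ 20% SSE
improvement over a single line and ≥ 2× the baseline at the breakpoint) the
cutoff at the breakpoint defines the high-confidence target set.  Union
over timepoints gives the final call.

**Supporting analyses.**  Replicate-reproducible peak derivation (≥ 1 bp
overlap), temporal membership classes, nearest-gene assignment, feature
annotation, a Monte Carlo null for peaks-per-gene clustering, and
promoter-proximal pausing analysis (proximal/body density ratios, metagene
profiles, permutation and hypergeometric enrichment tests).

A synthetic-data generator (`occutarget.synthetic_data`) produces complete
studies — annotation, peaks, DE tables, coverage — with a ground-truth
ledger, so every stage is testable without external downloads.

## Worked example

```python
from occutarget.synthetic_data import SimulationConfig, simulate_dataset
from occutarget.pipeline import call_targets_from_dataset, reproducible_sets
from occutarget import peak_analysis as pa, pausing_analysis as pz

ds = simulate_dataset(SimulationConfig.default(seed=1))
sets = reproducible_sets(ds.peaks)
summ = pa.classify_temporal(sets)
print(f"temporal classes: {summ.n_regions} regions, "
      f"{summ.unique_fraction:.1%} unique, {summ.constitutive_fraction:.1%} constitutive")

scores, res = call_targets_from_dataset(ds, n_reps=100, seed=1)
for tp, (curve, call) in res.per_timepoint.items():
    thr = f"{call.threshold_score:.3f}" if call.detected else "none detected"
    print(f"{tp}: score threshold {thr}, {len(call.targets)} targets")
print(f"union: {len(res.union)} high-confidence targets")

table = pz.pausing_table(ds.genes, ds.coverage)
enr = pz.compare_sets(table, res.union, {g.gene_id for g in ds.genes},
                      n_perm=999, seed=1)
print(f"pausing enrichment: +{enr.statistic:.2f} log2 ratio, p = {enr.p_value:.3g}")
```

prints

```
temporal classes: 378 regions, 52.4% unique, 11.4% constitutive
t1: score threshold 0.528, 20 targets
t2: score threshold 0.711, 43 targets
t3: score threshold 0.690, 37 targets
union: 52 high-confidence targets
pausing enrichment: +2.10 log2 ratio, p = 0.001
```

The simulated study plants 50 down-regulated target genes with clustered
peaks among 2000 genes; the per-timepoint thresholds are the detected
inflection points of the response curves, and the 52-gene union recovers 47
of the 50 planted targets.  The called set is strongly enriched for
promoter-proximal transcript density (the planted pausing signal), with the
smallest p-value 999 permutations can report.

The same steps are available from the shell:

```
occutarget simulate --preset default --seed 1 --out sim/
occutarget score --peaks sim/peaks_t2_r1.bed --genes sim/genes.gtf --out scores_t2.tsv
occutarget call-targets --scores t1.tsv t2.tsv t3.tsv --de sim/de_t1.tsv sim/de_t2.tsv sim/de_t3.tsv
```

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
synthetic-data generator, numerical choices, and known limitations.
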