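# arcc

Analysis toolkit for **ARC-C** (Accessible Region Conformation Capture), a
proximity-ligation assay that uses light DNase I digestion to bias chromatin
contacts toward accessible, regulatory chromatin. Starting from aligned
paired-end reads, the package classifies read pairs, builds and normalizes
contact matrices, calls significant interactions between regulatory-element
sized (~500 bp) bins, aggregates contact signal over binding sites and
chromatin domains, compares genotypes, and relates promoter–promoter
interactions to gene co-expression. A seeded simulator with planted
structure makes every stage testable without sequencing data.

Intended users: genomicists analyzing ARC-C (or similar accessibility-biased
3C) libraries, and method developers who need a transparent, testable
reference implementation of the statistical pipeline.

## The statistical core

ARC-C coverage is intentionally non-uniform: open chromatin is
over-represented, and part of that enrichment *is* the signal. Plain matrix
balancing would flatten it away, so interaction calling corrects for
representation with a per-interval **visibility** factor derived from
"off-peak" coverage (contacts whose partner is not a top-decile-coverage
interval):

    v_i = (c_offpeak,i / median(c_offpeak,·))^0.87

where 0.87 is the exponent at which reciprocal powered coverage best
approximates true matrix-balancing correction factors (the package can
re-estimate it on any dataset, `matrix.estimate_correction_exponent`).
Intervals in the bottom coverage decile are removed; the top decile are the
"peaks" excluded from off-peak coverage.

Distance-dependent background contact frequency `F(d)` is fitted per
chromosome as a cubic smoothing spline in log–log space over 1 kb – 1 Mb, in
two passes so that genuine interactions do not inflate the background. The
observed count of an interval pair is then tested against

    n_ij ~ Binomial(N, f_ij),   f_ij = v_i · v_j · F(d_ij)

with `N` the chromosome's total cis-informative contacts, one-sided
p-values, Benjamini–Hochberg correction over all tested pairs, and a
post-filter requiring support by more than five read pairs.

Aggregate analyses (binding-site ACA/APA at 1 kb and 10 kb, domain and
compartment strength on scaled 19×19 grids at 5 kb) run on Knight–Ruiz
balanced, decay-normalized maps, with permutation nulls matched on distance
and end accessibility, HOT-interval filtering, and residual-bootstrap
comparison of genotypes.

## Worked example

Simulate an ARC-C library with 50 planted 8-fold interactions, then run the
full calling pipeline:

```python
import numpy as np
from arcc import simulate, pairs, binning, matrix, calling

cfg = simulate.SimConfig(
    seed=7, chrom_sizes={"chrS1": 2_000_000}, n_pairs=500_000,
    re_density=0.0, bias_lognorm_sigma=0.5,
    n_loops=50, loop_fold=8.0, loop_distance_range=(2_000, 50_000),
)
ann = simulate.simulate_annotation(cfg)
reads, truth = simulate.simulate_pairs(cfg, ann)

labeled, stats = pairs.classify_pairs(reads, cfg.chrom_sizes)
labeled, stats = pairs.deduplicate(labeled)
print("pair classes:", {k: v for k, v in stats.counts.items() if v})

cis = labeled[labeled["label"] == "cis_informative"]
bins = binning.make_fixed_bins(cfg.chrom_sizes, 500)
cm = matrix.count_contacts(cis, bins)
vis = calling.compute_visibility(cm, alpha=0.87)
decay = matrix.fit_distance_decay(cm, d_min=1_000, d_max=1_000_000, visibility=vis)
calls = calling.call_interactions(cm, vis, decay, fdr_level=0.05, support_min=5)
print(f"significant interactions: {int(calls['passed'].sum())}")

report = simulate.evaluate_recovery(calls, truth, bins)
print(f"planted: {report['n_planted']}  recovered: {report['n_called']}  "
      f"sensitivity: {report['sensitivity']:.2f}  FDP: {report['fdp']:.3f}")
```

Output:

```
pair classes: {'duplicate': 4, 'valid_noninformative': 107952, 'cis_informative': 392044}
significant interactions: 10
planted: 50  recovered: 10  sensitivity: 0.20  FDP: 0.000
```

All ten passing calls are planted interactions (FDP 0): at this modest depth
the caller recovers the strongest (shortest-range) planted loops and nothing
spurious. Deeper libraries recover more (`arcc.benchmarks.fdr_benchmark`
measures both quantities under the reference conditions).

The same pipeline is available from the shell:

```sh
arcc sim --seed 7 --n-pairs 500000 --n-loops 50 --out-prefix sim
arcc pairs classify --pairs sim.pairs.tsv --sizes sim.chrom.sizes --out classified.tsv
arcc call --pairs classified.tsv --sizes sim.chrom.sizes --out calls.tsv
```

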