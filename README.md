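# myorra

Meta-analysis of differential expression across heterogeneous RNA-Seq
datasets by robust rank aggregation (RRA), plus the regulatory-genomics
analyses that build on the resulting robust gene sets: transcription-factor
co-binding classification, motif-dependence inference, permutation-based
interval enrichment, GREAT-style region-to-gene annotation, and anchored
coverage metaprofiles. Everything is exercisable end-to-end on synthetic
data with planted ground truth, so the statistical machinery can be
validated without downloading any public dataset.

## Who this is for

Comparing myoblast-to-myotube (MB → MT) differentiation — or any two-state
contrast — across many published RNA-Seq datasets runs into batch effects:
each dataset yields a different DEG list, and intersecting the lists
discards most true signal. RRA instead ranks every gene in every dataset by
effect size and asks how improbably high a gene's ranks are under a null of
independent random orderings. The toolkit is for computational biologists
who want that integration step, and the downstream ChIP-seq-style interval
statistics, as a tested Python library with a CLI.

## The statistic

For a gene with normalised ranks `r_(1) ≤ … ≤ r_(n)` across `n` datasets
(rank position divided by the number of genes; 1.0 when the gene is absent
from a list), the score is

```
ρ = min_k  P( Beta(k, n−k+1) ≤ r_(k) )
  = min_k  Σ_{j=k}^{n} C(n,j) · r_(k)^j · (1−r_(k))^{n−j}
```

the probability that the k-th smallest of n independent Uniform(0,1) ranks
would be at most `r_(k)`. The reported per-gene p-value is the Bonferroni
correction `min(1, n·ρ)`. A robust DEG additionally requires the median
across-dataset log2 fold change to exceed the fold-change cutoff
(defaults: corrected p < 0.01 and |log2FC| > 1, i.e. |FC| > 2).

The interval statistics are: peak-level overlap fractions and the
A+B+/A+B−/A−B+ co-binding partition; log-odds PWM scanning to measure per-
class motif fractions and classify a TF pair as binding independently or
via the partner's motif; length-preserving uniform shuffles giving a
permutation null for fold enrichment (`observed / mean(null)`); basal
(−5 kb/+1 kb around the TSS) regulatory domains extended up to 1 Mb toward
neighbouring genes for site-to-gene association; and hypergeometric term
enrichment with Benjamini–Hochberg adjustment.

## Worked example

Generate a fully synthetic study (3 datasets, 300 genes, 30 planted
up- and 30 down-regulated genes), run differential expression and RRA, and
validate the robust calls against the planted truth:

```yaml
# cfg.yaml
seed: 3
stages: [simulate, de, rra, validate]
sim: {n_genes: 300, n_datasets: 3, n_true_up: 30, n_true_down: 30}
```

```
$ myorra run --config cfg.yaml --out-dir out
```

`out/validation.json` then reports how many robust calls are planted truth.
The simulated peak files support the interval statistics; with the files a
full default run writes (`tfA.bed`, `tfB.bed` with a designed 80 % overlap,
`se_like.bed` planted at 3-fold enrichment over `tfA`):

```
$ myorra overlap --a out/tfB.bed --b out/tfA.bed
400/500 peaks of tfB overlap tfA (80.0%)

$ myorra enrich --target out/tfA.bed --annotation out/se_like.bed \
      --genome out/chrom.sizes --n-perm 200 --seed 4 --out out/enr.tsv
fold=3.304 (observed 424, null mean 128.34, p=0.004975)
```

The overlap line says 400 of the 500 tfB peaks share ≥ 1 bp with a tfA
peak — recovering the designed 0.8 overlap fraction. The enrichment line
says 424 of the 800 SE-like intervals touch a tfA peak, against a mean of
128 under 200 random re-placements: a 3.3-fold enrichment with an empirical
p of ~0.005, recovering the planted 3-fold signal.

In the library, the aggregation score is one call:

```python
>>> from myorra.rra import rho_score
>>> rho_score([0.1, 0.2])     # a gene ranked in the top 10% and top 20% of two lists
(0.04, 0.08)                  # (rho, Bonferroni-corrected p)
```

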