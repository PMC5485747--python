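# emtint — multi-study expression integration for phenotype contrasts

`emtint` is a tested, reusable pipeline for integrating gene-expression
matrices from multiple independent studies to find genes that separate two
cell phenotypes — epithelial vs mesenchymal — consistently across studies,
platforms and tissue types. It is aimed at computational biologists who
have several already-processed (probe-collapsed, log-scale) expression
matrices plus per-sample phenotype labels, and who need the cross-study
batch structure handled before any differential-expression claim is
credible.

## What it computes

Given studies merged over their common gene set, the pipeline applies four
correction schemes and aggregates the evidence:

* **QN** — quantile normalization: every sample mapped onto the reference
  distribution given by row means of the column-sorted matrix.
* **SVA** — surrogate variable analysis: hidden confounders estimated as
  the leading singular vectors of the matrix residualized on the phenotype
  (the number of factors chosen by permutation parallel analysis), then
  removed by regression with the phenotype term protected.
* **QN + SVA** — the composition of the two.
* **MCtr** — per-study column standardization followed by gene-wise median
  centering, merged afterwards.

Per scheme, each gene g is tested with an equal-variance two-sample t-test
of H₀: μ_epi(g) = μ_mes(g), with Bonferroni and Benjamini–Hochberg
adjustment and log2 fold change Δ(g) = mean_epi − mean_mes. Genes are
ranked by raw p per scheme and the **consensus rank** is the per-gene mean
of the four ranks. Candidates are the top consensus genes passing
|FC| > 1.2 and BH-FDR < 0.005 in SVA, QN+SVA and MCtr simultaneously.

How well each scheme restores phenotype grouping is scored by the
**Baker–Hubert gamma index**, BH = (S⁺ − S⁻)/(S⁺ + S⁻), counting
within-phenotype vs between-phenotype sample-distance comparisons (1 =
perfect grouping, 0 = none). Candidate genes are then screened for
residual co-expression structure with an unsigned weighted network
(adjacency |corr|^β, scale-free β selection, topological overlap,
average-linkage clustering with minimum module size 15, module
eigengenes), and for gene-set enrichment with a right-tailed Fisher's
exact test over the common-gene background.

A synthetic multi-study generator with known ground truth (planted
differential genes, per-(gene, study) batch effects, platform scale/shift,
technical replicates, per-study gene dropout) drives validation; every
statistical primitive is checked against an independent oracle
(brute-force enumeration, exact rational tail sums, closed forms).
See `docs/methods.md` for the full model description.

## Worked example

```python
from emtint import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(outdir="example_run", seed=7))
print(manifest["stages"]["merge"]["n_common_genes"])
print({m: round(v, 3) for m, v in manifest["stages"]["cluster_evaluation"].items()})
rec = manifest["stages"]["candidates"]["recovery"]
print({k: round(v, 3) if isinstance(v, float) else v for k, v in rec.items()})
```

prints (default configuration: six simulated studies, 2000 genes, 10%
differential at ~1 log2 unit, batch noise twice the measurement noise):

```
1476
{'NONE': 0.101, 'QN': 0.145, 'SVA': 0.816, 'QN_SVA': 0.796, 'MCtr': 0.72}
{'n_candidates': 66, 'n_true': 200, 'n_hits': 65, 'precision': 0.985, 'recall': 0.325}
```

Reading: 1476 of 2000 genes survive the per-study 5% dropout intersection.
On uncorrected data the Baker–Hubert index is ~0.10 — samples group by
study, not phenotype. Surrogate-variable correction lifts it to ~0.8
(five surrogate variables, matching the six-study batch structure), with
quantile normalization alone barely helping — the qualitative pattern
expected when latent per-gene batch effects, not distributional
differences, dominate. Of the 66 genes passing all consensus filters, 65
are truly differential (precision 0.985); recall is limited by the strict
FDR < 0.005-in-three-schemes rule, which only strong effects survive at
these sample sizes. Every intermediate (normalized matrices, per-scheme DE
tables, consensus ranking, concordance matrix, module assignments,
enrichment table) is written to `example_run/` as TSV with a checksummed
JSON manifest.

The same workflow is scriptable from the shell:

```sh
emtint run --config run.yaml          # full pipeline from a YAML config
emtint simulate --seed 7 --outdir sim # generator only, with ground truth
emtint normalize --method qn+sva ...  # individual stages, re-runnable
emtint de ... / cluster-eval ... / modules ... / enrich ...
```

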