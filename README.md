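# mirmaster

Network-based identification of subtype-specific **master-regulator miRNAs**
from matched miRNA and mRNA expression cohorts, with downstream target
prioritization and clinical/pharmacological relevance scoring.

The motivating setting is the squamous subtype of pancreatic ductal
adenocarcinoma (PDAC): a minority subtype with poor prognosis in which a
handful of miRNAs, silenced specifically in those tumors, de-repress a
program of target genes. `mirmaster` reconstructs that regulatory program
from expression data alone and scores its genes as prognostic and predictive
biomarkers. A seeded synthetic-cohort generator with planted ground truth
makes every stage testable end to end.

## The method

Given a feature × sample log2 miRNA matrix, a gene matrix and a two-group
subtype labelling:

1. **Differential expression** — an empirical-Bayes moderated t per feature
   (per-feature variances shrunk toward a prior fitted by moment matching),
   Benjamini–Hochberg correction. Candidate *regulators* are miRNAs with
   adj. p < 0.05 and log2 FC < −0.5; candidate *targets* are genes with
   adj. p < 0.05 and log2 FC > 0.25.
2. **Network inference** — mutual information I(m; g) on equal-frequency
   bins of ranks (⌈√n⌉ bins, nats) for every regulator–target pair, filtered
   in three stages: a per-regulator permutation null (pooled over targets),
   a bootstrap stability filter (edges must beat a per-resample permutation
   threshold in ≥ 95% of resamples), and data-processing-inequality (DPI)
   pruning: in every (m₁, m₂, g) triplet the weakest of the three MI values,
   if it is a regulator–target edge, is marked as indirect and removed.
3. **Master regulator analysis (MRA)** — for each regulon R with |R| > 15,
   the upper-tail hypergeometric probability

   P(X ≥ k), X ~ Hypergeom(N = |universe|, K = |signature ∩ universe|, n = |R|)

   where k counts signature genes inside the regulon; BH over tested
   regulons.
4. **Target prioritization** — the four-set intersection of regulon,
   signature, and two physical target-prediction databases, annotated with
   the Spearman ρ between miRNA and gene (true targets are inversely
   correlated); plus a promoter-methylation screen for the regulators
   themselves.
5. **Clinical and drug relevance** — per prioritized gene: quantile-split
   Kaplan–Meier + log-rank, univariate Cox proportional hazards (Efron
   ties, damped Newton); and on cell lines: median-split Welch t-tests on
   IC50 plus the Mann–Whitney AUC of expression for predicting drug
   resistance (IC50 above the mean).

## Worked example

```python
from mirmaster import SimulationConfig, NetInfParams
from mirmaster.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="run",
    simulation=SimulationConfig(seed=1),   # 149 samples, 31 squamous,
    net=NetInfParams(n_perm=250),          # 44 miRNAs, 1486 genes
    seed=1,
)
report = run_pipeline(cfg)
print(report.counts)
```

prints

```
{'mirnas_selected': 8, 'genes_selected': 481,
 'edges_after_permutation': 80, 'edges_after_bootstrap': 80,
 'edges_after_dpi': 80, 'regulons_tested': 2, 'masters_called': 2,
 'targets_prioritized': 23, 'genes_survival_screened': 23, 'drug_tests': 184}
```

and `run/mra.tsv` holds the enrichment table:

```
regulator  universe_size  regulon_size  total_hits  expected_hits  observed_hits        p     adj_p
miR-039    481            40            46          3.83           14             0.000003  0.000006
miR-009    481            40            46          3.83           9              0.008537  0.008537
```

Both planted master miRNAs are recovered (the cohort's ground truth is in
`run/inputs/truth.json`): their regulons of 40 genes contain 14 and 9
signature genes where ~3.8 would be expected by chance. `run/targets.tsv`
lists the prioritized direct targets with their inverse correlations
(ρ ≈ −0.91 for the strongest pairs), and `run/survival_screen.tsv` their
hazard ratios (e.g. `GENE00009  HR 1.54 [1.24–1.90], p = 7.5e-05`) — higher
target expression, worse survival, as planted.

The same workflow is available from the shell:

```sh
mirmaster simulate --out cohort --seed 1
mirmaster de --expr cohort/mirna_expr.tsv --labels cohort/annotation.tsv --out de_mirna.tsv
mirmaster net --reg sel_mirna.tsv --tgt sel_genes.tsv --seed 1 --out net.json
mirmaster mra --net net.json --signature cohort/signature.gmt --out mra.tsv
mirmaster run --config pipeline.yaml
```

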