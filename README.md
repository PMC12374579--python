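# depselect

Ensemble differential-protein discovery for label-free DIA proteomics.

Small-n quantitative proteomics experiments (typically n = 5 biological
replicates per group) produce protein-group intensity matrices with
intensity-dependent missingness and batch structure. `depselect` implements
a multi-stage procedure for calling differentially expressed proteins
(DEPs) between two groups from such a matrix:

1. **Imputation** — each missing cell of protein *p* is filled with
   min(observed values of *p*) − 0.05 on the log2 scale, placing imputed
   values just under the protein's detection floor (missingness in DIA is
   censoring of low intensities, not random).
2. **Three normalization branches**, run in parallel: *mean* (each sample
   centered on the grand mean), *ratio* (log-ratio to a per-protein
   reference profile) and *binomial* (dichotomization at the per-protein
   median into over/under categories).
3. **Attribute-weighting ensemble** — ten relevance criteria per
   continuous branch (information gain, information-gain ratio, χ²,
   deviation, rule, Gini index, Relief, linear-SVM |coefficient|,
   symmetric uncertainty, PCA loading) and the seven that accept
   categorical features on the binomial branch. Each criterion's weights
   are min-max scaled and thresholded into binary votes; votes are pooled
   over algorithms × branches into a cumulative score (max 27) and the
   **top 200** proteins are kept.
4. **Recursive feature elimination** under three ranking models (L2
   logistic regression, random forest Gini importance, linear SVM), with
   leave-one-out accuracy curves; the per-model optimal subsets are
   combined by intersection and union.
5. **Two-pass Mann-Whitney U validation** — an exact two-sided U test
   (p < 0.05, no multiple-testing correction) filters the candidates, the
   RFE subset and the significant set are merged with provenance flags, and
   a second pass on the merged list produces the final DEP table.
6. **Reporting** — per-protein z-scores ((x − mean)/sd, mean 0 / sd 1) for
   heatmaps, plain gene lists and a signed −log10(p) ranked list for
   network and enrichment tools.

A synthetic spike-in generator (`depselect.simulate`) emulates the target
data regime — ~2,000 log-normal protein groups, 5 replicates per group in
three batches, a configurable spiked-DEP fraction and fold change, additive
batch shifts and logistic MNAR dropout — and scores recovery (sensitivity
and false-discovery proportion) of any caller against known ground truth.

The selection stages are scikit-learn estimators (`MinObservedImputer`,
`EnsembleAttributeWeighter`, `ModelRFE`, …) and compose with sklearn
pipelines; the module-level functions wrap them for the proteins × samples
orientation used on disk.

## Worked example

```sh
depselect run --config config.yaml
```

with `config.yaml`:

```yaml
seed: 7
outdir: demo_run
synthetic: {n_proteins: 300, dep_fraction: 0.05}
ensemble: {top_k: 50}
```

prints the per-stage counts of the run (values from this exact config):

```json
{
  "batches_flagged": 0,
  "final_deps": 17,
  "first_pass_significant": 17,
  "genes_exported": 17,
  "merged": 17,
  "proteins_after_filters": 270,
  "proteins_dropped_all_missing": 0,
  "proteins_dropped_incomplete": 30,
  "proteins_in_input": 300,
  "rfe_fallback_to_union": false,
  "rfe_intersection": 0,
  "rfe_union": 2,
  "samples_after_batch_filter": 10,
  "samples_in_input": 10,
  "top_k": 50,
  "vote_columns": 27
}
```

Reading: of 300 simulated proteins, 30 were observed in fewer than half the
samples of both groups and dropped; the 27 pooled votes selected a
50-protein candidate set; RFE's three models agreed on a 2-protein core
(union), 17 candidates passed the first exact U test at p < 0.05, and all
17 survived the second pass — the final DEP table
(`demo_run/dep_table.tsv`) lists each with effect direction, both p-values
and which branch selected it. Scoring against the generator's truth table:

```sh
depselect recover --dep demo_run/dep_table.tsv --truth demo_run/truth.tsv
```

```json
{
  "by_branch": {"ensemble": 17, "mwu1": 17, "rfe": 2},
  "false_discovery_proportion": 0.35294117647058826,
  "n_called": 17,
  "n_true": 15,
  "sensitivity": 0.7333333333333333
}
```

Eleven of the fifteen spiked proteins are recovered; the false calls are
null proteins whose chance separation at n = 5 per group survives the
uncorrected p < 0.05 gates — see `docs/methods.md` for why this
selection-bias FDP is intrinsic to the procedure and how `bh_correct`
trades sensitivity for control of it.

`depselect simulate --seed 1 --out data/` writes a standalone synthetic
dataset, and `depselect validate-config --config c.yaml` checks a config
without running anything.

## Output formats

Everything on disk is TSV (plus one JSON manifest per run). The DEP table
columns, in order: `protein_id`, `gene_symbol`, `log2_effect` (median
group-B − group-A on the analysis scale, groups in sorted label order),
`direction`, `u_statistic`, `method`, `p_first_pass`, `p_second_pass`,
`selected_by`, `final`. The weight table holds one `weight:<branch>:<alg>`
and `vote:<branch>:<alg>` column pair per criterion plus the pooled
`score`. Gene lists are one symbol per line; the ranked list is the
two-column tab-separated `.rnk` layout.
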