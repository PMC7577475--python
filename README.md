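# filterdca

Interpretable supervised prediction of inter-domain residue–residue
contacts.  The method combines two features per residue pair:

- **x1** — the coevolutionary (DCA) coupling score of the pair itself, and
- **x2** — the *filter score*: the maximum Pearson correlation between the
  local k×k window of DCA scores around the pair and six
  secondary-structure-derived contact-pattern filters (the centroids of a
  3-means clustering of contact-map windows around helix–helix and
  strand–strand contacts), with the central element removed from both.

The two features are fused by an L2-regularized logistic regression trained
on structurally resolved domain pairs (training restricted to pairs with
positive DCA score; filter scores min–max rescaled by the training
extremes).  The output is a contact probability per residue pair, ranked
for evaluation by positive predictive value (PPV = TP/(TP+FP)) and checked
for probability calibration.

## Layout

| module | role |
|---|---|
| `filterdca.structure`  | distance matrices from PDB coordinates, 8 Å contact maps, 3-state secondary structure, dataset filters |
| `filterdca.dca_io`     | plmDCA-style `i j score` file parsing, effective-sequence-number (M_eff) binning |
| `filterdca.patterns`   | window extraction, average contact patterns, 3-means centroid filters |
| `filterdca.scoring`    | masked Pearson correlation, filter score, per-pair feature tables |
| `filterdca.classifier` | feature scaling, logistic fit/predict, decision boundary, family-level splits |
| `filterdca.evaluation` | PPV curves, family averaging, calibration tables |
| `filterdca.synthetic`  | synthetic benchmark generator (periodic helix / diagonal strand contact patterns, DCA-like scores with tunable signal detection probability) |
| `filterdca.config` / `filterdca.pipeline` / `filterdca.cli` | run configuration, end-to-end workflow, command line |

## CLI

All stages are exposed as subcommands of `filterdca`:

```bash
filterdca simulate --families 20 --p-det 0.5 --seed 1 --out data/
filterdca build-filters --data data/ --k 15 --seed 0 --out filters.json
filterdca score --scores data/fam0000.scores --la 100 --lb 110 \
    --filters filters.json --contacts data/fam0000.contacts \
    --family fam0000 --out fam0000.features.tsv
filterdca train --features fam0000.features.tsv --bin large --k 15 \
    --seed 1 --out model.json
filterdca predict --model model.json --features fam0001.features.tsv \
    --bin large --out pred.tsv
filterdca evaluate --predictions pred.tsv --features fam0001.features.tsv \
    --n 100 --out eval
filterdca run --k 15 --families 40 --seed 1 --out run/   # all-in-one
```

Family inputs are plain text: `<fam>.scores` (whitespace `i j score`
triplets, 1-based, optional `# Meff=` header), `<fam>.contacts` (1-based
contact pairs with a `# shape L_A L_B` header) and `<fam>.ss` (two lines of
H/E/O strings).  The default window size is k = 45 (k must be odd, 5–69);
M_eff bins are large (> 200), medium (50 < M_eff ≤ 200) and small (≤ 50).

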