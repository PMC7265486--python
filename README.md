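# synprio

Drug-combination prioritization and per-cell-line synergy stratification
from monotherapy drug response, basal gene expression and drug→target
annotations — no combination training data required.

The pipeline:

1. **Pathway activities** (`synprio.pathway_activity`) — fit a footprint-style
   gene weight matrix from perturbation z-scores and score samples by
   multiplying expression with the weights (11 signalling pathways by default).
2. **Matrix factorization** (`synprio.factorization`) — a Gibbs sampler for
   Bayesian matrix factorization of the (drugs × cell lines) IC50 matrix with
   side information on both axes (binary drug targets, real-valued cell
   pathway activities). The product of the two link matrices, averaged over
   posterior samples and independent chains, is the **targets × pathways
   interaction matrix** (sensitivity-oriented: positive = pathway activation
   associates with drug sensitivity when targeting that protein).
3. **Target functional similarity** (`synprio.similarity`) — Pearson
   correlation of two targets' interaction profiles; combinations are ranked
   by |similarity| with a strict pass threshold (default 0.7).
4. **Stratification** (`synprio.stratification`) — Delta Pathway Activity
   models: mechanism 1 (synergy by similarity) scores
   mean(top-N sensitive) − mean(top-M resistant) (+ signed binary genomics
   terms); mechanism 2 (synergy by compensation) is the reverse. Group sizes
   are picked by leave-one-out cross-validation; drug-specificity and
   eligibility filters included.
5. **Significance** (`synprio.significance`) — permutation nulls (pair-label
   and per-combination cell-label shuffling), two-tailed empirical p, a
   count-ratio Bayes factor, and Benjamini–Hochberg FDR flags.
6. **Dose response** (`synprio.dose_response`) — Hill-curve fits, Loewe
   additivity surfaces, and excess-volume synergy scores from 5×5 dose
   matrices.
7. **Synthetic data** (`synprio.synthetic_data`) — complete input panels with
   known ground truth (interaction matrix, pathway weights, synergy model) so
   every stage is testable offline.

## CLI

All matrices are TSV (row names in the first column, header row).

```sh
synprio simulate --n-drugs 40 --n-cells 120 --seed 1 --outdir panel/
synprio score-pathways --expression panel/expression.tsv --weights weights.tsv \
    --standardize on --out activities.tsv
synprio fit --response panel/response.tsv --drug-targets panel/targets.tsv \
    --cell-activities activities.tsv --config macau.yaml --out fit/
synprio interactions --fit-dir fit/ --out interactions.tsv
synprio similarity --interactions interactions.tsv --out similarity.tsv
synprio prioritize --similarity similarity.tsv --targets panel/targets.tsv \
    --threshold 0.7 --out ranked.tsv
synprio stratify --interactions interactions.tsv --activities activities.tsv \
    --genomics panel/genomics.tsv --pair T00,T01 --mechanism auto \
    --combos panel/combos.tsv --out-prefix strat
synprio significance --mode cells --predictions strat_predictions.tsv \
    --combos panel/combos.tsv --b 1000 --seed 0 --out sig.json
synprio synergy-score --doses dose_matrix.tsv --out scores.tsv
```

`macau.yaml` may set any `MacauConfig` field, e.g.:

```yaml
L: 10
n_burnin: 200
n_samples: 600
n_repeats: 40
seed: 1
```

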