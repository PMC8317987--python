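# lbpnet

Graph-theoretic resting-state functional-connectivity (rsFC) classification
for chronic low back pain (LBP) — a reusable, tested pipeline for asking
whether local network properties of the brain's functional connectome can
discriminate patients from healthy controls (HC), and which cortical
parcels drive that discrimination.

The pipeline targets researchers working with parcellated resting-state
fMRI: each subject is a parcel-by-time matrix (or a precomputed
connectivity matrix), each cohort a two-group subject table with optional
disability scores (Oswestry Disability Index, 0–100).

## Method

1. **Connectivity.** For each subject, Pearson correlations between all
   parcel time-series pairs, Fisher-z transformed: `z_ij = atanh(r_ij)`.
   Self-connections are excluded.
2. **Binary graph metrics.** Each connectivity matrix is thresholded to
   keep the strongest `round(d·N(N−1)/2)` edges at network densities
   d ∈ {15%, 17.5%, …, 30%} and binarized. Per node, four local metrics —
   degree centrality (DC), clustering coefficient (CC), betweenness
   centrality (BC, unnormalized Brandes), local efficiency (LE) — are
   computed at every density and averaged across the grid.
3. **Feature selection.** Elastic-net-penalized logistic regression over a
   (λ, α) grid selects nonzero-coefficient features (Enet). The hybrid
   **Enet-subset** extension ranks those features by |coefficient| and
   scores growing top-k subsets (k = 25, 50, …) by nested 4-fold
   cross-validated AUC of a linear SVM, keeping the best subset — removing
   variables the elastic net retains but the classifier does not need.
4. **Evaluation.** 100 iterations of: stratified 70/30 split → selection on
   the training rows only → linear SVM with cost C ∈ {1..10} tuned by
   4-fold CV repeated 5× → confusion-matrix metrics and rank-based AUC on
   the held-out rows; metrics averaged arithmetically, with HC as the
   positive class.
5. **Statistics.** Per-node rank-sum group tests with Benjamini–Hochberg
   FDR control; label-permutation significance for accuracy/AUC (selection
   re-run inside every permutation); Pearson correlation of frequently
   selected node metrics with disability scores.

Because clinical rsFC cohorts are rarely shareable, the package includes a
first-class synthetic-cohort generator: two groups drawn from modular
Gaussian covariances in which a known set of "affected" parcels carries a
controllable connectivity perturbation, plus truncated-normal disability
scores matching the clinical score moments. Every downstream stage is
validated against this ground truth.

## Worked example

```python
from lbpnet import (CohortSpec, EnetConfig, EvalConfig,
                    cohort_feature_table, generate_cohort, run_protocol)

spec = CohortSpec(n_hc=27, n_lbp=24, n_nodes=60, n_timepoints=200,
                  n_affected=8, effect_size=2.0, seed=1)
cohort = generate_cohort(spec)
X, y = cohort_feature_table(cohort, metrics=("BC", "CC", "DC"))

report = run_protocol(
    X.to_numpy(), y.to_numpy(),
    EvalConfig(n_iterations=100, cost_grid=(1.0,), cv_repeats=1, seed=1),
    selector="enet_subset",
    enet_cfg=EnetConfig(lambda_grid=(0.5,), alpha_grid=(0.0011,)),
)
print(report.summary())
```

prints

```
{'n_iterations': 100, 'mean_accuracy': 0.877, 'mean_auc': 0.943,
 'mean_sensitivity': 0.876, 'mean_specificity': 0.879,
 'mean_feature_count': 29.2}
```

i.e. on a 51-subject synthetic cohort where 8 of 60 parcels carry a strong
connectivity effect, the Enet-subset/SVM pipeline classifies held-out
subjects with ~88% mean accuracy and AUC 0.94 using ~29 of the 180
available node-metric features. `report.top_features(60)` lists the most
frequently selected features across iterations; on this cohort the
top-ranked nodes are dominated by the 8 truly affected parcels.

The same analysis is scriptable from a shell:

```sh
lbpnet simulate --n-nodes 60 --n-affected 8 --effect-size 2 --seed 1 --out cohort/
lbpnet metrics --subjects cohort/subjects.csv --series-dir cohort/series \
       --metrics BC,CC,DC --out metrics.csv
lbpnet classify --metric-table metrics.csv --subjects cohort/subjects.csv \
       --method enet_subset --out results/
```

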