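# mbsig

Multiblock sparse PLS-DA signature discovery for two-block plasma
metabolomics.

`mbsig` is for analysts of small-cohort metabolomics studies who hold two
complementary feature blocks on the same subjects — typically a ^1H-NMR
bucket table of polar metabolites and an MS lipidomics intensity table —
plus a two-level clinical outcome (here: future cognitive decline, defined
as a ≥ 2-point longitudinal drop in the MMSE), and who want a *small,
stable* metabolite signature rather than a black-box classifier. At n ≈ 20
neither block alone usually supports a valid supervised model; the package
implements the integrative workflow that can.

## The model

Per latent component h, the integrator finds one sparse unit-norm weight
vector per block, a_b, maximizing the design-weighted sum of covariances
among block scores and outcome scores,

    max Σ_{b<b'} D[b,b'] cov(X_b a_b, X_b' a_b') + Σ_b D[b,Y] cov(X_b a_b, Y c),

subject to ‖a_b‖₂ = 1 and exactly keepX_b nonzero entries (soft
thresholding at the (keepX+1)-th largest |w|). X_b are unit-variance
standardized blocks, Y the centered class-indicator matrix, D the design
matrix (default: full, all weights 1). Blocks are deflated per component;
class prediction is nearest training centroid per block with a
correlation-weighted vote across blocks; performance is the balanced error
rate BER = ½(err₁/n₁ + err₀/n₀).

Hyperparameters (1–5 components; keepX over 1–9 step 1 then 10–p step 5 per
block) are tuned by 4-fold-CV BER *inside each of 100 stratified bootstrap
replicates*; per-feature selection frequencies across replicates are the
stability evidence, and the signature is the set of final-model variables
(modal hyperparameters, full sample) whose metabolite-level frequency
reaches 60%. Around it: total-intensity normalization of NMR buckets,
Pareto scaling, single-block PLS-DA with a 7-fold-CV Q2 > 0.4 validity
gate, ROC/AUC with rank-based p-values, a repeated 2-fold CV optimism
(bias) estimate, clustered image maps, and Fisher / Mann-Whitney baseline
tables. Details and assumptions: [docs/methods.md](docs/methods.md).

## Worked example

Generate a study-shaped synthetic dataset (12 non-decliners + 8 decliners;
102 NMR buckets with 7 informative metabolites, one spanning 4 correlated
buckets; 290 lipids with 2 informative; effect 1.5 SD through a shared
latent) and run the full pipeline:

```python
from mbsig import SimulationSpec, generate_dataset, PipelineConfig, run_pipeline

dataset, truth = generate_dataset(SimulationSpec(seed=1))
result = run_pipeline(dataset, PipelineConfig(seed=11, n_bootstrap=50))
print(result.summary())
print(result.signature.to_string(index=False))
```

Output (abridged):

```
PLS-DA nmr: best Q2cum=0.487 -> valid
PLS-DA lipid: best Q2cum=0.082 -> not valid
Bootstrap stability selection
replicates: 50
modal components: 1
modal keepX: {'nmr': 40, 'lipid': 1}
Model evaluation
  nmr: AUC=0.9896  p=3.175e-05
  lipid: AUC=0.8646  p=0.005493
  nmr: apparent AUC=0.990 cv AUC=0.904 bias=-0.085
  lipid: apparent AUC=0.865 cv AUC=0.648 bias=-0.217

metabolite  frequency  fold_change                         features
     met01       0.90     0.545771 [7.2880, 3.8399, 2.8211, 1.9263]
   PI_35.1       0.82     1.616284                        [PI_35.1]
     met06       0.78     1.761622                         [5.0432]
     met02       0.66     1.897380                         [8.3164]
     met04       0.66     1.439362                         [5.3927]
     met07       0.64     1.543070                         [1.4997]
     met05       0.62     0.676679                         [5.3287]
     met03       0.60     0.708870                         [3.2230]
```

Reading this: the lipid block alone fails the Q2 validity gate (no valid
single-block model), yet the integrated one-component model discriminates
well (per-block AUCs with Mann-Whitney p-values; the negative bias is the
usual apparent-AUC optimism). The signature table lists the metabolites of
the final model that were selected in ≥ 60% of bootstrap replicates, with
their selection frequency, Decline/NoDecline fold change on the intensity
scale, and member features — note `met01` collapses its four NMR buckets
into one row. Here 8 of the 9 planted metabolites (`truth["metabolites"]`)
are recovered with no false positives.

The same workflow runs from the shell on CSV inputs:

```bash
mbsig simulate --config config.yaml --out data/
mbsig run      --config config.yaml --out results/
mbsig baseline-table --samples data/samples.csv --out baseline.csv
```

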