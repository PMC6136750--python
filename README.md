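# bayesvar

Gene-specific Bayesian prediction and 5-tier classification of missense
variant pathogenicity.

The pipeline has four stages:

1. **Normalisation** (`bayesvar.variant_io`) — derive consensus classes from
   multi-submitter labels, unit-scale 16 in silico predictor scores with
   per-predictor affine constants, and impute missing cells with a
   k-nearest-neighbour mean (k = 40 by default).
2. **In silico models** (`bayesvar.ivp_model`) — per gene, build a training
   set (borrowing class-known variants from the most similar genes when a
   gene has fewer than 5 effective negatives/positives, counting likely
   benign/pathogenic at half weight), select a predictor subset by
   penalised bidirectional stepwise logistic regression (penalty sweep 2-8,
   winner by cross-validated error), and fit Bayesian logistic regression by
   Pólya-Gamma Gibbs sampling (20,000 burn-in, 1,000 retained joint
   coefficient samples by default).  Each variant gets a Monte-Carlo
   distribution of pathogenicity probabilities.
3. **Evidence aggregation** (`bayesvar.evidence_lr`,
   `bayesvar.mvp_posterior`) — qualitative evidence levels (P-1 … B-1) map
   to likelihood ratios via `(p_cut/(1-p_cut))**p_frac`; correlated sources
   within a category combine by max/min/product; the 7 category LRs
   (FAA, COC, CSG, FHX, FUN, STR, OTH; missing = 1) multiply into a total
   LR.  The in silico distribution is rescaled into a [0.1, 0.9] prior and
   updated per-sample by Bayes' rule.
4. **Classification & evaluation** (`bayesvar.classify`,
   `bayesvar.evaluation`) — a tier is assigned only when the whole
   equal-tailed 95% credible interval clears a boundary
   (0.001 / 0.1 / 0.9 / 0.99); everything else is VUS.  A leave-one-out
   harness refits selection and sampling without each held-out variant and
   reports sensitivity/specificity (VUS-penalising denominators), PPV, NPV,
   accuracy, VUS proportion, rank AUC, DeLong AUC comparisons and binomial
   CIs.

`bayesvar.synthetic_data` generates panels with the assumed structure
(class-shifted Beta scores, missingness, sparse genes, truth-aligned
evidence) so the whole pipeline is testable offline.

The Pólya-Gamma sampler (`bayesvar.pg`) is a self-contained vectorised
implementation of the exact Devroye alternating-series method.

## CLI

```bash
# make a synthetic panel with evidence and ground truth
bayesvar simulate --out panel.csv --evidence evid.csv --truth truth.json --n-genes 5 --seed 1

# full pipeline: normalize -> LOOCV train/predict/classify -> evaluate
bayesvar run --panel panel.csv --evidence evid.csv --out-dir results/ --seed 17

# individual stages
bayesvar normalize --panel panel.csv --out norm.csv
bayesvar train-ivp --panel norm.csv --gene GENE01 --out model.json --seed 17
bayesvar predict   --model model.json --panel norm.csv --out pred.csv --samples-out samples.csv
bayesvar mvp       --samples samples.csv --evidence evid.csv --out posterior.csv
bayesvar classify  --samples samples.csv --out classes.csv
bayesvar evaluate  --predictions predictions.csv --out report.json
```

`bayesvar run` accepts `--burn-in/--n-samples` overrides; the production
defaults (20,000 / 1,000) are slow under LOOCV, so scale them down for
exploratory runs.  All outputs embed the config hash and seed.

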