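# evmodsig

Network-module prognostic signatures from extracellular-vesicle-associated
genes, for bulk-expression cancer cohorts.

Pancreatic tumors shed extracellular vesicles (EVs) whose cargo mirrors the
tumor's own transcriptome, which makes EV-associated genes attractive
prognostic biomarkers. `evmodsig` implements a pipeline that turns an
expression cohort, a confidence-scored protein–protein interaction (PPI)
network and an EV gene list into a compact, survival-stratifying *module*
signature:

1. **Candidate genes** — per-gene z-transform; tumor-vs-normal differential
   genes (Wilcoxon rank-sum + Benjamini–Hochberg, or an externally supplied
   list) intersected with the EV-associated universe.
2. **Dense modules** — edges filtered at confidence ≥ 0.4; MCODE complex
   detection (degree cutoff 2, node score cutoff 0.2, k-core 2, max depth
   100) on the induced candidate subnetwork.
3. **Stage-discriminant selection** — per-sample module activity
   *e<sub>j</sub>* = Σ<sub>i∈M</sub> Z<sub>ij</sub> (normalized by √m by
   default), discretized into ⌈log₂ N + 1⌉ equal-width bins; the discriminant
   score S(M) = MI(e′, c) against the dichotomized stage (I/II vs III/IV);
   significance from 1000 random same-size gene sets drawn from the network,
   gate at P < 0.001.
4. **Signature** — random-forest backward elimination over the selected
   modules' activities (initial 5000 trees, 3000 per iteration, 10% of
   features dropped per step down to 2), final size chosen by the
   one-standard-error rule on stratified CV error; risk = fraction of trees
   voting the poor-prognosis class (out-of-bag for training samples), cohorts
   median-split into low/high risk.
5. **Evaluation** — Kaplan–Meier curves, log-rank test, multivariate Cox
   (Efron ties), IPCW time-dependent AUC at 1/3/5 years; transfer to
   independent cohorts by re-z-scoring within each cohort.
6. **Microenvironment** — hypoxia/angiogenesis/inflammation context scores as
   mean z of biomarker gene sets, Pearson correlations of module activities
   with context scores and cell abundances (BH-adjusted), and Welch t-test
   contrasts between risk groups.

Because the original cohorts (TCGA/ICGC expression, STRING, exoRBase) are
controlled or external resources, the package ships a first-class synthetic
cohort generator (`evmodsig.simulate`) that plants dense network modules,
stage-shifted and hazard-driving expression programs, a hypoxia latent
factor and linked cell abundances — with the full ground truth recorded —
so every stage of the pipeline is testable end to end.

## Worked example

```python
from evmodsig.simulate import SyntheticCohortConfig, generate_cohort, generate_network
from evmodsig.pipeline import PipelineConfig, run_bundle

cfg = SyntheticCohortConfig(seed=2)          # 900 genes, 200 tumors, 12 planted modules
bundle = generate_cohort(cfg, generate_network(cfg))
pcfg = PipelineConfig(seed=2, rfe_n_trees_initial=300, rfe_n_trees_iter=150,
                      outcome_horizon_days=600)
res = run_bundle(bundle, pcfg)

print(res["selected_by_gate"])                       # modules passing P<0.001
print(res["signature"])                              # the compact signature
print(res["survival"]["cox_unadjusted"]["terms"]["group_high"]["hr"])
print(res["survival"]["logrank"]["p"])
```

prints

```
['mod_1', 'mod_4', 'mod_7', 'mod_8']
['mod_1', 'mod_8']
2.475554693063705
6.713310769477631e-08
```

Four detected modules beat all 1000 random gene sets on the
stage-discriminant score; backward elimination keeps two of them; the
resulting median risk split separates overall survival with hazard ratio
≈ 2.5 (high vs low risk) and a log-rank p of 7 × 10⁻⁸. Ground truth for the
planted prognostic modules is in `bundle.ground_truth`.

The same pipeline runs from files via the CLI:

```bash
evmodsig simulate --seed 2 --outdir cohort/
evmodsig run --config config.yaml --outdir results/
evmodsig report --outdir results/
```

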