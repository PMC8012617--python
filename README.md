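# gcnsurv

Seed-gene co-expression network modeling of breast-cancer relapse-free
survival (RFS): network-widened candidate pools, stepwise Cox panel
selection, partial Cox risk scores, and censoring-aware evaluation — with
a ground-truth simulator for every stage.

## The problem

Prognostic gene panels for breast-cancer relapse are usually selected from
a fixed list of differentially expressed or literature-derived seed genes.
But relapse biology is coordinated: a gene that drives outcome may be
absent from the seed list while being strongly co-expressed with a seed.
A panel restricted to the seeds can then only see that gene through a
noisy proxy.  `gcnsurv` implements the alternative: build a genetic
co-expression network (GCN) anchored on the seeds, widen the candidate
pool to the network's nodes, and let survival-model selection decide.

For people working on expression-based survival signatures, the package
provides the full pipeline as a tested library:

1. **Preprocessing** — probe-to-gene median collapse, quantile
   normalization, quantile alignment of one dataset onto a reference.
2. **Networks** — Spearman profiles of every seed against the genome over
   the relapse stratum, thresholding at a correlation r, and top-2
   edge pruning (each node keeps its two most associative edges; the kept
   set is the union of nominations).
3. **Panel selection** — stepwise forward Cox proportional-hazards
   regression with entry level SLE = 0.08, stay level SLS = 0.05, and a
   VIF < 10 collinearity guard, with lymph-node status as a mandatory
   covariate.  Model 1 selects from the seeds; models 2–4 from networks
   at r = 0.82, 0.80, 0.79; model 5 (stepwise network modeling, SNM)
   refits the pooled panel genes that pass an adjusted univariable filter
   (p < 0.001, HR > 1.5 or HR < 0.7).
4. **Risk scores** — partial Cox regression: mutually uncorrelated
   components chi_k (linear combinations of the panel genes), components
   kept at p < 0.05, risk score = sum_k beta_k chi_ik, and a high/low
   split at the natural cut-off of zero.
5. **Evaluation** — horizon accuracy/AUC at 3/5/10/15 years, IPCW
   time-dependent AUC and Brier prediction error, node-adjusted hazard
   ratios of the risk groups, and univariable odds ratios for clinical
   contingency tables.
6. **Pathways** — chi-square-share gene importance and a PC-stable CPDAG
   (Fisher-z tests, alpha = 0.01) over the top genes.
7. **Simulation** — cohorts with seed-anchored correlation blocks at
   exact Spearman targets, proportional-hazards relapse times, censoring
   calibrated to a target fraction, and known ground truth.

The model behind everything is the Cox proportional-hazards model
h(t | x) = h0(t) exp(beta' x); risk scores use the component form
riskscore_i = sum_k beta_k chi_ik.  See `docs/methods.md` for the
statistical details and design decisions.

## Worked example

```python
from gcnsurv import make_canonical_scenario, build_reference_model, build_gcn_model
from gcnsurv.evaluation import horizon_labels, horizon_metrics
from gcnsurv.partial_cox import risk_group_hr

m, surv, truth, seeds = make_canonical_scenario(rng_seed=7)
print(f"cohort: {m.n_genes} genes x {m.n_samples} samples, "
      f"{surv.event.mean():.0%} relapse")

ref = build_reference_model(seeds, m, surv)
gcn = build_gcn_model(0.82, seeds, m, surv)
print(f"reference panel ({len(ref.final_genes)} genes): {', '.join(ref.final_genes)}")
print(f"network panel   ({len(gcn.final_genes)} genes): {', '.join(gcn.final_genes)}")

labels = horizon_labels(surv, 3.0)
for name, model in [("reference", ref), ("network@0.82", gcn)]:
    scores = model.scores(m)
    auc = horizon_metrics(scores, labels).auc
    hr = risk_group_hr(scores, surv).hr_high_vs_low
    print(f"{name:>13}: 3-year AUC {auc:.3f}, high-vs-low HR {hr:.2f}")
```

Output:

```
cohort: 400 genes x 900 samples, 37% relapse
reference panel (7 genes): SEED001, SEED002, SEED003, SEED004, SEED005, SEED027, SEED033
network panel   (9 genes): SEED002_P01, SEED003_P01, SEED001_P01, SEED004, SEED005_P01, SEED008, SEED001, SEED033, SEED027
    reference: 3-year AUC 0.762, high-vs-low HR 3.77
 network@0.82: 3-year AUC 0.798, high-vs-low HR 4.69
```

The simulated cohort hides three strongly prognostic genes among non-seed
network partners (`SEED001_P01`, `SEED002_P01`, `SEED003_P01`).  The
reference model can only reach them through their seed proxies; the
network model recovers the genes themselves, and both discrimination
(AUC 0.798 vs 0.762 at three years) and risk-group separation (hazard
ratio 4.69 vs 3.77, node-adjusted) improve accordingly.

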