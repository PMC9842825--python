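# fuseroc

Score-level fusion and ROC benchmarking of multi-modal breast-screening AI
against simulated radiologist reading strategies.

## The problem

In populations with predominantly dense breasts, digital mammography (DM)
misses cancers hidden by overlapping tissue, and automated 3D breast
ultrasound (ABUS) is used as a supplemental screening modality.  AI detection
systems exist for both modalities, each emitting one continuous suspicion
score per exam.  `fuseroc` is a toolkit for the evaluation question this
raises: *does combining the two AI scores detect more cancer than either
system alone, and how does the combination compare with radiologists reading
the same modalities?*

It is written for biostatisticians and imaging-AI researchers who have (or
want to simulate) a case table with one row per exam — ground truth
(malignant / benign / normal), a DM score, an ABUS score, and optionally
per-reader BI-RADS categories — and want the full evaluation chain with
reproducible statistics.

## Methods at the core

* **Late fusion.** Each modality's scores are min–max normalized to [0, 1]
  and combined per case as `s = w·s_DM + (1−w)·s_ABUS`; `w` is chosen on a
  grid (0.01…0.99, step 0.01) to maximize the empirical AUC.
* **ROC / AUC.** Empirical ROC curves and the Mann–Whitney AUC
  `Â = mean over (pos, neg) pairs of 1[x > y] + ½·1[x = y]`, with only
  biopsy-proven malignant cases counted positive.
* **DeLong paired test.** Nonparametric variance and covariance of
  correlated AUCs from structural components (midranks for ties);
  `z = (Â_a − Â_b)/√(v_a + v_b − 2c)` with a two-sided normal p-value.
  Verified to 1e-9 against R `pROC` on fixed data.
* **Youden operating points.** The threshold maximizing
  `J = sensitivity + specificity − 1` per arm.
* **Reader strategies.** Recall = BI-RADS ≥ threshold (default category 3);
  either-recall double reading (logical OR of recalls) and a four-reader
  majority-vote panel on categories; sensitivity/specificity with
  class-stratified percentile-bootstrap 95% CIs.
* **Synthetic cohorts.** A binormal generator (class-conditional bivariate
  Gaussian scores with inter-modality correlation ρ) with a closed-form AUC
  `Φ((μ₁−μ₀)/√(σ₁²+σ₀²))` used as an exact oracle, plus ordinal reader
  simulation calibrated to target operating points.

## Worked example

```python
import fuseroc as fr

table = fr.generate_cohort(fr.CohortConfig(seed=0))   # 42/114/274 cases
labels = fr.binary_labels(table)

res = fr.weight_sweep(table)
print(res.optimal_weight_dm, res.auc_at_optimum)

test = fr.delong_paired_test(res.fused_scores, table["score_dm"].to_numpy(), labels)
print(test.p_value)
```

Running `python examples/03_fusion_sweep.py` (which does the above) prints:

```
optimal weights: dm = 0.34, abus = 0.66; fused AUC = 0.869
multimodal vs dm: AUC 0.869 vs 0.791, z = 2.53, p = 0.011
multimodal vs abus: AUC 0.869 vs 0.844, z = 1.66, p = 0.096
```

The fused score separates cancers from non-cancers better than mammography
alone on this cohort (p = 0.011); the improvement over ABUS alone does not
reach significance at this sample size.  The other `examples/` scripts walk
through cohort generation, single-modality ROC/Youden analysis, the reader
panel, and the full pipeline; `fuseroc --help` exposes the same stages as a
command line (`simulate`, `evaluate`, `fuse`, `readers`, `report`).

## Layout

```
src/fuseroc/
  cohort.py     synthetic cohorts, binormal model, reader profiles
  roc.py        ROC, AUC, DeLong, Youden, bootstrap
  fusion.py     normalization, weighted fusion, weight sweep
  readers.py    recall rules, double reading, majority panel
  pipeline.py   study orchestration, case-table IO, report rendering
  cli.py        thin command-line front end
examples/       one narrative script per capability
docs/methods.md model assumptions, parameter choices, limitations
```
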