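# cachetraj

Longitudinal cancer-cachexia severity trajectories: consensus-criteria
scoring, dynamic-time-warping clustering, and survival evaluation.

## The problem

Cachexia — involuntary weight and muscle loss in cancer — is usually graded
from a *single* measurement with the 2011 weight-based consensus criteria:
with BMI ≥ 20, more than 5% weight loss is *cachexia*, 1–5% is
*pre-cachexia*, under 1% is *no cachexia*; with BMI < 20 the cachexia
threshold tightens to 2% loss.  But cachexia is dynamic, and patients whose
severity persists, smoulders, or spikes and recovers can look identical at
diagnosis.  `cachetraj` turns each patient's dated weight/BMI series into
an ordinal severity sequence and groups patients by the *shape* of their
progression, then asks whether those trajectory groups predict survival
better than the single baseline category.

## The method

1. **Scoring.** The reference weight is the maximum weight in the 6 months
   before diagnosis.  The baseline category classifies the percent change
   of the measurement closest to diagnosis,
   `100 · (w_anchor − w_ref) / w_ref`, with cohort-level Tukey-fence
   (Q₁ − 1.5·IQR, Q₃ + 1.5·IQR) outlier flagging.  Every post-diagnosis
   measurement is classified the same way against the fixed reference,
   giving an ordinal sequence `s ∈ {0,1,2}^n` per patient.
2. **Trajectory distance.** Normalized dynamic time warping with local cost
   `d(i,j) = |a_i − b_j|` and the three-direction recursion
   `D(i,j) = d(i,j) + min(D(i−1,j), D(i,j−1), D(i−1,j−1))`, normalized by
   the summed sequence lengths: `dtw(a,b) = D(n,m)/(n+m)`.  Timestamps are
   deliberately ignored; only the shape is compared.
3. **Clustering.** PAM k-medoids (BUILD + SWAP, deterministic tie-breaks)
   on the distance matrix; k ∈ 2…10 chosen by maximum average silhouette
   width.  A null clustering on `|n_i − n_j|` (measurement counts) and the
   Adjusted Rand Index verify the result is not an artifact of sequence
   length.
4. **Characterization.** Weekly at-risk cachexia prevalence per cluster
   (carry-forward categories, risk set = alive and in follow-up), and
   automatic naming of the three canonical morphologies: *persistent*
   (sustained high), *smouldering* (low flat), *rapid with recovery*
   (early spike that decays).
5. **Survival evaluation.** Kaplan–Meier/log-rank, Cox proportional hazards
   (Efron ties) with Harrell concordance, and IPCW cumulative/dynamic
   time-dependent AUC at monthly horizons up to the median overall
   survival, comparing two dichotomous markers: baseline cachexia versus
   persistent-cluster membership.

A synthetic cohort generator produces irregularly sampled weight series
from three latent archetypes with archetype-dependent event hazards, so
the whole pipeline is testable without patient data.

## Worked example

```python
from cachetraj import CohortSpec, RunConfig, generate_cohort, run_pipeline

patients = generate_cohort(CohortSpec(seed=11))   # 600 synthetic patients
result = run_pipeline(RunConfig(seed=11, n_boot=50), patients=patients)
print(result.evaluation[result.evaluation.endpoint == "overall"]
      [["marker", "logrank_p", "hazard_ratio", "concordance"]])
```

prints (overall survival, markers only):

```
         marker    logrank_p  hazard_ratio  concordance
marker_baseline 5.828554e-05      0.623532     0.557806
marker_temporal 1.587727e-54      5.048509     0.679547
```

Reading this: the single baseline category barely orders survival times
(concordance 0.56) — here it is even mildly *protective* (HR 0.62), because
patients who later recover rapidly show the deepest loss at diagnosis.
Membership in the persistent trajectory cluster carries a hazard ratio of
5.0 and concordance 0.68, and its IPCW AUC exceeds the baseline marker's at
every monthly horizon (mean 0.73 vs 0.42).  Trajectory shape, not the
diagnosis-day snapshot, carries the prognostic signal.

The `examples/` directory walks through each capability
(`01_simulate_cohort.py` … `05_survival_comparison.py`); each script prints
its numbers with a line on what they mean.  A thin CLI mirrors the stages:

```bash
cachetraj simulate --out sim/
cachetraj run-all --measurements sim/measurements.csv \
    --outcomes sim/outcomes.csv --truth sim/truth.csv --out run/
```

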