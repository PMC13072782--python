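# markerdyn

Serial tumor-marker dynamics and survival: a tested, reusable pipeline for
analyzing early on-treatment percentage changes in serum markers (CEA,
CA-19-9) as prognostic factors for right-censored endpoints (PFS, OS) in
small oncology cohorts — the setting of late-line metastatic colorectal
cancer, where a marker drawn at baseline and after ~3 treatment cycles is
often the only early readout of benefit.

The analytical core, for marker change Δ = (post − baseline)/baseline × 100:

* **Continuous Cox association** — hazard ratios per 10 percentage points,
  `exp(10β)` with Wald CIs, plus a restricted-cubic-spline likelihood-ratio
  test of log-hazard linearity.
* **AIC-driven cutpoint optimization** — a scan of candidate cutoffs c
  fitting Cox models on I(Δ > c), selecting the admissible cutoff
  (≥ 10 patients per stratum, p < 0.05) with minimal AIC; equivalently the
  maximally selected likelihood-ratio profile.  Both a fixed −50..+50 by 5
  grid and an observed-value (off-grid) scan are supported.
* **Kaplan-Meier / log-rank stratification** with Greenwood variance,
  log-log median CIs and risk tables.
* **Internal validation** — bootstrap re-optimization (distribution of
  re-derived cutoffs, proportion within ±5 points of the original) and
  leave-one-out cross-validated classification concordance.
* **Time-dependent ROC** at a fixed horizon (IPCW cumulative/dynamic AUC).
* **Model selection** — univariable screen (p < 0.10) and multivariable
  Cox by backward elimination (p < 0.05) or forced-full fit.
* **Synthetic cohort generator** — log-normal marker levels, heavily
  right-skewed changes, Weibull proportional-hazards survival with
  threshold / linear / null marker effects and tuned independent
  censoring — so the whole pipeline is testable without patient data.

The Cox engine (Efron ties, Newton-Raphson, declared non-convergence on
monotone likelihoods) is implemented in vectorized NumPy so that the
thousands of refits behind the scan/bootstrap/LOOCV stack run in seconds;
it is verified against brute-force likelihood grids and lifelines.  See
`docs/methods.md` for the model details, defaults, and limitations.

## Worked example

```python
import math
from markerdyn import (
    CohortConfig, generate_cohort, continuous_cox_per10,
    scan_thresholds, select_cutoff, bootstrap_stability,
    loocv_concordance, td_roc,
)

cfg = CohortConfig(n_patients=61, seed=5, effect_type="threshold",
                   true_cutoff_pct=15.0, log_hazard_ratio=math.log(2.0))
cohort = generate_cohort(cfg)

cont = continuous_cox_per10(cohort, "CEA", "OS")
print(f"CEA-OS HR per 10 points: {cont.hr_per10:.4f} "
      f"({cont.hr_per10_ci[0]:.4f}-{cont.hr_per10_ci[1]:.4f}), p = {cont.p_value:.4f}")

scans = {ep: scan_thresholds(cohort, "CEA", ep) for ep in ("PFS", "OS")}
sel = select_cutoff(scans["PFS"], scans["OS"])
print(f"selected CEA cutoff: {sel.cutoff:+.1f}%")

boot = bootstrap_stability(cohort, "CEA", "PFS", n_iter=1000, seed=1)
print(f"bootstrap: {boot.prop_within_window:.1%} of cutoffs within +/-5 points "
      f"(95% CI {boot.ci95[0]:+.1f} to {boot.ci95[1]:+.1f})")

cv = loocv_concordance(cohort, "CEA", "PFS")
print(f"LOOCV concordance: {cv.concordance_pct:.1f}% "
      f"({cv.n_unclassifiable} unclassifiable)")

roc = td_roc(cohort, "CEA", "PFS", horizon=6.0)
print(f"6-month AUC (PFS): {roc.auc:.3f}")
```

Output:

```
CEA-OS HR per 10 points: 1.0071 (0.9989-1.0154), p = 0.0878
selected CEA cutoff: +14.2%
bootstrap: 56.4% of cutoffs within +/-5 points (95% CI -13.5 to +14.2)
LOOCV concordance: 98.4% (0 unclassifiable)
6-month AUC (PFS): 0.825
```

Reading it: the 61-patient synthetic cohort carries a true +15% threshold
effect (group HR 2).  The continuous model sees a per-10-point OS hazard
ratio of 1.007; the joint PFS/OS scan recovers a cutoff of +14.2%, close
to the true +15%.  The bootstrap is the honest part of the story: only
56% of resamples re-derive a cutoff within ±5 points, and the 95% CI spans
−13.5% to +14.2% — data-driven cutpoints are unstable at n = 61 even when
a real threshold exists.  Individual patient classification is far more
robust (98.4% LOOCV concordance), because most patients sit well away from
any plausible cutoff.

## Command line

```bash
markerdyn simulate --n 61 --seed 4 --out cohort.csv
markerdyn analyze --input cohort.csv --bootstrap 1000 --out results/
markerdyn report results/report.json
```

`analyze` writes `report.json` (every number reproducible from input +
config + seed; byte-identical across reruns) plus CSV artifacts: the scan
profile per marker × endpoint (the data behind an AIC-vs-threshold
figure), the bootstrap cutoff vectors (histogram data), LOOCV tables, and
KM curves.  `analyze` without `--input` generates a synthetic cohort from
the config; configs are YAML/JSON mirroring `CohortConfig` /
`AnalysisConfig`.

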