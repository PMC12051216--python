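# trajrecur

Latent HbA1c trajectory classes and recurrent heart-failure risk for
type 2 diabetes cohorts.

People with type 2 diabetes differ enormously in how their glycemia
(HbA1c, %) evolves over the decades after diagnosis, and those
long-run patterns carry information about the risk of repeated
hospitalization for heart failure (HHF). `trajrecur` is a library and
command-line tool for biostatisticians working with registry-style
data: long, irregularly sampled HbA1c series on a weeks-since-
diagnosis axis, plus recurrent hospitalization records that are only
observed inside a per-subject window of complete follow-up.

Two models sit at its core:

1. **A latent class growth model (LCGM) with B-spline trajectories.**
   Subject *i* in latent class *k* has

   $$y_i \sim \mathcal N\!\left(B_i\beta_k,\; \sigma_{b,k}^2 J + \sigma_e^2 I\right),$$

   where $B_i$ is a cubic B-spline design matrix, $\beta_k$ the class
   mean trajectory, $\sigma_{b,k}$ a class-specific random-intercept
   SD and $\sigma_e$ the residual SD. The mixture is fitted by EM
   (rank-1 Woodbury algebra, longitudinal k-means initialization),
   and the number of interior knots, their placement (equidistant vs
   equipotent) and the number of classes K are chosen by an iterated
   BIC / cross-validated-BIC search.

2. **A window-observed power-law nonhomogeneous Poisson process
   (NHPP)** for recurrent events, with intensity

   $$\lambda(t\mid x) = \frac{\beta}{\eta}\left(\frac{t}{\eta}\right)^{\beta-1} e^{x^\top\gamma},$$

   so $\Lambda(t\mid x) = (t/\eta)^\beta e^{x^\top\gamma}$. Events are
   observed only in $(L, R]$; the likelihood conditions on the window,
   and $e^{\gamma}$ are hazard ratios for the trajectory classes and
   baseline risk factors. The same model yields horizon risk
   predictions $p = 1 - e^{-[\Lambda(s+h|x)-\Lambda(s|x)]}$, evaluated
   by ROC/AUC after balanced case-control down-sampling and a
   stratified 80/20 split.

Because the registry this methodology targets is access-restricted,
the package ships a first-class synthetic-cohort generator
(`trajrecur.synthetic`) whose defaults reproduce the published study
conditions: eight classes (low stable 22.2% ... high volatility
10.2%), published baseline HbA1c means (6.27–11.60%), qualitative
shapes (stable / ascending / descending / sharp decline / volatile),
published per-class covariate prevalences, and NHPP class effects
equal to the published hazard ratios (0.79–2.88). See
`docs/methods.md` for the model details and every calibration choice.

## Worked example

Generate a 2,000-subject cohort under the default (published)
conditions, cluster the trajectories, fit the recurrent-event model
on the class indicators, and evaluate a two-year horizon prediction:

```python
import numpy as np
from trajrecur import (default_registry_config, generate_cohort, fit_lcgm,
                       fit_nhpp, hazard_ratios, predict_trajectory, roc_auc,
                       downsample_balance, stratified_split, event_probability)
from trajrecur.splines import make_spec

cfg = default_registry_config()
cohort, truth = generate_cohort(cfg, n_subjects=2000, seed=7)
times = np.concatenate([s.times for s in cohort.series.values()])
spec = make_spec(times, 10, "equipotent")

fit = fit_lcgm(cohort, K=8, spec=spec, n_starts=5, seed=7)
print("mixing proportions (%):", np.round(100 * fit.pi, 1))
print("baseline HbA1c by class (%):",
      np.round([predict_trajectory(fit, k, [0.0])[0] for k in range(1, 9)], 2))

nfit = fit_nhpp(list(cohort.windows.values()),
                covariate_names=[f"class_{k}" for k in range(2, 9)])
print(hazard_ratios(nfit).round(2).to_string(index=False))
```

This prints (exactly, for seed 7):

```
mixing proportions (%): [21.3 17.5 13.1 11.1 10.4  9.9  9.   7.6]
baseline HbA1c by class (%): [ 6.29  7.73  7.4   6.7   9.28 10.85  8.64 11.61]
   name   HR  CI_low  CI_high    p
class_2 0.72    0.26     1.99 0.52
class_3 1.11    0.48     2.57 0.81
class_4 1.94    0.99     3.82 0.05
class_5 4.09    2.16     7.78 0.00
class_6 3.01    1.50     6.06 0.00
class_7 1.73    0.75     4.01 0.20
class_8 3.19    1.62     6.27 0.00
```

Classes come out in descending-size order: the largest fitted class
(21.3%, baseline 6.29%) recovers the generated low stable class
(22.2%, 6.27%), and every generated baseline mean (6.27, 6.70, 7.41,
7.73, 8.63, 9.28, 10.81, 11.60) is matched by a fitted class within a
few hundredths of a percent. The hazard-ratio table is what a rare-
event registry analysis looks like at n = 2,000 (125 events): the
high-risk volatile/descending classes (generated at HR 1.89–2.88) are
clearly elevated, with wide intervals at this sample size.

Continuing with the prediction protocol — down-sample controls to the
case count, split 80/20 per group, fit on training subjects, and
score a 104-week horizon on the held-out subjects:

```python
labels = {sid: len(w.event_times) > 0 for sid, w in cohort.windows.items()}
bal = downsample_balance(labels, seed=7)
train, test = stratified_split({s: labels[s] for s in bal}, 0.8, seed=7)
tfit = fit_nhpp([cohort.windows[s] for s in train])
probs = [event_probability(tfit, cohort.windows[s].x, cohort.windows[s].L, 104.0)
         for s in test]
obs = [bool(np.any((cohort.windows[s].event_times > cohort.windows[s].L)
                   & (cohort.windows[s].event_times <= cohort.windows[s].L + 104.0)))
       for s in test]
_, auc = roc_auc(obs, probs)
print(f"2-year horizon AUC on held-out subjects: {auc:.3f}")
# 2-year horizon AUC on held-out subjects: 0.769
```

The same pipeline is available from the shell:

```bash
trajrecur simulate --n 2000 --out cohort/ --seed 7
trajrecur fit-lcgm --cohort cohort/ --classes 8 --knots 10 --strategy equipotent \
                   --starts 5 --seed 7 --out model.json
trajrecur select   --cohort cohort/ --k0 3 --folds 10 --seed 7 --out selection.json
trajrecur fit-nhpp --cohort cohort/ --out nhpp.json --hr-table hr.csv
trajrecur predict  --cohort cohort/ --lcgm model.json --nhpp nhpp.json \
                   --horizon 104 --out predictions.csv
trajrecur evaluate --predictions predictions.csv --out roc.csv
```

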