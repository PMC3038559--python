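# restconn

Resting-state ROI functional connectivity and directed causal-network
inference for multi-subject brain time-series cohorts — with a synthetic
vector-autoregression (VAR) cohort generator whose ground truth lets the
whole analysis chain be validated end to end.

`restconn` is for researchers analysing regional (ROI-averaged) BOLD
fMRI series — or any multi-subject, multi-channel slow time series —
who want two complementary network views of the same cohort:

* **Undirected functional connectivity.** Per subject, the Pearson
  correlation between each pair of ROI series

  $$r = \frac{\sum_i (X_i-\bar X)(Y_i-\bar Y)}
             {\sqrt{\sum_i (X_i-\bar X)^2\,\sum_i (Y_i-\bar Y)^2}}$$

  is variance-stabilised with the Fisher transform
  $z = \operatorname{arctanh}(r)$, and the cohort is summarised per pair
  by the standardized group Z-matrix $Z_{ij} = \bar z_{ij} / s_{ij}$
  (cross-subject mean over standard deviation, diagonal set to 1).
  Significance per pair comes from the one-sample t statistic
  $t = Z\sqrt{n}$ with $n-1$ degrees of freedom, Bonferroni-corrected
  over the $R(R-1)/2$ pairs, with edges graded into significance tiers.

* **Directed causal structure (Granger causality).** X "Granger causes"
  Y when X's past improves the prediction of Y beyond Y's own past.
  For lag order $m$, the restricted model regresses $Y(t)$ on its own
  $m$ lags, the unrestricted model adds the lags of $X$, and

  $$F = \frac{(\mathrm{RSS}_r - \mathrm{RSS}_{ur})/m}
             {\mathrm{RSS}_{ur}/(T - 2m - 1)}$$

  is referred to $F(m,\,T-2m-1)$; the causal-influence magnitude is
  $\log(\mathrm{RSS}_r/\mathrm{RSS}_{ur})$.  The conditional
  (multivariate) variant fits the full VAR over all ROIs so an
  $i \to j$ influence is assessed controlling for every other region —
  pairwise causality flags indirect routes ($x \to y \to z$ makes
  $x \to z$ look causal), conditional causality clears them.  Series
  are segmented into successive 60-s windows to restore covariance
  stationarity; group inference pools each subject's windowed residual
  sums of squares and refers the null-bias-corrected influence sum to
  its exact null distribution (log-Beta moments), Bonferroni-corrected
  over ordered pairs.

Temporal preprocessing mirrors a standard resting-state chain at the
ROI level: discard initial volumes, remove linear drift and temporal
mean, express signals as fractional change about the raw mean, and
band-pass to the 0.01–0.08 Hz band where resting-state synchrony lives.

The synthetic cohort module generates multi-subject cohorts from stable
VAR processes with a known directed skeleton (lag coefficients) and a
known band-limited correlation pattern (calibrated innovation
covariance), including an 18-ROI reference network — left/right visual,
auditory, motor, somatosensory, olfactory, prefrontal, ACC, PCC and
amygdala — in which the amygdala exchanges with the sensory cortices,
the prefrontal cortex receives from the olfactory and motor cortices,
and the cingulate hubs bridge the two streams.

## Worked example

```python
from restconn import (build_var_model, sensory_pattern_graph, simulate_cohort,
                      preprocess, cohort_correlations, group_z_matrix,
                      correlation_edges)

spec = sensory_pattern_graph()            # calibrated 18-ROI generator
cohort = simulate_cohort(build_var_model(spec), 29, 200, seed=2)
filtered = preprocess(cohort)             # discard 10, detrend, ratio,
                                          # 0.01-0.08 Hz, demean
gz = group_z_matrix(cohort_correlations(filtered))
edges = correlation_edges(gz, alpha_family=0.005)
print(f"{len(edges)} of {gz.n_pairs} ROI pairs survive Bonferroni P < .005")
```

prints

```
84 of 153 ROI pairs survive Bonferroni P < .005
```

and the strongest surviving pairs (from `examples/02_correlation_network.py`)

```
  auditory_R -- prefrontal_R       Z=+6.23 (+) tier 3
  amygdala_R -- somatosensory_R    Z=+5.41 (+) tier 3
       PCC_R -- olfactory_R        Z=+5.25 (+) tier 3
       ACC_L -- amygdala_L         Z=-5.13 (-) tier 3
```

Each line is one undirected edge: Z is the cross-subject mean Fisher-z
divided by its spread (larger |Z| = more consistent coupling), the sign
marks correlated vs anticorrelated regions, and tier 3 means the
Bonferroni-corrected p is below $10^{-4}$.  The directed analysis on the
same cohorts (`examples/03_granger_network.py`, `04_full_pipeline.py`)
recovers the planted causal links; on a chain $x \to y \to z$ it prints

```
pairwise   x->z: F=    97.9  p=3.41e-21  influence=0.180
conditional x->z: F=     2.6  p=1.05e-01  influence=0.005
```

— the pairwise test is fooled by the indirect route, the conditional
test is not.

A thin CLI wraps the same functions:

```bash
restconn simulate --subjects 29 --timepoints 200 --seed 1 --out cohort/
restconn corr     --in cohort/ --alpha 0.005 --out corr-out/
restconn granger  --in cohort/ --mode conditional --alpha 0.001 --out gc-out/
restconn pipeline --seed 1 --out run/
```

Outputs are plain text: per-subject TSV, labelled CSV matrices, edge
TSVs, Pajek `.net` graphs, and a `manifest.json` that makes every run
byte-for-byte reproducible.

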