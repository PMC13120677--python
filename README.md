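# flukeprints

Whale size class, swimming speed and orientation inferred from
drone-based **thermal flukeprints** — the smooth, elliptical surface
patches that a whale's tailbeats leave on the sea surface, which persist
in thermal infrared (TIR) imagery long after the animal has submerged.

The package is aimed at researchers running dual-sensor (RGB + TIR) UAV
surveys of cetaceans. It implements the full measurement and inference
chain for annotated nadir footage of humpback whales and validates every
stage against synchronized RGB reference measurements:

* **Photogrammetry** — pixel-to-metre scaling for a nadir camera
  (GSD = altitude / focal length), Brown–Conrady radial undistortion, and
  accuracy validation against a reference object of known length.
* **Morphometrics** — per-individual means of flukeprint width, body
  length and fluke span (quality window ≤ 5 s after fluke emergence);
  pooled / within-class / interaction regressions with 10-fold
  cross-validation; logistic age classification with ROC analysis and the
  Youden-optimal width threshold.
* **Kinematics** — event speeds from RGB rostrum tracking and from TIR
  flukeprint spacing, plus the method-agreement battery: Bland–Altman
  bias and limits of agreement, RMSE/MAE/nRMSE, MAPE and median MAPE,
  ICC(A,1), paired *t*, proportional bias, Deming calibration.
* **Speed model** — the random-intercept log-log model

      log(speed_ij) = β₀ + β₁ log(spacing_ij) + u_i + ε_ij,
      u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²)

  fitted by REML, with Nakagawa–Schielzeth marginal/conditional R²,
  leave-one-whale-out cross-validation, and still-image speed prediction
  with propagated 95 % prediction intervals
  (PI = exp(η ± 1.96 √(xᵀVx + σ_u² + σ_e²))).
* **Orientation** — compass headings from the posterior→anterior print
  axis (TIR) and the tail→rostrum body axis (RGB); circular mean,
  resultant length, circular SD √(−2 ln R̄), Rayleigh test, Fisher–Lee
  circular correlation, wrapped differences and agreement categories
  (Excellent ≤ 5°, Good ≤ 15°, Acceptable ≤ 20°, Discrepant > 20°).
* **Synthetic data** — a dual-sensor survey generator with known ground
  truth (two age classes, linear tracks, one print per tailbeat, 30 Hz
  sampling at 90 m altitude, configurable noise channels) so every stage
  is testable without field footage.

## Worked example

Simulate a small survey (16 adults, 4 calves, two surfacing events each)
and run every analysis stage:

```python
import flukeprints as fp

cfg = fp.RunConfig(
    simulation=fp.SimulationConfig(seed=1, n_adults=16, n_calves=4,
                                   prints_per_event=4)
)
report = fp.run_pipeline(cfg)
```

Headline numbers from this run:

* `morphometrics.classifier`: Youden threshold **2.10 m**, sensitivity
  **1.0**, specificity **1.0** — calf and adult flukeprint widths form
  disjoint clusters, so a single width threshold separates the age
  classes perfectly.
* `speed.agreement`: bias **0.046 m/s**, RMSE **0.053 m/s**, MAPE
  **4.1 %**, ICC(A,1) **0.97** — RGB-tracked and TIR-spacing speeds agree
  closely under the default annotation-noise model.
* `speed.lmm`: β₁ = **0.72 ± 0.08**, marginal R² **0.59**, conditional R²
  **0.77**; leave-one-whale-out 95 % prediction intervals cover **95 %**
  of held-out speeds (RMSE 0.15 m/s). (On these kinematic tracks the
  spacing–speed elasticity is steeper than on spacing observations drawn
  from the observation model itself, where β₁ recovers its generative
  value of 0.33.)
* `orientation`: mean TIR−RGB offset **0.6°** (circular SD 10.7°),
  circular correlation **0.97** — print axes track the body axis.

The same stages are exposed on the command line:

```bash
flukeprints simulate --seed 1 --out out/
flukeprints report --annotations out/annotations.csv --out out/
```

`out/report.json` is byte-identical across reruns with the same
configuration and seed.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its defaults, numerical choices, and known limitations.
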