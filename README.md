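# homeodyn

Dynamic stability analysis and in silico combination-treatment screening
for first-order feedback models of SOD1-G93A ALS mouse physiology.

## The problem

Amyotrophic lateral sclerosis (ALS) in the high-copy SOD1-G93A
transgenic mouse is multifactorial: apoptosis, bioenergetics, metal-ion
chemistry, excitotoxicity, inflammation, oxidative stress and
proteostasis interact through regulatory feedback. One hypothesis for
disease onset (around postnatal day 100) is *homeostatic instability*:
hypervigilant, over-gained regulation that over-corrects perturbations
and drives growing oscillations instead of returning to baseline.

`homeodyn` models this as a linear first-order feedback network over 14
"factors" — seven functional categories, each with a positively and a
negatively regulated subcategory:

```
dx/dt = G · x(t)
```

where `x(t)` is the vector of relative factor changes (baseline 1) and
`G` is the 14×14 **gain matrix** in day⁻¹; entry `(j, i)` is the per-day
influence of factor *i* on factor *j*. A treated/control measurement
over a study of `D` days contributes the gain

```
g = (3 / D) · (Treated/Control − 1)
```

and multiple measurements per entry are averaged. The system is
homeostatic iff every eigenvalue of `G` has negative real part; an
eigenvalue with positive real part and nonzero imaginary part is the
signature of oscillatory instability, with amplitude doubling time
`ln 2 / Re(λ)`.

The package provides the complete workflow:

* **ontology** — the 14-factor ontology; conversion of measurement
  records (CSV) into a partially observed gain matrix.
* **synthetic_data** — generators for stable wild-type-like and
  unstable oscillatory ALS-like matrices, noisy measurement records
  consistent with a known matrix, and WT reference trajectories.
* **dynamics** — explicit-Euler simulation, the analytic eigensolution
  `x(t) = Σᵢ c₀ᵢ e^{λᵢt} vᵢ`, stability classification. Days 1–54 are
  simulated but masked in reported outputs.
* **calibration** — genetic-algorithm completion of missing entries by
  minimising the homeostasis cost `MSE = (1/n) Σᵢ xᵢ′(200)²`.
* **treatments** — differential-evolution screening of the 364
  three-factor treatments (state modulation at days 1/109/125, log-cosh
  fitness vs a WT reference over days 140–200) and of the 105 gain
  treatments (diagonal "one-way" and off-diagonal-pair "two-way"
  modulation capped at 5×/10×/15× the original magnitude, judged by the
  spectral abscissa).
* **postanalysis** — DTW k-means time-series clustering, eigenvalue
  feature clustering, dominant-term tables of the analytic solution,
  spectrogram/PSD, zero-lag cross-correlation, Pearson pairs, and
  aggregated factor-pair ranking.

## Worked example

```python
import homeodyn as hd

spec = hd.SyntheticSpec(seed=7)
wt = hd.generate_wt_matrix(spec)
als = hd.generate_als_matrix(spec)

for name, G in [("WT", wt), ("ALS", als)]:
    rep = hd.classify_stability(G)
    print(f"{name}: {rep.label} ({rep.mode}), max Re(lambda) = {rep.max_real:+.4f} / day")
print(f"ALS doubling time: {hd.doubling_time(hd.classify_stability(als).max_real):.0f} days")

# complete a partially observed wild-type matrix by GA
partial = hd.mask_matrix(wt, missing_frac=0.2, seed=3)
res = hd.ga_fill_missing(partial, hd.GAConfig(seed=0))
rep = hd.classify_stability(res.matrix)
print(f"GA fill: cost {res.best_cost:.3g}, {rep.label}, max Re(lambda) = {rep.max_real:+.4f} / day")

# screen all 105 gain treatments at caps 5x / 10x / 15x
results = hd.evaluate_gain_treatments(als, caps=(5.0, 10.0, 15.0),
                                      config=hd.DEConfig(maxiter=100), seed=11)
print("stable gain treatments per cap:", hd.count_stable_gain_treatments(results))
```

prints

```
WT: stable (oscillatory), max Re(lambda) = -0.0158 / day
ALS: unstable (oscillatory), max Re(lambda) = +0.0065 / day
ALS doubling time: 106 days
GA fill: cost 1.21e-13, stable, max Re(lambda) = -0.0526 / day
stable gain treatments per cap: {5.0: 3, 10.0: 5, 15.0: 7}
```

The wild-type model decays back to baseline (damped oscillation); the
ALS model's dominant mode is a growing oscillation whose amplitude
doubles every ~106 days, so divergence becomes visible near day-100
disease onset. GA completion of the masked matrix restores a stable
spectrum with near-zero day-200 derivatives. Of the 105 candidate gain
treatments, 3 stabilise the ALS system within a 5-fold modulation cap;
relaxing the cap to 10× and 15× adds further stabilising combinations,
and every combination that stabilises at a smaller cap remains stable
at larger ones (search-space nesting).

A thin CLI mirrors the library:

```sh
homeodyn synth --kind als --seed 7 --out als.json
homeodyn simulate --matrix als.json --days 200 --out traj.csv
homeodyn calibrate --records records.csv --seed 0 --out filled.json
homeodyn treat-gains --als als.json --max-effect 5,10,15 --out gains.json
homeodyn analyze --matrix als.json --horizons 200,365,730 --out-dir analysis/
```

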