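# Methods

## Model

The physiology of the (wild-type or SOD1-G93A ALS) mouse is reduced to
14 state variables — seven functional categories (apoptosis,
bioenergetics, chemistry, excitotoxicity, inflammation, oxidative
stress, proteomics), each split into a positively and a negatively
regulated subcategory. The state vector x(t) holds the relative change
of each factor from its baseline (taken as 1), and evolves by the
linear first-order feedback system

    dx/dt = G x(t),

with G the 14×14 gain matrix (day⁻¹), rows target-major: G[j, i] is the
per-day influence of factor i on factor j. Stability is read off the
spectrum: homeostasis iff max Re(λ) < 0; a dominant eigenvalue with
positive real part and nonzero imaginary part is a growing oscillation
(hypervigilant over-correction), with amplitude doubling time
ln 2 / Re(λ).

A literature measurement (treated vs. control assay values over a study
of D days) contributes a per-day gain

    g = (3 / D) · (Treated/Control − 1).

Alternative algebraic readings of this formula exist (the placement of
the fraction bar is ambiguous in common typesetting); this reading is
adopted because the quantity is explicitly a *daily* rate,
which requires the division by D. The constant 3 is retained as stated.
Multiple measurements mapping to one matrix entry are combined by
unweighted arithmetic mean; per-record confidence labels (high, medium,
low) are carried through but not used as weights, since no weighting
rule is available. Entries with no measurements are *missing* and are
later completed by optimisation.

## Simulation and analytic solution

Integration is explicit Euler, x(t+dt) = x(t) + dt·G·x(t), the model's
native scheme. The baseline state (default: all ones) is placed at
t = 0 and states are reported on the day grid 1, 1+dt, …, t_end; the
default step is dt = 1 day, adequate while |λ|·dt ≲ 0.1 (the synthetic
matrices have |λ| ≤ ~0.1 day⁻¹; a convergence test against the matrix
exponential confirms first-order error decay, and dt is configurable).
Days 1–54 are simulated but masked in all reported outputs: early
postnatal dynamics confound growth with regulation and the model is
only trusted from early adulthood (day 55) onward. A trajectory whose
max-norm exceeds 1e12 is truncated and flagged with its divergence day.

For diagonalizable G the analytic solution x(t) = Σᵢ c₀ᵢ e^{λᵢ t} vᵢ is
available, with V c₀ = x(0) solved directly; numerically defective
matrices raise an explicit error rather than being perturbed.

## Synthetic study conditions

No curated dataset is shipped; the generators emulate the statistical
structure of the curated-literature setting so every downstream stage
is testable end to end.

* **Spectrum shaping.** A Gaussian random matrix (entry sd 0.03 day⁻¹)
  is split into symmetric and antisymmetric parts and re-blended with
  antisymmetric weight 0.7, which guarantees several complex-conjugate
  eigenpairs (damped/growing oscillation). The diagonal is then shifted
  uniformly — translating every eigenvalue's real part while preserving
  eigenvectors and imaginary parts — to place the spectral abscissa at
  a random point of the target interval. Draws failing the posts
  (pair count, oscillatory dominance) are rejected and resampled.
* **Wild type:** max Re(λ) ∈ [−0.05, −0.005] day⁻¹ — decay over weeks
  to months, the time scale of murine physiology.
* **ALS:** max Re(λ) ∈ [ln2/140, ln2/70] ≈ [0.0050, 0.0099] day⁻¹ with
  an oscillatory dominant mode: amplitude doubling in 70–140 days, so
  instability becomes visible around the day-100 disease onset of the
  high-copy SOD1-G93A mouse.
* **Measurement records** invert the gain formula: for entry gain g and
  duration D ∈ {3,…,120} days (uniform; shortened when a strongly
  negative gain would drive the ratio non-positive), the noiseless
  treated/control ratio is 1 + g·D/3, perturbed by multiplicative
  log-normal noise of log-sd 0.05 (typical assay-level scatter), with 4
  records per entry and a Bernoulli(0.2) missing-entry mask by default.
  Control values are uniform on [0.5, 2] arbitrary assay units.
* All randomness flows from one integer seed through named
  `numpy.random.SeedSequence` streams (wt/als/records/mask), so
  generators are independently reproducible.

What the generators do *not* emulate: real curated data have
study-level heterogeneity (shared protocols, correlated errors within
articles), systematically unbalanced coverage of the ontology, and
confidence-dependent accuracy. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's machinery, not the
fidelity of any particular published gain matrix.

## GA completion of missing entries

Wild-type physiology maintains homeostasis, so missing entries are
chosen to make the completed system settle: the cost is the mean
squared state derivative at day 200,

    MSE = (1/14) Σᵢ (xᵢ′(200) − 0)²,  x′(200) = G x(200)

from the Euler trajectory; divergent candidates receive a large finite
penalty (1e12). The day-200 evaluation point is retained exactly as
specified by the cost's definition rather than a trajectory-wide norm.

The GA is the classic real-valued scheme: population 96, 200
generations, tournament selection (k = 3), uniform crossover (rate
0.7), per-gene Gaussian mutation (rate 0.15, sd 0.05 day⁻¹), elitism of
one (making the best-cost history non-increasing), bounds [−1, 1] day⁻¹
per entry — covering the magnitude range the gain formula produces on
plausible ratios. All missing entries are encoded jointly in one
chromosome. One chromosome of the initial population is all-zero, a
sparsity prior reflecting that unmeasured interactions plausibly default
to "no interaction". Candidate evaluation is vectorised (all Euler
trajectories of a generation advance in lock-step), so a full run takes
about a second. Identical seeds reproduce the fill bit for bit.

A caveat established by the package's own recovery experiments: the
day-200 derivative cost provides 14 constraints at a single time point
against (at 20% missingness) ~40 unknowns, so the completion is not
identifiable from the cost alone. The GA reliably restores stability
(max Re(λ) ≤ 1e−3 in 10/10 seeds at 20% masking), but the completed
trajectories are typically more damped than the generating truth; the
day-55–200 trajectory RMSE versus truth stays below 0.1 only when the
truth's own window amplitude is of that order (7/10 seeds under the
default conditions). Entry-level recovery should not be over-read.

## Treatment search

**Factor treatments** modulate the states of 3 of the 14 factors
(C(14,3) = 364 candidate triples) at the presymptomatic, symptomatic
and post-symptomatic intervention days 1, 109 and 125. Modulation is
multiplicative — states are relative changes with baseline 1 — with the
nine multipliers (3 factors × 3 days) bounded to [1−e, 1+e] for effect
size e ∈ {0.25, 0.5, 0.75, 1.0, 1.25}. Differential evolution
(scipy's rand/1/bin, population 15 per dimension, seeded, with a final
polish) minimises the log-cosh fitness

    fitness = mean over days 140–200 and factors of log cosh(y − ŷ)

against a wild-type reference trajectory. The identity treatment is
inside the bounds and seeded into the initial population, so treated
fitness never exceeds untreated fitness and the improvement ratio
(untreated ÷ treated fitness) is ≥ 1. Per effect size, triples are
ranked by fitness (ties → mean rank); the aggregate ranking is the rank
sum across the five effect sizes, ties broken lexicographically — rank
aggregation makes the result invariant to monotone rescaling of the
fitness within each effect size.

**Gain treatments** modulate matrix entries directly: one-way = a
single diagonal entry, two-way = the off-diagonal pair {(i,j),(j,i)},
105 templates in all. Each targeted entry with original value g₀ is
bounded to [−c·|g₀|, +c·|g₀|] for caps c ∈ {5, 10, 15} — up to c-fold
modulation of the original magnitude, sign reversal permitted (a
scaling-only variant [g₀/c, c·g₀] would forbid sign changes and is a
possible alternative; the symmetric bound was chosen because curative
interventions may plausibly invert a pathological feedback). DE
minimises the spectral abscissa max Re(λ); the treatment stabilises iff
the minimum is negative. Zero-valued g₀ degenerates the bounds to {0}
and the template is reported infeasible. Caps are processed in
increasing order, each warm-started from the previous cap's optimum
(whose bounds nest inside the larger ones), so stability nesting across
caps — anything stable at 5× is stable at 10× and 15× — holds exactly
by construction rather than up to optimiser luck.

## Post-simulation analyses

* **DTW k-means** (k = 3) clusters the 14 per-factor series (reported
  window only). DTW uses the standard dynamic program on squared
  pointwise costs (numba-accelerated); centers are pointwise means of
  members (all series share one day grid), empty clusters are re-seeded
  on the farthest series, and the best of 10 seeded restarts by inertia
  is kept. Co-occurrence tables count how often factor pairs share a
  cluster across treatments.
* **Eigen-feature clustering**: per treatment, 16 features — min, max,
  mean and population std of Re(λ), Im(λ), |λ| and arg(λ) — are
  z-scored (the scales are incommensurate) and K-means clustered
  (default k = 9, 10 restarts, fixed seed). Zero-variance features are
  dropped with a warning.
* **Dominant terms**: by magnitude, term i dominates factor j when
  e^{Re(λᵢ)·100}·|vᵢⱼ| is within 5% of the factor's maximum (day 100 ≈
  onset, half the ~200-day ALS lifespan); by decay rate, for stable
  systems only, the slow modes (|Re(λ)|·t_ref < 0.1 with t_ref = 200
  days — the linearisation e^{Re(λ)t} ≈ 1 − |Re(λ)|t requires
  |Re(λ)|t ≪ 1, and 0.1 operationalises "≪") are scored by
  |Re(λᵢ)|·|vᵢⱼ| and the minimum and anything within 5% flagged. The
  initial-condition coefficients are deliberately ignored for
  generality. If no mode meets the cutoff the single slowest mode is
  used.
* **Spectral/correlation pair metrics**: Hann-window STFT with 16-day
  segments and 8-day overlap, normalised to PSD (2-day overlap when
  feeding the ranking pipeline); PSD discrepancy = sum of absolute
  differences over all time-frequency bins; zero-lag cross-correlation
  = dot product of mean-centered series (centering is essential — raw
  dot products are dominated by baselines); Pearson correlation over
  horizons 200/365/730/1825/3650 days for the 105 unordered factor
  pairs (self-pairs included, exactly 1 by construction; zero-variance
  series yield NaN, not 0). Pairs are ranked per metric — low PSD
  discrepancy, high |cross-correlation|, high signed Pearson (an
  absolute-value variant is selectable) — and the final pair ranking is
  the rank sum, ties lexicographic; rankings, not raw metric values,
  are aggregated.

## Problem sizes and determinism

The test suite and the acceptance script run the stability dichotomy at
50 seeds, GA recovery at 10 seeds (20% masking, noise-free records),
the gain-treatment screen over all 105 templates × 3 caps with a
100-generation DE budget, the factor-treatment DE on small decoupled
toys against grid-search oracles plus an 8-triple screen of the full
system, and Monte-Carlo record-noise sweeps at 20 seeds — sizes chosen
so the whole pipeline reruns in a few minutes on one CPU while leaving
every property statistically decidable. All stochastic components
(generators, GA, DE, clustering) are seeded and bit-reproducible.

## Known limitations

* Linear first-order feedback cannot express bistability, hysteresis or
  saturation; "stability" here is strictly spectral.
* The gain formula's constant 3 and its algebraic reading are fixed
  design choices; if future measurements pin the formula down
  differently, `compute_gain` is the single point of change.
* The GA completion restores stability but not entry-level truth (see
  the identifiability caveat above).
* Treatment timing (days 1/109/125) is fixed, not optimised; only
  modulation magnitudes are searched.
* Published headline numbers from curated SOD1-G93A literature datasets
  (e.g. specific improvement ratios or stable-treatment counts) depend
  on fitted gain matrices that are not publicly available; this package
  reproduces the machinery and its qualitative/structural properties,
  not those exact values.
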