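# Methods

`cmpmonitor` monitors fed-batch cell-culture processes from *inside* the
cell: instead of charting macroscopic process conditions, it estimates the
internal metabolic reaction rates of the average cell at every sampling
time and builds multivariate control charts and classifiers on those rates.
This note documents the models, their assumptions, the tunable parameters,
and what the bundled synthetic-data generator does and does not emulate.

## 1. Synthetic fed-batch campaigns (`simdata`)

The generator emulates a CHO-style production process: cultures inoculated
at 0.3 × 10⁶ cells/mL run a 3-day unfed batch phase followed by a 7-day
fed-batch phase. A daily feed check restores glucose to 6.0 g/L whenever it
has fallen below 3.0 g/L; each bolus adds 1.5% to the working volume and
the resulting dilution of cells and by-products is tracked and recorded
with the feed event. Samples are taken daily (pre-feed by convention) plus
once immediately after every feed. In the *shifted* arm the culture
temperature is dropped at the moment of the first glucose feed; the shift
is modelled as a multiplicative factor `shift_factor` on the maximal growth
rate, the maximal per-cell glucose uptake, and the lactate yield.

State dynamics (Heun integration, step `dt`):

    dVCD/dt   = mu_max · s(t) · glc/(K_glc + glc) · VCD
    d[glc]/dt = q_glc · VCD,   q_glc = -q_glc_max · s(t) · glc/(K_glc + glc)
    d[lac]/dt = q_lac · VCD,   q_lac = -y_lac · s(t) · q_glc

with `s(t) = shift_factor` after the shift and 1 otherwise. Units are
chosen so no conversion constants appear: with VCD in 10⁶ cells/mL and q in
pmol/cell/h, `q · VCD` is exactly mM/h.

Defaults (units, value, why):

| parameter    | value | meaning |
|--------------|-------|---------|
| `mu_max`     | 0.012 /h | maximal specific growth rate at 37 °C. Chosen so that, under the fixed feed recipe, cultures stay glucose-replete for the full 10 days; faster growth drives the late culture glucose-limited, where per-cell uptake collapses for *normal* batches and the normal-vs-shifted rate ordering inverts. |
| `k_glc`      | 0.5 mM | Monod constant for glucose. |
| `q_glc_max`  | 0.25 pmol/cell/h | maximal per-cell glucose consumption, a typical CHO magnitude. |
| `y_lac`      | 1.4 mol/mol | lactate produced per glucose consumed (overflow regime). |
| `shift_factor` | 0.6 | metabolic slowdown imposed by the 37→33 °C shift. |
| `noise_cv`   | 0.05 | relative (multiplicative Gaussian, truncated at 0) measurement noise applied to sampled values only. |
| `init_glc`   | 4.0 g/L | initial glucose; calibrated once so the first feed — and hence the temperature shift — lands on day 3 under the default kinetics, matching the study design. |
| `dt`         | 0.1 h | integration step. |

The noise model deserves emphasis: batches within a campaign share
identical deterministic state trajectories and differ *only* in their
measurement-noise draws. Real campaigns additionally carry biological
batch-to-batch variation (inoculum state, media lots) that is slow and
strongly autocorrelated in time. Passing tests on this generator therefore
demonstrates that the pipeline detects a metabolic shift against analyzer
noise; it does not demonstrate robustness to confounding biological
variation. Cell death and declining viability are not modelled, nor are
pH/DO/osmolality dynamics or perfusion operation. Lactate accumulates
throughout (no lactate-consumption switch), reaching unrealistically high
absolute concentrations late in the run; only rates, not absolute
concentrations, feed the downstream models, and all models are
unit-variance scaled, so this distorts nothing the method consumes.

The generator retains its noise-free dense state trace (including the
instantaneous per-cell rates) on each `BatchRecord`; `true_specific_rates`
exposes it as the ground-truth oracle for rate-recovery tests.

## 2. Transport rates from mass balance (`transport`)

For a constant-volume vessel, medium mass conservation gives
`q_met(t) = (1/VCD(t)) · d[Met]/dt`, positive for secretion. Bolus feeds
make the raw concentration series non-differentiable, so a
*pseudo-concentration* is built first: for nutrients the recorded
concentration jump of each feed is subtracted from all later samples; for
by-products the concentration lost to feed dilution (last measured value
before the feed times 1 − dilution factor) is added back. The pseudo
series evolves by cellular activity alone.

Noise is removed by least-squares polynomials whose derivative is taken
analytically; VCD enters through its own smoothed series. Two choices
matter:

* **Per-phase fitting.** Polynomials are fitted separately to the unfed
  and fed phases (split at the first feed; a sample timestamped exactly at
  a feed belongs to the unfed phase). The phases differ in feeding regime
  and — in shift experiments — temperature, so a single global polynomial
  leaks information across the boundary: the fitted pre-shift segment of a
  shifted batch absorbs post-shift curvature, which both biases the
  recovered rates and lets control charts "detect" the shift a day before
  it happened. Per-phase fitting eliminates this leakage and also removes
  the systematic bias between 9-day and 10-day campaigns fitted over
  different domains.
* **Span-proportional degree.** The configured degree (default 4)
  describes the flexibility granted to the full 10-day trajectory — enough
  for one inflection without ringing. Each phase receives
  `ceil(degree · phase_span/total_span)` (so ~2 for the 3-day phase, ~3 for
  the 7-day phase), additionally capped at `n_points − 2` so the fit always
  retains a residual degree of freedom: an interpolating polynomial cannot
  smooth, and its derivative merely amplifies the noise.

Rates are reported at sample times only. Estimates within 12 h of any fit
boundary (batch start/end and the phase split) are flagged `edge` — the
derivative of a least-squares polynomial is least reliable there — but not
dropped; downstream consumers decide.

## 3. Constrained flux balance analysis (`network`, `fba`)

A stoichiometric network (JSON; bundled toy model of ~15 lumped
central-carbon reactions) defines `S`. At each sample time the measured
transport rates constrain their linked exchange reactions to
`[q − 0.3|q| − ε, q + 0.3|q| + ε]` (ε = 10⁻⁶ keeps a measured zero from
becoming a brittle equality), and biomass is maximized subject to
`S·v = 0` and bounds. Each timepoint is an independent pseudo-steady-state
snapshot. One derived quantity joins the flux vector: the total ATP
generation rate, `Σ_j max(0, s_ATP,j · v_j)`.

Numerical choices:

* LPs are solved with HiGHS (`scipy.optimize.linprog`); steady-state
  residual and bound satisfaction are asserted at 10⁻⁸ in tests.
* FBA optima are degenerate, and monitoring needs a reproducible flux
  vector, so every optimal solve is tie-broken parsimoniously: biomass is
  pinned at its optimum (equality row) and Σ|v| minimized via split
  variables.
* Infeasible timepoints (possible when noisy edge-of-batch rate estimates
  demand, e.g., glucose secretion) are recorded as missing rows with a
  diagnostic of the active bands; a batch infeasible everywhere is a hard
  error.
* The toy network's lumped oxidative phosphorylation yields an effective
  1.5 ATP per pooled NADH/FADH₂ carrier (~22 ATP per respired glucose).
  Besides being a defensible leak-inclusive P/O, this keeps the biomass LP
  ATP-limited across the whole physiological range of lactate:glucose flux
  ratios, so the optimal basis — and with it the mapping from measured
  rates to fluxes — does not flip between noise realizations. At textbook
  yields the carbon-/ATP-limited boundary falls inside the operating range
  and flux columns turn bimodal, which unit-variance scaling then amplifies
  into spurious chart excursions.
* ATP maintenance is a hydrolysis reaction with fixed lower bound
  0.02 pmol/cell/h, scaled to toy-network magnitudes.

## 4. Latent-variable core (`latent`)

All monitoring models operate on column-wise centred, unit-variance-scaled
matrices (zero-variance columns — fluxes pinned across all training rows —
are dropped, and new data always uses the training scaler). PCA runs on an
SVD; PLS1 (single response) runs NIPALS with the response as deterministic
start, tolerance 10⁻¹⁰, ≤ 500 iterations per component. Every loading /
weight vector is sign-normalized (largest-magnitude entry positive) so
refits are bit-reproducible. New-data projection for PLS1 uses
`R = W(PᵀW)⁻¹`, which reproduces training scores exactly. The response
(batch maturity, hours since inoculation) is centred and unit-scaled. The
component counts are configuration inputs (defaults: 3 for the evolution
model — its charts are read on components 1 and 3 — and 2 for the
batch-level model); no cross-validated selection is performed.

## 5. Monitoring (`monitor`)

**Alignment.** Batches are matched on a daily anchor grid (24 k hours): an
anchor survives if every batch has a sample within ±2 h, values come from
the nearest such sample (never extrapolated), and near-ties resolve to the
earlier sample, which automatically excludes post-feed extra samples. The
shortest batch ends the grid; `max_time_h` can truncate it further, which
is how a 10-day training campaign and a 9-day validation campaign are made
comparable (intersection truncation).

**Batch evolution model.** Observation-wise unfolding (one row per
batch/time pair), PLS1 against maturity, then per-component control charts:
mean ± 3 SD (n−1 denominator) of the training batches' scores at each grid
time. Training batches can never breach their own chart (a member of a
6-point sample lies within 2.04 SD of its mean); held-out batches are
projected with the training scaler and loadings. An *excursion* is a run of
`k` consecutive grid points with any monitored component outside its
limits; `k` defaults to 1, and the campaign-level detection analyses use
k = 3, because with limits estimated from six batches the per-point false
alarm rate is ~1–2% — isolated single-point flags are statistically
unavoidable and are what the coverage statistic accounts for, while a
three-day run is unambiguous. With daily sampling the shift (which occurs
at the day-3 feed) can first be expressed at the day-3 sample itself; a
first sustained excursion at exactly the shift timestamp is therefore
detection at onset, not a pre-shift false alarm.

**Batch level model.** Batch-wise unfolding (one row per batch, columns
time-major over time × variable), PCA, then a deliberately simple
classifier mirroring a left-half/right-half reading of the score plot: the
discriminating component maximizes |Δ class mean|/pooled SD, the threshold
is the midpoint of the class means, orientation records which side is
normal, and an exact tie classifies as shifted (conservative). Class score
means that coincide raise an error rather than producing a zero-width
threshold.

## 6. Problem sizes and determinism

The bundled study design — and the scale at which the acceptance analyses
run — is the full two-campaign experiment: 24 batches (12 normal,
12 shifted) for 10 days plus 22 batches (12 normal, 10 shifted) for 9
days, ~1 600 LP solves in total, a few seconds end to end on one CPU. All
randomness flows from a single seed through `numpy` `SeedSequence` spawns
(one child per batch), so identical seeds give byte-identical campaigns;
CSV outputs are pinned to 12 significant digits.

## 7. Known limitations

* The generator's batch-to-batch variation is measurement noise only
  (Section 1); chart false-alarm behaviour on real data, where slow batch
  effects dominate, will differ.
* Rate estimates at fit boundaries are noisy by construction; day-0
  estimates occasionally imply infeasible FBA constraints and produce
  missing flux rows, which alignment then drops from the common grid.
* The unfed phase offers only four samples, so its quadratic smoother has
  high variance; with 5% analyzer noise, single-batch rate estimates there
  carry ~20–30% uncertainty, and in roughly one simulated study in twenty
  a held-out shifted batch lands on the wrong side of the batch-level
  threshold.
* Flux magnitudes are only as accurate as the toy stoichiometry; because
  every model is unit-variance scaled, monitoring depends on relative, not
  absolute, flux correctness.
* Classification requires the stored alignment grid to be covered by the
  batch being classified; batches missing a grid anchor are rejected, not
  imputed.
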