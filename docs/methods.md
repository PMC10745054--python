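# Methods

This note records the models implemented by `franzperm`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic generator does and does not emulate.

## Study conventions and units

All computation uses a single unit system — µg, µg/mL (≡ µg/cm³), mL
(≡ cm³), cm², h — with water-loss values kept separately in g/(m²·h).
The default protocol constants mirror the static Franz-cell setup the
package models: receptor volume Vc = 3 mL, orifice area A = 1.86 cm²,
aliquot volume Vs = 0.2 mL, sampling at 0, 0.5, 1, 2 and 4 h, and a
pseudo-infinite dose of 300 µL at 1% w/v (C0 = 10,000 µg/mL, 3,000 µg
applied). All are overridable through `FranzCellSpec`, `DoseSpec` and
the YAML config.

The "1%" donor solution is interpreted as w/v, giving C0 = 10⁴ µg/mL;
this is the reading under which `Kp = J/C0` lands in the reported
10⁻³ cm/h range for all seven analytes.

## Sampling-corrected cumulative release

With withdraw-and-replace sampling, the receptor is diluted at every
sample. The cumulative amount per unit area

    Qn = (Cn·Vc + Σ_{i=1..n−1} Ci·Vs) / A

restores exactly the mass removed by earlier aliquots; the module's
invariant (tested against an independent mass ledger) is that on
noise-free simulated data the correction reproduces the true
transferred mass to better than 1e−10 relative at every time point.
The correction sum runs over all strictly earlier samples; a time-0
sample (usually ≈ 0) participates like any other withdrawn aliquot.

Two data-hygiene rules sit in front of the correction:

* **Quantification limits.** Readings strictly below the analyte's LoQ
  are replaced according to a policy — `zero` (default), `half_loq`, or
  `keep`. Source studies rarely state how sub-LoQ readings were treated;
  zeroing is the conservative choice and the replacement count is kept
  in metadata so the effect is auditable.
* **Negative readings.** The CSV reader rejects negative concentrations
  outright (they indicate a corrupted table); for series assembled in
  memory, small negatives from instrument noise are clipped to zero
  before the correction, with a warning count in metadata.

Percent-of-dose profiles default to normalizing by the applied donor
mass (`Qn·A / dose × 100`); normalizing by the final recovered amount
is available (`basis="recovered"`) because both conventions appear in
published permeation figures.

## Kinetic models and selection

The three candidate laws are the standard ones used in release-kinetics
work:

| model | form | parameters p |
|---|---|---|
| zero order | Q = J·(t − Tl) | 2 |
| first order | Q = Q∞·(1 − e^{−k·t}) | 2 |
| Higuchi | Q = K_H·√t | 1 |

The zero-order fit is the plain two-parameter OLS of Q on t (J = slope,
Tl = −intercept/slope clipped to [0, t_max)); R² is computed on the OLS
line. The Higuchi coefficient has the closed form K_H = Σ Q√t / Σ t
(one-parameter least squares through the origin in √t). The first-order
fit is a bounded Levenberg–Marquardt/TRF solve with starting values
Q∞₀ = 1.2·max Q and k₀ log-linearized from the first two nonzero
points, up to 5 deterministic restarts. Q∞ is capped at 10³ × max Q: a
larger Q∞ is observationally indistinguishable from a straight line on
the sampling window, and an unbounded solver stalls while drifting
toward infinity. Failures and non-positive parameters yield a fit
flagged *degenerate* rather than an exception; an all-zero profile is
degenerate for every model.

Selection maximizes R² adjusted for degrees of freedom,
R²_adj = 1 − (1 − R²)(N − 1)/(N − p − 1), over the non-degenerate
candidates, with ties broken toward fewer parameters and then by the
fixed order zero-order → Higuchi → first-order. With N ≤ p + 1 the
adjustment is undefined and the fit scores −∞.

## Flux, permeability, lag

Steady-state flux is estimated independently of the model fit, from the
terminal linear portion of Q(t): the longest contiguous window ending
at the last sample, of at least 3 points, whose straight-line R²
reaches 0.99; if none qualifies, the terminal 3 points. Both thresholds
are exposed (`--linear-r2`, `--min-window`); 0.99 is strict enough to
exclude the lag phase while keeping the 3 post-lag points of the
standard 5-point schedule. J is the window slope clipped at zero; the
lag time Tl is the window line's time-intercept clipped at zero. Since
the zero-order model fit also produces a lag estimate, both are
reported (`lag_tl` from the window, `lag_tl_model` from the fit) — the
two conventions coexist in practice and need not agree on curved data.

Kp = J/C0 holds exactly by construction, and is invariant to jointly
rescaling C0 and the measured concentrations. Cmax is reported as the
maximum measured receptor concentration (µg/mL) together with the
maximum per-area amount (µg/cm²), because both units are used as
"maximum concentration" in the literature; tmax is the earliest sampled
time attaining the concentration maximum. AUC is the linear trapezoid
over the sampled times (exact for piecewise-linear profiles).

## Barrier screening

Percent reduction is (control − treated)/control × 100, with the
control taken as the mean over the membrane's untreated replicates.
The cross-membrane regression is OLS of tissue TMWL on surrogate TMWL
over formulation means — means, not replicates, because the bundled
panel reports means; R² is direction-invariant but slope/intercept
follow the tissue-on-surrogate convention. The regression is pooled
across formulation classes by default (per-class regressions are
available by filtering the records).

The Kruskal–Wallis test uses midranks and the standard tie correction,
with the chi-square p-value (k − 1 degrees of freedom) by default. At
the group sizes typical of permeation work (n = 3–4 per group) the
chi-square approximation is known to be rough — differences from the
exact permutation p of up to ~0.1 are normal and are a property of the
approximation, not of the implementation. A seeded Monte-Carlo
permutation p (`exact=True`) is therefore provided and is the
recommended p-value at small n; it is validated against full
enumeration of group assignments in the test suite.

## The synthetic generator

The generator emulates the measurement chain of a Franz-cell study:

1. **Membrane transport.** An ideal homogeneous Fickian slab with a
   constant-concentration donor face and perfect-sink receptor face;
   Q(t) follows the classical lag-time eigenfunction series with
   J∞ = K·D·C0/h and T_lag = h²/(6D). The series is truncated at
   `n_series_terms` (default 50) and refuses to run if the first
   neglected term at the earliest positive time exceeds 1e−9 of the
   steady-state slope; truncation residue at t ≈ 0 is clipped to keep
   Q non-negative.
2. **Sampling.** An exact mass ledger: before sample n the receptor
   holds the transferred mass minus all previously withdrawn aliquots;
   the measured concentration is the true receptor concentration times
   (1 + ε) with ε ~ Normal(0, CV), truncated at −3σ so concentrations
   stay positive. Proportional (CV-parameterized) noise matches how
   chromatographic error behaves over these concentration ranges.
   Default CV 5%.
3. **TMWL panels.** tmwl(membrane, formulation) = baseline × multiplier
   × (1 + ε), with baselines 80.8 and 72.4 g/(m²·h) for the synthetic
   membrane and mucosa, multipliers shared across membranes (optional
   per-membrane jitter emulates formulation–membrane interaction), and
   controls at multiplier 1. Default multipliers are derived from the
   bundled panel's synthetic-membrane column, so the simulated panel
   has the observed class structure (hydrophobic ≪ liposomal <
   hydrophilic).

**Membrane presets.** Slab thicknesses follow the study preparations —
0.05 cm (skin) and 0.06 cm (mucosa) from the dermatome setting, 10 µm
for the track-etched polycarbonate. Diffusivities (1.5, 2.4, 1.0 ×10⁻³
cm²/h respectively) are set so lag times are a fraction of an hour,
consistent with profiles that approach steady state within the 4-h
sampling window. The per-analyte partition coefficient is then
back-solved as K = Kp·h/D from the bundled reference Kp table, so each
simulated membrane×analyte pair has exactly the published true Kp
(0.2–5 ×10⁻³ cm/h for skin up to ~40–70 ×10⁻³ cm/h for the synthetic
membrane). These presets are order-of-magnitude stand-ins that place
the generator in the right permeability regime; they are not fitted
transport constants for real tissue.

**Seeding.** One root seed; `SeedSequence.spawn` assigns an independent
child stream to every diffusion cell in membrane × analyte × replicate
enumeration order, with a final stream for the TMWL panel. Fixture
output is byte-identical for identical configurations.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: donor depletion (the sink/pseudo-infinite
idealization means a high-permeability membrane can nominally transfer
more than the applied dose over 4 h), solvent evaporation and
penetration enhancement, membrane heterogeneity and biological
variability between cells, mucus/saliva binding, metabolism, and any
mechanistic action of the formulations (their effects are
phenomenological multipliers). Recovery results on synthetic data
demonstrate the correctness of the bookkeeping and estimation, not the
biological fidelity of the transport model.

## Problem sizes in the verification runs

The recovery experiments use one cell per membrane per seed over 20
seeds at noise CV 5% (60 analyses) for Kp recovery, 10 random membranes
for the exactness check, 20 seeds of the 16-formulation two-membrane
panel for correlation recovery, and 10⁵ permutations against a
560-arrangement full enumeration for the rank-test check. These sizes
give stable medians while keeping the scripts quick to re-run.

## Known limitations

* The linear-portion rule (R² ≥ 0.99, ≥ 3 points, terminal window) is a
  reasonable default, not a universal standard; strongly concave
  profiles fall back to the terminal 3 points, where "steady-state
  flux" is itself questionable.
* First-order parameters are weakly identified when the data do not
  plateau inside the sampling window; such fits are legitimate but
  their Q∞ should not be over-interpreted.
* The chi-square Kruskal–Wallis p is inaccurate at n ≤ 8; use the
  permutation p there.
* With only 5 sampling points, the adjusted-R² comparison between
  2-parameter models rests on 2 residual degrees of freedom; model
  attribution is reliable for clean data but noisy profiles can swap
  closely competing models.
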