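# Methods

## Model

The network couples five two-state proteins to a survival score.  Each
protein X exists as an active amount `Xac` and an inactive amount `Xi`; every
transition is first-order mass action, and the two forms of a pair share one
flux with opposite signs, so `Xac + Xi` is conserved exactly — in the code
the flux is computed once and applied as ±f, making the conservation identity
hold in floating point, not merely to solver tolerance.

Herceptin is a constant input (level 100), not a state variable: it drives
HER2 inactivation (`d1·HER2ac·Herceptin`) without being consumed.  Active
HER2 activates ERK1/2, JNK1/2 and p38; active DUSP deactivates JNK1/2 and
p38 (not ERK1/2).  The survival score integrates
`s1·ERK12ac − s2·(JNK12ac·P38ac)^hill` with hill = 0.6, a modified Hill
term expressing the cooperative anti-proliferative action of JNK and p38.
The power is evaluated as 0 when the product is 0; no smoothing is applied,
and no floor is placed on Survival — it is an abstract score whose *shape*
carries the biology, so it may go negative.

Three topologies differ only in the DUSP activation flux `k5·DUSPi·I`:

* **CONSTITUTIVE** — `I = 1`; the baseline model of DUSP16, which has no
  known inducer.
* **ERK12** / **JNK12** — `I = ERK12ac` or `I = JNK12ac`; candidate
  induction mechanisms for DUSP8.  Multiplying the activation flux by the
  inducer's active amount is the simplest mass-action reading of "inducible
  by", and it preserves the pair conservation structure.

## Parameters and initial condition

The model's behaviour is reported for a **reference parameterization**: all
activation/inactivation rates `k1–k5, d1–d5` and both survival weights
`s1, s2` equal 1, `hill = 0.6`, `herceptin = 100`, and every protein total
100 (all in consistent but arbitrary model units; the time unit is likewise
arbitrary).  Only the Hill exponent, the Herceptin level and the initial
amounts are externally prescribed; the unit rates are the package's own
reconstruction, chosen as the least-informative point that reproduces the
full qualitative phenomenology — verified analytically via the closed-form
asymptotic slope: positive at d5 ∈ {1, 10, 20}, negative from d5 = 50
upward in the constitutive topology, and positive at every scanned d5 in
both induced topologies.

Initial amounts are read as **active**-form amounts: HER2ac = ERK12ac =
DUSPac = 100 and JNK12ac = P38ac = 0, with each inactive pool set to
total − active (so JNK12i = P38i = 100, the others 0).  This gives the
initially-inactive kinases a working pool to activate from and makes every
pair share the same conserved total.  Survival starts at 0; since only the
trajectory's shape is interpreted, the offset is immaterial.

`d5`, the DUSP inactivation rate, is the inhibition knob: the published scan
grid is {1, 10, 20, 50, 100, 500}.

## Integration

`scipy.integrate.solve_ivp` with LSODA, rel_tol 1e-8 / abs_tol 1e-10.  The
`Herceptin·HER2` term creates rates ~1e4 beside relaxation rates ~1, so a
stiff-capable adaptive method is required.  The default horizon is t = 10
with 1001 output points: the slowest protein mode relaxes at rate ≥ k5 + d5
≥ 1 (MAPK pairs faster), so by t = 10 the protein subsystem has fully
equilibrated and the survival tail is governed by the asymptotic slope.
Halving the relative tolerance changes final survival by < 1e-4 relative
(tested).  Two identical runs produce bitwise-identical output.

The constitutive DUSP pair is autonomous and linear, with exact solution
`DUSPac(t) = C + (100 − C)·e^−(k5+d5)t`, `C = 100·k5/(k5+d5)`.  The test
suite requires the integrator to match this closed form to ≤ 1e-6 relative
error at every grid point, and requires the closed-form fixed point to zero
the derivatives to ≤ 1e-8.

## Regime classification

A survival curve is summarised by its initial, final and maximum values and
its range (max − min) on the discrete output grid — no interpolation, for
exact reproducibility.  Labels:

* **INCREASING** when `s_max − s_end ≤ eps_frac·range` (the maximum is
  effectively terminal); zero-range curves are INCREASING by convention.
* **INFLECTED** otherwise, when the interior rise `s_max − s0 >
  delta_frac·range` (substantial growth before the fall, as at d5 = 50).
* **DECREASING** otherwise (only a brief transient rise, as at d5 ≥ 100).

Defaults `eps_frac = 0.01`, `delta_frac = 0.05` separate the visually
"inflected" curve from the near-immediately decreasing ones; the decision
uses only ratios of survival excursions, so it is invariant to positive
affine rescaling of the survival column.  "Eventually decreasing" means
`s_max − s_end > eps_frac·range`, and the smallest such d5 in a scan is the
re-sensitization threshold; it coincides with the first grid point whose
analytic slope is negative in all three topologies (tested).

## Synthetic data

The generators are pure functions of their inputs and a seed
(`numpy.random.default_rng`); they emulate the *statistical structure* of
the study's assays, not their biology:

* **Noisy trajectories** — multiplicative Gaussian noise,
  `obs = true·(1 + sd·Z)`, per replicate and grid point.  Default sd 5%,
  3 replicates.
* **Cell counts** — per condition (sensitive/resistant × NT/shDUSP8/shDUSP16
  × ±Herceptin), replicates are `truth·exp(sd·Z)` (lognormal, so counts stay
  positive; the truth is the median).  The default effect map encodes the
  qualitative experimental outcome: under Herceptin, resistant NT cells grow
  1.8× relative to sensitive, DUSP16 silencing pulls them back to 1.0
  (decrease vs NT) and DUSP8 silencing pushes them to 2.3 (increase vs NT);
  without drug all lines grow alike.  The magnitudes are free choices of
  plausible size — the study reports directions and significance, not
  replicate variances — and 5% noise with 2 replicates makes the DUSP16
  contrast callable in ≥ 90% of seeds (tested over 50).
* **qPCR Ct tables** — per sample (line × silencing), targets DUSP8/DUSP16
  plus housekeeping genes ACTB and GAPDH at fixed baseline Ct (18/20 for the
  housekeepers, 25 for targets); the silenced sample's own target Ct is
  raised by `−log2(1 − kd)` cycles so the noiseless ddCt fold change equals
  `1 − kd` exactly (round-trip tested).  Default knockdown 75%, matching the
  selection rule that retained only vectors with > 70% suppression.  Gaussian
  Ct noise, clipped to (0, 40].

What passing these tests does **not** show: the generators have no plate or
batch effects, no primer-efficiency deviations from 2-fold per cycle, no
correlation between replicates, and no mechanistic link between the model's
survival score and the 72-h fold changes — concordance is directional only.
Real data would stress exactly those gaps.

## Parameter estimation

Unweighted least squares between simulated and observed species over the
output grid, replicates pooled (no variance model is available to weight
with).  Free parameters are optimised in log-space
(`scipy.optimize.least_squares`, trf), which enforces positivity without
constraints; initial guesses are explicit, with no random restarts.
Non-convergence is reported in the result, not raised.  The constitutive
DUSP subsystem identifies d5 from DUSPac alone (relaxation rate k5 + d5 and
asymptote 100·k5/(k5+d5)); survival observations add leverage on the
s-weights.  Recovery contracts (tested): d5 = 50 from 5%-noise data to
≤ 10% relative error, noiseless recovery to ≤ 0.1%, and median error
non-decreasing in noise over 20 seeds.  The recovery tests use a coarser
101-point grid, which retains full identifiability.

## Experiment statistics

* **ddCt** — `dCt = Ct(target) − mean Ct(housekeeping)` per sample (the two
  housekeepers are combined by the arithmetic mean of their Ct, making the
  result order-invariant), `ddCt = dCt(sample) − dCt(reference)`, fold
  `2^−ddCt`.  By default each sensitivity group's NT sample is its own
  reference, the usual contrast for knockdown efficiency.
* **Z-test** — two-sample test on means with independent standard errors,
  `z = (m_a − m_b)/√(se_a² + se_b²)`, two-sided normal p.  Identical groups
  give z = 0, p = 1; zero spread in both groups is undefined and rejected.
  With n = 2 per group the normal reference is anti-conservative — this
  mirrors the assay's analysis choice rather than recommending it.
* **Concordance** — per silencing condition, the model's direction
  ("decrease" if any scanned d5 gives a negative asymptotic slope under that
  condition's induction topology: constitutive for DUSP16, ERK12-induced for
  DUSP8) is compared with the observed direction (sign of silenced − NT
  means in resistant cells under Herceptin, called only when p < alpha,
  default 0.05; otherwise "none" and flagged non-informative).

## Pipeline

A YAML config (empty file = defaults) selects parameter overrides, topology,
d5 grid, solver options and synthetic-data settings; unknown keys are
rejected by name.  `run_pipeline` chains scan → classification → synthetic
experiments → ddCt → concordance and writes CSV/JSON/TSV artifacts, each
embedding provenance (config hash, seed, package version) and no timestamps,
so identical configs yield byte-identical outputs (tested).  The `duspkin`
CLI exposes the stages as subcommands.

## Known limitations

* The unit-rate reference parameterization is a reconstruction validated
  against qualitative regime behaviour, not against measured kinetics; only
  relative statements (regime boundaries, direction of change) should be
  interpreted.
* Model time and amounts are unitless; the mapping between the model's
  Herceptin level 100 and the experimental 50 µM dose is unspecified.
* One DUSP node lumps DUSP8 and DUSP16; DUSP overexpression in resistant
  lines is not represented in the qPCR baselines.
* Survival is a phenomenological score (proliferation and death are not
  separated), and no stochastic, spatial or pharmacokinetic effects are
  modelled.
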