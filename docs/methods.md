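# Methods

## Model structure

The heat shock response is modelled as a deterministic ODE system over 12
species: functional and misfolded protein (P, P#), inactive and active stress
kinase (SK, SK\*), free and phosphorylated heat shock factor (HSF, HSF\*),
the generic heat-shock gene locus in three occupancy states (G free, HSFG
blocked by unphosphorylated HSF, HSF\*G transcribing), the two mRNAs (mR_F,
mR_HP) and the generic heat shock protein HP. The cytosolic and chloroplast
chaperone families are deliberately collapsed into the single HP variable,
and all heat-shock promoters into the single locus G; the model aims at the
dynamics of the response as a whole, not at isoform resolution.

Rate laws: protein denaturation is Arrhenius in temperature, anchored at a
reference temperature so that `k_TP` is the denaturation rate at `T_ref`
(25 °C) rather than an extrapolated prefactor — the two forms are equivalent
up to reparameterization, but the anchored one is numerically
well-conditioned and directly interpretable. Kinase activation is Hill in
P# (cooperative sensing of misfolded protein); HSF phosphorylation by SK\*
is Michaelis–Menten; everything else is mass action. Phosphorylation and
dephosphorylation act only on free HSF; gene-bound HSF does not interconvert
on the promoter (the simplest mechanism consistent with the network
topology). HSF is an open pool — it is synthesized from its own mRNA and
degraded first order — whereas the protein, kinase and gene pools are closed:
P + P#, SK + SK\*, G + HSFG + HSF\*G are conserved identically. The
right-hand side is assembled so the conservation is exact in floating point
(the free-gene derivative is computed as minus the sum of the bound-state
derivatives).

Units: concentrations in mM (forced by the printed unit of the refolding
constant, (mM s)⁻¹), time in seconds internally (minutes/hours at
interfaces), temperature in Kelvin internally (°C at interfaces). The three
conserved pool totals are configuration, set to 1.0 mM each, so the protein,
kinase and gene panels read directly as fractions; the mRNA and HP scales
are arbitrary units — every comparison with data is made on max-normalized
curves, and the package exposes (and tests) the corresponding exact
invariances.

## Parameters

All defaults live in `src/hsrsim/data/final.txt`; `fiducial.txt` holds the
same values rounded to two significant figures and is the starting point of
the calibration machinery. The two constants printed in the literature for
this system are adopted verbatim: `kp_F = 1.09 s⁻¹` (HSF phosphorylation
catalytic constant) and `k_P = 9.938 (mM s)⁻¹` (chaperone-mediated
refolding). The remaining values are this package's own calibration: the
source study's full parameter table is not publicly deposited, so the set
bundled here was tuned once — against the study's printed, physiology-scale
outcomes rather than against its raw curves — and then frozen. The anchors
used were: ~5% peak misfolded protein and ~80% peak kinase activation after
a 25→42 °C step; mRNA peaking 0.5–1.5 h after the shock and decaying
afterwards; relaxation of the system within ~5 h; < 0.25% misfolded protein
and ~4% kinase activation under a 22–40 °C diel cycle; a ~20-fold ratio
between the fast- and slow-ramp plateaus of the peak misfolded fraction; and
a double-shock recovery interval of 5 h. No value was adjusted after that
freeze.

| parameter | value | units | meaning / rationale |
| --- | --- | --- | --- |
| k_TP | 3.542e-8 | s⁻¹ | denaturation rate at 25 °C; sets the resting misfolded fraction (~0.02%) |
| E_A | 3.5e5 | J mol⁻¹ | activation energy, inside the literature range for protein denaturation (1–6 ×10⁵); gives a ~2000-fold rate increase from 25 to 42 °C, needed so a quiet baseline coexists with a strong shock |
| T_ref | 298.15 | K | Arrhenius anchor (25 °C) |
| k_P | 9.938 | mM⁻¹ s⁻¹ | refolding by HP (printed value) |
| k_S / kp_S | 7.16e-2 / 1.63e-2 | s⁻¹ | kinase (de)activation; ratio sets 80% activation at the shock's P# level and ~4% at diel levels; kp_S gives ~1 min response time |
| m, P0 | 2.354, 1.461e-2 mM | – | Hill sensing of P#; the threshold sits well below the shock peak (5% of pool) and just above diel excursions |
| kp_F, K_F | 1.09 s⁻¹ (printed), 4.19e-2 mM | | Michaelis–Menten phosphorylation of HSF by SK\* |
| k_F | 2.976 | s⁻¹ | HSF\* dephosphorylation; fast, so promoter occupancy tracks kinase activity |
| k_FaG / kp_FaG | 50 / 2.12e-2 | mM⁻¹s⁻¹ / s⁻¹ | HSF\*–gene binding (association well below the diffusion limit) |
| k_FG / kp_FG | 5 / 3.17e-4 | mM⁻¹s⁻¹ / s⁻¹ | inactive-HSF–gene binding; slow unbinding makes the blocked state a slow variable |
| pi_mF, pi_mH | 1e-2 | s⁻¹ | transcription from HSF\*G (arbitrary-unit scale) |
| pi_F, pi_H | 3.01e-7, 4.30e-3 | s⁻¹ | translation |
| eta_mF, eta_mH | 4.55e-4, 8.47e-4 | s⁻¹ | mRNA decay (~25 and ~14 min lifetimes): sets the ~1 h mRNA peak |
| eta_F | 3.30e-5 | s⁻¹ | HSF decay (~8 h): slow accumulation of HSF is part of the stress memory |
| eta_H | 1.53e-4 | s⁻¹ | HP decay (~1.8 h): fast enough that double-shock sensitivity recovers in ~5 h, slow enough that HP outlives the mRNA burst |

"Rate constants" here means these 19 kinetic constants; `m`, `P0`, `E_A` and
`T_ref` are regulatory/thermodynamic parameters and the pool totals are
configuration — the calibration machinery scans and optimizes the 19 by
default and holds the rest fixed.

## Simulation

Runs start from the steady state at the protocol's initial temperature
(evaluated just *before* t₀, so a shock applied exactly at t₀ starts from
the unstressed culture). Steady states are found by long-horizon LSODA
integration (default 4×10⁷ s in 16 checkpointed chunks) followed by a Newton
polish (`scipy.optimize.root`, hybr) in log coordinates on the pool-reduced
9-dimensional system; convergence means a right-hand-side max-norm below
10⁻⁹ mM/s. The integrator is restarted at every protocol discontinuity
(step and pulse edges, ramp endpoints), with the temperature clamped to the
open segment so the stiff solver never samples across a jump. Defaults:
LSODA, rtol 10⁻⁸, atol 10⁻¹³ (far below the smallest resting concentrations,
~10⁻⁹ mM). Output concentrations are clipped at zero; the pre-clip minimum
is retained as a diagnostic and stays above −10⁻¹² in all scenarios.
Conserved pools drift by < 10⁻¹⁴ relative in practice (asserted < 10⁻⁶).
Time-of-maximum ties break to the earliest grid point.

One numerical caveat, discovered during validation and kept deliberately
visible: the calibrated system has a very slow relaxation manifold (the HSF
feedback loop is close to marginal at its operating point), so after hours at
high temperature the observable fractions sit on a quasi-steady plateau that
drifts toward the mathematical fixed point over much longer times. The
acclimation detector therefore reports a *quasi-steady* phase — trailing-1 h
relative drift below 2×10⁻³ — and the distance to the asymptotic steady
state separately; the misfolded fraction at the 10 h plateau is within a
factor ~2 of its asymptotic value.

## Calibration

The objective is a single pooled RMS over all observation points of both
mRNA species and all replicate curves, with equal weight per point. Because
the data are relative (each measured curve normalized to its own maximum),
the simulated curve is max-normalized over the species' observation times
before comparison; this is the declared convention, and it has a structural
consequence worth stating: the scale of the mH→HP arm is a *gauge freedom*.
Multiplying `pi_mH` (or `pi_H`) by c and conceptually dividing HP's unit by
c leaves every observable unchanged, and `k_P` compensates the HP scale
exactly. These parameters are therefore individually unidentifiable from
relative mRNA data — only products along the chain are constrained — which
is the package-level reflection of the general observation that such data do
not pin down this model's parameters uniquely. The default recovery study
consequently perturbs three *identifiable* constants (kp_F, eta_mF, eta_mH);
recovery from noise-free data is exact to ≪1% in log space, and the
test suite demonstrates both this and the gauge degeneracy.

The Monte Carlo scan draws each rate constant independently and uniformly
(linear scale) in [0.5, 2.0] × its fiducial value, evaluates the RMS per
draw (integration failures score +∞ rather than being redrawn, keeping the
prior flat), and is reproducible from its seed. `select_best` keeps the k
lowest-RMS draws with ties broken by draw order, for projection plots. An
optional validator warns when second-order constants exceed a configurable
association-rate ceiling (diffusion-limit guard).

Steepest descent works in log-parameter space: central finite-difference
gradients (relative step 10⁻³), a normalized descent direction, and a
backtracking line search that halves the step until the objective decreases
— so the RMS history is non-increasing by construction. Stopping: relative
improvement < 10⁻⁴ (10⁻⁵ in recovery studies), a stalled line search, or the
iteration cap. The one-at-a-time sensitivity analysis reports the RMS at
(1 ± ε) × each constant (default ε = 0.05).

## Synthetic data

The generator emulates the structure of relative qRT-PCR-style feeding-
experiment controls: a 25→40 °C step at t = 0, both mRNAs sampled every
15 min over 2.5 h, six replicate curves per species, multiplicative
lognormal noise (median 1, log-sd σ = 0.2) applied independently per sample,
then per-curve max-normalization. σ = 0.2 is a typical proportional-error
level for such measurements; the replicate count mirrors the usual six
control curves per species. What it does *not* emulate: correlated errors
between time points or species, measurement-time jitter, inhibitor-treated
conditions, and any systematic normalization bias — so passing recovery
tests demonstrate the pipeline's correctness and the data's information
content under ideal noise, not robustness to real-world structured error.
Per-curve max-normalization makes the pointwise replicate log-sd slightly
exceed σ (a common-mode term from normalizing by a noisy maximum); the test
suite checks the observed scatter against this expectation.

## Experiments

- **Inhibitor titrations** scale one rate constant and re-run the standard
  25→40 °C shock from the untreated steady state: a kinase inhibitor
  (staurosporine) scales kp_F (doses 1.0/0.6/0.1; read out on HSF mRNA), an
  HSP90 inhibitor (radicicol) scales k_P (doses 1.0/0.6/0.3; read out on HP
  mRNA). The model reproduces the characteristic signatures: reduced,
  delayed HSF-mRNA response under kinase inhibition; larger, longer HP-mRNA
  response under chaperone inhibition.
- **Double heat shock** applies two 30-min 25→42 °C pulses separated by a
  recovery interval, defined end-of-first to start-of-second (a
  start-to-start convention is available). An arylsulfatase (ARS) reporter —
  transcribed from the same active promoter, translated slowly, very stable
  — is attached as a pure output (two linear ODEs driven by the gene
  occupancy trace; it feeds nothing back, and its parameters mirror the
  HP cascade with slower translation so the reporter lags the mRNA). A
  "full" second response means the second HP-mRNA peak reaches ≥ 90% of the
  first (configurable); with the bundled set the ratio grows
  0.44 → 0.68 → 0.84 → 0.91 over 2/3/4/5 h intervals, crossing the threshold
  first at 5 h, while the second misfolded-protein peak stays far below the
  first — the accumulated chaperone suppresses the stress signal but the
  Hill-sensitive kinase still fires the transcriptional program.
- **Diel forcing** is a sinusoid with the daily maximum at 15:00 and t = 0
  at midnight; one spin-up day is discarded. The response onset detector is
  a threshold on the active-kinase fraction (default 0.005, configurable);
  the response maximum precedes the temperature maximum by ~1 h.
- **Ramp scan**: temperature rises 25→42 °C along a half-cosine of duration
  τ, then stays high; the metric is the peak misfolded fraction over the
  run. Fast plateau below τ ≈ 1 min, steep fall over ~1–100 min, slow
  plateau past ~100 min; the plateau ratio is ~20 and is robust to doubling
  or halving the Hill parameters m and P0 (checked by `run_hill_robustness`).
- **Steady-state scan / HSP map**: per-temperature steady states with a
  viability flag (no convergence, or misfolded fraction above 0.5); with the
  bundled set the flag first appears near 50 °C. The HP accumulation map
  reports end-of-pulse HP relative to baseline over a (T, duration) grid;
  accumulation is monotone in duration up to the HP peak (~2 h), beyond
  which HP turnover (eta_H) bends the curve down.

## Problem sizes

Default grids were chosen so every scenario resolves its fastest visible
feature: 1200–2900 output points per run, five τ values per decade in scans,
10⁴ draws for prior-uniformity checks, 10⁶ random states for the rate-law
oracle comparison, and three perturbed constants per recovery study. The
full test suite runs in ~2 min and the acceptance script in ~2 min on one
CPU.

## Known limitations

Deterministic continuum description only (no Gillespie simulation, no
spatial or isoform resolution); total protein, kinase and gene pools are
constant, which is questionable under prolonged extreme stress or in
synchronized diurnal cultures; the bundled parameter set is calibrated to
printed summary outcomes, not to the original raw curves, so individual
rate constants should be read as one consistent realization rather than
measurements; relative mRNA data leave the chaperone-arm scale unidentified
(see Calibration); and the diel scenario ignores the circadian clock's own
regulation of heat shock genes — temperature is the only input.
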