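# hsrsim

Kinetic modelling of the heat shock response (HSR) in the green alga
*Chlamydomonas reinhardtii*.

When temperature rises, proteins denature. The cell senses the accumulating
misfolded protein P#, activates a stress kinase (SK → SK\*), which
phosphorylates the heat shock factor (HSF → HSF\*); HSF\* bound to the heat
shock gene locus G drives transcription of mRNA for HSF itself and for heat
shock proteins (HP). HP is a chaperone: it refolds P# back to functional P,
closing a negative feedback loop that shuts the response down. `hsrsim`
implements this network as a 12-species ODE system and provides everything
needed to study it quantitatively: temperature-forcing protocols, a stiff
integrator with pre-equilibration, a calibration pipeline against relative
mRNA time courses, scripted simulation experiments, and a synthetic-data
generator for parameter-recovery studies.

The package is for systems biologists who want to simulate HSR dynamics under
arbitrary temperature forcing — sudden laboratory shocks, inhibitor
treatments, repeated shocks, or the smooth diel temperature cycles a cell
meets in nature — and for method-minded users who want a compact, fully
testable example of time-course calibration (Monte Carlo prior scan plus
steepest-descent refinement with an RMS objective).

## The model

Temperature enters through Arrhenius-law denaturation of functional protein,

```
ω_TP(T) = k_TP · exp(−(E_A/R) · (1/T − 1/T_ref)),        v'_P = ω_TP(T)·[P]
```

refolding is chaperone-mediated mass action, `v_P = k_P·[HP]·[P#]`. Kinase
activation follows Hill kinetics in the misfolded protein,

```
ω_PS = [P#]^m / (P0^m + [P#]^m),         activation = k_S · ω_PS · [SK]
```

and HSF phosphorylation by SK\* is Michaelis–Menten,
`ν'_F = k'_F·[SK*]·[HSF]/(K_F + [HSF])`. Both HSF forms bind the gene locus,
but only the HSF\*-bound complex transcribes; the HSF-bound complex blocks
the promoter. All remaining steps (binding, transcription, translation,
first-order decay) are mass action. Three moiety pools are conserved exactly:
P + P#, SK + SK\*, and G + HSF\*G + HSFG; concentrations are expressed in mM
with each pool normalized to 1 mM.

Two bundled parameter files drive all experiments: `fiducial` (the manually
tuned starting point, round numbers) and `final` (the calibrated set used
everywhere, including the printed rate constants k'_F = 1.09 s⁻¹ and
k_P = 9.938 (mM s)⁻¹). See `docs/methods.md` for every parameter, its units
and its rationale.

## Worked example

```python
from hsrsim import Step, final_parameters, integrate, summarize
from hsrsim.protocols import HOUR, MINUTE

params = final_parameters()
shock = Step(T_low=25.0, T_high=42.0, t_shift=20 * MINUTE)
traj = integrate(params, shock, t_end=4 * HOUR + 20 * MINUTE)
stats = summarize(traj)

pm = stats["misfolded_fraction"]
sk = stats["active_kinase_fraction"]
print(f"peak misfolded protein : {100 * pm['max']:.1f}% of the protein pool "
      f"at t = {pm['t_max'] / 60:.0f} min")
print(f"peak kinase activation : {100 * sk['max']:.1f}% of the kinase pool "
      f"at t = {sk['t_max'] / 60:.0f} min")
print(f"HSP mRNA peaks at t = {stats['mH']['t_max'] / 60:.0f} min, "
      f"chaperone at t = {stats['H']['t_max'] / 60:.0f} min")
print(f"residual misfolded fraction after 4 h: {100 * pm['final']:.2f}%")
```

prints

```
peak misfolded protein : 4.9% of the protein pool at t = 36 min
peak kinase activation : 80.6% of the kinase pool at t = 36 min
HSP mRNA peaks at t = 72 min, chaperone at t = 120 min
residual misfolded fraction after 4 h: 0.23%
```

A sudden 17 °C shock misfolds about 5% of the protein pool and transiently
activates ~80% of the stress kinase; the transcriptional response peaks
within ~1 h and the chaperone build-up clears the misfolded protein within a
few hours. Running the same model under a smooth 22–40 °C day
(`hsrsim.experiments.run_diel`) keeps the misfolded fraction below 0.25% with
only ~4% kinase activation — the response comfortably handles natural
temperature variation, and the ramp-duration scan
(`run_tau_scan`) shows the ~20-fold gap between sudden and gradual warming.

The same functionality is available from the shell:

```sh
hsrsim simulate -p "step:T_low=25,T_high=42,t_shift=20min" --t-end 4.5h -o run.csv
hsrsim experiment diel -o out/diel
hsrsim make-fixtures -o fixtures --seed 1
hsrsim scan --data fixtures/synthetic_calibration.csv -n 200 -o scan.csv
hsrsim calibrate --data fixtures/synthetic_calibration.csv -o fitted.txt
```

## Layout

| module | contents |
| --- | --- |
| `hsrsim.model_core` | state, rate laws, reaction fluxes, ODE right-hand side |
| `hsrsim.params` | parameter container, validation, bundled fiducial/final sets |
| `hsrsim.protocols` | constant/step/pulse/double-pulse/sinusoid/cosine-ramp forcing |
| `hsrsim.simulator` | steady states, stiff integration, trajectories, summaries, CSV/JSON IO |
| `hsrsim.calibration` | RMS objective, Monte Carlo scan, steepest descent, sensitivity |
| `hsrsim.synthetic_data` | noisy relative time-course generator, recovery studies |
| `hsrsim.experiments` | scripted scenarios: inhibitors, double shocks, diel, ramps, maps |
| `hsrsim.cli` | `hsrsim` command-line interface |
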