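# memprobe

Quantitative analysis of small-molecule / lipid-bilayer interactions, built
for the workflow used to characterise membrane-active plant metabolites
(allelochemicals such as the barley alkaloids gramine and hordenine) against
model plant plasma membranes:

* **ITC** — integrate a titration thermogram into per-injection heats and fit
  the lipid-partition model to estimate the partition constant *K* and the
  water→bilayer transfer enthalpy ΔH_D^{w→b},

      Σₖ δhₖ = ΔH_D^{w→b} · V_cell · C_A⁰ · K·C_L⁰ / (1 + K·C_L⁰)

* **FTIR** — extract the sνCH₂ band position (≈2850 cm⁻¹) across temperature,
  fit a Boltzmann sigmoid, and report the lipid phase-transition temperature
  Tm and additive-induced shifts ΔTm,
* **Trajectories** — geometric post-processing of bilayer + solute coordinate
  trajectories (multi-frame GRO): insertion-depth profiles along the bilayer
  normal, hydrogen-bond counts classified by lipid chemical group
  (phosphate / ester / glycerol oxygens), and orientation-angle distributions
  of solute bond vectors and ring-plane normals,
* **Bioassay** — seedling root-length statistics: treatment summaries,
  growth-inhibition percentages, randomized-block ANOVA and Tukey HSD with a
  compact letter display,
* **Synthetic data** — ground-truth-known generators for all four input
  kinds, used throughout the test suite.

The fitting cores are scikit-learn-style estimators (`PartitionFitter`,
`BoltzmannMelt`, `BlockAnovaTukey`) with `fit`, fitted attributes
(`K_`, `tm_`, `letters_`, …) and `get_params`; thin functions
(`fit_partition`, `fit_boltzmann`, `anova_tukey_cld`, …) wrap them for
script use, and a `memprobe` CLI wraps the lot.

## Worked example

Generate a synthetic titration with known truth (K = 800 L/mol,
ΔH = −4000 cal/mol) and fit it back:

```bash
$ memprobe synth itc --seed 3 --out itc
wrote thermogram.csv, schedule.yaml, truth.json to itc
$ memprobe itc fit --thermogram itc/thermogram.csv --schedule itc/schedule.yaml --out itc
K = 800 L/mol, dH = -4000 cal/mol (converged=True)
```

The fit recovers the generating parameters: K is the partition constant
(water→bilayer) in L/mol and dH the molar transfer enthalpy in cal/mol;
`itc/partition_fit.json` adds standard errors and the residual sum of
squares, `itc/injections.csv` the per-injection heat/concentration table.

The same round trip for an FTIR melting curve (truth Tm = 23.69 °C):

```bash
$ memprobe synth ftir --seed 1 --out ftir
$ memprobe ftir tm --curve ftir/melting_curve.csv --out ftir
Tm = 23.69 C (SE 0.00), converged=True
```

and for a six-treatment root-length bioassay (`--seed 2`; means in mm,
treatments sharing a Tukey letter are not significantly different at
α = 0.05):

```bash
$ memprobe synth bioassay --seed 2 --out bio
$ memprobe bioassay --table bio/bioassay.csv --out bio
                        treatment      mean       sd  n tukey_letters  inhibition_pct
                          Control 22.425336 2.159864 14             a             0.0
                   Gramine 0.5 mM  8.782494 0.872839  7             b            60.8
Gramine 0.5 mM + Hordenine 0.5 mM  7.845177 2.533077  7             b            65.0
                     Gramine 1 mM  6.799557 2.019953  7             b            69.7
                 Hordenine 0.5 mM 17.755243 1.714850  7             c            20.8
                   Hordenine 1 mM 16.192486 1.829534  7             c            27.8
```

Here the gramine-like treatments suppress root growth by 60–70 % and
separate cleanly (letter *b*) from both the control (*a*) and the milder
hordenine-like treatments (*c*).

Trajectory analyses read a multi-frame GRO file plus a YAML selection
config mapping residues/atoms to roles:

```bash
memprobe synth traj --seed 1 --out traj
memprobe traj depth  --traj traj/traj.gro --select traj/selections.yaml --out traj
memprobe traj hbonds --traj traj/traj.gro --select traj/selections.yaml --window-ns 100 --out traj
memprobe traj angles --traj traj/traj.gro --select traj/selections.yaml --fold --out traj
```

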