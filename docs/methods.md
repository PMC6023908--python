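# Methods

`memprobe` implements the quantitative analyses used to characterise how small
amphipathic solutes — in the motivating application, the barley alkaloids
gramine and hordenine — interact with lipid bilayers that mimic a plant plasma
membrane, together with the statistics of the companion phytotoxicity
bioassay. This note records the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## ITC partition fitting (`memprobe.itc`)

**Model.** Titrating a lipid-vesicle suspension into a dilute solute solution
produces, after *i* injections, a cumulative heat

    Σₖ δhₖ = ΔH_D^{w→b} · V_cell · C_A⁰ · K·C_L⁰ / (1 + K·C_L⁰)

where K (L/mol) is the water→bilayer partition constant, ΔH_D^{w→b} (cal/mol)
the molar transfer enthalpy, V_cell the cell volume and C_A⁰, C_L⁰ the total
solute and lipid concentrations in the cell after injection *i*. The model
assumes a single partition equilibrium, fast mixing, and heats proportional to
the newly partitioned amount; no multi-site binding or kinetics.

**Dilution bookkeeping.** The instrument cell is an overflow cell of fixed
volume: each injection of volume v displaces a perfectly mixed aliquot, so the
retained fraction after injection *i* is fᵢ = Π(1 − vⱼ/V). Solute dilutes as
C_A⁰ = C_A(0)·fᵢ and syringe lipid accumulates as C_L⁰ = C_syr·(1 − fᵢ). A
no-dilution variant (C_A constant) is available as an option since published
analyses do not always state which convention their software used. Total
lipid is used in C_L⁰ — no outer-leaflet accessibility factor — for fidelity
to the printed model; an analyst wanting the ×0.5 correction can rescale K.

**Integration.** Injection windows run from tᵢ = i·spacing to the next
injection. The baseline anchors at the median of the last 10 % of each window
(the signal has relaxed there; the median resists pulse tails) and is
interpolated linearly between anchors; per-injection heat is the trapezoidal
integral of the corrected heat flow. A small priming injection (the default
programme is 2 µL followed by 28 × 10 µL into a 1456.5 µL cell, 600 s apart)
is excluded from the fitted series but kept in the dilution bookkeeping, and
the model is correspondingly re-zeroed: the fitted prediction is
F(i) − F(ref) with ref the state after the excluded injection. Skipping this
re-referencing biases K by several percent.

**Fitting.** ΔH enters the model linearly, so the fit uses variable
projection: for each K the optimal ΔH and the profiled residual sum of
squares are closed-form; the profile is scanned over log₁₀K ∈ [−3, 10]
(261 points) and refined by bounded Brent minimisation, then a final
Levenberg–Marquardt polish supplies the Jacobian for asymptotic standard
errors. A joint two-parameter descent was found to stall in the long
K·ΔH-degenerate valley at small or very large K; the projected profile has no
such valley. All-zero heat series are flagged non-identifiable rather than
fitted. Internal units are calories, mol/L and litres; file I/O is µcal/µL.

**Noise model used in recovery checks.** Parameter-recovery simulations add
iid Gaussian noise with σ = 1 % of the cumulative-heat plateau to the
cumulative series that the fit consumes. The thermogram generator instead
adds white noise to the heat flow (µcal/s), which is what a raw instrument
trace shows; both paths are exercised in tests.

## FTIR thermotropics (`memprobe.ftir`)

The symmetric methylene stretching band (sνCH₂, ≈2850 cm⁻¹) shifts upward as
acyl chains melt. Band maxima are located inside a default window of
2840–2865 cm⁻¹ and refined by a three-point parabola through the discrete
maximum, giving sub-grid precision on the 2 cm⁻¹ instrument grid; a maximum
on the window edge is flagged rather than trusted. Replicate peak positions
(three replicates by default) are averaged per temperature.

The melting curve is fitted with a four-parameter Boltzmann sigmoid

    ν(T) = ν_fluid + (ν_gel − ν_fluid) / (1 + exp((T − Tm)/w))

whose inflection is Tm. The exact parameterisation used by commercial fitting
software is rarely printed; this logistic form has its inflection exactly at
Tm, which is the quantity of interest. Initialisation: asymptotes from the
data extremes, Tm₀ at half height, w₀ = 1 °C. Fits are rejected
(converged = False) when the curve is flat, when ν_fluid ≤ ν_gel, when the
fitted width collapses below 10⁻³ °C (step-like relative to sampling), or
when the inflection falls outside the sampled range. Reported uncertainties
are asymptotic standard errors of Tm. ΔTm = Tm(with additive) − Tm(without),
with root-sum-square uncertainty; Tm is echoed at two decimals in reports and
kept at full precision internally.

## Trajectory geometry (`memprobe.traj`)

Inputs are multi-frame GRO coordinates plus a YAML selection config that tags
atoms with roles (lipid, solute, phosphate, ester, glycerol oxygens,
headgroup P, hydrogen-bond donors with their attached H, acceptors with a
chemical-group class, an orientation atom pair and a ring triplet per
solute). Masses come from a built-in element table keyed by the leading
letter of the atom name, overridable per atom name.

* **Bilayer normal** is fixed to z (the convention of the simulations these
  analyses target); no frame-wise normal refitting.
* **Periodicity**: minimal-image convention per axis; molecules are made
  whole before centre-of-mass computation.
* **Depth profile**: per frame, the mass-weighted COM of all lipid atoms
  defines the bilayer centre; solute depths are means over solute-molecule
  COM |z| offsets, phosphate and glycerol depths are means over the P and
  glycerol-oxygen atoms.
* **Leaflet assignment**: sign of the P atom's z offset from the bilayer COM.
* **Hydrogen bonds**: donor–acceptor distance ≤ 0.35 nm and H–donor–acceptor
  angle ≤ 30°, the de-facto MD community criterion (the choice is exposed as
  config since analyses differ). Both directions count — solute donors to
  lipid acceptors (classified by acceptor group: phosphate, ester, glycerol
  oxygens) and lipid donors to solute acceptors where the config defines them
  (classified by the lipid donor's group). Counts are normalised per solute;
  trailing-window means (default 100 ns) summarise the equilibrated tail.
* **Orientation angles**: θ = arccos(v_z/|v|) per solute per frame for the
  configured bond vector, and for the ring-plane normal (cross product of two
  ring edge vectors). Distributions use 2° bins on [0, 180°]; solutes in
  opposite leaflets produce supplementary populations (θ, 180° − θ), and
  `fold=True` maps both onto [0, 90°]. Mode estimates refine the winning bin
  by a local sample mean, so constructed geometries are recovered well below
  the bin width. Degenerate vectors or collinear triplets are skipped and
  counted. Which atoms define the orientation vector of a given solute is an
  interpretation the user supplies in the config; for gramine-like solutes a
  ring-carbon→amine-N vector is the natural choice, for hordenine-like ones
  phenol-O→amine-N.

## Bioassay statistics (`memprobe.bioassay`)

The experimental unit is the dish: seedling-level rows are aggregated to
per-dish means before any statistic, matching a design of 7 dishes per
treatment (14 for the twice-per-block control) even when ~75 seedlings are
measured per dish. Summaries report the arithmetic mean, sample SD (n − 1)
and n per treatment; growth inhibition is 100·(mean_control − mean)/
mean_control, reported to one decimal.

Significance uses a randomized-complete-block two-way fixed-effects ANOVA
(treatment + block; statsmodels OLS/anova_lm), with an optional one-way
fallback for designs with missing cells. Pairwise treatment comparisons use
the studentized-range distribution on the ANOVA residual mean square with the
Tukey–Kramer adjustment for unequal n, and are rendered as a compact letter
display built by insert-and-absorb, so two treatments share a letter iff
their comparison is non-significant. The letter display is verified in tests
against an exhaustive textbook sums-of-squares oracle, and the one-way mode
against statsmodels' `pairwise_tukeyhsd`.

## Synthetic data (`memprobe.synth`)

Every generator returns a truth record, and each analysis at zero noise
recovers its truth to numerical precision; identical seeds give identical
outputs.

* **ITC**: per-injection heats are successive differences of the partition
  model under the default 2 µL + 28 × 10 µL programme (10 mM syringe lipid,
  10 µM cell solute), rendered as exponential pulses (τ = 30 s) whose
  trapezoid-measured areas equal the heats, plus optional white heat-flow
  noise. Default truth K = 800 L/mol, ΔH = −4000 cal/mol — mid-range values
  for small aromatic amphiphiles. The pulse shape is schematic; only its
  area carries information.
* **FTIR**: Boltzmann curves on a 15-temperature grid with 1–3 °C steps
  (fine near the transition), three replicates, Gaussian noise; defaults
  (Tm 23.69 °C, width 0.8 °C, asymptotes 2850.5/2853.0 cm⁻¹) mimic a
  DMPC-like transition. Optional Gaussian-band spectra centred at the
  sigmoid value exercise the peak picker.
* **Trajectory**: two leaflets of role-tagged pseudo-lipids (P, phosphate and
  ester oxygens, glycerol oxygen, chain beads) on a lattice, with rigid
  5-atom pseudo-solutes (ring triplet, amine N, H) split between leaflets at
  a prescribed COM depth, bond tilt and ring tilt, mirrored across the
  midplane. Default composition 128 lipids / 32 solutes (the 4:1 ratio of
  the simulated systems), a handful of frames ~10 ns apart. A per-frame
  hydrogen-bond schedule (0–4 bonds per solute) is realised by moving a
  partner lipid's phosphate oxygen to 0.30 nm along the donor's N→H
  direction; the generator verifies no accidental contacts contaminate the
  schedule and rejects depths where they would. There is no force field,
  water, or dynamics: only the geometric observables the analyses measure
  are controlled, so passing tests validate the measurement code, not any
  physical realism.
* **Bioassay**: per-dish means = control mean × (1 − effect) + block effect +
  noise, truncated at 0; defaults are a 22.6 mm control, six treatments with
  effects from 0 to 0.726, seven blocks with the control twice per block,
  block SD 1.0 mm and dish SD 1.5 mm — magnitudes typical of seedling
  root-length assays.

## What the tests show — and what they cannot

Recovery tests demonstrate that the estimators are correct and well
conditioned under the stated noise models; they say nothing about instrument
artifacts (ITC feedback dynamics, heat-of-dilution structure beyond a smooth
baseline), spectral interference beyond a linear baseline, force-field
accuracy, or biological variability beyond additive block effects. Measured
simulation observables (adsorption kinetics, specific tilt angles of real
alkaloids) and wet-lab raw data require the original simulations and
experiments; the generator scenarios reproduce their geometric *signatures*
(interfacial location between the glycerol and phosphate shells, bimodal
supplementary tilt populations, hydrogen-bond gain on adsorption) so the
analysis code can be exercised end to end, and nothing more is claimed.

## Problem sizes

Default analysis and test sizes — 29-injection titrations, 15-temperature
melting curves, 128-lipid/32-solute toy trajectories with ≤ 6 frames,
6-treatment × 7-block assay tables, and Monte-Carlo batches of 100–500
replicates — were chosen so every recovery statistic is well resolved while
the full suite runs in a couple of minutes on one core.
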