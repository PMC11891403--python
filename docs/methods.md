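# Methods

## Scope and intent

`acylsim` implements a deliberately simplified kinetic model of the
*E. coli* fatty-acid synthesis (FAS) pathway coupled to the first two
acyltransferase steps of phospholipid synthesis, built around one
mechanistic hypothesis: acyl-CoA generated from exogenous fatty acids
inhibits FAS *indirectly*, by competing with acyl-ACP for PlsB and PlsC
and thereby letting long-chain acyl-ACP accumulate and feedback-inhibit
the ACC–FabD initiation step. Everything outside that loop is lumped or
omitted: hydroxy- and enoyl-ACP intermediates and FabI are not modelled
(initiation and elongation only), there is no transcriptional regulation
(FadR/FabR), no β-oxidation, and the PG/PE headgroup chemistry is a
single phospholipid sink. The simulator is deterministic (ODE) —
copy-number noise is irrelevant at these pool sizes.

## Model structure

Units are µM and seconds throughout; the state is a named non-negative
concentration vector over 55 species.

**Initiation.** A single lumped ACC–FabD reaction (holo-ACP +
acetyl-CoA → malonyl-ACP) with two-substrate irreversible
Michaelis–Menten kinetics and a noncompetitive Hill inhibition factor
`1/(1+(I/Ki)^n)`, where `I` is the sum of free C16:0-, C16:1-, C18:0-
and C18:1-ACP. Enzyme-bound thioesters are excluded from `I`: the
inhibitory species are the accumulating free pools.

**Condensation and elongation.** FabH (malonyl-ACP + acetyl-CoA →
C4:0-ACP; CoA and CO2 are not tracked) seeds a generic elongation ladder
in which every Cn → Cn+2 step consumes one malonyl-ACP and releases one
holo-ACP. Chain-length preference of the condensing enzymes is a
per-product-chain weight multiplying a shared Vmax. The C16 → C18 steps
carry small weights (0.002 saturated, 0.06 unsaturated) so the C18 pools
are minor at baseline, mirroring the observed pre-treatment ranking of
pool sizes.

**Branch point.** Two parallel reactions consume C10:0-ACP: continued
saturated elongation, and a lumped FabA/FabB isomerisation producing
C10:1-ACP that commits flux to the unsaturated branch. Their kinetic
balance sets the saturated/unsaturated allocation.

**Acyltransferases.** For each of the six substrates (C16:0, C16:1,
C18:1 as acyl-ACP or acyl-CoA) PlsB and PlsC carry explicit binding
(kon·[E]·[S]), unbinding (koff·[E:S]) and catalytic steps. PlsB
acylates G3P to LPA; PlsC acylates each LPA species to PA, with the LPA
species competing through a shared Km. ACP-carried substrates release
holo-ACP on catalysis; CoA-carried ones do not touch the ACP pool.
Substrate preference is encoded in kon: the disfavoured chain (C16:1 at
PlsB, C16:0 at PlsC) is reduced 10-fold, and C18:1 at PlsB carries an
additional 0.15 preference weight so that the C18:1-ACP pool is drained
mainly through PlsC. That asymmetry is what lets a palmitate step
(which loads PlsB) leave C18:1-ACP nearly untouched while an
unsaturated-CoA step (which loads PlsC) sends it up severalfold — the
qualitative fingerprint that distinguishes the three feeding
experiments.

**Lipid sink and flux holding.** PA converts to a lumped membrane
phospholipid (PL) at a first-order rate; LPA, PA and PL are all diluted
at µ = ln2/2500 s⁻¹ (a 42-minute doubling), which gives the system a
genuine pre-feeding steady state. PlsB catalysis carries a
phospholipid feedback factor `1/(1+(PL/K)^h)` with h = 4, which holds
overall phospholipid flux nearly constant when substrate supply
changes. The alternative reading of this controller — explicit flux
servo instead of product inhibition — would hold the same steady-state
property; product inhibition plus dilution was chosen as the simplest
mechanism with a well-defined ODE.

**Turnover of long-chain acyl-ACP.** The four long-chain acyl-ACP pools
hydrolyse slowly back to holo-ACP (thioesterase-like, 0.003 s⁻¹).
This serves two purposes. First, C18:0-ACP is otherwise a dead end (it
is produced by elongation but is not a PlsB/PlsC substrate), so no
steady state would exist. Second, it bounds long-chain accumulation
when the ACC feedback is disabled: without any turnover the
feedback-knockout system can only self-limit by exhausting holo-ACP,
which would make malonyl-ACP spuriously sensitive to feeding even with
the feedback removed. The rate is small: at baseline hydrolysis carries
under a fifth of the flux through any long-chain pool.

**Feeding.** Exogenous fatty-acid feeding is a clamp: the corresponding
acyl-CoA (palmitate → C16:0-CoA, palmitoleate → C16:1-CoA,
cis-vaccenate → C18:1-CoA) is a boundary species held at 0 before the
step and at a fixed concentration (default 30 µM) afterwards. A clamp,
rather than a bolus, reflects the large external fatty-acid reservoir
(0.8 mM) relative to intracellular consumption. The step occurs at
8000 s, after the residual criterion certifies steady state.

## Parameters

All parameter values are this package's own calibrated defaults,
chosen at realistic intracellular scales (total ACP 100 µM, acyl
transferases 1 µM each, acetyl-CoA 500 µM, G3P 200 µM, acyl-ACP pools
0.1–4 µM, lipid synthesis flux ~0.06 µM/s) and then adjusted — by
forward simulation only — until the pre-feeding steady state and the
immediate feeding responses matched the observed operating point:

* pre-feeding C16:0 fraction of the PlsB acyl-ACP substrate pool ≈ 0.8,
* palmitate: C16:0-ACP up ~2-fold, C18:0-ACP up, malonyl-ACP down ~50%,
* palmitoleate / cis-vaccenate: C18:1-ACP up ~5-fold, malonyl-ACP down
  ~50%,

all measured 60–300 s after the step, mirroring the ~1-minute
experimental response. The calibrated defaults land at fraction 0.81
and folds 1.66 / 0.50 (palmitate C16:0 / malonyl) and 4.37 / 0.53
(palmitoleate C18:1 / malonyl).

Parameters a user is most likely to vary:

| parameter | default | meaning |
| --- | --- | --- |
| `ki_acc`, `hill_acc` | 8.5 µM, 4 | ACC–FabD feedback set point and steepness |
| `disfavor_factor` | 10 | kon reduction for the disfavoured chain at each acyltransferase |
| `kon_weights` | PlsB C18:1 → 0.15 | extra per-chain binding preferences |
| `elong_weights` | C18:0 → 0.002, C18:1 → 0.06 | chain-length preference of the elongation ladder |
| `vmax_branch` | 4 µM/s | saturated/unsaturated allocation at C10 |
| `mu_dilution` | ln2/2500 s⁻¹ | growth dilution of lipid pools |
| `k_thioesterase` | 0.003 s⁻¹ | long-chain acyl-ACP turnover |
| feeding clamp | 30 µM | post-step acyl-CoA concentration |

The ACC feedback runs with Hill coefficient 4 at a low point on its
inhibition curve (baseline rate ≈ 0.8 of the uninhibited rate). A
shallower feedback (n = 1–2) operated deep on the curve reproduces the
fold changes equally well, but leaves a large "feedback reserve": with
the feedback knocked out, initiation flux then exceeds what the lipid
sink can absorb by several-fold and the knockout model drifts into an
ACP-exhausted regime in which malonyl-ACP becomes feeding-sensitive for
reasons unrelated to the mechanism under study. The steep/low
configuration keeps the knockout control clean (malonyl-ACP moves < 1%
under any feeding step when `ki_acc → ∞`).

## Numerics

* Integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
  atol 1e-12 µM; results are stable to tolerance halving within 1e-6
  relative. Concentrations are clipped at zero inside the RHS;
  conservation is enforced structurally (the ACP/PlsB/PlsC weight
  vectors lie in the left null space of the stoichiometry matrix, so
  drift is solver error only, < 1e-6 relative over 10⁴ s).
* Steady state: long integration in growing chunks with an explicit
  residual criterion, max over non-clamped species of
  |dx/dt|/(|x|+1e-6) < 1e-8 s⁻¹ (the slowest mode is lipid dilution,
  τ ≈ 1 h, so convergence needs a few tens of thousands of simulated
  seconds). Algebraic root-finding was rejected because the conserved
  moieties make the Jacobian singular along the conservation
  directions.
* The feeding step restarts the integrator exactly at t_step; the
  reporting grid uses 10 s resolution for the first 10 min after the
  step and 60 s afterwards.
* Degenerate inputs: clamp value equal to the baseline produces fold
  changes of exactly 1 within 1e-4 (null-perturbation control); an
  elongation weight of 0 removes the step and disconnects everything
  downstream of it; fold changes are undefined (error) for species with
  zero pre-step concentration.

## Synthetic measurement data

`acylsim.synthdata` emulates the structure of the study's targeted-LCMS
time series, not its physics: for each analyte, time point and
replicate a count is drawn as `scale · concentration · ε` with ε
lognormal and unit mean, plus an independent normaliser channel (the
stand-in for a nonacylated ACP reference peptide, or a constitutive
reference protein for protein-level data) with the same coefficient of
variation. Defaults follow the study design: two biological
replicates, three pre-feeding baseline samples, cv 0.15 (a typical
targeted-LCMS replicate scatter; the study does not quantify its
replicate variance, so this is a modelling choice). The count scale is
arbitrary (10⁴ per µM) because every downstream statistic is
ratio-based.

What the generator does **not** emulate: chromatographic peak shape,
isotope envelopes, ionisation suppression, missing values, or any
correlation between analytes sharing a run. Passing the end-to-end
recovery test therefore shows that the analysis pipeline is unbiased
under well-behaved multiplicative noise — it does not validate the
pipeline against the failure modes of real LCMS data.

A phenomenological induction curve
`baseline·(1+(fold−1)(1−e^{−t/τ}))` with τ = 2400 s (95% of the
plateau at ~2 h) stands in for the slow adaptation of the
unsaturated-branch enzymes; transcription is deliberately not
modelled, so post-adaptation steady states (e.g. restoration of the
substrate-pool ratio after two doublings) are outside this model's
reach.

## Analysis conventions

* Fold changes divide the 60–300 s post-step window mean by the
  pre-step steady-state value.
* The PlsB substrate-pool fraction uses acyl-ACP only,
  [C16:0-ACP]/([C16:0-ACP]+[C18:1-ACP]); an `include_coa` flag adds the
  CoA pools for sensitivity analyses.
* Measurement normalisation divides pooled replicate means by the mean
  of the three pre-treatment samples (a per-replicate variant is a
  flag; pooled is the default because replicate-specific baselines are
  not identifiable from two replicates).
* The two-sample test is Welch's t (unequal variances,
  Welch–Satterthwaite df, two-tailed); p-values are reported raw, with
  no multiple-testing correction, matching the single-threshold usage
  they support.
* "Steady state after feeding" readouts are taken two simulated
  doublings (5000 s) after the step.

## Known limitations

* Absolute concentrations and rate constants are order-of-magnitude
  realistic but not measured; only the calibrated observables above
  should be compared quantitatively to data.
* Without transcriptional adaptation the post-feeding steady state
  keeps the perturbed acyl-ACP composition indefinitely; the model is
  for the fast (seconds-to-minutes) response only.
* C20:1-ACP, hydroxy-/enoyl-ACP intermediates and FabI are absent, so
  inhibitor experiments targeting FabI cannot be represented.
* The SBML export is structural (species, reactions, stoichiometry,
  boundary conditions) and carries no kinetic laws; it supports
  stoichiometric cross-checks in other tools, not re-simulation.
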