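# Methods

## The modelled system

A single presomitic-mesoderm cell carries two coupled genetic oscillators.
On the Notch side, Dll1 ligand binding releases the Notch intracellular
domain (NICD), which partners with RBP-j in the nucleus to activate *Lfng*
and *Hes7*; Lfng feeds back on NICD release (the "big" loop) and nuclear
Hes7 represses both target promoters including its own (the "small" loop).
On the Wnt side, Wnt-activated Dishevelled (Dsh) destroys Axin2, sparing
β-catenin from the Axin2–GSK3 degradation complex; β-catenin/Lef1 then
drives *Axin2*, *Lef1* and *Dll1*, closing the Wnt negative loop through
Axin2.  The combined model couples the two at three levels: Wnt supplies
the *Dll1* transcript, NICD and active Dsh antagonise each other, and the
Wnt/Hes7-co-regulated Nkd1 protein captures active Dsh.

All species are well-mixed concentrations in arbitrary units (a.u.) over a
two-compartment cell (nucleus/cytoplasm, with membrane species treated as
cytoplasmic concentrations); time is in minutes.  Conventions applied
throughout: mRNAs are exported nucleus→cytoplasm and degraded only in the
cytoplasm; shuttling transcription factors (NICD, Hes7) degrade in both
compartments; protein and mRNA degradation is Michaelis–Menten (the
saturable degradation is what lets a two-site Hill repressor drive a
relaxation oscillation at these chain lengths); dual-regulated promoters
combine activator and repressor Hill factors multiplicatively (AND logic,
chosen for smoothness).  RBP-j, GSK3, Lef1 and Dsh are conserved pools
represented algebraically (free = total − bound), so their conservation is
exact by construction.  Within the shipped models every Hill exponent is 1
(single-site: Dll1 on Notch cleavage, Wnt on Dsh) or 2 (two-site: the
transcriptional activators and repressors), with repression written as
K²/(K² + x²) — the "Hill coefficient −2" convention.

## Model structure decisions

Several reactions are not pinned down by the qualitative description the
models derive from and were reconstructed; the notable choices:

* **Lef1.** Lef1 protein is a conserved nuclear pool whose free remainder
  binds β-catenin; *Lef1* mRNA is transcribed, exported and degraded as a
  pure readout.  This mirrors RBP-j on the Notch side and keeps the
  isolated Wnt model at exactly 13 ODEs while retaining Dll1 protein and
  its translation.
* **β-catenin.** One cytoplasmic unphosphorylated pool binding nuclear
  Lef1 directly, plus a phosphorylated form that is dephosphorylated or
  rapidly degraded.  Phosphorylation is Michaelis–Menten with catalytic
  rate scaled by the GSK3–Axin2 fraction of total GSK3.
* **Dsh recycling.** When active Dsh destroys Axin2, the engaged Dsh
  returns to the *inactive* pool.  This makes Axin2 a genuine inhibitor of
  Dsh activity, produces the observed Dsh–Axin2 antiphase, and is what
  lets Axin2 overexpression raise free NICD (and hence Lfng) by draining
  active Dsh.
* **Crosstalk complex turnover.** The NICD·Dsh and Nkd1·Dsh complexes are
  not inert: each turns over by first-order degradation of its
  NICD/Nkd1 moiety with the Dsh recycled inactive.  A pure binding
  equilibrium carries no net flux at steady state, so it cannot transmit a
  *sustained* change in one pathway's level to the other; the turnover
  flux is what lets a lowered Wnt input lengthen the clock period and lets
  persistently high Nkd1 suppress Wnt signalling.  Dynamically, the
  NICD·Dsh pool also buffers the Dsh economy: perturbations that leave
  NICD in place (Hes7 knockout) are absorbed, while perturbations that
  remove NICD (receptor knockout) expose the Wnt side to the full Nkd1
  load — reproducing the asymmetry between those two knockouts.
* **Knockout semantics.** Gene knockout zeroes the gene's transcription
  Vmax at the event time (constant-rate supplies tagged with a gene, such
  as the isolated Notch model's Dll1 source, count as that gene's supply
  step); species knockout zeroes a synthesis rate; input perturbations
  set or scale the piecewise-constant input.  Existing molecules always
  decay through their normal reactions.

## Reference parameter sets

Parameters (40 for Notch, 43 for Wnt, 95 for the combined model) are
shipped per model in `somiteclock/data/reference_<model>.json`, tagged
`reference_calibrated`, together with the post-burn-in state used as the
initial condition.  They were obtained with the package's own machinery:
correlation-fitness search against synthetic 120-minute target profiles
(phase-tagged sinusoids emulating a microarray time course) combined with
seeded stochastic local search scored on the phenotype suite — the
oscillation, phase-architecture and knockout-response checks — used as a
feasibility filter, followed by an exact global rate rescale to place the
period at 120 min (multiplying every rate constant and Vmax by c rescales
time by 1/c; Hill constants and pool totals are untouched).  The three
models are calibrated independently: the combined model is *not*
constrained to reuse the isolated models' constants, mirroring the fact
that each network is its own fit.

The synthetic profile generator defines the training conditions: five
genes (Lfng/Hes7/Nkd1 in phase; Axin2/Dll1 in antiphase), period 120 min,
13 samples over two cycles, baseline 2 a.u., amplitude 1 a.u., optional
multiplicative log-normal noise.  It emulates only the periodicity and
phase structure of a real time course — not probe-level noise models,
trends, or unequal sampling — so passing the calibration tests shows the
machinery recovers phases and periods, not that it is robust to real
microarray artefacts.

## Simulation and measurement

Integration uses LSODA (stiffness-switching) with rel_tol 1e-6 and
abs_tol 1e-9 on a dense 1-minute output grid; the binding steps are fast
relative to transcription, so a stiff-capable method is required.  Timed
perturbations restart the solver segment-wise — the model is modified and
recompiled at the event time, never discontinuously inside one solver
call — so the pre-event trajectory is bit-identical to the unperturbed
run.  Burn-in integrates from the stored initial values until the last
three peaks of every readout vary by < 1% (flagging fixed points
separately) and returns the state at the last readout peak; production
runs start there, and burn-in is idempotent up to solver tolerance.

Oscillation measurement is peak-based (robust at the ≤ 10 cycles these
horizons contain): peaks need prominence ≥ 10% of the window range;
period is the mean inter-peak interval; amplitude is max − min over the
last complete cycle; a signal with fewer than three peaks or relative
amplitude < 5% is "not oscillating".  Phase lags are circular means of
nearest-peak offsets mapped to [−T/2, T/2]; |lag| < T/6 is in phase and
|lag − T/2| < T/6 antiphase.  Response delays compare per-cycle peak
envelopes (linear interpolation through peak points, continued by a
trailing-window maximum where the perturbed signal stops peaking); the
delay is the first post-event time at which the envelopes depart by more
than 20%.  These are declared operationalizations, not biological
constants: the 5% death floor separates every sustained-versus-dead case
on the reference parameter sets, while the 20% envelope threshold is
deliberately strict — two knockout responses of the shipped combined
model move its readout envelope by less than 20% and are reported as
"no response" rather than being given a softer threshold (see Known
limitations).

## Parameter learning

The fitness of a parameter set is S = Σᵢ (1 − corr(Ṽᵢ, Vᵢ)) over target
genes, where the simulated profile is sampled at the targets' absolute
post-burn-in time points with no phase-shift search — the score is
deliberately phase-sensitive, since the inter-gene phase relations are
part of the biology being fitted.  S is 0 iff every correlation is 1, at
most 2N, invariant to per-gene affine rescaling of the targets; dead or
failed simulations score 2N rather than raising, so a search never loses
swarm members.

The optimizer is a particle swarm (default 30 particles, inertia 0.72,
cognitive = social = 1.49, reflection at the bounds) with
simulated-annealing acceptance embedded at the personal-best update: a
worse candidate may replace a particle's personal best (and through it
the published global best) with probability exp(−ΔS/T), T cooled
geometrically (0.95/iteration from T₀ = 1).  The returned optimum is the
best point ever evaluated, immune to the annealed acceptance; the
published-best trace is monotone only in the T → 0 limit, which is the
tested contract.  Identical seeds give bitwise-identical runs.

## Sensitivity analysis

One-at-a-time positive perturbations p → p(1+δ) at δ = 1%, 10% and 50%;
the model is re-burned-in and re-measured per perturbation, and the
normalized finite differences S_τ and S_A are reported per readout gene
with the |S| ≥ 1 significance rule (the rule is applied to the magnitude;
a strongly negative sensitivity is plainly significant).  Perturbations
that kill the oscillation yield a status rather than a number and are
excluded from numeric tables but reported.  Zero-valued parameters cannot
be perturbed multiplicatively and scan as exactly insensitive.

## Problem sizes and numerical checks

The shipped test and acceptance runs use 1200-minute production horizons
(about ten cycles) after burn-ins capped at 4800–6000 minutes, chosen so
every measurement sits on a converged limit cycle while a full suite run
remains a desk-scale computation.  Key invariants under test: the
time-rescaling oracle (rates × c ⇒ period × 1/c, exact), conservation of
every algebraic pool (exact by construction; bound forms never exceed
totals beyond solver tolerance), non-negativity within a 1e-9 solver
band, dense-output consistency under grid refinement, and SBML round
trips reproducing the compiled right-hand side to 1e-12.

## Known limitations

Single cell only: no cell–cell coupling, no PSM gradient, no FGF pathway,
no delay terms (delays are emergent from the reaction chains), no
stochastic kinetics.  The models are qualitative — calibrated to period
and phase structure, not to measured concentrations; amplitudes are in
arbitrary units and inter-gene amplitude ratios are not meaningful.  The
SBML layer covers the rate-law grammar the models use (plus opaque
import of other mass-balance kinetics); events, rules beyond
conservation assignments, and SBML Level 3 packages are out of scope.

Two measurement conventions deserve emphasis: oscillation-death checks on
perturbed runs are judged on the final 360 minutes of the horizon, past
the damped ringing of the approach to rest, and the oscillation detector
carries an absolute amplitude floor of 1e-6 a.u. so solver-noise ripples
around zero never register as rhythm.

The shipped combined-model reference set does not reproduce every
qualitative knockout claim; the failures are visible as red tests rather
than hidden.  In particular, the delayed Wnt responses measured as >20%
departures of the Axin2 peak envelope (after Lfng and Nkd1 knockouts) do
not reach the 20% threshold in this parameterization: the Lfng-knockout
NICD surge is bounded by receptor supply (cleavage consumes the
receptor), and the Nkd1-knockout amplitude rise is trough-driven rather
than peak-driven.  Likewise, at tenfold Wnt the Wnt-side amplitude
flattens below the oscillation detector (the Notch-side period is
unchanged, as claimed), and after Wnt removal the Notch-side genes stop
cycling but settle at an elevated plateau instead of collapsing, because
losing active Dsh releases NICD from the NICD·Dsh pool.  Parameter
directions that repair any one of these were found to break the
antiphase locking or the relaxation character of the oscillator; a joint
fix likely requires a structurally different receptor module.
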