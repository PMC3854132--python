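# Methods

## The model

`badnet` models the signaling network that controls apoptosis of prostate
cancer (LNCaP-like) cells through phosphorylation of the BH3-only protein
BAD.  Three inputs converge on BAD:

* **EGF** phosphorylates Ser112 through EGFR → Raf → ERK1/2 → an
  ERK-dependent BAD kinase ("KinaseX"), and Ser136 through Rac → PAK;
* **PI3K/AKT**, constitutively active in these cells, phosphorylates
  Ser136 and partially sustains Ser112;
* **stress hormones** (epinephrine or VIP, one shared input channel)
  phosphorylate Ser112 through β2AR → cAMP → PKA, and activate CREB —
  which proxies stress-stabilized Mcl-1, a BAD-independent anti-apoptotic
  arm.

The state vector holds 13 dimensionless activity levels
(EGFR\*, Raf\*, ERK1/2\*, KinaseX\*, Rac\*, PAK\*, PI3K\*, AKT\*, cAMP,
PKA\*, CREB\*, pS112-BAD, pS136-BAD), normalized so the untreated baseline
is `(0,0,0,0,0,0,1,1,0,0,0,1,1)`.  Each activation is a Hill term
`V x^n/(K^n + x^n)` of the upstream regulator.  Deactivation is linear,
with one deliberate exception: the four EGFR-branch species decay at rate
`d_i · t · x_i`.  This time-growing dephosphorylation is a phenomenological
surrogate for receptor desensitization/internalization; it is what lets a
constant EGF input produce the observed transient pERK peak that decays
within the first hour.  The time variable in that term is absolute
simulation time, so stimuli applied later in a schedule produce smaller
transients — a consequence to keep in mind when designing schedules with
late EGF onsets.

### Steady-state closure

The decay rates of the four species with non-zero baseline (PI3K, AKT,
pS112-BAD, pS136-BAD) are never fitted.  They are *derived* by requiring
the untreated baseline to be an exact fixed point: each rate equals the
species' baseline production flux divided by its baseline level (e.g.
`d8 = V8·1/(K8^n+1)` for AKT, whose upstream PI3K sits at 1).  The five
zero-baseline species (Rac, PAK, cAMP, PKA, CREB) have no baseline
production, so their closure is degenerate; their decay rates are ordinary
free parameters.  This partition fixes the free signaling parameter count
at exactly 37: 14 velocities + 14 Michaelis coefficients + d1–d4 + the
five degenerate decays.  A corollary of the closure worth knowing: a
velocity whose decay is closed against it (e.g. V7 for PI3K) cancels from
its own steady state and only sets the relaxation *speed*, which flips the
sign of some finite-time sensitivity coefficients.

Because the 37-parameter budget is exactly exhausted, all signaling Hill
exponents are fixed structural constants (n = 2 throughout — cooperative
kinetics, one step beyond plain Michaelis–Menten); only the two apoptosis
Hill exponents are fitted.

### Partial AKT control of Ser112

AKT regulates Ser112 only partially and through an unidentified
intermediate.  pS112-BAD therefore receives a single Hill term on the
*summed* drive `KinaseX + PKA + (0.5 + 0.5·AKT)`: half of the
AKT-associated share is basal, so complete PI3K inhibition halves, but
never abolishes, Ser112 phosphorylation (its residual level under strong
LY294002 matches the reported "low but non-zero" behaviour).  The 0.5
split is a structural constant (`AKT_PARTIAL_BASAL`).  The summed-drive
form is the only single-(V,K) form compatible with the 37-parameter
budget; pS136-BAD, by contrast, has two additive Hill routes (PAK and
AKT), the `13a/13b` pair.

### Drugs

Seven of the eight interventions multiply their target reaction's maximal
velocity by `1/(1+u)`, with the normalized dose `u` expressed in units of
the half-inhibition concentration (`u = 1` halves the velocity; no new
parameters).  The phosphorylation-deficient mutant BADS112A instead scales
the pS112-BAD dephosphorylation rate by `(1+u)` — the algebraic mirror,
halving the steady phospho-level at `u = 1`.  Doses of a drug "combined
with itself" simply add, which is what makes both combination indices
score an exact 1 on sham combinations.

### Apoptosis readout

Apoptosis percentage `C_a ∈ [0, 100]` accumulates on top of a signaling
trajectory:

    dC_a/dt = k_a · t · (100 − C_a) · F_bad [· F_creb]

with `pb = (pS112 + w_s136·pS136)/bad_total`,
`F_bad = k_bad^n_bad/(k_bad^n_bad + pb^n_bad)` and, in the BAD+Mcl-1
variant (model 2), `F_creb = k_creb^n_creb/(k_creb^n_creb + CREB^n_creb)`.
Either serine suffices to protect (additive incorporation), with `w_s136`
the relative anti-apoptotic weight of Ser136.  The explicit `t` factor
reproduces the accelerating commitment to death seen in the assay time
courses; survival is the complement `C_s = 100 − C_a`, and the rate is
clipped to zero at the 100 % cap.  Model 1 (BAD-only) omits `F_creb` and
is exactly nested in model 2 (they coincide whenever CREB ≡ 0, i.e. in
any stress-free schedule).  The seven fitted apoptosis parameters are
`k_a, bad_total, k_bad, n_bad, w_s136, k_creb, n_creb`.

## Numerics

* Fixed-step RK4 (default 0.01 h), integrated segment-by-segment over the
  piecewise-constant schedule.  A stability guard shrinks the step
  whenever a decay rate (including the `d_i·t` terms at late times or a
  BADS112A-boosted d12) would leave RK4's stability region, so extreme
  doses degrade into smaller steps instead of blow-ups.
* Negative excursions larger than −1e−9 abort with an error naming the
  time; smaller ones are clipped to 0 (float noise, not model error).
* The compiled (numba) kernel is cross-checked in the test suite against
  an untouched pure-Python RHS driven by scipy's adaptive RK45 at
  rtol 1e−10 (sup-norm agreement ≤ 1e−6) and against step-halving
  (endpoint change < 1e−8).
* Dose-response inversion is monotone bisection to |effect − x| < 1e−4
  (absolute, percentage points), returning the smallest such dose; an
  effect above the plateau raises a dedicated unreachable-effect error.
* Apoptosis rows enter the fitting objective on the fraction scale
  (value/100) so signaling and apoptosis residuals are commensurate.

## Estimation

The objective is the plain mean squared error over all observation rows,
with conditions weighted equally.  Free parameters are searched in log10
space by a seeded genetic algorithm (defaults: population 100,
200 generations, tournament-of-3 selection, uniform crossover 0.8,
per-gene Gaussian mutation with probability 0.15 and σ of 10 % of the box
width, elitism 2) inside positive bounds (`V, K ∈ [1e−3, 1e2]`,
`d ∈ [1e−3, 10]`, `k_a ∈ [1e−4, 10]`, Hill exponents `[1, 4]`).  The
apoptosis-stage bounds are preset from the range of the normalized
observables: phospho-BAD fractions stay within ~[0, 1.5], so `k_bad`,
`w_s136` and `bad_total` are confined near that range (`[0.05, 2]`,
`[0.1, 2]`, `[0.5, 4]`) — half-inhibition constants far outside the
observable span are unidentifiable and, left free, produce train-perfect
fits that transfer badly to held-out treatments.  `k_creb` keeps a high
upper bound (10) on purpose: a large half-inhibition constant switches
the CREB/Mcl-1 arm off, preserving the exact nesting of the BAD-only
model inside the BAD+Mcl-1 fit.  Fitting
is staged: signaling parameters first, then the 7 apoptosis parameters
with signaling frozen — the apoptosis stage re-integrates only the 1-D
accumulation equation over cached signaling trajectories, which makes
model selection cheap.

Model selection fits both apoptosis variants on the training treatments
(LY294002; LY294002+EGF; LY294002+VIP) and compares mean squared error on
the holdout panel, with ties resolved toward the BAD-only model
(parsimony).  The default holdout panel mixes inhibitor combinations with
growth-factor and stress rescue conditions; a stress-containing holdout
condition is what gives the comparison power to detect the Mcl-1 arm.

Identifiability caveat: several parameters are structurally invisible to
the standard designs (decays of unobserved transient species; velocities
cancelled by closure; scale factors removed by to-max normalization).
Recovery experiments therefore target identifiable parameters
(`d3, d10, K8, K12` in the shipped tests); fitting the full 37 with 56
points will reach the error floor without pinning every coordinate.

## Sensitivity analysis

One-sided forward differences: each free parameter (all 44 by default) is
increased by 1 % from its value, derived decays are re-closed, and the
percentage change of each of the 14 variables (13 proteins + apoptosis) is
averaged in absolute value over the 10-point equal partition of [0, 100] h.
The analysis condition is part of the configuration and defaults to
LY294002 at dose 1 without stress — the model's central fitted scenario;
variables below 1e−8 at a partition point are skipped there (relative
change undefined at zero) and the skip counts are recorded in the
metadata.  Coefficients are reported as absolute magnitudes.

## Synergy

The Loewe index `d1/D_x1 + d2/D_x2` is evaluated on isobolograms traced by
sweeping one dose and bisecting the other.  The response-scale combination
index compares the combination against the *better single agent at the
same total dose*: `CI = max(E1(d1+d2), E2(d1+d2)) / E12(d1,d2)`, so CI < 1
exactly when splitting the dose budget across both drugs beats
concentrating it in either one.  Labels use a 1 % additivity band around
CI = 1: at vanishing doses the index tends to 1 to first order, so a
strict threshold would classify the additivity boundary by floating-point
accident.

A structural property of this index worth stating explicitly: in grid
corners where the combination is dominated by the weaker drug, the better
single agent at total dose wins at first order, so a 2-D dose map can
never be strictly synergistic everywhere for two non-identical
dose-response curves.  The all-synergy claim at low stress is therefore
assessed on the equal-dose sweep `d1 = d2 ∈ [0.01, 100]` (no antagonistic
cell, synergy at all but the boundary doses), while the stress-100
analysis uses the full 2-D map, which splits into exactly two contiguous
regions with synergy confined to high doses — the stress-triggered
synergism-pattern switch.  Dose-grid defaults: 20×20, log-spaced over
[0.01, 100].

## Synthetic data generator

The generator is the package's only data source and shares the simulation
code path (a zero-noise table is bit-identical to the model output).  It
reproduces the three study designs: the epinephrine dose series (8
conditions: control, LY294002 alone, and LY294002 2 h → epinephrine
0.01–1000 nM for 1 h; pS112-BAD to-control, pCREB to-max; 16 points), the
LY294002/EGF time course (10 conditions; pAKT-S473, pERK to-total,
pS112-BAD, pS136-BAD; 40 points — 56 signaling points in total), and the
apoptosis panel (3 training treatments × 9 time points = 27 fit points,
plus a validation panel of combinations with EGF/VIP rescue).
Epinephrine concentrations map to the dimensionless stress input by a
saturating log transform `log10(1 + c_nM)` (unit EC50 on the nM scale);
the switch analyses drive the stress channel directly at level 100.

Noise model: signaling readouts get multiplicative log-normal noise
(σ = 0.1 on the log scale — a western-blot densitometry magnitude) plus
optional additive Gaussian noise clipped at 0 (clip count recorded);
apoptosis percentages get binomial counting noise with 350 cells per
measurement, matching the assay's counting procedure and giving the
1/√n shrinkage the tests verify.

What the generator does *not* emulate: blot saturation/background
artifacts, batch effects between assay environments (the scaling
operation exists precisely because real datasets need it; synthetic ones
are born on one scale), biological replicate variability beyond the noise
model, and single-cell stochasticity (population percentages only).
Passing recovery tests therefore demonstrate correctness of the machinery
under the stated noise model, not robustness to real-blot pathologies.

## Reference parameter set

The originally estimated parameter values for this network are not
available in machine-readable form, so
`badnet.reference.reference_parameters()` ships a *synthetic* stand-in,
calibrated once against the qualitatively reported behaviour of the
fitted model (transient pERK; suppressed pAKT under LY294002; low
phospho-BAD under the double treatment with stress rescue of pS112 and
CREB; LY294002 the strongest single agent and LY294002+BADS112A the
strongest pair; both single agents crossing the 25 % isobologram with
comparable potency; stress suppressing every combination and switching
the synergism pattern).  Its values are frozen — it defines the study
conditions for the generator and all reproduction runs, and is not a
tuning knob.  With this stand-in the maximum time-averaged sensitivity is
1.92 %, the Loewe CI on the 25 % isobologram averages ≈ 0.88, and the
LY294002+BADS112A pair reaches ≈ 78 % apoptosis at 48 h without stress
versus ≈ 19 % under stress 100.

## Known limitations

* Downstream effectors (BclXL, BAX, BAK) are not modelled; apoptosis is a
  phenomenological percentage, not a mechanistic cascade.
* The EGFR-branch `d·t` decay uses absolute time (see above).
* The response-scale combination index and the exact Hill placements in
  the apoptosis model are reconstructions constrained by the stated parameter counts, limits
  and sign behaviour, not transcriptions of typeset equations.
* The assay horizon for apoptosis endpoints defaults to 48 h and is a
  configurable, recorded choice.
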