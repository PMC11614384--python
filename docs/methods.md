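# Methods

`vestephys` analyzes whole-cell patch-clamp recordings from type I and
type II vestibular hair cells and ships a conductance-based simulator whose
presets carry the population-mean parameters of wildtype (`+/+`),
heterozygote (`+/-`) and Kcna10-null (`-/-`) cells from the three zones of
the utricular epithelium (lateral/medial extrastriola, striola). This note
documents the models, the fitting conventions, the preset calibration, and
what the synthetic data can and cannot establish about real recordings.

## Units and conventions

mV, pA, ms, nS, pF, GΩ throughout (series resistance is quoted in MΩ in
metadata, as in the field). Outward current is positive. The liquid
junction potential is subtracted from command potentials
(`V_m = V_pipette − I·Rs_residual − LJP`); the correction uses the
uncompensated fraction of the measured series resistance.

## Electrochemistry

`nernst_potential` evaluates `E_K = (RT/F)·ln([K]_out/[K]_in)`. With the
recording solutions modeled here (165 mM internal K⁺ from 135 mM KCl plus
~30 mM KOH titration; ~5.77 mM K⁺ in L-15-based external medium, 25 °C)
this gives −86.15 mV, the value used as the default reversal potential for
all K⁺ conductances.

## Gating model

Each conductance carries one activation gate `m` with first-order kinetics
`dm/dt = (m_∞(V) − m)/τ`, Boltzmann steady state, and integer power `p`
(`G ∝ m^p`). Two parameterization conventions are used deliberately:

* **Single-gate conductances** (g_K,L, the K_V7-like residual rectifier)
  use `p = 1`, so the conductance–voltage relation is *exactly* the
  reported population-mean Boltzmann. This is what makes the tail
  G–V recovery tests exact.
* **Type II K_V1.8 conductances** (g_A, g_DR(K_V1.8)) use classic
  Hodgkin–Huxley `p = 3` gating. Gate-level `(v_half, s)` are derived from
  the target conductance-level Boltzmann by matching value and slope at
  half-activation (`s_gate = 2p(1 − 2^{−1/p})·S`,
  midpoint shifted by `s_gate·ln(2^{1/p} − 1)`). A Boltzmann fit of the
  simulated G–V then lands close to the table values while the activation
  "foot" near rest stays realistically small — the alternative
  (`m_∞ = σ^{1/p}`) put enough conductance at −71 mV to halve the cell's
  input resistance.

Inactivation is a weighted pair of first-order gates (fast and slow,
fraction `f` fast) sharing the steady state `1 − Z(V)`, with
`Z(V) = z_total·σ((V − V_half)/S)` rising toward `z_total` with
depolarization. At a clamped voltage, a step from rest therefore follows
exactly the activation × bi-exponential-inactivation form

    I(t) = I_max (1 − e^{−t/τ_w})^n [1 − Z(f(1 − e^{−t/τ_zf}) + (1 − f)(1 − e^{−t/τ_zs}))] + I_0

which is also the model the kinetics module fits. `analytic_step_current`
implements this closed form independently of the integrator and serves as
the oracle: the exponential-integrator trajectory at fixed voltage agrees
with it to machine precision (the update `m ← m_∞ + (m − m_∞)e^{−dt/τ}` is
exact for first-order kinetics at constant voltage).

Time constants are voltage-independent by default; a per-gate bell-shaped
`τ(V)` (Gaussian in V, floored at 10% of its peak) is available and is used
for the K_V7 conductance (below).

## Presets

### Type I

Wildtype/heterozygote type I cells carry g_K,L at the table means
(extrastriola `+/+`: V½ −85 mV, S 4.3 mV, g_max 270 nS) plus the lumped
inward conductance and leak. g_K,L's activation τ is not reported (the conductance
activates slowly); it is set to 80 ms, which balances
equilibration within the 500 ms test step against relaxation during the
1 ms tail-measurement latency so the tail-fit g_max stays within 2% of the
preset value (closed-form error ≈1.4%). The small K_V7 component that
coexists with g_K,L in real control cells is omitted from `+/+`/`+/-`
type I presets: it is unmeasurable behind g_K,L (the blocker experiments
avoided control type I cells because g_K,L runs down), and including it
would corrupt the recovery of the reported pure-g_K,L fit parameters.

Knockout type I presets carry only the K_V7-like rectifier (V½ −40.2 mV,
S 5.7 mV, 5.4 nS extrastriolar) plus HCN/Kir and leak.

### Type II

The whole-cell outward current decomposes into:

* **g_A** — fully inactivating (`z_total = 1`), fast fraction and τ_zf at
  the zone/genotype means (LES `+/+`: f 0.46, τ_zf 23 ms), activation V½
  −23 mV / S 11.2 mV, τ_w = the measured activation constant (2.11 ms),
  h_∞ midpoint −42 mV, slope 11 mV. τ_zs is not reported; it is fixed at
  200 ms.
* **g_DR(K_V1.8)** — non-inactivating rectifier at the steady-state G–V
  means (LES `+/+`: V½ −25.0 mV, S 8.7 mV).
* **g_DR(K_V7)** — the knockout residual (LES: 1.8 nS/pF, V½ −19 mV,
  S 12.1 mV), present in every genotype of the zone.

The g_A density is calibrated in closed form so that the *measured* percent
inactivation of a 200 ms step to +30 mV — raw peak versus end-of-step
current, including the overlap of activation (τ_w ≈ 2 ms) with fast
inactivation (τ_zf ≈ 23 ms) and the baseline inactivation left by the
standard 50 ms prestep — equals the population mean (45% in LES `+/+`),
while the end-of-step conductance density stays at its mean (7.1 nS/pF).
The kinetic overlap suppresses the measured peak, so the calibrated g_A
densities exceed the reported A-type density (which is a
fitted-peak construct); the measured %-inactivation was prioritized because
the A-current classification rule (">30% within 200 ms") operates on it.
The reported striolar `+/-` τ_zf (300 ± 200 ms) is longer than any slow
constant reachable in a 200 ms window; its preset uses the deepest
attainable inactivation.

### K_V7 kinetics and electrical resonance

K_V7 activation is slow near rest (M-current-like): `τ(V)` is bell-shaped,
peaking at ≈36 ms near −50 mV and anchored so `τ(+30 mV)` equals the
knockout's measured activation constant (4.4 ms in LES). This choice is
what reproduces the key current-clamp physiology: knockout type II cells
(high input resistance, only the slow rectifier) ring after a current step
(f_e ≈ 17 Hz, Q_e ≈ 0.8 at a 20 pA step), while control cells — dominated
by large, fast K_V1.8 conductances — are overdamped (Q_e → 0.5). With a
voltage-independent K_V7 τ the direction inverts, because fast strong
feedback oscillates at high frequency.

### HCN/Kir and leak

HCN and Kir are lumped into one inward conductance (reversal −44 mV,
activation below ≈−80 mV, τ 30 ms, 1–2 nS); it produces the inward current
at −124 mV and the sag on hyperpolarizing steps. The ohmic leak per preset
is solved in closed form from the target resting potential and input
resistance (zero net current and slope conductance `1/R_in` at `V_rest`);
when the gated conductances alone exceed the target slope (type I control
cells, where ≈150 nS of g_K,L is open at rest) a token 0.1 nS leak is used
and the cell rests at ≈E_K, as observed. `scripts/calibrate_presets.py`
prints all solved constants.

## Measurement conventions

* Tail G–V: current at the sample nearest 1 ms after the test step ends,
  divided by `V_tail − E_K`; steady-state G–V: 1 ms before step end; both
  nearest-sample (≥10 kHz sampling keeps the timing error < 0.1 ms).
* Raw peak searches blank the first 0.5 ms of each segment (capacitive
  transient); fitted peaks use the selected kinetic model's maximum.
* Kinetic fits run on traces decimated to ≤2000 samples; τ ordering
  `τ_zf < τ_zs` is enforced by the parameterization
  `τ_zs = τ_zf(1 + e^u)`, so swapped initial guesses converge to the same
  canonical solution. The state factor n is fixed at 3 (a diagnostic mode
  refits n ∈ {1..4}).
* Model selection: the full bi-exponential-inactivation model is kept only
  if it improves adjusted R² (`1 − (1−R²)(N−1)/(N−p−1)`) over the f = 0
  fit by strictly more than 0.01. On noiseless canonical fixtures (Z 0.45,
  f 0.46, τ 23/200 ms, 200 ms window) the one-exponential fit is within
  0.0035 adjusted R² of the truth, so the parsimony rule selects it; the
  full model wins when the components are well separated (e.g. Z 0.9,
  τ 5/500 ms).
* Steady-state inactivation (h_∞): conditioning steps (500 ms, −124…0 mV)
  are followed by a fixed test step at +30 mV; the peak current there — an
  A-type transient riding on a conditioning-independent rectifier
  background — indexes availability. The background enters affinely, so
  the falling-Boltzmann V½ and S are unbiased (recovered to −42.2 mV /
  11.1 mV against the −42/11 truth). A test potential of −44 mV does not
  work on whole-cell mixtures: rectifier deactivation tails after
  depolarized conditioning dominate the peak and invert the curve.
* Passive properties: single-exponential fit of the whole onset of
  responses < 15 mV; `R_in = ΔV_SS/ΔI`; `C = τ/R_in` (identity by
  construction). In knockout type I cells the delayed-rectifier foot at
  rest produces a strong sag, which makes the fitted τ
  convention-sensitive (≈2–12 ms across defensible window choices for a
  slope-RC of ≈7.5 ms); the full-window convention used here yields
  ≈4.7 ms.
* Capacitance: two-resistor transient model on a ≤10 mV step negative to
  −90 mV; `Rs = ΔV/ΔI(0)`, `R_in = ΔV/ΔI_SS − Rs`,
  `C_m = τ(1/Rs + 1/R_in)`. Requires ≥5 samples per τ (≈10 µs for a 2 MΩ
  residual and 5 pF), i.e. a fast acquisition rate for this protocol.
* Resonance: damped sinusoid `V_SS + V_p e^{−t/τ_e} sin(2πf_e t − θ)` fit
  from the first half-maximum crossing of the initial depolarizing peak
  (found on a 1 ms median-smoothed copy; the fit uses raw samples) to the
  step end, multi-started over phase and an FFT-seeded frequency; some
  reported forms of this equation omit t inside the sine, which is treated
  as typographical. `Q_e = sqrt((πf_eτ_e)² + 0.25) ≥ 0.5`, with equality in
  the overdamped limit.

## Statistics

Dispatch: Shapiro–Wilk per group for n ≤ 50 (Lilliefors above; the
boundary case n = 50 is assigned to Shapiro–Wilk), Levene for variance homogeneity;
then two-way (genotype × zone, with interaction) or one-way ANOVA with
Tukey's HSD, Welch's one-way ANOVA with Games–Howell, or Kruskal–Wallis
with Dunn's test (implemented directly — rank z-tests with tie
correction — as no installed library provides it). Effect sizes are
Hedge's g with the small-sample correction `1 − 3/(4N − 9)`; α = 0.05 with
the conventional asterisk bands. Null calibration uses 10⁴ replicates per
path: three normal groups (n = 10, equal SD) for the ANOVA path, three
normal groups (n = 15, SDs 1/2/4) for Welch, three exponential groups
(n = 10) for Kruskal–Wallis; each path holds 0.05 ± 0.01.

## Problem sizes and numerical choices

Simulations integrate at dt = 0.005 ms by default; the analysis-scale runs
(test suite, acceptance script, cohort pipeline) use dt = 0.02 ms, which is
exact in voltage clamp (piecewise-constant command) and resolves the
fastest time constants by ≥80× in current clamp. The noisy kinetic-recovery
study uses a 500 ms fixture window: a 200 ms slow time constant is not
identifiable from a window of its own length at 2% noise (median error
≈24%), while 2.5 multiples bring all five parameters under 5% median
error. Cohort pipelines jitter preset parameters per cell (log-normal 10%
on conductances, 2 mV SD on midpoints, 5% on capacitance) to emulate
biological scatter.

## What the synthetic data do and do not show

Passing recovery tests demonstrates that the estimators are unbiased and
precise on data generated by the stated model — first-order Boltzmann
gating with the population-mean parameters, Gaussian noise, ideal clamp
(apart from the modeled series-resistance artifact). Real recordings add
features the generator deliberately omits: K⁺ accumulation in the calyceal
cleft (which distorts type I driving forces at large tail currents),
rundown between pharmacology epochs, BK/erg/Ca_V currents, seal leak
nonlinearity, and temperature dependence of gating. Population directions
(knockout vs control resting potential, input resistance, charging time,
resonance, XE991 block) are reproduced by construction of the presets plus
the physics; exact population means of fitted kinetic quantities are not
all simultaneously reproducible (see the g_A density calibration above),
which mirrors the fact that they are averages of different per-cell
constructs.
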