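# vestephys

Whole-cell patch-clamp analysis for vestibular hair-cell potassium
currents, with a conductance-based simulator for validation.

Type I and type II vestibular hair cells of the amniote utricle carry
strikingly different outwardly rectifying K⁺ conductances. Mature type I
cells express g_K,L — a very large conductance with a Boltzmann activation
midpoint near −85 mV, far negative to rest — which clamps the resting
potential near E_K, collapses input resistance, and speeds voltage
responses. Type II cells carry a fast-inactivating A-type conductance
(g_A, defined as inactivating by more than 30% within 200 ms) plus delayed
rectifiers that activate positive to rest. Knocking out the K_V1.8 subunit
(*Kcna10*) removes g_K,L, g_A and much of the delayed rectifier, leaving a
small K_V7-like rectifier — and transforms the cells' passive properties
and electrical resonance. This package implements the analysis chain used
to quantify all of that, and a simulator that generates recordings with
the statistical structure of each genotype/zone/cell-type group so every
stage can be tested without raw data.

## What it does

- **`vestephys.recording`** — data model for sweeps, step protocols, and
  cell metadata; Nernst potential from solutions; series-resistance and
  junction-potential corrections; plain-text recording directories
  (`meta.json` + one CSV per sweep).
- **`vestephys.synth`** — Hodgkin–Huxley-style simulator with presets per
  (cell type × genotype × zone); exact closed-form step-current oracle;
  seeded noise and series-resistance artifacts.
- **`vestephys.gv`** — tail/peak/steady-state conductance–voltage curves
  and first-order Boltzmann fits `G(V) = G_min + G_max/(1 + e^{(V_½−V)/S})`;
  steady-state inactivation (h_∞) curves; conductance densities.
- **`vestephys.kinetics`** — step-current fits
  `I(t) = I_max(1−e^{−t/τ_w})^n·[1 − Z(f(1−e^{−t/τ_zf}) + (1−f)(1−e^{−t/τ_zs}))] + I_0`,
  the adjusted-R² parsimony rule for freeing the fast fraction, percent
  inactivation, and A-current classification.
- **`vestephys.membrane`** — resting potential, input resistance and
  membrane time constant from small current steps, capacitance from the
  whole-cell transient, damped-sinusoid resonance fits and
  `Q_e = √((πf_eτ_e)² + ¼)`, peak metrics.
- **`vestephys.pharm`** — control-minus-drug subtraction (XE991/K_V7,
  iberiotoxin/BK style), percent block, drug-sensitive G–V curves.
- **`vestephys.stats`** — the group-comparison dispatch (Shapiro–Wilk /
  Levene → ANOVA+Tukey, Welch+Games–Howell, or Kruskal–Wallis+Dunn),
  Hedge's g, mean ± SEM (n) summary tables, and an end-to-end cohort
  pipeline.

See `docs/methods.md` for the models, calibrations and conventions.

## Worked example

Simulate a wildtype type I cell with 5 pA of recording noise, build the
tail G–V curve, and fit it:

```python
import vestephys as vp
from vestephys import membrane as mem

model = vp.make_preset("type_I", "+/+", "LES")
protocol = vp.build_protocol("type_I")   # hold −74, prestep −124/200 ms,
                                         # 500 ms steps, tail −44 mV
rec = vp.simulate_voltage_clamp(model, protocol,
                                vp.SimConfig(dt=0.02, seed=1, noise_sd=5.0))
fit = vp.fit_boltzmann(vp.extract_tail_gv(rec, model.e_k))
print(f"V_half = {fit.v_half:.1f} mV, S = {fit.s:.2f} mV, "
      f"g_max = {fit.g_max:.0f} nS")
```

```
V_half = -85.0 mV, S = 4.31 mV, g_max = 266 nS
```

The fitted midpoint and slope recover the preset's g_K,L parameters
(−85 mV, 4.3 mV); the maximal tail conductance reads ≈1.5% low because
channels deactivate slightly during the 1 ms tail-measurement latency —
the same bias a real rig produces. A knockout type II cell, in current
clamp, rings after a small current step:

```python
ko = vp.make_preset("type_II", "-/-", "LES")
cc = vp.simulate_current_clamp(ko, [20.0], vp.SimConfig(dt=0.02),
                               baseline_dur=150, step_dur=500, post_dur=20)
res = mem.fit_resonance(cc.sweeps[0])
print(f"f_e = {res.f_e:.1f} Hz, tau_e = {res.tau_e:.1f} ms, Q_e = {res.q_e:.2f}")
```

```
f_e = 16.8 Hz, tau_e = 12.0 ms, Q_e = 0.81
```

i.e. a ~17 Hz damped oscillation with quality factor well above the
overdamped limit of 0.5 — whereas the corresponding wildtype preset, with
its large fast conductances, fits as overdamped (Q_e ≈ 0.5).

A `vestephys` command-line tool wraps the same functions
(`vestephys protocol`, `vestephys simulate`, `vestephys analyze gv|kinetics|cc|drug`,
`vestephys report`).

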