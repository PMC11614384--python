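"""Group-comparison dispatch, effect sizes and table-style summaries.

The dispatch policy mirrors common electrophysiology practice: per-group
normality (Shapiro–Wilk for n ≤ 50, Lilliefors/Kolmogorov–Smirnov above),
Levene's test for homogeneity of variance, then

* normal + homogeneous  → ANOVA (two-way genotype × zone when both factors
  vary, else one-way) with Tukey's HSD post hoc,
* normal + heterogeneous → one-way Welch ANOVA with Games–Howell post hoc,
* non-normal            → Kruskal–Wallis with Dunn's post hoc.

Effect size for every pairwise contrast is Hedge's g (bias-corrected
standardized mean difference). α = 0.05; asterisk bands at
0.05/0.01/0.001/0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasure",
    "ComparisonReport",
    "hedges_g",
    "compare_groups",
    "summarize_table",
    "run_pipeline",
    "PipelineReport",
    "omnibus_anova_p",
    "omnibus_welch_p",
    "omnibus_kw_p",
]

ALPHA = 0.05
_SHAPIRO_MAX_N = 50  # Shapiro–Wilk up to and including this n


def significance_band(p: float) -> str:
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def hedges_g(group_a, group_b) -> float:
    """Bias-corrected standardized mean difference (pooled SD)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n ≥ 2")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled variance: effect size undefined")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(d * correction)


@dataclass
class GroupedMeasure:
    """One measured quantity with per-value group labels."""

    name: str
    units: str
    values: np.ndarray
    genotype: list[str]
    zone: list[str]
    cell_type: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.size
        if len(self.genotype) != n or len(self.zone) != n:
            raise ValueError("labels must match values in length")
        if self.cell_type and len(self.cell_type) != n:
            raise ValueError("labels must match values in length")

    def frame(self) -> pd.DataFrame:
        d = {"value": self.values, "genotype": self.genotype, "zone": self.zone}
        if self.cell_type:
            d["cell_type"] = self.cell_type
        return pd.DataFrame(d)


# --- omnibus tests (the dispatcher's three paths) -------------------------

def omnibus_anova_p(groups: Sequence[np.ndarray],
                    frame: pd.DataFrame | None = None) -> float:
    """Fisher ANOVA p. With a genotype×zone frame, two-way with interaction."""
    if frame is not None and frame["zone"].nunique() > 1 \
            and frame["genotype"].nunique() > 1:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        model = ols("value ~ C(genotype) * C(zone)", data=frame).fit()
        table = sm.stats.anova_lm(model, typ=2)
        return float(table.loc["C(genotype)", "PR(>F)"])
    return float(sps.f_oneway(*groups).pvalue)


def omnibus_welch_p(groups: Sequence[np.ndarray]) -> float:
    """One-way Welch ANOVA p (heteroscedastic groups)."""
    import pingouin as pg
    frame = pd.DataFrame({
        "value": np.concatenate(list(groups)),
        "group": np.repeat(np.arange(len(groups)),
                           [len(g) for g in groups]),
    })
    return float(pg.welch_anova(data=frame, dv="value",
                                between="group")["p_unc"].iloc[0])


def omnibus_kw_p(groups: Sequence[np.ndarray]) -> float:
    return float(sps.kruskal(*groups).pvalue)


def _normal_p(x: np.ndarray) -> float:
    if x.size <= _SHAPIRO_MAX_N:
        return float(sps.shapiro(x).pvalue)
    from statsmodels.stats.diagnostic import lilliefors
    return float(lilliefors(x, dist="norm")[1])


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post hoc z-tests with tie correction."""
    names = list(groups)
    all_vals = np.concatenate([groups[k] for k in names])
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    mean_ranks, sizes = {}, {}
    start = 0
    for k in names:
        n = groups[k].size
        mean_ranks[k] = ranks[start:start + n].mean()
        sizes[k] = n
        start += n
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "statistic": z, "p": p})
    return pd.DataFrame(rows)


def _tukey_posthoc(frame: pd.DataFrame, key: str) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    res = pairwise_tukeyhsd(frame["value"], frame[key], alpha=ALPHA)
    tab = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return pd.DataFrame({
        "group_a": tab["group1"], "group_b": tab["group2"],
        "statistic": tab["meandiff"].astype(float),
        "p": tab["p-adj"].astype(float),
    })


def _games_howell_posthoc(frame: pd.DataFrame, key: str) -> pd.DataFrame:
    import pingouin as pg
    tab = pg.pairwise_gameshowell(data=frame, dv="value", between=key)
    return pd.DataFrame({
        "group_a": tab["A"], "group_b": tab["B"],
        "statistic": tab["T"].astype(float),
        "p": tab["pval"].astype(float),
    })


@dataclass
class ComparisonReport:
    measure: str
    path: str  # anova_tukey | welch_games_howell | kruskal_dunn | skipped
    normality_p: dict[str, float]
    levene_p: float
    omnibus_p: float
    posthoc: pd.DataFrame
    group_ns: dict[str, int]

    @property
    def band(self) -> str:
        return significance_band(self.omnibus_p)


def compare_groups(measure: GroupedMeasure, design: str = "auto",
                   by: str = "genotype", min_n: int = 3) -> ComparisonReport:
    """Dispatch a group comparison per the normality/variance policy.

    ``by`` names the factor whose levels are compared (post hoc pairs);
    ``design='two_way'`` (or 'auto' with both factors varying) uses the
    genotype × zone two-way ANOVA on the parametric path.
    """
    frame = measure.frame().dropna(subset=["value"])
    groups = {k: g["value"].to_numpy() for k, g in frame.groupby(by, sort=True)}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    ns = {k: int(v.size) for k, v in groups.items()}
    if len(groups) < 2 or any(n < min_n for n in ns.values()):
        return ComparisonReport(measure.name, "skipped", {}, np.nan, np.nan,
                                pd.DataFrame(), ns)

    normality = {k: _normal_p(v) for k, v in groups.items()}
    all_normal = all(p > ALPHA for p in normality.values())
    levene_p = float(sps.levene(*groups.values()).pvalue)
    glist = list(groups.values())

    use_frame = frame if (design == "two_way" or
                          (design == "auto" and frame["zone"].nunique() > 1
                           and by == "genotype")) else None
    if not all_normal:
        path = "kruskal_dunn"
        omnibus = omnibus_kw_p(glist)
        posthoc = _dunn_posthoc(groups)
    elif levene_p > ALPHA:
        path = "anova_tukey"
        omnibus = omnibus_anova_p(glist, frame=use_frame)
        posthoc = _tukey_posthoc(frame, by)
    else:
        path = "welch_games_howell"
        omnibus = omnibus_welch_p(glist)
        posthoc = _games_howell_posthoc(frame, by)

    effect = []
    for _, row in posthoc.iterrows():
        a, b = groups[row["group_a"]], groups[row["group_b"]]
        try:
            effect.append(hedges_g(a, b))
        except (ValueError, ZeroDivisionError):
            effect.append(np.nan)
    posthoc = posthoc.assign(hedges_g=effect,
                             band=[significance_band(p) for p in posthoc["p"]])
    return ComparisonReport(measure.name, path, normality, levene_p,
                            float(omnibus), posthoc, ns)


def summarize_table(measures: Sequence[GroupedMeasure],
                    grouping: tuple[str, ...] = ("genotype", "zone")
                    ) -> pd.DataFrame:
    """Mean ± SEM (n) per group cell, one row per measure × group."""
    rows = []
    for m in measures:
        frame = m.frame().dropna(subset=["value"])
        for key, g in frame.groupby(list(grouping), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            vals = g["value"].to_numpy()
            n = vals.size
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            formatted = (f"{mean:.3g} ± {sem:.2g} ({n})" if n > 1
                         else f"{mean:.3g} (1)")
            rows.append({"measure": m.name, "units": m.units,
                         **dict(zip(grouping, key)),
                         "mean": mean, "sem": sem, "n": n,
                         "formatted": formatted})
    return pd.DataFrame(rows)


# --- end-to-end pipeline ---------------------------------------------------

@dataclass
class PipelineReport:
    cells: pd.DataFrame
    summary: pd.DataFrame
    comparisons: dict[str, ComparisonReport]
    warnings: list[str] = field(default_factory=list)


def _jitter_model(model, rng, rel_sd=0.10, vh_sd=2.0, cm_rel_sd=0.05):
    """Per-cell biological variability around the preset means."""
    out = model.copy()
    out.cm = float(out.cm * rng.lognormal(0.0, cm_rel_sd))
    for c in out.conductances:
        c.g_max = float(c.g_max * rng.lognormal(0.0, rel_sd))
        if c.activation is not None:
            c.activation.v_half = float(c.activation.v_half + rng.normal(0, vh_sd))
    return out


def _analyze_cell(model, cell_type, seed, dt, noise_sd):
    from . import gv as _gv
    from . import kinetics as _kin
    from . import membrane as _mem
    from . import synth as _synth
    from .recording import build_protocol

    cfg = _synth.SimConfig(dt=dt, seed=seed, noise_sd=noise_sd)
    row: dict[str, float] = {}

    proto = build_protocol("type_I" if cell_type == "type_I" else "type_II")
    rec = _synth.simulate_voltage_clamp(model, proto, cfg)
    if cell_type == "type_I":
        curve = _gv.extract_tail_gv(rec, model.e_k)
        fit = _gv.fit_boltzmann(curve)
    else:
        curve = _gv.extract_peak_ss_gv(rec, model.e_k, use_fit=False).steady_state
        fit = _gv.fit_boltzmann(curve)
        # kinetics at the +30 mV step
        k30 = int(np.argmin(np.abs(np.asarray(proto.step_voltages) - 30.0)))
        sweep = rec.sweeps[k30]
        sel = (sweep.time >= proto.t_step + _kin.BLANK_MS) & (sweep.time < proto.t_tail)
        t30 = sweep.time[sel] - proto.t_step
        i30 = sweep.response[sel]
        i_peak = float(np.max(i30))
        i_end = float(i30[-1])
        row["pct_inact"] = _kin.percent_inactivation(i_peak, i_end)
        row["a_type"] = 1.0 if _kin.classify_a_current(t30, i30) == "A_type" else 0.0
    row["v_half"] = fit.v_half
    row["slope"] = fit.s
    row["g_max"] = fit.g_max
    row["g_density"] = _gv.conductance_density(fit.g_max, model.cm)

    # passive properties from small current steps sized from the rest slope
    v_rest = _synth.zero_current_potential(model)
    dv = 0.01
    g_rest = (model.total_ss_current(v_rest + dv)
              - model.total_ss_current(v_rest - dv)) / (2 * dv)  # nS
    i_small = 8.0 * g_rest  # targets ≈8 mV deflection
    cc = _synth.simulate_current_clamp(model, [-i_small, i_small], cfg,
                                       baseline_dur=80.0, step_dur=300.0,
                                       post_dur=20.0)
    passive = _mem.fit_passive_response(cc)
    row["v_rest"] = passive.v_rest
    row["r_in"] = passive.r_in
    row["tau_rc"] = passive.tau_rc

    if cell_type == "type_II":
        cc2 = _synth.simulate_current_clamp(model, [30.0], cfg,
                                            baseline_dur=80.0, step_dur=400.0,
                                            post_dur=20.0)
        res = _mem.fit_resonance(cc2.sweeps[0])
        row["q_e"] = res.q_e
        row["f_e"] = res.f_e
    return row


def run_pipeline(config: dict) -> PipelineReport:
    """Simulate cohorts from presets and run the per-cell analyses.

    ``config`` keys: ``cohorts`` (list of dicts with cell_type, genotype,
    zone, n_cells, optional jitter), ``seed``, optional ``dt`` (default
    0.02 ms), ``noise_sd`` (default 0), ``measures`` to compare (default all
    numeric), ``design`` for the dispatcher. Deterministic given ``seed``.
    """
    from . import synth as _synth

    cohorts = config.get("cohorts", [])
    warnings: list[str] = []
    if not cohorts:
        warnings.append("empty config: no cohorts to simulate")
        return PipelineReport(pd.DataFrame(), pd.DataFrame(), {}, warnings)
    seed = int(config.get("seed", 0))
    dt = float(config.get("dt", 0.02))
    noise_sd = float(config.get("noise_sd", 0.0))
    ss = np.random.SeedSequence(seed)

    rows = []
    for cohort in cohorts:
        n_cells = int(cohort.get("n_cells", 6))
        jitter = float(cohort.get("jitter", 0.10))
        base = _synth.make_preset(cohort["cell_type"], cohort["genotype"],
                                  cohort["zone"])
        child_seeds = ss.spawn(n_cells)
        for k in range(n_cells):
            rng = np.random.default_rng(child_seeds[k])
            model = _jitter_model(base, rng, rel_sd=jitter) if jitter > 0 else base
            cell_seed = int(child_seeds[k].generate_state(1)[0] % (2 ** 31))
            try:
                row = _analyze_cell(model, cohort["cell_type"], cell_seed,
                                    dt, noise_sd)
            except Exception as exc:  # noqa: BLE001 — per-cell failures logged
                warnings.append(
                    f"cell {cohort['cell_type']}:{cohort['genotype']}:"
                    f"{cohort['zone']}#{k} failed: {exc}")
                continue
            row.update(cell_type=cohort["cell_type"],
                       genotype=cohort["genotype"], zone=cohort["zone"])
            rows.append(row)

    cells = pd.DataFrame(rows)
    if cells.empty:
        return PipelineReport(cells, pd.DataFrame(), {}, warnings)
    measure_cols = config.get("measures") or [
        c for c in cells.columns
        if c not in ("cell_type", "genotype", "zone") and cells[c].notna().any()
    ]
    measures = [
        GroupedMeasure(c, "", cells[c].to_numpy(),
                       list(cells["genotype"]), list(cells["zone"]),
                       list(cells["cell_type"]))
        for c in measure_cols
    ]
    summary = summarize_table(measures)
    comparisons = {}
    for m in measures:
        rep = compare_groups(m, design=config.get("design", "auto"))
        comparisons[m.name] = rep
    return PipelineReport(cells, summary, comparisons, warnings)
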