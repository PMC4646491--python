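"""Hit-characterization analyses.

After the primary screen, candidate inhibitors are characterized by:
independent validation against vehicle control (paired t-test with the
conventional significance stars), concentration dependence (one-sided
monotone trend), 5 h vs 10 h readouts separating a *delay* (treated
catches up to control by the late readout) from an *arrest* (suppression
persists), washout reversibility, and cytospin morphology-class
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    """Conventional significance stars: * p<0.05 ... **** p<0.0001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class ValidationResult:
    compound_id: str
    n_experiments: int
    mean_treated: float
    sd_treated: float
    mean_control: float
    sd_control: float
    t_statistic: float
    p_value: float
    stars: str
    degenerate: bool = False  # zero-variance paired differences


def paired_ttest(treated, control, compound_id: str = "") -> ValidationResult:
    """Two-sided paired t-test of treated vs control enucleation %.

    Experiments are paired element-wise (each index is one biological
    experiment with its own vehicle control).  With zero-variance
    differences the t distribution degenerates; we report p = 1 for a
    zero mean difference and p = 0 otherwise, flagged ``degenerate``,
    since tiny replicate counts make this reachable in practice.
    """
    t_arr = np.asarray(treated, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.shape != c_arr.shape:
        raise ValueError("treated and control must pair element-wise")
    n = t_arr.size
    if n < 2:
        raise ValueError(f"need >= 2 paired experiments, got {n}")
    diffs = t_arr - c_arr
    if np.all(diffs == diffs[0]):
        mean_d = float(diffs[0])
        t_stat = 0.0 if mean_d == 0.0 else float(np.sign(mean_d) * np.inf)
        p = 1.0 if mean_d == 0.0 else 0.0
        degenerate = True
    else:
        res = stats.ttest_rel(t_arr, c_arr)
        t_stat, p = float(res.statistic), float(res.pvalue)
        degenerate = False
    return ValidationResult(
        compound_id=compound_id,
        n_experiments=n,
        mean_treated=float(t_arr.mean()),
        sd_treated=float(t_arr.std(ddof=1)),
        mean_control=float(c_arr.mean()),
        sd_control=float(c_arr.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p,
        stars=p_to_stars(p),
        degenerate=degenerate,
    )


def validate_compounds(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Paired-t validation of every compound in a tidy validation table.

    ``table`` columns: compound_id, experiment_id, arm
    ('treated' | 'control'), enucleation_pct.  Per-compound p-values are
    reported uncorrected by default (the star convention is per
    compound); ``bh_correct=True`` adds a Benjamini-Hochberg adjusted
    column and stars based on it.
    """
    rows = []
    for cpd, grp in table.groupby("compound_id", sort=True):
        pivot = grp.pivot_table(
            index="experiment_id", columns="arm", values="enucleation_pct"
        )
        if not {"treated", "control"} <= set(pivot.columns):
            raise ValueError(f"compound {cpd!r}: need both 'treated' and 'control' arms")
        pivot = pivot.dropna(subset=["treated", "control"])
        res = paired_ttest(pivot["treated"], pivot["control"], compound_id=str(cpd))
        rows.append(res.__dict__ | {"significant": res.p_value < alpha})
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        ranked = out["p_value"].to_numpy()[order]
        running = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
        adj[order] = np.clip(running, 0.0, 1.0)
        out["p_adjusted"] = adj
        out["stars"] = [p_to_stars(p) for p in adj]
        out["significant"] = out["p_adjusted"] < alpha
    return out


@dataclass(frozen=True)
class DoseTrendResult:
    rho: float
    p_value: float  # one-sided, decreasing
    n_doses: int
    monotone_inhibition: bool


def dose_trend(concentrations, responses, alpha: float = 0.05) -> DoseTrendResult:
    """One-sided Spearman trend test for concentration-dependent inhibition.

    Tests whether enucleation % decreases with concentration (rho < 0).
    Replicated measurements at the same concentration may be passed as
    repeated (concentration, response) pairs.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    if np.unique(conc).size < 3:
        raise ValueError(f"need >= 3 distinct concentrations, got {np.unique(conc).size}")
    import warnings

    with warnings.catch_warnings():
        # a constant response is a legitimate negative result, not a warning
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(conc, resp, alternative="less")
    rho = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(rho):  # constant response: no trend
        rho, p = 0.0, 1.0
    return DoseTrendResult(
        rho=rho, p_value=p, n_doses=int(np.unique(conc).size),
        monotone_inhibition=bool(p < alpha),
    )


@dataclass(frozen=True)
class MechanismCall:
    compound_id: str
    call: str  # no_effect | delay | arrest
    delta_5h: float  # mean treated - control at 5 h
    p_5h: float
    delta_10h: float
    p_10h: float


def classify_mechanism(
    treated_5h,
    control_5h,
    treated_10h,
    control_10h,
    alpha: float = 0.05,
    compound_id: str = "",
) -> MechanismCall:
    """Delay-vs-arrest classification from 5 h and 10 h paired readouts.

    Suppression at a timepoint means a significant paired difference
    (two-sided, at ``alpha``) with the treated mean below control.
    *delay*: suppressed at 5 h but indistinguishable from control at
    10 h; *arrest*: suppressed at both; anything else is *no_effect*.
    """
    r5 = paired_ttest(treated_5h, control_5h)
    r10 = paired_ttest(treated_10h, control_10h)
    d5 = r5.mean_treated - r5.mean_control
    d10 = r10.mean_treated - r10.mean_control
    sup5 = r5.p_value < alpha and d5 < 0
    sup10 = r10.p_value < alpha and d10 < 0
    if sup5 and sup10:
        call = "arrest"
    elif sup5 and not sup10:
        call = "delay"
    else:
        call = "no_effect"
    return MechanismCall(
        compound_id=compound_id,
        call=call,
        delta_5h=float(d5),
        p_5h=r5.p_value,
        delta_10h=float(d10),
        p_10h=r10.p_value,
    )


@dataclass(frozen=True)
class WashoutResult:
    recovered: bool
    recovery_time_h: float | None  # first post-washout timepoint within margin
    final_gap_pct: float


def washout_recovery(
    timepoints_h,
    treated_pct,
    control_pct,
    margin_pct: float = 10.0,
) -> WashoutResult:
    """Recovery verdict after compound washout.

    The culture counts as recovered when the treated enucleation % comes
    within ``margin_pct`` percentage points of the control at the final
    post-washout timepoint; the first timepoint at which that margin is
    reached is reported as the recovery time.
    """
    t = np.asarray(timepoints_h, dtype=float)
    trt = np.asarray(treated_pct, dtype=float)
    ctl = np.asarray(control_pct, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one post-washout timepoint")
    if not (t.shape == trt.shape == ctl.shape):
        raise ValueError("timepoints, treated and control must align")
    order = np.argsort(t)
    t, trt, ctl = t[order], trt[order], ctl[order]
    gap = ctl - trt
    within = gap <= margin_pct
    recovered = bool(within[-1])
    rec_time = float(t[np.argmax(within)]) if within.any() else None
    return WashoutResult(
        recovered=recovered,
        recovery_time_h=rec_time if recovered or within.any() else None,
        final_gap_pct=float(gap[-1]),
    )


@dataclass(frozen=True)
class MorphologySummary:
    classes: tuple[str, ...]
    mean_proportion: dict[str, float]
    sd_proportion: dict[str, float]
    n_experiments: int
    per_experiment: pd.DataFrame = field(repr=False, default=None)


def morphology_proportions(counts: pd.DataFrame) -> MorphologySummary:
    """Per-class mean proportion +/- SD across cytospin experiments.

    ``counts`` columns: experiment_id, class, count.  Proportions are
    computed within each experiment first (classes absent from an
    experiment count as zero), then averaged across experiments; with a
    single experiment the SD is reported as 0.
    """
    if counts.empty:
        raise ValueError("need at least one experiment")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    wide = (
        counts.pivot_table(index="experiment_id", columns="class", values="count",
                           aggfunc="sum", fill_value=0)
        .astype(float)
    )
    totals = wide.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every experiment must enumerate at least one cell")
    props = wide.div(totals, axis=0)
    mean = props.mean(axis=0)
    sd = props.std(axis=0, ddof=1) if len(props) > 1 else props.iloc[0] * 0.0
    return MorphologySummary(
        classes=tuple(props.columns),
        mean_proportion={c: float(mean[c]) for c in props.columns},
        sd_proportion={c: float(sd[c]) for c in props.columns},
        n_experiments=len(props),
        per_experiment=props,
    )
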