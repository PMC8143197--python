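"""Survival and seeding-curve statistics.

Kaplan–Meier curves with right censoring (Greenwood bands), two-group
log-rank tests with an optional permutation p-value, Cox proportional
hazards with Efron tie handling (the 2-hour frame grid produces heavy
ties), cumulative aggregation-onset curves, aggregate-fraction time points,
trapezoidal AUC of seeding curves with two-way line-by-dose ANOVA, early
seeding-slope comparisons and expression correlations.

Kaplan–Meier and Cox fits are delegated to ``lifelines``; the log-rank
statistic is computed directly (vectorised, so permutation nulls and
replicate sweeps are cheap) and cross-checked against ``lifelines`` in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

EARLY_AGGREGATOR_CUTOFF_H = 48.0


# ----------------------------------------------------------------------
@dataclass
class KMCurve:
    """Product-limit estimate S(t) with risk sets and a 95% band."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_estimate(time_h, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator with right censoring."""
    time_h = np.asarray(time_h, float)
    event = np.asarray(event, bool)
    if len(time_h) == 0:
        raise ValueError("no records")
    if (time_h <= 0).all():
        raise ValueError("all times non-positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time_h, event_observed=event)
    tab = kmf.event_table
    times = tab.index.to_numpy(float)
    keep = times > 0
    sf = kmf.survival_function_["KM_estimate"].to_numpy()[keep]
    ci = kmf.confidence_interval_.to_numpy()[keep]
    return KMCurve(
        times=times[keep],
        survival=sf,
        at_risk=tab["at_risk"].to_numpy()[keep],
        events=tab["observed"].to_numpy()[keep],
        ci_lower=ci[:, 0],
        ci_upper=ci[:, 1],
    )


# ----------------------------------------------------------------------
def _logrank_tables(time, event, group):
    """Pooled risk/death tables at the distinct event times.

    Returns (n, n1, d, d1) arrays over event times, where group 1 counts
    carry the subscript.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group)
    ev_times = np.unique(time[event])
    # at risk: T_i >= t_j
    n = (time[:, None] >= ev_times[None, :]).sum(axis=0)
    n1 = ((time[:, None] >= ev_times[None, :]) & group[:, None]).sum(axis=0)
    d = ((time[:, None] == ev_times[None, :]) & event[:, None]).sum(axis=0)
    d1 = (
        (time[:, None] == ev_times[None, :]) & event[:, None] & group[:, None]
    ).sum(axis=0)
    return n, n1, d, d1


def _logrank_chi2(time, event, group) -> float:
    n, n1, d, d1 = _logrank_tables(time, event, group)
    valid = n > 1
    e1 = d * n1 / n
    v = d * (n1 / n) * (1 - n1 / n) * (n - d) / np.maximum(n - 1, 1)
    u = (d1 - e1)[valid].sum()
    var = v[valid].sum()
    if var <= 0:
        return 0.0
    return float(u * u / var)


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    p_permutation: float | None = None
    n_permutations: int | None = None


def log_rank(
    time_a, event_a, time_b, event_b,
    permutations: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> LogRankResult:
    """Two-group log-rank test (df = 1).

    With ``permutations`` set, also estimates the p-value by permuting the
    group labels and recomputing the statistic.
    """
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, bool), np.asarray(event_b, bool)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (event_a.any() or event_b.any()):
        raise ValueError("no events in either group")
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    group = np.concatenate(
        [np.ones(len(time_a), bool), np.zeros(len(time_b), bool)]
    )
    chi2 = _logrank_chi2(time, event, group)
    p = float(stats.chi2.sf(chi2, df=1))
    p_perm = None
    if permutations:
        rng = np.random.default_rng(rng)
        ev_times = np.unique(time[event])
        A = (time[:, None] >= ev_times[None, :]).astype(np.float64)
        B = ((time[:, None] == ev_times[None, :]) & event[:, None]).astype(
            np.float64
        )
        n = A.sum(axis=0)
        d = B.sum(axis=0)
        G = np.empty((permutations, len(time)))
        for i in range(permutations):
            G[i] = rng.permutation(group).astype(np.float64)
        N1 = G @ A
        D1 = G @ B
        E1 = d * N1 / n
        V = d * (N1 / n) * (1 - N1 / n) * (n - d) / np.maximum(n - 1, 1)
        valid = n > 1
        U = (D1 - E1)[:, valid].sum(axis=1)
        VV = V[:, valid].sum(axis=1)
        chis = np.where(VV > 0, U * U / np.maximum(VV, 1e-300), 0.0)
        p_perm = float((np.sum(chis >= chi2 - 1e-12) + 1) / (permutations + 1))
    return LogRankResult(chi2, p, p_perm, permutations)


def cox_score_test(time, event, group) -> tuple[float, float]:
    """Score test of a single binary covariate in the Cox model at beta=0.

    Uses the Breslow partial likelihood, whose score statistic coincides
    with the log-rank statistic when event times are untied.
    """
    n, n1, d, d1 = _logrank_tables(time, event, np.asarray(group, bool))
    u = (d1 - d * n1 / n).sum()
    info = (d * (n1 / n) * (1 - n1 / n)).sum()
    if info <= 0:
        return 0.0, 1.0
    chi2 = float(u * u / info)
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ----------------------------------------------------------------------
@dataclass
class CoxResult:
    """Covariate table of a proportional-hazards fit."""

    summary: pd.DataFrame  # index: covariate; coef, hazard_ratio, ci, p
    ties_method: str = "efron"

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time_h",
    event_col: str = "event",
    covariates: list[str] | None = None,
    ties_method: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards partial-likelihood fit (Efron ties).

    Wald confidence intervals and p-values per covariate.  The Efron
    approximation is used throughout because the imaging frame grid ties
    many event times; ``lifelines`` implements it natively.
    """
    if ties_method != "efron":
        raise NotImplementedError("only Efron tie handling is provided")
    covariates = covariates or [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    sub = df[[duration_col, event_col] + covariates].dropna()
    cph = CoxPHFitter()
    cph.fit(sub, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "se": s["se(coef)"],
            "ci_lower": s["coef lower 95%"],
            "ci_upper": s["coef upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(summary=out, ties_method=ties_method)


# ----------------------------------------------------------------------
def onset_records(df: pd.DataFrame, clock: str = "seed_addition") -> pd.DataFrame:
    """Records treating aggregation onset as the event of interest.

    Death or censoring before onset censors the onset clock.
    """
    onset = df["onset_h"].to_numpy(float)
    time = np.where(np.isnan(onset), df["time_h"].to_numpy(float), onset)
    event = ~np.isnan(onset)
    return pd.DataFrame(
        {"time_h": time, "event": event, "line": df.get("line")}
    )


def cumulative_onset(df: pd.DataFrame) -> pd.DataFrame:
    """Cumulative incidence of aggregation onset, 1 - KM on the onset clock."""
    rec = onset_records(df)
    if not rec["event"].any():
        return pd.DataFrame(
            {"time_h": [0.0], "cumulative_incidence": [0.0]}
        )
    km = km_estimate(rec["time_h"], rec["event"])
    return pd.DataFrame(
        {"time_h": km.times, "cumulative_incidence": 1.0 - km.survival}
    )


def post_onset_records(df: pd.DataFrame) -> pd.DataFrame:
    """Survival records on the post-onset clock (aggregate formers only).

    Each aggregate-forming cell's clock restarts at its onset; left
    truncation is ignored by construction of this design.  Zero-length
    intervals (event at the onset frame) are nudged by half a frame so the
    records remain valid survival times.
    """
    sub = df[df["onset_h"].notna()].copy()
    dur = sub["time_h"].to_numpy(float) - sub["onset_h"].to_numpy(float)
    dur = np.maximum(dur, 1.0)  # half of the 2-h frame interval
    return pd.DataFrame(
        {"time_h": dur, "event": sub["event"].to_numpy(bool), "line": sub["line"]}
    )


def aggregate_fraction_at(
    df: pd.DataFrame,
    timepoints_h: tuple[float, ...] = (48.0, 168.0),
    group_col: str = "line",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Per-replicate fraction of neurons with onset by each time point.

    The denominator is the neurons still under observation at the time
    point (not yet dead or censored).  Groups are compared per time point
    with a Welch two-sample t test across replicate fractions.
    """
    rows = []
    for tp in timepoints_h:
        per_rep = []
        for (grp, rep), sub in df.groupby([group_col, replicate_col]):
            observable = sub["time_h"] >= tp
            if observable.sum() == 0:
                raise ValueError(f"empty replicate at t={tp}")
            frac = float(
                (sub.loc[observable, "onset_h"] <= tp).fillna(False).mean()
            )
            per_rep.append((grp, rep, tp, frac))
        per_rep = pd.DataFrame(
            per_rep, columns=[group_col, replicate_col, "time_h", "fraction"]
        )
        rows.append(per_rep)
    out = pd.concat(rows, ignore_index=True)
    groups = sorted(out[group_col].unique())
    tests = []
    for tp in timepoints_h:
        sub = out[out["time_h"] == tp]
        if len(groups) == 2:
            a = sub[sub[group_col] == groups[0]]["fraction"]
            b = sub[sub[group_col] == groups[1]]["fraction"]
            if len(a) > 1 and len(b) > 1:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                t, p = np.nan, np.nan
            tests.append(dict(time_h=tp, t=t, p=p,
                              mean_a=a.mean(), mean_b=b.mean(),
                              group_a=groups[0], group_b=groups[1]))
    return out, pd.DataFrame(tests)


# ----------------------------------------------------------------------
def auc_trapezoid(series) -> float:
    """Trapezoidal area under the baseline-corrected seeding curve."""
    t = np.asarray(series.time_h, float)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(series.corrected_counts, t))


@dataclass
class AnovaResult:
    table: pd.DataFrame  # index: term; columns F, df, p

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def anova_line_by_dose(df: pd.DataFrame, value_col: str = "auc") -> AnovaResult:
    """Two-way ANOVA of AUC on cell line and lysate dose (Type II SS).

    With the balanced simulated designs Type I/II/III sums of squares
    coincide; Type II is used for robustness to mild imbalance.
    """
    for col in ("line", "dose_ug"):
        if df[col].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {col}")
    counts = df.groupby(["line", "dose_ug"]).size()
    if (counts < 2).any():
        raise ValueError("need >= 2 observations per design cell")
    model = smf.ols(f"{value_col} ~ C(line) * C(dose_ug)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = pd.DataFrame(
        {
            "F": tab["F"],
            "df": tab["df"],
            "p": tab["PR(>F)"],
            "sum_sq": tab["sum_sq"],
        }
    )
    out.index = out.index.str.replace("C(line)", "line", regex=False)
    out.index = out.index.str.replace("C(dose_ug)", "dose", regex=False)
    out.index = out.index.str.replace("line:dose", "interaction", regex=False)
    return AnovaResult(out)


def seeding_slope(
    series_list: list,
    window_h: tuple[float, float] = (24.0, 48.0),
) -> tuple[pd.DataFrame, dict]:
    """Least-squares slope of each corrected seeding curve in a time window.

    Returns per-replicate slopes and, when exactly two lines are present, a
    Welch two-sample t test between them.
    """
    rows = []
    for s in series_list:
        sel = (s.time_h >= window_h[0]) & (s.time_h <= window_h[1])
        if sel.sum() < 2:
            raise ValueError("window contains fewer than two points")
        res = stats.linregress(s.time_h[sel], s.corrected_counts[sel])
        rows.append(
            dict(
                well_id=s.well_id, line=s.line, dose_ug=s.dose_ug,
                replicate=s.replicate, slope_per_h=res.slope,
            )
        )
    slopes = pd.DataFrame(rows)
    test: dict = {}
    lines = sorted(slopes["line"].dropna().unique())
    if len(lines) == 2:
        a = slopes[slopes["line"] == lines[0]]["slope_per_h"]
        b = slopes[slopes["line"] == lines[1]]["slope_per_h"]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        test = dict(t=float(t), p=float(p), group_a=lines[0], group_b=lines[1],
                    mean_a=float(a.mean()), mean_b=float(b.mean()))
    return slopes, test


# ----------------------------------------------------------------------
def onset_expression_correlation(
    df: pd.DataFrame,
    outcome_col: str = "onset_h",
    intensity_col: str = "t0_intensity_norm",
) -> dict:
    """Pearson correlation of an outcome with normalised t0 expression.

    Reports r, the two-sided p-value, r² and adjusted R² side by side (the
    three are easily conflated when correlations are near zero).
    """
    sub = df[[outcome_col, intensity_col]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need >= 3 cells")
    x = sub[intensity_col].to_numpy(float)
    y = sub[outcome_col].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    r2 = r * r
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return dict(r=float(r), p=float(p), r_squared=float(r2),
                adjusted_r_squared=float(adj_r2), n=n)


# ----------------------------------------------------------------------
def plot_km_curves(curves: dict[str, KMCurve], path, title: str = "",
                   xlabel: str = "hours post seed addition") -> None:
    """Write a step plot of one or more KM curves with their 95% bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, km in curves.items():
        t = np.r_[0.0, km.times]
        s = np.r_[1.0, km.survival]
        (line,) = ax.step(t, s, where="post", label=label)
        ax.fill_between(
            np.r_[0.0, km.times],
            np.r_[1.0, km.ci_lower],
            np.r_[1.0, km.ci_upper],
            step="post", alpha=0.2, color=line.get_color(),
        )
    ax.set_xlabel(xlabel)
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    if len(curves) > 1:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ----------------------------------------------------------------------
def early_aggregator_groups(
    df: pd.DataFrame, cutoff_h: float = EARLY_AGGREGATOR_CUTOFF_H
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tracked neurons into early aggregators vs all others.

    Early aggregators form a soma aggregate within ``cutoff_h`` of seed
    addition; the comparison group is every other neuron still under
    observation at the cutoff (cells lost before the cutoff cannot be
    assigned and are dropped).
    """
    early = (df["onset_h"] <= cutoff_h).fillna(False)
    observable = df["time_h"] >= cutoff_h
    return df[early & observable], df[~early & observable]
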