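"""Gait parameters from footfall events, mixed ANOVA and correlations.

Footfall event streams (contact/lift times and print positions for the
four paws — contralesional/ipsilesional front and hind: CF, CH, IF, IH)
are reduced to the standard CatWalk-style parameters:

* stance duration  = t_lift - t_contact
* swing duration   = next t_contact (same paw) - t_lift
* stride length    = distance between successive placements of the paw
* swing speed      = stride length / swing duration
* body speed (paw) = stride length / (stance + swing)
* cadence          = total steps / run duration
* average speed    = displacement of the paw-position centroid over the
  centroid's contact-sampling window

Runs failing the compliance rule (duration over 5 s or body-speed
variation over 60%) are excluded.  Group x paw effects are tested with a
two-way mixed-design ANOVA (between factor: treatment; within factor:
paw), and brain-behaviour relations with Pearson correlations whose
p-values come from t = r*sqrt(n-2)/sqrt(1-r^2) at n-2 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import PAWS, GaitRun

__all__ = [
    "ComplianceResult",
    "AnovaResult",
    "CorrelationResult",
    "run_compliance",
    "compute_gait_params",
    "aggregate_animal",
    "build_param_table",
    "mixed_anova",
    "fdist_pvalue",
    "posthoc_pairwise",
    "correlate",
    "p_from_r",
]

STEP_PARAMS = (
    "swing_duration",
    "stance_duration",
    "swing_speed",
    "stride_length",
    "body_speed",
    "print_area",
)
GLOBAL_PARAMS = ("average_speed", "cadence", "number_of_steps")


@dataclass
class ComplianceResult:
    compliant: bool
    reasons: list[str]
    duration_s: float
    speed_variation_pct: float | None


@dataclass
class AnovaResult:
    """Split-plot ANOVA table with separate between/within error strata."""

    table: pd.DataFrame  # rows: treatment, subjects_within_groups, paw, interaction, paw_x_subjects
    parameter: str

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float
    x_name: str = "x"
    y_name: str = "y"


# ---------------------------------------------------------------------------
# per-run computation


def _run_duration(run: GaitRun) -> float:
    t0 = min(e.t_contact for e in run.events)
    t1 = max(e.t_lift for e in run.events)
    return t1 - t0


def _step_records(run: GaitRun) -> pd.DataFrame:
    """Per-step parameters for each paw (steps = complete cycles)."""
    rows = []
    by_paw: dict[str, list] = {}
    for e in run.events:
        by_paw.setdefault(e.paw, []).append(e)
    for paw, events in by_paw.items():
        events.sort(key=lambda e: e.t_contact)
        for e in events:
            if e.t_lift <= e.t_contact:
                raise ValueError(f"event with t_lift <= t_contact for paw {paw}")
        for a, b in zip(events, events[1:]):
            stance = a.t_lift - a.t_contact
            swing = b.t_contact - a.t_lift
            if swing <= 0:
                raise ValueError(
                    f"overlapping events for paw {paw}: negative swing duration"
                )
            stride = float(np.hypot(b.x - a.x, b.y - a.y))
            rows.append(
                {
                    "paw": paw,
                    "t_contact": a.t_contact,
                    "stance_duration": stance,
                    "swing_duration": swing,
                    "stride_length": stride,
                    "swing_speed": stride / swing,
                    "body_speed": stride / (stance + swing),
                    "print_area": a.print_area,
                }
            )
    return pd.DataFrame(rows)


def run_compliance(
    run: GaitRun,
    max_duration_s: float = 5.0,
    max_speed_variation_pct: float = 60.0,
) -> ComplianceResult:
    """Apply the compliance rule: duration <= 5 s, speed variation <= 60%.

    Speed variation is 100 * (v_max - v_min) / v_mean over mean body-speed
    estimates in the three thirds of the run (per-step body speeds binned
    by contact time).  The CatWalk instrument's exact definition is
    proprietary; both limits and this estimator are configurable.
    """
    reasons: list[str] = []
    counts: dict[str, int] = {}
    for e in run.events:
        counts[e.paw] = counts.get(e.paw, 0) + 1
    if any(counts.get(p, 0) < 2 for p in PAWS):
        return ComplianceResult(False, ["insufficient steps"], _run_duration(run), None)

    duration = _run_duration(run)
    if duration > max_duration_s:
        reasons.append(f"duration {duration:.2f} s exceeds {max_duration_s} s")

    steps = _step_records(run)
    t0 = steps["t_contact"].min()
    rel = (steps["t_contact"] - t0) / max(duration, 1e-12)
    thirds = np.clip((rel * 3).astype(int), 0, 2)
    v = steps.groupby(thirds)["body_speed"].mean()
    variation = None
    if len(v) >= 2 and v.mean() > 0:
        variation = 100.0 * (v.max() - v.min()) / v.mean()
        if variation > max_speed_variation_pct:
            reasons.append(
                f"speed variation {variation:.0f}% exceeds {max_speed_variation_pct}%"
            )
    return ComplianceResult(not reasons, reasons, duration, variation)


def compute_gait_params(run: GaitRun) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-paw step records plus per-run global parameters."""
    steps = _step_records(run)
    if steps.empty:
        raise ValueError(f"run {run.run_id} has no complete step cycles")
    duration = _run_duration(run)
    n_contacts = len(run.events)
    # centroid displacement between first and last contact of each paw
    first = {}
    last = {}
    for e in run.events:
        if e.paw not in first or e.t_contact < first[e.paw].t_contact:
            first[e.paw] = e
        if e.paw not in last or e.t_contact > last[e.paw].t_contact:
            last[e.paw] = e
    c0 = np.mean([[first[p].x, first[p].y] for p in first], axis=0)
    c1 = np.mean([[last[p].x, last[p].y] for p in last], axis=0)
    t_span = np.mean(
        [last[p].t_contact - first[p].t_contact for p in first]
    )  # centroid sampled at matched contact events of each paw
    globals_ = {
        "average_speed": float(np.hypot(*(c1 - c0))) / max(t_span, 1e-12),
        "cadence": n_contacts / duration,
        "number_of_steps": float(n_contacts),
    }
    return steps, globals_


def aggregate_animal(
    runs: list[GaitRun],
    animal_id: str,
    compliance_kwargs: dict | None = None,
    enforce_compliance: bool = True,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Average step->run->animal, weighting runs equally.

    Returns (per-paw parameter rows, per-animal global parameters, number
    of compliant runs used).
    """
    kw = compliance_kwargs or {}
    per_run_paw = []
    per_run_global = []
    n_used = 0
    for run in runs:
        if enforce_compliance and not run_compliance(run, **kw).compliant:
            continue
        steps, globals_ = compute_gait_params(run)
        per_run_paw.append(steps.groupby("paw")[list(STEP_PARAMS)].mean())
        per_run_global.append(globals_)
        n_used += 1
    if n_used == 0:
        raise ValueError(f"animal {animal_id}: no compliant runs")
    paw_means = (
        pd.concat(per_run_paw)
        .groupby(level=0)
        .mean()
        .reindex(list(PAWS))
        .reset_index()
        .rename(columns={"index": "paw"})
    )
    paw_means.insert(0, "animal_id", animal_id)
    glob = pd.DataFrame(per_run_global).mean()
    glob["animal_id"] = animal_id
    return paw_means, glob, n_used


def build_param_table(
    animal_runs: dict[str, list[GaitRun]],
    groups: dict[str, str],
    compliance_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level per-paw table and per-animal global table."""
    paw_rows, glob_rows = [], []
    for animal_id, runs in animal_runs.items():
        paw, glob, _ = aggregate_animal(runs, animal_id, compliance_kwargs)
        paw["group"] = groups[animal_id]
        paw_rows.append(paw)
        glob["group"] = groups[animal_id]
        glob_rows.append(glob)
    return (
        pd.concat(paw_rows, ignore_index=True),
        pd.DataFrame(glob_rows).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# statistics


def fdist_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 with positive degrees of freedom")
    return float(stats.f.sf(F, df1, df2))


def mixed_anova(
    table: pd.DataFrame,
    parameter: str,
    subject: str = "animal_id",
    between: str = "group",
    within: str = "paw",
) -> AnovaResult:
    """Two-way mixed-design (split-plot) ANOVA.

    The between-subjects factor (treatment) is tested against the
    subjects-within-groups mean square; the within-subjects factor (paw)
    and the interaction against the paw x subjects-within-groups mean
    square.  The decomposition is exact (sums of squares are additive)
    for unequal group sizes as long as every subject has every level of
    the within factor; missing cells raise.
    """
    df = table[[subject, between, within, parameter]].copy()
    if df[parameter].isna().any():
        raise ValueError("missing values in parameter column")
    wide = df.pivot_table(
        index=[subject, between], columns=within, values=parameter, aggfunc="mean"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete design: every subject needs every paw level")
    levels = list(wide.columns)
    p = len(levels)
    groups = wide.index.get_level_values(between)
    group_levels = list(pd.unique(groups))
    g = len(group_levels)
    if g < 2:
        raise ValueError("between factor needs at least two levels")
    Y = wide.to_numpy(dtype=np.float64)  # subjects x paw levels
    n_total = Y.shape[0]
    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    group_sizes = np.array([(groups == lvl).sum() for lvl in group_levels])
    group_mean = np.array([Y[groups == lvl].mean() for lvl in group_levels])
    paw_mean = Y.mean(axis=0)
    cell_mean = np.vstack([Y[groups == lvl].mean(axis=0) for lvl in group_levels])

    ss_treat = p * float(np.sum(group_sizes * (group_mean - grand) ** 2))
    ss_subj = p * sum(
        float(np.sum((subj_mean[groups == lvl] - group_mean[i]) ** 2))
        for i, lvl in enumerate(group_levels)
    )
    ss_paw = n_total * float(np.sum((paw_mean - grand) ** 2))
    ss_inter = float(
        np.sum(
            group_sizes[:, None]
            * (cell_mean - group_mean[:, None] - paw_mean[None, :] + grand) ** 2
        )
    )
    ss_err_within = 0.0
    for i, lvl in enumerate(group_levels):
        sel = groups == lvl
        resid = Y[sel] - subj_mean[sel][:, None] - cell_mean[i][None, :] + group_mean[i]
        ss_err_within += float(np.sum(resid**2))

    df_treat, df_subj = g - 1, n_total - g
    df_paw = p - 1
    df_inter = (g - 1) * (p - 1)
    df_err_within = (n_total - g) * (p - 1)

    ms_subj = ss_subj / df_subj
    ms_err = ss_err_within / df_err_within

    def row(name, ss, d1, err_ss, err_df):
        ms = ss / d1
        err_ms = err_ss / err_df
        F = ms / err_ms if err_ms > 0 else np.inf
        return {
            "SS": ss,
            "df1": d1,
            "df2": err_df,
            "MS": ms,
            "F": F,
            "p": fdist_pvalue(F, d1, err_df) if np.isfinite(F) else 0.0,
        }

    out = pd.DataFrame(
        {
            "treatment": row("treatment", ss_treat, df_treat, ss_subj, df_subj),
            "subjects_within_groups": {
                "SS": ss_subj,
                "df1": df_subj,
                "df2": np.nan,
                "MS": ms_subj,
                "F": np.nan,
                "p": np.nan,
            },
            "paw": row("paw", ss_paw, df_paw, ss_err_within, df_err_within),
            "interaction": row("interaction", ss_inter, df_inter, ss_err_within, df_err_within),
            "paw_x_subjects": {
                "SS": ss_err_within,
                "df1": df_err_within,
                "df2": np.nan,
                "MS": ms_err,
                "F": np.nan,
                "p": np.nan,
            },
        }
    ).T
    return AnovaResult(out, parameter)


def posthoc_pairwise(
    table: pd.DataFrame,
    parameter: str,
    scheme: str = "holm",
    subject: str = "animal_id",
    between: str = "group",
    within: str = "paw",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Post hoc tests after the mixed ANOVA.

    Between-group two-sample t per paw, and within-group paired t for each
    paw pair; p-values corrected per family with the chosen scheme
    ("holm" or "none").
    """
    if scheme not in ("holm", "none"):
        raise ValueError("scheme must be 'holm' or 'none'")
    wide = table.pivot_table(
        index=[subject, between], columns=within, values=parameter, aggfunc="mean"
    )
    groups = wide.index.get_level_values(between)
    group_levels = list(pd.unique(groups))
    rows = []
    # between-group, per paw
    for paw in wide.columns:
        a = wide.loc[groups == group_levels[0], paw].to_numpy()
        b = wide.loc[groups == group_levels[1], paw].to_numpy()
        t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "family": "between_groups",
                "comparison": f"{group_levels[0]} vs {group_levels[1]} @ {paw}",
                "t": float(t),
                "p_raw": float(p),
            }
        )
    # within-group, paw pairs
    for lvl in group_levels:
        sub = wide.loc[groups == lvl]
        paws = list(wide.columns)
        for i in range(len(paws)):
            for j in range(i + 1, len(paws)):
                t, p = stats.ttest_rel(sub[paws[i]], sub[paws[j]])
                rows.append(
                    {
                        "family": f"within_{lvl}",
                        "comparison": f"{paws[i]} vs {paws[j]} in {lvl}",
                        "t": float(t),
                        "p_raw": float(p),
                    }
                )
    out = pd.DataFrame(rows)
    if scheme == "none":
        out["p_adj"] = out["p_raw"]
    else:
        out["p_adj"] = np.nan
        for fam, idx in out.groupby("family").groups.items():
            out.loc[idx, "p_adj"] = multipletests(
                out.loc[idx, "p_raw"].to_numpy(), method="holm"
            )[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t transform.

    t = r * sqrt(n-2) / sqrt(1-r^2), referred to the t distribution with
    n-2 degrees of freedom.  Exposed directly so printed (r, n) pairs can
    be validated against their reported p-values.
    """
    if n < 4:
        raise ValueError("p_from_r requires n >= 4")
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


def correlate(x_values, y_values, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson correlation with the t-based two-sided p value."""
    x = np.asarray(x_values, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("correlate requires two equal-length 1D samples")
    n = x.size
    if n < 4:
        raise ValueError("correlate requires n >= 4")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance sample: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    p = p_from_r(r, n)
    t = float(r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, 1e-300)))
    return CorrelationResult(r=r, n=n, t=t, p=p, x_name=x_name, y_name=y_name)
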