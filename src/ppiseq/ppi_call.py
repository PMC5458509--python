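"""Genotype-pair interaction scoring and dynamic-interaction detection.

Each bait:prey genotype pair is measured by ~75 usable fitness estimates
(25 barcode pairs x 3 growth replicates).  A pair scores as an interaction
when its fitness sample exceeds that of the pooled reporter-negative
control lineages by a one-sided Welch t-test, Bonferroni-corrected
(x 500 tests by default).  A detected interaction is *dynamic* when its
fitness sample in a perturbation environment differs from the permissive
environment by a two-sided Welch t-test, Bonferroni-corrected (x 400).

Also provided are the two orthogonal validation scores used to confirm
individual interactions: relative fitness from isolated-growth OD curves
(area under the curve, differenced against a control strain and normalized
to the vehicle condition) and the luciferase-reporter luminescence ratio.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PAIR_COLUMNS = ["Bait", "Prey"]
ENV_COLUMNS = ["Condition", "Methotrexate_selection"]


def _usable(estimates: pd.DataFrame) -> pd.DataFrame:
    df = estimates
    if "Trajectory_used" in df.columns:
        df = df.loc[df["Trajectory_used"].astype(bool)]
    return df.loc[np.isfinite(df["Fitness"])]


def _bonferroni(p: float, n_tests: int) -> float:
    return float(min(1.0, p * n_tests))


def score_ppis(
    estimates: pd.DataFrame,
    n_tests: int = 500,
    alpha: float = 0.05,
    equal_var: bool = False,
    control_label: str = "ctrl",
) -> pd.DataFrame:
    """Score every genotype pair against the pooled control lineages.

    Parameters
    ----------
    estimates
        Per-lineage table with columns ``Bait, Prey, Condition,
        Methotrexate_selection, Replicate, Fitness`` and optionally
        ``Trajectory_used`` (only used estimates enter the test).
        Control lineages are those whose bait *and* prey equal
        ``control_label``.
    n_tests
        Bonferroni denominator (the designed number of comparisons, not
        the number actually performed).
    equal_var
        ``False`` (default) uses Welch's unequal-variance t-test;
        ``True`` restores the pooled-variance Student form.

    Returns one row per (pair, environment) with the mean fitness, its
    s.e.m., the one-sided (greater) corrected p-value and a significance
    flag at ``alpha``.
    """
    df = _usable(estimates)
    is_ctrl = (df["Bait"] == control_label) & (df["Prey"] == control_label)
    rows = []
    for env, env_df in df.groupby(ENV_COLUMNS, sort=False):
        ctrl = env_df.loc[is_ctrl.loc[env_df.index], "Fitness"].to_numpy()
        for (bait, prey), grp in env_df.loc[~is_ctrl.loc[env_df.index]].groupby(
            PAIR_COLUMNS, sort=False
        ):
            x = grp["Fitness"].to_numpy()
            rec = {
                "Bait": bait,
                "Prey": prey,
                "Condition": env[0],
                "Methotrexate_selection": env[1],
                "mean_fitness": float(x.mean()) if len(x) else np.nan,
                "sem": float(stats.sem(x)) if len(x) > 1 else np.nan,
                "n": len(x),
                "n_control": len(ctrl),
            }
            if len(x) < 2 or len(ctrl) < 2:
                rec.update(p_raw=np.nan, p_bonferroni=np.nan, significant=False,
                           skipped="fewer than 2 estimates in a group")
            else:
                t = stats.ttest_ind(x, ctrl, equal_var=equal_var, alternative="greater")
                rec.update(
                    p_raw=float(t.pvalue),
                    p_bonferroni=_bonferroni(t.pvalue, n_tests),
                    significant=bool(_bonferroni(t.pvalue, n_tests) < alpha),
                    skipped="",
                )
            rows.append(rec)
    return pd.DataFrame(rows)


def detect_dynamic(
    estimates: pd.DataFrame,
    reference_condition: str = "DMSO",
    n_tests: int = 400,
    alpha: float = 0.05,
    equal_var: bool = False,
    mtx_only: bool = True,
    control_label: str = "ctrl",
) -> pd.DataFrame:
    """Test every pair's fitness in each environment against the reference.

    The reference (permissive) environment is the vehicle condition under
    selection; it is excluded from its own comparison.  Returns one row
    per (pair, non-reference environment) with the fitness difference, the
    two-sided corrected p-value, and the direction of change.
    """
    df = _usable(estimates)
    if mtx_only and "Methotrexate_selection" in df.columns:
        df = df.loc[df["Methotrexate_selection"].astype(bool)]
    df = df.loc[(df["Bait"] != control_label) | (df["Prey"] != control_label)]
    rows = []
    for (bait, prey), grp in df.groupby(PAIR_COLUMNS, sort=False):
        ref = grp.loc[grp["Condition"] == reference_condition, "Fitness"].to_numpy()
        for cond, sub in grp.loc[grp["Condition"] != reference_condition].groupby(
            "Condition", sort=False
        ):
            x = sub["Fitness"].to_numpy()
            rec = {
                "Bait": bait,
                "Prey": prey,
                "Condition": cond,
                "mean_fitness": float(x.mean()) if len(x) else np.nan,
                "reference_fitness": float(ref.mean()) if len(ref) else np.nan,
                "delta_fitness": float(x.mean() - ref.mean()) if len(x) and len(ref) else np.nan,
            }
            if len(x) < 2 or len(ref) < 2:
                rec.update(p_raw=np.nan, p_bonferroni=np.nan, significant=False,
                           direction="", skipped="missing environment or <2 estimates")
            else:
                t = stats.ttest_ind(x, ref, equal_var=equal_var)
                p_corr = _bonferroni(t.pvalue, n_tests)
                rec.update(
                    p_raw=float(t.pvalue),
                    p_bonferroni=p_corr,
                    significant=bool(p_corr < alpha),
                    direction="gain" if rec["delta_fitness"] > 0 else "loss",
                    skipped="",
                )
            rows.append(rec)
    columns = [
        "Bait", "Prey", "Condition", "mean_fitness", "reference_fitness",
        "delta_fitness", "p_raw", "p_bonferroni", "significant", "direction",
        "skipped",
    ]
    return pd.DataFrame(rows, columns=columns)


def dynamic_summary(
    scores: pd.DataFrame,
    dynamic: pd.DataFrame,
) -> dict:
    """Summaries over the detected interaction set.

    "Detected" = significant versus control in at least one environment
    (the denominator of the published 12/14 and 7/14 fractions).  Returns
    the detected pair list, the fraction with >= 1 significant change
    relative to the permissive environment, and the fraction undetectable
    (not significant versus control) in >= 1 environment.
    """
    sig = scores.loc[scores["significant"]]
    detected = set(map(tuple, sig[PAIR_COLUMNS].drop_duplicates().to_numpy()))
    if not detected:
        return {"detected": [], "n_detected": 0, "fraction_changed": np.nan,
                "fraction_undetectable": np.nan}
    changed = 0
    undetectable = 0
    for pair in detected:
        mask_d = (dynamic["Bait"] == pair[0]) & (dynamic["Prey"] == pair[1])
        if dynamic.loc[mask_d, "significant"].any():
            changed += 1
        mask_s = (scores["Bait"] == pair[0]) & (scores["Prey"] == pair[1])
        if (~scores.loc[mask_s, "significant"]).any():
            undetectable += 1
    n = len(detected)
    return {
        "detected": sorted(detected),
        "n_detected": n,
        "fraction_changed": changed / n,
        "fraction_undetectable": undetectable / n,
    }


def od_auc_relative_fitness(
    od_curves: pd.DataFrame,
    control_strain: str,
    saturation_time: float = 32.0,
    reference_condition: str = "DMSO",
) -> pd.DataFrame:
    """Relative fitness from isolated-growth optical-density curves.

    ``od_curves`` is long-form with columns ``strain, condition, time_h,
    od``.  The area under the curve is the sum of OD readings strictly
    before ``saturation_time``; relative fitness of a strain in a
    condition is (AUC_strain - AUC_control)_condition divided by the same
    difference in the reference condition.  Rows where the reference
    denominator is <= 0 are flagged undefined (NaN).
    """
    required = {"strain", "condition", "time_h", "od"}
    if not required <= set(od_curves.columns):
        raise ValueError(f"od_curves needs columns {sorted(required)}")
    pre = od_curves.loc[od_curves["time_h"] < saturation_time]
    auc = pre.groupby(["strain", "condition"])["od"].sum().unstack("condition")
    if control_strain not in auc.index:
        raise ValueError(f"control strain {control_strain!r} missing from OD table")
    if auc.loc[[control_strain]].isna().any().any():
        raise ValueError("control strain must be measured in every condition")
    diff = auc.subtract(auc.loc[control_strain], axis=1)
    denom = diff[reference_condition]
    rows = []
    for strain in auc.index:
        if strain == control_strain:
            continue
        for cond in auc.columns:
            d = denom.loc[strain]
            rows.append(
                {
                    "strain": strain,
                    "condition": cond,
                    "auc": float(auc.loc[strain, cond]),
                    "relative_fitness": float(diff.loc[strain, cond] / d) if d > 0 else np.nan,
                    "undefined": bool(d <= 0),
                }
            )
    return pd.DataFrame(rows)


def rluc_response(lum_condition: float, lum_dmso: float) -> tuple[float, float]:
    """Luminescence response ratio (condition / vehicle) and its log2.

    Both inputs must be positive reporter luminescence readings.
    """
    if lum_condition <= 0 or lum_dmso <= 0:
        raise ValueError("luminescence readings must be positive")
    ratio = float(lum_condition / lum_dmso)
    return ratio, float(np.log2(ratio))
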