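"""End-to-end orchestration: counts -> corrected counts -> fitness -> calls.

These helpers wire the per-module operations together over the flat
trajectory schema (see :mod:`ppiseq.io`) and back the command-line
interface, the simulation-based validation, and reproduction of the
published analysis from its per-trajectory count table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import chimera as _chimera
from . import fitness as _fitness
from . import io as _io
from . import ppi_call as _ppi
from . import simulate as _sim


def fit_trajectories(
    df: pd.DataFrame,
    corrected: bool = True,
    control_label: str = "ctrl",
    control_pairs: Sequence[str] | None = None,
    likelihood_threshold: float = _fitness.DEFAULT_LIKELIHOOD_THRESHOLD,
) -> pd.DataFrame:
    """Fit lineage fitnesses culture by culture and annotate the table.

    Each (Condition, Methotrexate_selection, Replicate) group is one
    growth culture fitted jointly; fitnesses are zeroed on the control
    lineages (``Bait == Prey == control_label``, or membership of
    ``PPI_pair`` in ``control_pairs``).  Adds ``Fitness``, ``Likelihood``
    and ``Trajectory_used`` columns.
    """
    cols = _io.reads_columns(df, corrected=corrected)
    if not cols:
        if corrected:
            cols = _io.reads_columns(df, corrected=False)
        if not cols:
            raise ValueError("no read-count columns found")
    gens = [int(c.split("_")[1]) for c in cols]
    out = df.copy()
    out["Fitness"] = np.nan
    out["Likelihood"] = np.nan
    out["Trajectory_used"] = False
    for _, idx in out.groupby(_io.CULTURE_COLUMNS, sort=False).indices.items():
        block = out.iloc[idx]
        counts = block[cols].to_numpy(dtype=float)
        fit = _fitness.infer_fitness(
            counts, gens, likelihood_threshold=likelihood_threshold
        )
        est = fit.estimates
        if control_pairs is not None:
            ctrl_mask = block["PPI_pair"].isin(set(control_pairs)).to_numpy()
        else:
            ctrl_mask = (
                (block["Bait"] == control_label) & (block["Prey"] == control_label)
            ).to_numpy()
        est = _fitness.normalize_to_reference(
            est.set_index(pd.RangeIndex(len(est))), np.flatnonzero(ctrl_mask)
        )
        out.iloc[idx, out.columns.get_loc("Fitness")] = est["fitness"].to_numpy()
        out.iloc[idx, out.columns.get_loc("Likelihood")] = est["log_likelihood"].to_numpy()
        out.iloc[idx, out.columns.get_loc("Trajectory_used")] = est["used"].to_numpy()
    return out


def validate_inference(
    config: _sim.SimConfig | None = None,
    seed: int = 0,
    chimera_rate: float | str = "config",
    used_only: bool = True,
) -> dict:
    """Simulate one culture, run the full pipeline, compare to truth.

    Returns the Pearson correlation between true and inferred fitness,
    the fitted table, and bookkeeping on the chimera correction.
    ``chimera_rate`` may be a float, ``"config"`` (use the simulator's
    true rate, as when the rate is known from a prior calibration) or
    ``"estimate"`` (estimate from off-target pairs; requires a sparse
    library).
    """
    config = config or _sim.default_experiment_config()
    result = _sim.simulate_pool(config, seed=seed)
    traj = _sim.to_trajectories(result)
    if chimera_rate == "config":
        rate = config.chimera_rate
    elif chimera_rate == "estimate":
        lib = result.library_table
        rate = _chimera.estimate_chimera_rate(
            result.reads_observed.sum(axis=1),
            lib["b1_idx"],
            lib["b2_idx"],
            result.off_target.rename(columns={"b1_idx": "barcode1", "b2_idx": "barcode2"}),
        )
    else:
        rate = float(chimera_rate)
    corrected = _chimera.correct_trajectories(traj, rate)
    fitted = fit_trajectories(corrected)
    truth = result.true_fitness
    inferred = fitted["Fitness"].to_numpy()
    mask = np.isfinite(inferred)
    if used_only:
        mask &= fitted["Trajectory_used"].to_numpy()
    r = float(_stats.pearsonr(truth[mask], inferred[mask]).statistic)
    raw_cols = _io.reads_columns(corrected, corrected=False)
    cor_cols = _io.reads_columns(corrected, corrected=True)
    subtracted = corrected[raw_cols].to_numpy().sum() - corrected[cor_cols].to_numpy().sum()
    return {
        "pearson_r": r,
        "n_lineages": int(len(truth)),
        "n_used": int(mask.sum()),
        "chimera_rate": float(rate),
        "subtracted_fraction": float(subtracted / corrected[raw_cols].to_numpy().sum()),
        "fitted": fitted,
        "truth": truth,
    }


def reproduce_reference_analysis(
    counts_path,
    chimera_rate: float = 0.002,
    blacklist: Sequence[str] = ("Prs3:Fpr1",),
    control_label: str = "ctrl",
    control_pairs: Sequence[str] | None = None,
    reference_condition: str = "DMSO",
    already_corrected: bool | None = None,
) -> dict:
    """Run the published analysis end to end from a per-trajectory table.

    ``counts_path`` must follow the flat trajectory schema (the published
    per-trajectory count table's columns).  Computes: replicate fitness
    concordance under selection, interaction calls in the permissive
    environment (after excluding ``blacklist`` pairs), dynamic-change
    summaries, specific pair fitnesses, the chimera-subtracted read
    fraction, and the s.e.m. profile of high-fitness pairs.
    """
    df = _io.read_trajectories(counts_path)
    has_corr = bool(_io.reads_columns(df, corrected=True))
    if already_corrected is None:
        already_corrected = has_corr
    if not already_corrected:
        df = _chimera.correct_trajectories(df, chimera_rate)
    raw = df[_io.reads_columns(df, corrected=False)].to_numpy().sum()
    cor = df[_io.reads_columns(df, corrected=True)].to_numpy().sum()
    fitted = fit_trajectories(
        df, control_label=control_label, control_pairs=control_pairs
    )

    # replicate concordance among used MTX(+) permissive trajectories
    mtx = fitted.loc[
        fitted["Methotrexate_selection"]
        & (fitted["Condition"] == reference_condition)
        & fitted["Trajectory_used"]
    ]
    wide = mtx.pivot_table(
        index="barcode_pair", columns="Replicate", values="Fitness"
    ).dropna()
    rs = []
    reps = list(wide.columns)
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            rs.append(float(_stats.pearsonr(wide[reps[i]], wide[reps[j]]).statistic))

    keep = ~fitted["PPI_pair"].isin(set(blacklist))
    scores = _ppi.score_ppis(fitted.loc[keep], control_label=control_label)
    permissive = scores.loc[
        (scores["Condition"] == reference_condition) & scores["Methotrexate_selection"]
    ]
    dynamic = _ppi.detect_dynamic(
        fitted.loc[keep], reference_condition=reference_condition,
        control_label=control_label,
    )
    summary = _ppi.dynamic_summary(
        scores.loc[scores["Methotrexate_selection"]], dynamic
    )

    def pair_fitness(name: str, condition: str) -> float:
        m = fitted.loc[
            (fitted["PPI_pair"] == name)
            & (fitted["Condition"] == condition)
            & fitted["Methotrexate_selection"]
            & fitted["Trajectory_used"],
            "Fitness",
        ]
        return float(m.mean()) if len(m) else np.nan

    high = permissive.loc[permissive["mean_fitness"] > 0.07, "sem"]
    return {
        "replicate_r": rs,
        "replicate_r_min": min(rs) if rs else np.nan,
        "n_significant_permissive": int(permissive["significant"].sum()),
        "significant_pairs": sorted(
            permissive.loc[permissive["significant"], "Bait"]
            + ":"
            + permissive.loc[permissive["significant"], "Prey"]
        ),
        "fraction_changed": summary["fraction_changed"],
        "fraction_undetectable": summary["fraction_undetectable"],
        "n_detected": summary["n_detected"],
        "subtracted_fraction": float((raw - cor) / raw) if raw else np.nan,
        "max_sem_high_fitness": float(high.max()) if len(high) else np.nan,
        "pair_fitness": pair_fitness,
        "scores": scores,
        "dynamic": dynamic,
        "fitted": fitted,
    }
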