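"""Beta-series functional connectivity between a hippocampal seed and
cortical targets, computed separately within hit and CR trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ROIMask
from .rsa import fisher_z
from .stats import TTestResult, bonferroni_threshold, mixed_anova, paired_t

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRIALS = 10
CONDITIONS = ("hit", "CR")
DEFAULT_TARGETS = ("ANG", "VLPFC", "DLPFC")


@dataclass
class BetaSeries:
    """Per-trial scalar series (spatial mean over an ROI) with outcomes."""

    values: np.ndarray
    outcomes: np.ndarray
    roi_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.outcomes = np.asarray(self.outcomes)
        if self.values.shape != self.outcomes.shape:
            raise ValueError("values and outcomes must align")

    def condition(self, outcome: str) -> np.ndarray:
        return self.values[self.outcomes == outcome]


def roi_beta_series(
    trial_betas: np.ndarray, roi: ROIMask, outcomes: np.ndarray
) -> BetaSeries:
    """Mean beta over ROI voxels per trial.

    Trials whose ROI voxels are all missing become NaN entries.
    """
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    B = np.asarray(trial_betas, float)[:, roi.flat_indices]
    with np.errstate(invalid="ignore"):
        values = np.nanmean(B, axis=1)
    all_missing = np.all(~np.isfinite(B), axis=1)
    values[all_missing] = np.nan
    if all_missing.any():
        logger.warning("%d trials with no finite ROI voxels", all_missing.sum())
    return BetaSeries(values=values, outcomes=np.asarray(outcomes), roi_name=roi.name)


def condition_connectivity(
    seed: BetaSeries,
    target: BetaSeries,
    outcome: str,
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> float:
    """Pearson r between seed and target series across one outcome's trials.

    Returns NaN (with a log record) below the minimum trial count.
    """
    a = seed.condition(outcome)
    b = target.condition(outcome)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < max(3, min_trials):
        logger.warning(
            "only %d usable %s trials (< %d); connectivity marked missing",
            a.size, outcome, max(3, min_trials),
        )
        return float("nan")
    if a.std() == 0 or b.std() == 0:
        logger.warning("constant beta series; connectivity marked missing")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def seed_to_voxel(
    seed: BetaSeries,
    trial_betas: np.ndarray,
    outcome: str,
    brain_mask: ROIMask,
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> np.ndarray:
    """Voxelwise Fisher-z map of seed-to-voxel beta-series correlation
    within one outcome; voxels outside the mask are NaN."""
    sel = seed.outcomes == outcome
    a = seed.values[sel]
    B = np.asarray(trial_betas, float)[sel][:, brain_mask.flat_indices]
    ok = np.isfinite(a)
    a, B = a[ok], B[ok]
    out = np.full(brain_mask.grid.n_voxels, np.nan)
    if a.size < max(3, min_trials):
        logger.warning("too few %s trials for seed-to-voxel map", outcome)
        return out
    ac = a - a.mean()
    Bc = B - B.mean(axis=0)
    denom = np.sqrt((ac**2).sum()) * np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Bc.T @ ac) / denom
    out[brain_mask.flat_indices] = fisher_z(np.clip(r, -1.0, 1.0))
    return out


def subject_connectivity(
    seed: BetaSeries,
    targets: dict[str, BetaSeries],
    subject: str = "",
    group: str = "",
    min_trials: int = DEFAULT_MIN_TRIALS,
) -> pd.DataFrame:
    """Tidy per-subject connectivity: one row per target x condition."""
    rows = []
    for name, series in targets.items():
        for cond in CONDITIONS:
            r = condition_connectivity(seed, series, cond, min_trials=min_trials)
            rows.append(
                {"subject": subject, "group": group, "target": name,
                 "condition": cond, "r": r,
                 "z": float(fisher_z(r)) if np.isfinite(r) else np.nan,
                 "n_trials": int((seed.outcomes == cond).sum())}
            )
    return pd.DataFrame(rows)


def connectivity_anova(
    results: pd.DataFrame,
    targets: tuple[str, ...] = DEFAULT_TARGETS,
    alpha: float = 0.05,
) -> dict:
    """Per-target Group x TrialType mixed ANOVA on Fisher-z connectivity,
    Bonferroni-corrected over targets, with per-group paired follow-ups.

    Subjects missing either condition for a target are dropped (logged).
    """
    threshold = bonferroni_threshold(alpha, len(targets))
    out: dict = {"alpha_adjusted": threshold, "targets": {}}
    for target in targets:
        sub = results[(results["target"] == target) & np.isfinite(results["z"])]
        counts = sub.groupby("subject")["condition"].nunique()
        complete = counts[counts == len(CONDITIONS)].index
        dropped = sorted(set(results.loc[results["target"] == target, "subject"])
                         - set(complete))
        if dropped:
            logger.warning("target %s: dropped subjects %s (missing condition)",
                           target, dropped)
        sub = sub[sub["subject"].isin(complete)]
        anova = mixed_anova(
            sub.rename(columns={"condition": "trial_type", "z": "value"}),
            dv="value", within="trial_type", subject="subject", between="group",
        )
        followups: dict[str, TTestResult] = {}
        for g in pd.unique(sub["group"]):
            wide = sub[sub["group"] == g].pivot(index="subject",
                                                columns="condition", values="z")
            followups[str(g)] = paired_t(wide["CR"].to_numpy(), wide["hit"].to_numpy())
        inter = anova.loc[anova["effect"] == "group * trial_type"].iloc[0]
        out["targets"][target] = {
            "anova": anova,
            "significant": bool(inter["p"] < threshold),
            "paired_cr_minus_hit": followups,
            "n_dropped": len(dropped),
        }
    return out
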