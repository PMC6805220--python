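"""Parameter-recovery and calibration harness.

Runs the full simulate -> analyze pipeline on in-memory cohorts at a
reduced grid (no file I/O, no smoothing, float32 volumes) so that
many-replicate power and type-I-error studies stay tractable on one CPU.
The analysis path is exactly :func:`dediff.pipeline.analyze_subject`.
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .pipeline import RunConfig, analyze_subject, group_statistics
from .simulate import GroupPreset, default_regions


def reduced_setup(grid_shape: tuple[int, int, int] = (12, 12, 10)):
    """Config, grid and regions for fast recovery replicates."""
    config = RunConfig(grid_shape=grid_shape, smoothing_fwhm=0.0)
    grid = config.grid()
    regions = default_regions(grid)
    return config, grid, regions


def simulate_and_analyze(
    seed: int,
    n_per_group: int = 20,
    presets: dict[str, GroupPreset] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """One replicate: simulate a cohort and return its group statistics."""
    if config is None:
        config, grid, regions = reduced_setup()
    else:
        grid = config.grid()
        regions = default_regions(grid)
    presets = presets or simulate.default_presets()
    seeds = np.random.SeedSequence(seed).spawn(len(presets) * n_per_group)
    results = []
    design_cache: dict = {}
    idx = 0
    for gname, preset in presets.items():
        for k in range(n_per_group):
            sid = f"sub-{idx + 1:02d}"
            sub = simulate.simulate_subject(
                sid, preset, grid=grid, regions=regions,
                seed=np.random.default_rng(seeds[idx]),
                tr=config.tr, n_volumes=config.n_volumes,
                n_pairs=config.n_pairs, n_lists=config.n_lists,
                version=k % 2, dtype=np.float32,
            )
            results.append(
                analyze_subject(
                    sub.study_runs, sub.test_runs,
                    sub.study_events, sub.test_events,
                    grid, regions, config=config, subject=sid, group=gname,
                    design_cache=design_cache,
                )
            )
            idx += 1
    return group_statistics(results, alpha=config.alpha)


def _paired(g: dict, roi: str, group: str):
    """Paired hit-minus-CR t for a univariate ROI."""
    return g["psc_anovas"][roi]["paired_hit_minus_cr"][group]


def effect_flags(g: dict, alpha: float = 0.05) -> dict[str, bool]:
    """Detection flags for each planted effect in one replicate.

    Directional effects are flagged when the relevant t has the planted sign
    and the (two-sided) p falls below ``alpha``; "young-only" effects
    additionally require the old group NOT to show the same significant
    direction.
    """
    groups = g["groups"]
    young = "young" if "young" in groups else groups[-1]
    old = "old" if "old" in groups else groups[0]

    levels = g["rsa_tidy"][g["rsa_tidy"]["measure"] == "level"]
    young_means = (
        levels[levels["group"] == young].groupby("name")["value"].mean()
    )
    ordering = bool(
        young_means["SE"] > young_means["SS"]
        > young_means["SC"] > young_means["DC"]
    )
    anova = g["rsa_stats"]["anova"]
    inter_p = float(anova.loc[anova["effect"] == "group * level", "p"].iloc[0])

    def hit_gt_cr(roi, grp):
        t = _paired(g, roi, grp)
        return t.t > 0 and t.p < alpha

    def cr_gt_hit(roi, grp):
        t = _paired(g, roi, grp)
        return t.t < 0 and t.p < alpha

    conn = g["connectivity_stats"]["targets"]["VLPFC"]["paired_cr_minus_hit"]
    conn_young = conn[young].t > 0 and conn[young].p < alpha
    conn_old = conn[old].t > 0 and conn[old].p < alpha

    return {
        "level_ordering": ordering,
        "rsa_interaction": inter_p < alpha,
        "hipp_hit_gt_cr": hit_gt_cr("HIPP", young) and hit_gt_cr("HIPP", old),
        "ang_hit_gt_cr": hit_gt_cr("ANG", young) and hit_gt_cr("ANG", old),
        "dlpfc_cr_gt_hit_young_only": cr_gt_hit("DLPFC", young)
        and not cr_gt_hit("DLPFC", old),
        "conn_vlpfc_cr_gt_hit_young_only": conn_young and not conn_old,
    }


def null_pvalues(g: dict) -> dict[str, float]:
    """P-values of contrasts that are null under a no-effect preset."""
    anova = g["rsa_stats"]["anova"]
    out = {
        "rsa_interaction": float(
            anova.loc[anova["effect"] == "group * level", "p"].iloc[0]
        )
    }
    for roi, d in g["psc_anovas"].items():
        a = d["anova"]
        out[f"psc_{roi}_trial_type"] = float(
            a.loc[a["effect"] == "trial_type", "p"].iloc[0]
        )
        out[f"psc_{roi}_interaction"] = float(
            a.loc[a["effect"] == "group * trial_type", "p"].iloc[0]
        )
    for target, d in g["connectivity_stats"]["targets"].items():
        a = d["anova"]
        out[f"conn_{target}_trial_type"] = float(
            a.loc[a["effect"] == "trial_type", "p"].iloc[0]
        )
        out[f"conn_{target}_interaction"] = float(
            a.loc[a["effect"] == "group * trial_type", "p"].iloc[0]
        )
    return out


def connectivity_differences(g: dict) -> np.ndarray:
    """Per-subject z(CR) - z(hit) for every target (null-calibration probe)."""
    conn = g["connectivity"]
    wide = conn.pivot_table(index=["subject", "target"], columns="condition",
                            values="z")
    return (wide["CR"] - wide["hit"]).to_numpy()
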