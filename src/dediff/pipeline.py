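"""End-to-end orchestration: simulate (or ingest) a dataset tree, run the
subject-level GLMs, build ROIs, compute RSA / univariate / connectivity
results, and write group statistics, tidy CSVs and figure-analog plots.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from . import connectivity as conn
from . import glm, rsa, simulate, stats
from .design import build_hierarchy, read_events_tsv
from .grid import ROIMask, VolumeGrid
from .roi import participant_seed

logger = logging.getLogger(__name__)

UNIVARIATE_ROIS = ("HIPP", "ANG", "DLPFC", "VLPFC")
CONNECTIVITY_TARGETS = ("ANG", "VLPFC", "DLPFC")


@dataclass
class RunConfig:
    """Single config that drives both simulation and analysis."""

    seed: int = 0
    n_per_group: int = 4
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: float = 3.0
    tr: float = simulate.TR_S
    n_volumes: int = simulate.N_VOLUMES
    n_pairs: int = 192
    n_lists: int = 3
    smoothing_fwhm: float = 8.0
    accuracy_filter: str = "all"
    whitening: str = "none"
    min_trials_per_condition: int = 10
    alpha: float = 0.05
    hp_cutoff_s: float = 128.0
    seed_radius_mm: float = 5.0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def grid(self) -> VolumeGrid:
        return VolumeGrid(shape=self.grid_shape, voxel_size=self.voxel_size)


def run_simulation(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort dataset tree under ``out_dir`` (wraps
    :func:`simulate.simulate_cohort`)."""
    grid = config.grid()
    return simulate.simulate_cohort(
        out_dir,
        n_per_group=config.n_per_group,
        seed=config.seed,
        grid=grid,
        regions=simulate.default_regions(grid),
        tr=config.tr,
        n_volumes=config.n_volumes,
        n_pairs=config.n_pairs,
        n_lists=config.n_lists,
    )


# --- subject-level analysis -------------------------------------------------

def _flatten_runs(runs: list[np.ndarray]) -> np.ndarray:
    """Stack 4D runs into one (total volumes, voxels) matrix."""
    return np.concatenate(
        [r.reshape(-1, r.shape[-1]).T for r in runs], axis=0
    )


def _lsa_design(events_by_run, n_volumes, tr, hp_cutoff_s, cache):
    """Single-trial design, memoized on timing structure when a cache dict
    is supplied (betas are consumed positionally, so identical onset
    lattices can share one design and its pseudoinverse)."""
    if cache is None:
        return glm.single_trial_design(events_by_run, n_volumes, tr,
                                       hp_cutoff_s=hp_cutoff_s)
    onsets = tuple(
        float(o) for ev in events_by_run for o in ev["onset"].round(3)
    )
    key = ("lsa", tuple(n_volumes), tr, hp_cutoff_s, onsets)
    if key not in cache:
        cache[key] = glm.single_trial_design(events_by_run, n_volumes, tr,
                                             hp_cutoff_s=hp_cutoff_s)
    return cache[key]


def analyze_subject(
    study_runs: list[np.ndarray],
    test_runs: list[np.ndarray],
    study_events: list[pd.DataFrame],
    test_events: list[pd.DataFrame],
    grid: VolumeGrid,
    regions: dict[str, ROIMask],
    config: RunConfig | None = None,
    subject: str = "",
    group: str = "",
    design_cache: dict | None = None,
) -> dict:
    """Full single-subject analysis on in-memory arrays.

    Study runs are modeled unsmoothed (single-trial LSA) for RSA over the
    VTC; test runs are smoothed and modeled twice: a hit/CR/other condition
    GLM for percent signal change, contrasts and the hippocampal seed, and a
    single-trial LSA for beta-series connectivity.
    """
    config = config or RunConfig()
    hierarchy = build_hierarchy()
    n_volumes = [r.shape[-1] for r in study_runs]

    # behavior
    behavior = stats.score_behavior(pd.concat(test_events, ignore_index=True))

    # encoding RSA on unsmoothed single-trial betas
    design_study = _lsa_design(study_events, n_volumes, config.tr,
                               config.hp_cutoff_s, design_cache)
    fit_study = glm.fit_glm(_flatten_runs(study_runs), design_study,
                            whitening=config.whitening)
    n_trials = int(design_study.interest.sum())
    study_betas = fit_study.betas[:n_trials]
    study_meta = pd.concat(study_events, ignore_index=True)
    sim_matrix = rsa.similarity_matrix(study_betas, regions["VTC"])
    sim_result = rsa.level_means(sim_matrix, study_meta, hierarchy,
                                 accuracy_filter=config.accuracy_filter)

    # retrieval: smoothed data, condition GLM
    smoothed = [
        glm.smooth_volumes(r, config.smoothing_fwhm, grid.voxel_size)
        for r in test_runs
    ]
    y_test = _flatten_runs(smoothed)
    nv_test = [r.shape[-1] for r in test_runs]
    design_cond = glm.condition_design_runs(
        test_events, nv_test, config.tr, hp_cutoff_s=config.hp_cutoff_s
    )
    fit_cond = glm.fit_glm(y_test, design_cond, whitening=config.whitening)
    psc_rows = []
    psc_maps = {c: glm.percent_signal_change(fit_cond, c)
                for c in ("hit", "CR") if c in fit_cond.names}
    for roi_name in UNIVARIATE_ROIS:
        idx = regions[roi_name].flat_indices
        for cond, pmap in psc_maps.items():
            psc_rows.append(
                {"subject": subject, "group": group, "roi": roi_name,
                 "condition": cond, "psc": float(np.nanmean(pmap[idx]))}
            )
    psc = pd.DataFrame(psc_rows)

    # participant-specific hippocampal seed from the hit > CR contrast
    contrast = glm.contrast_map(fit_cond, {"hit": 1.0, "CR": -1.0})
    seed_spec, seed_mask = participant_seed(
        contrast, regions["HIPP"], radius_mm=config.seed_radius_mm,
        subject=subject,
    )

    # beta-series connectivity on smoothed single-trial betas
    design_test = _lsa_design(test_events, nv_test, config.tr,
                              config.hp_cutoff_s, design_cache)
    fit_test = glm.fit_glm(y_test, design_test, whitening=config.whitening)
    n_test_trials = int(design_test.interest.sum())
    test_betas = fit_test.betas[:n_test_trials]
    test_meta = pd.concat(test_events, ignore_index=True)
    outcomes = test_meta["outcome"].to_numpy()
    seed_series = conn.roi_beta_series(test_betas, seed_mask, outcomes)
    targets = {
        name: conn.roi_beta_series(test_betas, regions[name], outcomes)
        for name in CONNECTIVITY_TARGETS
    }
    connectivity = conn.subject_connectivity(
        seed_series, targets, subject=subject, group=group,
        min_trials=config.min_trials_per_condition,
    )

    return {
        "subject": subject,
        "group": group,
        "behavior": behavior,
        "rsa": sim_result,
        "similarity_matrix": sim_matrix,
        "psc": psc,
        "seed": seed_spec,
        "connectivity": connectivity,
    }


# --- group-level analysis ---------------------------------------------------

def group_statistics(subject_results: list[dict], alpha: float = 0.05) -> dict:
    """All group-level tables from a list of per-subject analysis dicts."""
    groups = sorted({r["group"] for r in subject_results})

    behavior_rows = []
    for r in subject_results:
        b = r["behavior"]
        behavior_rows.append(
            {"subject": r["subject"], "group": r["group"], **b.counts,
             "p_hit": b.p_hit, "p_cr": b.p_cr, "p_fa": b.p_fa,
             "corrected_recognition": b.corrected_recognition}
        )
    behavior = pd.DataFrame(behavior_rows)
    behavior_tests = {}
    group_sizes = behavior.groupby("group")["subject"].nunique()
    if len(groups) == 2 and group_sizes.min() >= 2:
        a, b = groups
        for measure in ("hit", "CR"):
            va = behavior.loc[behavior["group"] == a, measure].to_numpy(float)
            vb = behavior.loc[behavior["group"] == b, measure].to_numpy(float)
            behavior_tests[measure] = stats.independent_t_from_data(va, vb)

    rsa_tidy = pd.concat(
        [r["rsa"].as_frame(r["subject"], r["group"]) for r in subject_results],
        ignore_index=True,
    )
    rsa_stats = rsa.group_rsa_stats(rsa_tidy)

    psc = pd.concat([r["psc"] for r in subject_results], ignore_index=True)
    psc_alpha = stats.bonferroni_threshold(alpha, len(UNIVARIATE_ROIS))
    psc_anovas = {}
    for roi_name in UNIVARIATE_ROIS:
        sub = psc[psc["roi"] == roi_name]
        anova = stats.mixed_anova(
            sub.rename(columns={"condition": "trial_type", "psc": "value"}),
            dv="value", within="trial_type", subject="subject", between="group",
        )
        followups = {}
        for g in groups:
            wide = sub[sub["group"] == g].pivot(index="subject",
                                                columns="condition", values="psc")
            followups[g] = stats.paired_t(wide["hit"].to_numpy(), wide["CR"].to_numpy())
        psc_anovas[roi_name] = {
            "anova": anova,
            "alpha_adjusted": psc_alpha,
            "paired_hit_minus_cr": followups,
        }

    connectivity = pd.concat([r["connectivity"] for r in subject_results],
                             ignore_index=True)
    conn_stats = conn.connectivity_anova(connectivity,
                                         targets=CONNECTIVITY_TARGETS, alpha=alpha)

    return {
        "groups": groups,
        "behavior": behavior,
        "behavior_tests": behavior_tests,
        "rsa_tidy": rsa_tidy,
        "rsa_stats": rsa_stats,
        "psc": psc,
        "psc_anovas": psc_anovas,
        "connectivity": connectivity,
        "connectivity_stats": conn_stats,
    }


# --- dataset tree I/O -------------------------------------------------------

def _load_subject_tree(tree: Path, sid: str, n_lists: int):
    func = tree / sid / "func"
    study_runs, test_runs, study_events, test_events = [], [], [], []
    for r in range(1, n_lists + 1):
        for task, runs, events in (
            ("study", study_runs, study_events),
            ("test", test_runs, test_events),
        ):
            img = nib.load(str(func / f"{sid}_task-{task}_run-{r}_bold.nii"))
            runs.append(np.asarray(img.dataobj, float))
            events.append(read_events_tsv(func / f"{sid}_task-{task}_run-{r}_events.tsv"))
    return study_runs, test_runs, study_events, test_events


def _load_masks(tree: Path, grid: VolumeGrid) -> dict[str, ROIMask]:
    masks = {}
    for path in sorted((tree / "masks").glob("*_mask.nii")):
        name = path.name.replace("_mask.nii", "")
        data = np.asarray(nib.load(str(path)).dataobj) > 0
        masks[name] = ROIMask(grid, data, name=name)
    return masks


def validate_dataset(tree: str | Path) -> dict:
    """Structural checks on a dataset tree; returns a report dict with
    ``passed`` and a list of named ``failures``."""
    tree = Path(tree)
    failures: list[str] = []
    if not (tree / "participants.tsv").exists():
        return {"passed": False, "failures": ["missing participants.tsv"]}
    participants = pd.read_csv(tree / "participants.tsv", sep="\t")
    truth = json.loads((tree / "truth.json").read_text()) if (tree / "truth.json").exists() else {}
    shape = tuple(truth.get("grid", {}).get("shape", ())) or None
    n_lists = int(truth.get("n_lists", 3))
    n_runs = 0
    for sid in participants["participant_id"]:
        func = tree / sid / "func"
        for task in ("study", "test"):
            run_files = sorted(func.glob(f"{sid}_task-{task}_run-*_bold.nii"))
            if len(run_files) != n_lists:
                failures.append(
                    f"{sid}: {len(run_files)} {task} runs != {n_lists}"
                )
            if not run_files:
                continue
            for bold in run_files:
                n_runs += 1
                img = nib.load(str(bold))
                if shape and img.shape[:3] != shape:
                    failures.append(f"{bold.name}: grid {img.shape[:3]} != {shape}")
                ev_path = Path(str(bold).replace("_bold.nii", "_events.tsv"))
                if not ev_path.exists():
                    failures.append(f"{sid}: missing {ev_path.name}")
                    continue
                ev = read_events_tsv(ev_path)
                if len(ev) != 64:
                    failures.append(f"{ev_path.name}: {len(ev)} trials != 64")
                if not np.all(np.diff(ev["onset"]) > 0):
                    failures.append(f"{ev_path.name}: onsets not increasing")
    if not (tree / "masks").exists() or not list((tree / "masks").glob("*_mask.nii")):
        failures.append("missing region masks")
    return {"passed": not failures, "failures": failures,
            "n_subjects": len(participants), "n_runs": n_runs}


def run_analysis(config: RunConfig, data_dir: str | Path,
                 out_dir: str | Path, make_plots: bool = True) -> Path:
    """Analyze a dataset tree and write the report directory.

    Per-subject failures are quarantined (logged, subject skipped); group
    statistics are computed over the survivors.
    """
    t0 = time.time()
    tree = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(tree / "participants.tsv", sep="\t")
    truth = json.loads((tree / "truth.json").read_text())
    grid = VolumeGrid(shape=tuple(truth["grid"]["shape"]),
                      voxel_size=truth["grid"]["voxel_size"])
    regions = _load_masks(tree, grid)

    results, quarantined = [], []
    for sid, group in zip(participants["participant_id"], participants["group"]):
        try:
            study_runs, test_runs, study_events, test_events = _load_subject_tree(
                tree, sid, config.n_lists
            )
            res = analyze_subject(
                study_runs, test_runs, study_events, test_events,
                grid, regions, config=config, subject=sid, group=str(group),
            )
            results.append(res)
            logger.info("analyzed %s (%.1fs elapsed)", sid, time.time() - t0)
        except Exception as exc:  # quarantine, keep going
            logger.exception("subject %s failed: %s", sid, exc)
            quarantined.append({"subject": sid, "error": repr(exc)})
    if not results:
        raise RuntimeError("no subject could be analyzed")

    g = group_statistics(results, alpha=config.alpha)

    g["behavior"].to_csv(out / "behavior.csv", index=False)
    g["rsa_tidy"].to_csv(out / "rsa_levels.csv", index=False)
    g["rsa_stats"]["anova"].to_csv(out / "rsa_anova.csv", index=False)
    diff_rows = [
        {"score": name, "group": grp, "t": res.t, "df": res.df, "p": res.p}
        for name, per_group in g["rsa_stats"]["difference_tests"].items()
        for grp, res in per_group.items()
    ]
    pd.DataFrame(diff_rows).to_csv(out / "rsa_difference_tests.csv", index=False)
    g["psc"].to_csv(out / "roi_psc.csv", index=False)
    pd.concat(
        [d["anova"].assign(roi=roi) for roi, d in g["psc_anovas"].items()],
        ignore_index=True,
    ).to_csv(out / "roi_anova.csv", index=False)
    g["connectivity"].to_csv(out / "connectivity.csv", index=False)
    pd.concat(
        [d["anova"].assign(target=t) for t, d in g["connectivity_stats"]["targets"].items()],
        ignore_index=True,
    ).to_csv(out / "connectivity_anova.csv", index=False)

    behavior_tests = {
        m: {"t": r.t, "df": r.df, "p": r.p, "cohen_d": r.cohen_d}
        for m, r in g["behavior_tests"].items()
    }
    provenance = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "dataset_seed": truth.get("seed"),
        "n_subjects_analyzed": len(results),
        "quarantined": quarantined,
        "behavior_tests": behavior_tests,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    if make_plots:
        _write_plots(g, out)
    logger.info("analysis complete in %.1fs", time.time() - t0)
    return out


def _write_plots(g: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = g["groups"]

    fig, ax = plt.subplots(figsize=(4, 3))
    means = g["behavior"].groupby("group")[["p_hit", "p_cr"]].mean()
    means.loc[groups].plot.bar(ax=ax, rot=0)
    ax.set_ylabel("proportion correct")
    fig.tight_layout()
    fig.savefig(out / "behavior.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    levels = g["rsa_tidy"][g["rsa_tidy"]["measure"] == "level"]
    for grp in groups:
        sub = levels[levels["group"] == grp].groupby("name")["value"].mean()
        ax.plot(["SE", "SS", "SC", "DC"], sub.loc[["SE", "SS", "SC", "DC"]],
                marker="o", label=grp)
    ax.set_ylabel("mean similarity (z)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "rsa_levels.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(UNIVARIATE_ROIS), figsize=(10, 3), sharey=True)
    for ax, roi_name in zip(np.atleast_1d(axes), UNIVARIATE_ROIS):
        sub = g["psc"][g["psc"]["roi"] == roi_name]
        piv = sub.groupby(["group", "condition"])["psc"].mean().unstack()
        piv.loc[groups].plot.bar(ax=ax, rot=0, legend=(roi_name == UNIVARIATE_ROIS[0]))
        ax.set_title(roi_name)
    axes[0].set_ylabel("percent signal change")
    fig.tight_layout()
    fig.savefig(out / "roi_psc.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(CONNECTIVITY_TARGETS), figsize=(8, 3), sharey=True)
    for ax, target in zip(np.atleast_1d(axes), CONNECTIVITY_TARGETS):
        sub = g["connectivity"][g["connectivity"]["target"] == target]
        piv = sub.groupby(["group", "condition"])["r"].mean().unstack()
        piv.loc[groups].plot.bar(ax=ax, rot=0, legend=(target == CONNECTIVITY_TARGETS[0]))
        ax.set_title(f"HIPP-{target}")
    axes[0].set_ylabel("connectivity (r)")
    fig.tight_layout()
    fig.savefig(out / "connectivity.png", dpi=120)
    plt.close(fig)
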