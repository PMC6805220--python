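"""Synthetic multi-subject BOLD generator with planted effects.

Each trial contributes a spatial amplitude map convolved with the canonical
HRF: condition-dependent mean amplitudes per region, a hierarchical voxel
pattern inside the pattern region (shared baseline + category + subcategory
+ exemplar components + trial noise), and, at test, a per-trial latent
shared by the seed and target regions that plants beta-series connectivity.
AR(1) noise, slow cosine drift (inside the high-pass span, so filtering
removes it exactly) and a constant baseline are added on top.

Group presets ("young", "old") plant the qualitative effect structure the
analyses are meant to recover: graded pattern similarity SE > SS > SC > DC
that flattens at the fine-grained levels for the old preset, hit > CR
activation in HIPP/ANG for both groups, a CR > hit DLPFC effect and CR > hit
hippocampal-VLPFC coupling for the young preset only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import design as dsg
from .design import StimulusHierarchy, build_hierarchy
from .glm import highpass_basis, trial_regressor_matrix
from .grid import ROIMask, VolumeGrid
from .roi import sphere_roi

TR_S = 2.0
N_VOLUMES = 205  # 210 acquired minus 5 dummy volumes


# --- models -----------------------------------------------------------------

@dataclass(frozen=True)
class PatternModel:
    """Weights of the hierarchical voxel-pattern components."""

    w_base: float = 0.3
    w_cat: float = 0.8
    w_sub: float = 0.6
    w_ex: float = 0.5
    w_trial: float = 0.7
    region: str = "VTC"

    def __post_init__(self):
        if min(self.w_base, self.w_cat, self.w_sub, self.w_ex, self.w_trial) < 0:
            raise ValueError("pattern weights must be non-negative")


@dataclass(frozen=True)
class ActivationModel:
    """Mean trial amplitude per (region, phase, outcome).

    ``amplitudes[region][phase]`` maps an outcome (or ``"*"`` wildcard) to a
    mean amplitude in baseline-percent units.  Regions with an entry for a
    phase also receive independent per-trial amplitude jitter of SD
    ``trial_noise_sd``.
    """

    amplitudes: dict = field(default_factory=dict)
    trial_noise_sd: float = 0.4

    def amplitude(self, region: str, phase: str, outcome: str) -> float | None:
        """Mean amplitude, or None when the region is silent in this phase."""
        table = self.amplitudes.get(region, {}).get(phase)
        if table is None:
            return None
        if outcome in table:
            return float(table[outcome])
        if "*" in table:
            return float(table["*"])
        return 0.0


@dataclass(frozen=True)
class ConnectivityModel:
    """Trial-latent coupling between a seed region and target regions.

    A per-trial standard-normal latent is added to the seed region (scaled
    by ``seed_scale``) and to each target region scaled by the
    condition-dependent coupling ``kappa[target][outcome]``.
    """

    seed: str = "HIPP"
    kappa: dict = field(default_factory=dict)  # target -> outcome -> coupling
    seed_scale: float = 1.0
    phase: str = "test"

    def coupling(self, target: str, outcome: str) -> float:
        k = float(self.kappa.get(target, {}).get(outcome, 0.0))
        if k < 0:
            raise ValueError("coupling must be non-negative")
        return k


@dataclass(frozen=True)
class NoiseModel:
    """Scanner-noise stand-in: white + AR(1), cosine drift, flat baseline."""

    sd: float = 1.0
    ar1_rho: float = 0.2
    drift_amplitude: float = 1.0
    n_drift: int = 3
    baseline: float = 100.0

    def __post_init__(self):
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|AR(1) coefficient| must be < 1")
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class GroupPreset:
    """Everything group-dependent: geometry, activation, coupling, behavior."""

    name: str
    pattern: PatternModel
    activation: ActivationModel
    connectivity: ConnectivityModel
    noise: NoiseModel
    p_hit: float
    p_cr: float
    p_no_response: float = 0.0


# Behavioral rates: mean trial counts out of 96 intact / 96 recombined pairs
YOUNG_HITS, YOUNG_CRS = 85.05, 89.60
OLD_HITS, OLD_CRS = 71.90, 72.0
N_TEST_PER_STATUS = 96


def _retrieval_activation(dlpfc_hit: float, dlpfc_cr: float) -> dict:
    return {
        "VTC": {"study": {"*": 1.0}},
        "HIPP": {"test": {"hit": 1.2, "CR": 0.4}},
        "ANG": {"test": {"hit": 1.2, "CR": 0.5}},
        "DLPFC": {"test": {"hit": dlpfc_hit, "CR": dlpfc_cr}},
        "VLPFC": {"test": {"hit": 0.7, "CR": 0.9}},
    }


def young_preset() -> GroupPreset:
    return GroupPreset(
        name="young",
        pattern=PatternModel(w_base=0.3, w_cat=0.8, w_sub=0.6, w_ex=0.5, w_trial=0.7),
        activation=ActivationModel(_retrieval_activation(dlpfc_hit=0.4, dlpfc_cr=1.2)),
        connectivity=ConnectivityModel(
            seed="HIPP",
            kappa={"VLPFC": {"hit": 0.15, "CR": 0.9},
                   "DLPFC": {"hit": 0.3, "CR": 0.55},
                   "ANG": {"hit": 0.4, "CR": 0.4}},
        ),
        noise=NoiseModel(),
        p_hit=YOUNG_HITS / N_TEST_PER_STATUS,
        p_cr=YOUNG_CRS / N_TEST_PER_STATUS,
    )


def old_preset() -> GroupPreset:
    # dedifferentiation: weaker exemplar/subcategory components, stronger
    # shared baseline; no DLPFC CR>hit effect; flat seed-target coupling
    return GroupPreset(
        name="old",
        pattern=PatternModel(w_base=0.55, w_cat=0.45, w_sub=0.25, w_ex=0.1, w_trial=0.7),
        activation=ActivationModel(_retrieval_activation(dlpfc_hit=0.8, dlpfc_cr=0.65)),
        connectivity=ConnectivityModel(
            seed="HIPP",
            kappa={"VLPFC": {"hit": 0.45, "CR": 0.45},
                   "DLPFC": {"hit": 0.55, "CR": 0.55},
                   "ANG": {"hit": 0.55, "CR": 0.55}},
        ),
        noise=NoiseModel(),
        p_hit=OLD_HITS / N_TEST_PER_STATUS,
        p_cr=OLD_CRS / N_TEST_PER_STATUS,
    )


def null_preset(name: str = "null") -> GroupPreset:
    """No condition or group effects anywhere; used for calibration."""
    return GroupPreset(
        name=name,
        pattern=PatternModel(w_base=0.5, w_cat=0.5, w_sub=0.5, w_ex=0.5, w_trial=0.7),
        activation=ActivationModel(
            {
                "VTC": {"study": {"*": 1.0}},
                "HIPP": {"test": {"*": 0.8}},
                "ANG": {"test": {"*": 0.8}},
                "DLPFC": {"test": {"*": 0.8}},
                "VLPFC": {"test": {"*": 0.8}},
            }
        ),
        connectivity=ConnectivityModel(seed="HIPP", kappa={}),
        noise=NoiseModel(),
        p_hit=0.8,
        p_cr=0.8,
    )


def default_presets() -> dict[str, GroupPreset]:
    return {"young": young_preset(), "old": old_preset()}


# --- geometry ---------------------------------------------------------------

def default_grid(shape: tuple[int, int, int] = (16, 16, 12),
                 voxel_size: float = 3.0) -> VolumeGrid:
    """Modest 3 mm isotropic grid used by the simulator."""
    return VolumeGrid(shape=shape, voxel_size=voxel_size)


#: toy region centres as fractions of the grid extent, with radii in mm
DEFAULT_REGION_LAYOUT: dict[str, tuple[tuple[float, float, float], float]] = {
    "VTC": ((0.27, 0.27, 0.5), 8.4),
    "HIPP": ((0.72, 0.27, 0.5), 6.0),
    "ANG": ((0.27, 0.72, 0.5), 5.0),
    "DLPFC": ((0.72, 0.72, 0.25), 5.0),
    "VLPFC": ((0.72, 0.72, 0.78), 5.0),
}


def default_regions(grid: VolumeGrid,
                    layout: dict | None = None) -> dict[str, ROIMask]:
    """Disjoint toy spheres standing in for the analysis regions."""
    layout = DEFAULT_REGION_LAYOUT if layout is None else layout
    regions = {}
    shape = np.asarray(grid.shape)
    for name, (frac, radius) in layout.items():
        vox = np.rint(np.asarray(frac) * (shape - 1)).astype(int)
        center = grid.voxel_to_mm(vox)[0]
        regions[name] = sphere_roi(center, radius, grid, name=name)
    return regions


# --- pattern components -----------------------------------------------------

@dataclass
class PatternComponents:
    """Subject-specific standardized component maps over the pattern region."""

    base: np.ndarray
    cat: dict[str, np.ndarray]
    sub: dict[str, np.ndarray]
    ex: dict[str, np.ndarray]


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    s = v.std()
    if s == 0:
        raise ValueError("cannot standardize a constant component")
    return v / s


def sample_pattern_components(
    n_voxels: int, hierarchy: StimulusHierarchy, rng: np.random.Generator
) -> PatternComponents:
    """Draw subject-unique component maps (standard normal, standardized)."""
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels for pattern components")
    draw = lambda: _standardize(rng.standard_normal(n_voxels))
    cats = sorted(set(hierarchy.category_of.values()))
    subs = sorted(set(hierarchy.subcategory_of.values()))
    return PatternComponents(
        base=draw(),
        cat={c: draw() for c in cats},
        sub={s: draw() for s in subs},
        ex={e: draw() for e in hierarchy.exemplars},
    )


def trial_patterns(
    events: pd.DataFrame,
    components: PatternComponents,
    model: PatternModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_trials, n_voxels) planted patterns for one run's events."""
    n_vox = components.base.size
    out = np.empty((len(events), n_vox))
    fixed = model.w_base * components.base
    for i, (stim, sub, cat) in enumerate(
        zip(events["stimulus"], events["subcategory"], events["category"])
    ):
        out[i] = (
            fixed
            + model.w_cat * components.cat[cat]
            + model.w_sub * components.sub[sub]
            + model.w_ex * components.ex[stim]
            + model.w_trial * rng.standard_normal(n_vox)
        )
    return out


def expected_similarity(model: PatternModel) -> dict[str, float]:
    """Closed-form expected Pearson r of trial patterns at each level.

    Shared-component variance over total variance; mismatched levels drop
    their components from the numerator.
    """
    b2, c2 = model.w_base**2, model.w_cat**2
    s2, e2 = model.w_sub**2, model.w_ex**2
    t2 = model.w_trial**2
    den = b2 + c2 + s2 + e2 + t2
    if den == 0:
        raise ValueError("all pattern weights are zero; correlation undefined")
    return {
        "SE": (b2 + c2 + s2 + e2) / den,
        "SS": (b2 + c2 + s2) / den,
        "SC": (b2 + c2) / den,
        "DC": b2 / den,
    }


# --- run / subject / cohort simulation --------------------------------------

def simulate_run(
    events: pd.DataFrame,
    grid: VolumeGrid,
    regions: dict[str, ROIMask],
    pattern_model: PatternModel | None = None,
    activation_model: ActivationModel | None = None,
    connectivity_model: ConnectivityModel | None = None,
    noise_model: NoiseModel | None = None,
    tr: float = TR_S,
    n_volumes: int = N_VOLUMES,
    seed: int | np.random.Generator = 0,
    pattern_components: PatternComponents | None = None,
    return_truth: bool = False,
    dtype=np.float64,
):
    """Simulate one run as a 4D (x, y, z, t) array.

    Per-trial spatial amplitude maps are assembled from the activation,
    pattern and connectivity models, convolved with the canonical HRF and
    summed; baseline, drift and AR(1) noise are added.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise_model = noise_model or NoiseModel()
    phase = str(events["trial_type"].iloc[0])
    run_len = n_volumes * tr
    ends = events["onset"].to_numpy(float) + events["duration"].to_numpy(float)
    if np.any(ends > run_len):
        raise ValueError("events exceed the run length")
    n_trials = len(events)
    n_vox = grid.n_voxels
    outcomes = events["outcome"].astype(str).to_numpy()

    S = np.zeros((n_trials, n_vox))
    truth: dict = {"phase": phase}
    if activation_model is not None:
        for rname, mask in regions.items():
            amps = [activation_model.amplitude(rname, phase, o) for o in outcomes]
            if all(a is None for a in amps):
                continue
            series = np.array([0.0 if a is None else a for a in amps])
            series = series + activation_model.trial_noise_sd * rng.standard_normal(n_trials)
            S[:, mask.flat_indices] += series[:, None]
            truth.setdefault("amplitudes", {})[rname] = series
    if pattern_model is not None and phase == "study":
        mask = regions[pattern_model.region]
        if pattern_components is None:
            pattern_components = sample_pattern_components(
                mask.n_voxels, build_hierarchy(), rng
            )
        pats = trial_patterns(events, pattern_components, pattern_model, rng)
        S[:, mask.flat_indices] += pats
        truth["patterns"] = pats
    if connectivity_model is not None and phase == connectivity_model.phase:
        xi = rng.standard_normal(n_trials)
        S[:, regions[connectivity_model.seed].flat_indices] += (
            connectivity_model.seed_scale * xi[:, None]
        )
        for target in connectivity_model.kappa:
            k = np.array([connectivity_model.coupling(target, o) for o in outcomes])
            S[:, regions[target].flat_indices] += (k * xi)[:, None]
        truth["latent"] = xi

    R = trial_regressor_matrix(events["onset"].to_numpy(float), n_volumes, tr)
    Y = R @ S
    Y += noise_model.baseline
    if noise_model.n_drift > 0 and noise_model.drift_amplitude > 0:
        basis = highpass_basis(n_volumes, tr)[:, : noise_model.n_drift]
        if basis.shape[1]:
            coef = noise_model.drift_amplitude * rng.standard_normal((basis.shape[1], n_vox))
            Y += basis @ coef
    if noise_model.sd > 0:
        innov_sd = noise_model.sd * np.sqrt(1.0 - noise_model.ar1_rho**2)
        white = innov_sd * rng.standard_normal((n_volumes, n_vox))
        Y += lfilter([1.0], [1.0, -noise_model.ar1_rho], white, axis=0)

    data = np.ascontiguousarray(Y.T).reshape(grid.shape + (n_volumes,)).astype(dtype, copy=False)
    if return_truth:
        truth["trial_maps"] = S
        return data, truth
    return data


@dataclass
class SubjectData:
    """In-memory simulated subject: runs, events, and planted ground truth."""

    subject: str
    group: str
    study_runs: list[np.ndarray]
    test_runs: list[np.ndarray]
    study_events: list[pd.DataFrame]
    test_events: list[pd.DataFrame]
    truth: dict


def _draw_behavior(
    test_events: pd.DataFrame, preset: GroupPreset, rng: np.random.Generator
) -> pd.DataFrame:
    ev = test_events.copy()
    responses, outcomes = [], []
    for status in ev["status"]:
        if preset.p_no_response > 0 and rng.random() < preset.p_no_response:
            responses.append("none")
            outcomes.append("no-response")
            continue
        if status == "intact":
            correct = rng.random() < preset.p_hit
            responses.append("old" if correct else "new")
            outcomes.append("hit" if correct else "miss")
        else:
            correct = rng.random() < preset.p_cr
            responses.append("new" if correct else "old")
            outcomes.append("CR" if correct else "FA")
    ev["response"] = responses
    ev["outcome"] = outcomes
    return ev


def simulate_subject(
    subject: str,
    preset: GroupPreset,
    grid: VolumeGrid | None = None,
    regions: dict[str, ROIMask] | None = None,
    hierarchy: StimulusHierarchy | None = None,
    seed: int | np.random.Generator = 0,
    tr: float = TR_S,
    n_volumes: int = N_VOLUMES,
    n_pairs: int = 192,
    n_lists: int = 3,
    version: int = 0,
    dtype=np.float64,
) -> SubjectData:
    """Simulate one subject: design, behavior, and all study + test runs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = grid or default_grid()
    regions = regions or default_regions(grid)
    hierarchy = hierarchy or build_hierarchy()
    lists = dsg.make_lists(hierarchy, n_pairs=n_pairs, n_lists=n_lists,
                           seed=rng, version=version)
    components = sample_pattern_components(
        regions[preset.pattern.region].n_voxels, hierarchy, rng
    )

    study_events, test_events = [], []
    outcome_by_adjective: dict[str, str] = {}
    for run_idx, pairs in enumerate(lists, start=1):
        study_order = dsg.sequence_trials(pairs, "study", hierarchy, seed=rng)
        sev = dsg.make_run_events(study_order, "study", run_idx, hierarchy)
        sev["response"] = "1"
        study_events.append(sev)
        test_order = dsg.sequence_trials(pairs, "test", hierarchy, seed=rng)
        tev = dsg.make_run_events(test_order, "test", run_idx, hierarchy)
        tev = _draw_behavior(tev, preset, rng)
        outcome_by_adjective.update(zip(tev["adjective"], tev["outcome"]))
        test_events.append(tev)
    for sev in study_events:
        sev["outcome"] = sev["adjective"].map(outcome_by_adjective)
        sev["subsequent_correct"] = sev["outcome"].isin(["hit", "CR"])

    study_runs = [
        simulate_run(
            ev, grid, regions,
            pattern_model=preset.pattern,
            activation_model=preset.activation,
            noise_model=preset.noise,
            tr=tr, n_volumes=n_volumes, seed=rng,
            pattern_components=components, dtype=dtype,
        )
        for ev in study_events
    ]
    test_runs = [
        simulate_run(
            ev, grid, regions,
            activation_model=preset.activation,
            connectivity_model=preset.connectivity,
            noise_model=preset.noise,
            tr=tr, n_volumes=n_volumes, seed=rng, dtype=dtype,
        )
        for ev in test_events
    ]
    truth = {
        "preset": preset.name,
        "expected_similarity": expected_similarity(preset.pattern),
        "pattern_model": dataclasses.asdict(preset.pattern),
        "p_hit": preset.p_hit,
        "p_cr": preset.p_cr,
    }
    return SubjectData(
        subject=subject, group=preset.name,
        study_runs=study_runs, test_runs=test_runs,
        study_events=study_events, test_events=test_events,
        truth=truth,
    )


def _write_nifti(data: np.ndarray, grid: VolumeGrid, path: Path,
                 tr: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, np.float32), grid.affine)
    if tr is not None and data.ndim == 4:
        img.header.set_zooms((grid.voxel_size,) * 3 + (tr,))
    nib.save(img, str(path))


def simulate_cohort(
    out_dir: str | Path,
    n_per_group: int = 20,
    seed: int = 0,
    presets: dict[str, GroupPreset] | None = None,
    grid: VolumeGrid | None = None,
    regions: dict[str, ROIMask] | None = None,
    tr: float = TR_S,
    n_volumes: int = N_VOLUMES,
    n_pairs: int = 192,
    n_lists: int = 3,
) -> Path:
    """Simulate a full cohort and write a BIDS-like dataset tree.

    Layout: ``participants.tsv``, ``masks/<region>_mask.nii``,
    ``truth.json``, and per subject ``sub-XX/func/
    sub-XX_task-{study,test}_run-{r}_{bold.nii,events.tsv}``.
    Counterbalance versions alternate across subjects within each group.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = presets or default_presets()
    grid = grid or default_grid()
    regions = regions or default_regions(grid)
    hierarchy = build_hierarchy()

    (out / "masks").mkdir(exist_ok=True)
    for name, mask in regions.items():
        _write_nifti(mask.data.astype(np.uint8), grid, out / "masks" / f"{name}_mask.nii")

    seeds = np.random.SeedSequence(seed).spawn(len(presets) * n_per_group)
    participants = []
    truth: dict = {
        "seed": seed, "tr": tr, "n_volumes": n_volumes,
        "n_lists": n_lists, "n_pairs": n_pairs,
        "grid": {"shape": list(grid.shape), "voxel_size": grid.voxel_size},
        "groups": {
            name: {
                "pattern_model": dataclasses.asdict(p.pattern),
                "expected_similarity": expected_similarity(p.pattern),
                "activation": p.activation.amplitudes,
                "trial_noise_sd": p.activation.trial_noise_sd,
                "kappa": p.connectivity.kappa,
                "noise": dataclasses.asdict(p.noise),
                "p_hit": p.p_hit, "p_cr": p.p_cr,
            }
            for name, p in presets.items()
        },
        "subjects": {},
    }
    idx = 0
    for gname, preset in presets.items():
        for k in range(n_per_group):
            sid = f"sub-{idx + 1:02d}"
            sub_seed = seeds[idx]
            data = simulate_subject(
                sid, preset, grid=grid, regions=regions, hierarchy=hierarchy,
                seed=np.random.default_rng(sub_seed), tr=tr, n_volumes=n_volumes,
                n_pairs=n_pairs, n_lists=n_lists, version=k % 2,
            )
            func = out / sid / "func"
            func.mkdir(parents=True, exist_ok=True)
            for r, (vol, ev) in enumerate(zip(data.study_runs, data.study_events), 1):
                _write_nifti(vol, grid, func / f"{sid}_task-study_run-{r}_bold.nii", tr)
                dsg.write_events_tsv(ev, func / f"{sid}_task-study_run-{r}_events.tsv")
            for r, (vol, ev) in enumerate(zip(data.test_runs, data.test_events), 1):
                _write_nifti(vol, grid, func / f"{sid}_task-test_run-{r}_bold.nii", tr)
                dsg.write_events_tsv(ev, func / f"{sid}_task-test_run-{r}_events.tsv")
            participants.append({"participant_id": sid, "group": gname})
            truth["subjects"][sid] = {
                "group": gname,
                "seed_entropy": int(sub_seed.entropy),
                "spawn_key": [int(v) for v in sub_seed.spawn_key],
                "counterbalance_version": k % 2,
            }
            idx += 1
    pd.DataFrame(participants).to_csv(out / "participants.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
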