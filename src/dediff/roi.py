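"""ROI construction: mm-radius spheres on the voxel grid, the
localizer-defined category-selective cortex, and participant-specific
peak-centred seed spheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .grid import ROIMask, VolumeGrid

#: default cortical ROI table: name -> (centre mm, radius mm)
DEFAULT_ROI_TABLE: dict[str, tuple[tuple[float, float, float], float]] = {
    "DLPFC": ((-47.0, 17.0, 24.0), 10.0),
    "VLPFC": ((-45.0, 35.0, -4.0), 10.0),
    "ANG": ((-45.0, -69.0, -6.0), 10.0),
}

SEED_RADIUS_MM = 5.0


def sphere_roi(
    center_mm,
    radius_mm: float,
    grid: VolumeGrid,
    name: str = "sphere",
) -> ROIMask:
    """Spherical ROI by voxel-centre distance.

    The centre snaps to the centre of the voxel containing ``center_mm``; a
    voxel belongs to the mask iff its centre lies within ``radius_mm`` of
    that voxel's centre (so a 5 mm radius on a 3 mm grid gives 19 voxels).
    """
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if not grid.contains_mm(center_mm):
        raise ValueError(f"centre {center_mm} outside grid bounds")
    cvox = grid.mm_to_voxel(center_mm)[0]
    cmm = grid.voxel_to_mm(cvox)[0]
    centers = grid.voxel_centers_mm()
    dist2 = ((centers - cmm) ** 2).sum(axis=1)
    mask = (dist2 <= radius_mm**2 + 1e-9).reshape(grid.shape)
    if not mask.any():  # pragma: no cover - centre voxel always included
        raise ValueError("empty sphere mask")
    return ROIMask(
        grid, mask, name=name,
        provenance={"kind": "sphere", "center_mm": tuple(float(v) for v in cmm),
                    "radius_mm": float(radius_mm)},
    )


def default_roi_masks(grid: VolumeGrid,
                      table: dict | None = None) -> dict[str, ROIMask]:
    """Materialize a name -> (centre, radius) table as sphere masks."""
    table = DEFAULT_ROI_TABLE if table is None else table
    return {
        name: sphere_roi(center, radius, grid, name=name)
        for name, (center, radius) in table.items()
    }


def localizer_vtc(
    object_maps: np.ndarray,
    scene_maps: np.ndarray,
    anatomical_mask: ROIMask,
    alpha: float = 0.05,
) -> ROIMask:
    """Category-selective cortex from per-subject localizer contrast maps.

    ``object_maps`` / ``scene_maps`` are (n_subjects, n_voxels) flat maps on
    the grid (subjects pooled over groups).  A voxelwise paired contrast
    (one-sample t on object - scene) is thresholded at ``alpha`` Bonferroni
    corrected over in-mask voxels, in both directions; the union of the two
    suprathreshold sets intersected with the anatomical mask is returned.
    ``alpha >= 1`` degenerates to no thresholding (entire anatomical mask).
    """
    obj = np.asarray(object_maps, float)
    scn = np.asarray(scene_maps, float)
    if obj.shape != scn.shape or obj.ndim != 2:
        raise ValueError("need matching (n_subjects, n_voxels) map stacks")
    n_subj = obj.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    in_mask = anatomical_mask.flat_indices
    d = obj[:, in_mask] - scn[:, in_mask]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n_subj))
    t[sd == 0] = 0.0
    if alpha >= 1.0:
        supra = np.ones_like(t, bool)
    else:
        m = in_mask.size
        t_crit = sps.t.isf(alpha / m, n_subj - 1)  # one-sided per direction
        supra = (t > t_crit) | (t < -t_crit)
    if not supra.any():
        raise ValueError(
            f"no suprathreshold localizer voxels (max |t| = {np.nanmax(np.abs(t)):.3f})"
        )
    mask = np.zeros(anatomical_mask.grid.n_voxels, bool)
    mask[in_mask[supra]] = True
    return ROIMask(
        anatomical_mask.grid, mask.reshape(anatomical_mask.grid.shape), name="VTC",
        provenance={"kind": "localizer", "alpha": float(alpha), "n_subjects": n_subj},
    )


@dataclass
class SeedSpec:
    """Participant-specific seed definition."""

    subject: str
    peak_mm: tuple[float, float, float]
    radius_mm: float
    contrast: str
    search_mask: str


def participant_seed(
    contrast_map: np.ndarray,
    search_mask: ROIMask,
    radius_mm: float = SEED_RADIUS_MM,
    subject: str = "",
    contrast: str = "hit>CR",
) -> tuple[SeedSpec, ROIMask]:
    """Seed sphere centred on the peak contrast voxel inside a search mask.

    Ties are broken toward the smallest voxel index with a warning; the
    sphere is not clipped to the search mask.
    """
    grid = search_mask.grid
    values = np.asarray(contrast_map, float).ravel()
    if values.size != grid.n_voxels:
        raise ValueError("contrast map does not match the grid")
    idx = search_mask.flat_indices
    vals = values[idx]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("contrast map is all-NaN within the search mask")
    vmax = np.nanmax(vals)
    winners = idx[finite & (vals == vmax)]
    if winners.size > 1:
        warnings.warn(
            f"{winners.size} tied peak voxels in {search_mask.name or 'search mask'}; "
            "choosing the smallest voxel index"
        )
    peak_flat = int(winners.min())
    peak_vox = np.unravel_index(peak_flat, grid.shape)
    peak_mm = tuple(float(v) for v in grid.voxel_to_mm(np.array(peak_vox))[0])
    mask = sphere_roi(peak_mm, radius_mm, grid, name=f"seed-{subject}" if subject else "seed")
    mask.provenance.update({"contrast": contrast, "search_mask": search_mask.name})
    spec = SeedSpec(
        subject=subject, peak_mm=peak_mm, radius_mm=float(radius_mm),
        contrast=contrast, search_mask=search_mask.name,
    )
    return spec, mask


def permutation_max_t_threshold(
    diffs: np.ndarray, alpha: float = 0.05, n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Sign-flip permutation max-|t| threshold for one-sample voxelwise maps.

    Alternative to Bonferroni for family-wise error control; returns the
    (1 - alpha) quantile of the permutation distribution of the maximum
    absolute t statistic over voxels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(diffs, float)
    n = d.shape[0]
    maxes = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None]
        flipped = d * signs
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = flipped.mean(axis=0) / (sd / np.sqrt(n))
        maxes[i] = np.nanmax(np.abs(t))
    return float(np.quantile(maxes, 1.0 - alpha))
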