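"""Encoding-phase pattern similarity and distinctiveness scores.

Single-trial betas over an ROI are correlated across trials (Pearson),
Fisher-transformed, and averaged per relatedness level over across-run
trial pairs only.  Difference scores between successive levels (SE-SS,
SS-SC, SC-DC) quantify exemplar, subcategory and category distinctiveness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import RELATEDNESS_LEVELS, StimulusHierarchy, relatedness_level
from .grid import ROIMask
from .stats import TTestResult, independent_t_from_data, mixed_anova, one_sample_t

logger = logging.getLogger(__name__)

DIFFERENCE_SCORES = {"exemplar": ("SE", "SS"), "subcategory": ("SS", "SC"),
                     "category": ("SC", "DC")}

CLIP = 1.0 - 1e-7


def similarity_matrix(trial_betas: np.ndarray, roi: ROIMask | None = None) -> np.ndarray:
    """Trial-by-trial Pearson correlation matrix over ROI voxels.

    ``trial_betas`` is (n_trials, n_voxels) if ``roi`` is None, otherwise
    (n_trials, grid voxels) and the ROI columns are selected first.
    Zero-variance trial patterns yield NaN rows/columns (logged).
    """
    B = np.asarray(trial_betas, float)
    if roi is not None:
        B = B[:, roi.flat_indices]
    if B.ndim != 2 or B.shape[1] < 2:
        raise ValueError("need a (n_trials, >=2 voxels) beta array")
    Z = B - B.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    bad = sd == 0
    if bad.any():
        logger.warning("%d zero-variance trial patterns marked missing", bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = Z / sd[:, None]
    Z[bad] = np.nan
    C = (Z @ Z.T) / B.shape[1]
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    C[bad, :] = np.nan
    C[:, bad] = np.nan
    return C


def fisher_z(r):
    """Fisher transform arctanh(r); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("correlations at +/-1 clipped before Fisher transform")
        r = np.clip(r, -CLIP, CLIP)
    return np.arctanh(r)


@dataclass
class SimilarityResult:
    """Per-subject mean Fisher-z similarity by level, plus difference scores."""

    level_z: dict[str, float]
    differences: dict[str, float]
    pair_counts: dict[str, int]

    def as_frame(self, subject: str = "", group: str = "") -> pd.DataFrame:
        rows = [
            {"subject": subject, "group": group, "measure": "level", "name": lv,
             "value": self.level_z[lv], "n_pairs": self.pair_counts[lv]}
            for lv in RELATEDNESS_LEVELS
        ] + [
            {"subject": subject, "group": group, "measure": "difference",
             "name": nm, "value": v, "n_pairs": np.nan}
            for nm, v in self.differences.items()
        ]
        return pd.DataFrame(rows)


def level_means(
    matrix: np.ndarray,
    metadata: pd.DataFrame,
    hierarchy: StimulusHierarchy,
    accuracy_filter: str = "all",
) -> SimilarityResult:
    """Mean Fisher-z similarity per relatedness level, across-run pairs only.

    ``metadata`` needs one row per trial with ``run`` and ``stimulus``
    columns (and ``subsequent_correct`` for ``accuracy_filter ==
    "correct_only"``).  Unordered pairs are counted once; the diagonal and
    within-run pairs are excluded; NaN entries are dropped with their counts
    reflected in ``pair_counts``.
    """
    if accuracy_filter not in ("all", "correct_only"):
        raise ValueError(f"unknown accuracy filter {accuracy_filter!r}")
    C = np.asarray(matrix, float)
    n = C.shape[0]
    if C.shape != (n, n) or len(metadata) != n:
        raise ValueError("matrix and metadata disagree on trial count")
    runs = metadata["run"].to_numpy()
    stims = metadata["stimulus"].to_numpy()
    keep = np.ones(n, bool)
    if accuracy_filter == "correct_only":
        keep = metadata["subsequent_correct"].to_numpy(bool)

    # level code per trial pair from the 8x8 exemplar relatedness table
    exemplars = list(hierarchy.exemplars)
    lut = np.empty((len(exemplars), len(exemplars)), dtype=object)
    for i, a in enumerate(exemplars):
        for j, b in enumerate(exemplars):
            lut[i, j] = relatedness_level(hierarchy, a, b)
    stim_idx = np.array([exemplars.index(s) for s in stims])

    iu, ju = np.triu_indices(n, k=1)
    across = runs[iu] != runs[ju]
    valid = across & keep[iu] & keep[ju]
    vals = C[iu, ju]
    levels = lut[stim_idx[iu], stim_idx[ju]]

    level_z: dict[str, float] = {}
    counts: dict[str, int] = {}
    for lv in RELATEDNESS_LEVELS:
        sel = valid & (levels == lv) & np.isfinite(vals)
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            raise ValueError(f"no usable across-run pairs at level {lv}")
        level_z[lv] = float(np.mean(fisher_z(vals[sel])))
        counts[lv] = n_pairs
    diffs = {nm: level_z[a] - level_z[b] for nm, (a, b) in DIFFERENCE_SCORES.items()}
    return SimilarityResult(level_z=level_z, differences=diffs, pair_counts=counts)


def group_rsa_stats(results: pd.DataFrame) -> dict:
    """Group-level RSA statistics from tidy per-subject results.

    ``results`` is the concatenation of :meth:`SimilarityResult.as_frame`
    outputs with ``subject`` and ``group`` filled.  Returns the Group x
    Level mixed ANOVA, per-group one-sample t-tests on each difference
    score (two-sided), and between-group t-tests at each level.
    """
    levels = results[results["measure"] == "level"]
    diffs = results[results["measure"] == "difference"]
    groups = list(pd.unique(results["group"]))
    if levels.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    anova = mixed_anova(
        levels.rename(columns={"name": "level"}), dv="value",
        within="level", subject="subject", between="group",
    )
    diff_tests: dict[str, dict[str, TTestResult]] = {}
    for name in DIFFERENCE_SCORES:
        diff_tests[name] = {}
        for g in groups:
            vals = diffs.loc[(diffs["name"] == name) & (diffs["group"] == g), "value"]
            diff_tests[name][g] = one_sample_t(vals.to_numpy())
    level_tests: dict[str, TTestResult] = {}
    if len(groups) == 2:
        for lv in RELATEDNESS_LEVELS:
            a = levels.loc[(levels["name"] == lv) & (levels["group"] == groups[0]), "value"]
            b = levels.loc[(levels["name"] == lv) & (levels["group"] == groups[1]), "value"]
            level_tests[lv] = independent_t_from_data(a.to_numpy(), b.to_numpy())
    return {"anova": anova, "difference_tests": diff_tests,
            "level_tests": level_tests, "groups": groups}
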