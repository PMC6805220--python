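"""Event-related GLMs: canonical HRF, drift basis, condition-level and
single-trial (least-squares-all) design matrices, OLS / AR(1) fitting,
percent-signal-change scaling and contrasts.

Designs are built at a fine microtime resolution, convolved with the
double-gamma HRF and sampled at volume onsets.  Multi-run models are fitted
jointly with per-session mean and drift columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gammaln

DEFAULT_HP_CUTOFF_S = 128.0
MICROTIME_DT = 0.1  # s


def _spm_gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


@lru_cache(maxsize=32)
def _canonical_hrf_cached(dt, length_s, peak_delay, undershoot_delay,
                          peak_disp, undershoot_disp, ratio):
    def curve(t):
        return (
            _spm_gamma_pdf(t, peak_delay / peak_disp, peak_disp)
            - ratio * _spm_gamma_pdf(t, undershoot_delay / undershoot_disp,
                                     undershoot_disp)
        )

    t = np.arange(0, length_s + dt / 2, dt)
    # normalize by the continuous-curve peak so kernels at different dt are
    # consistent subsamples of one another
    peak = curve(np.arange(0, length_s, 1e-3)).max()
    out = curve(t) / peak
    out.setflags(write=False)
    return out


def canonical_hrf(
    dt: float,
    length_s: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds over 32 s.

    Difference of two gamma densities (peak at ~5 s, undershoot at ~15 s),
    normalized to unit peak so a unit event yields a regressor of peak 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return _canonical_hrf_cached(
        float(dt), float(length_s), float(peak_delay), float(undershoot_delay),
        float(peak_disp), float(undershoot_disp), float(ratio),
    )


def highpass_basis(n_volumes: int, tr: float, cutoff_s: float = DEFAULT_HP_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift regressors (constant excluded).

    Includes cosines k = 1..K with K = floor(2 * n_volumes * TR / cutoff),
    i.e. only components of period longer than the cutoff.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if not np.isfinite(cutoff_s):
        return np.empty((n_volumes, 0))
    k_max = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    n = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def event_regressor(
    onsets: np.ndarray,
    n_volumes: int,
    tr: float,
    amplitudes: np.ndarray | None = None,
    dt: float = MICROTIME_DT,
) -> np.ndarray:
    """Delta functions at event onsets convolved with the canonical HRF,
    sampled at volume onset times (0, TR, 2 TR, ...)."""
    onsets = np.atleast_1d(np.asarray(onsets, float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    run_len = n_volumes * tr
    if np.any(onsets < 0) or np.any(onsets >= run_len):
        raise ValueError("event onsets fall outside the run")
    n_fine = int(np.ceil(run_len / dt)) + 1
    fine = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(fine, idx, amplitudes)
    conv = np.convolve(fine, canonical_hrf(dt))[:n_fine]
    scan_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[scan_idx]


def trial_regressor_matrix(
    onsets: np.ndarray, n_volumes: int, tr: float, dt: float = MICROTIME_DT
) -> np.ndarray:
    """(n_volumes, n_trials) matrix of per-trial HRF regressors.

    Vectorized equivalent of calling :func:`event_regressor` per trial with
    a single onset (each column is the HRF kernel shifted to its onset).
    """
    onsets = np.atleast_1d(np.asarray(onsets, float))
    if np.any(onsets < 0) or np.any(onsets >= n_volumes * tr):
        raise ValueError("event onsets fall outside the run")
    hrf = canonical_hrf(dt)
    scan_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    onset_idx = np.round(onsets / dt).astype(int)
    rel = scan_idx[:, None] - onset_idx[None, :]
    valid = (rel >= 0) & (rel < hrf.size)
    out = np.zeros((n_volumes, onsets.size))
    out[valid] = hrf[rel[valid]]
    return out


@dataclass
class DesignMatrix:
    """GLM design: values, column names, interest flags, session structure."""

    matrix: np.ndarray
    names: list[str]
    interest: np.ndarray  # bool per column
    session_lengths: list[int]
    dropped: list[str] = field(default_factory=list)
    _pinv: np.ndarray | None = field(default=None, repr=False, compare=False)
    _rank: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.interest = np.asarray(self.interest, bool)
        if self.matrix.shape[1] != len(self.names) or self.interest.size != len(self.names):
            raise ValueError("design fields are inconsistent")
        if sum(self.session_lengths) != self.matrix.shape[0]:
            raise ValueError("session lengths do not sum to row count")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @property
    def interest_names(self) -> list[str]:
        return [n for n, f in zip(self.names, self.interest) if f]

    @property
    def rank(self) -> int:
        if self._rank is None:
            self._rank = int(np.linalg.matrix_rank(self.matrix))
        return self._rank

    @property
    def pinv(self) -> np.ndarray:
        """Moore-Penrose pseudoinverse, computed once and reused."""
        if self._pinv is None:
            self._pinv = np.linalg.pinv(self.matrix)
        return self._pinv


def _session_nuisance(
    n_volumes: int, tr: float, hp_cutoff_s: float, motion: np.ndarray | None, tag: str
) -> tuple[list[np.ndarray], list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape != (n_volumes, 6):
            raise ValueError("motion must be n_volumes x 6")
        for j in range(6):
            if np.ptp(motion[:, j]) > 0:
                cols.append(motion[:, j] - motion[:, j].mean())
                names.append(f"{tag}motion_{j}")
    hp = highpass_basis(n_volumes, tr, hp_cutoff_s)
    for j in range(hp.shape[1]):
        cols.append(hp[:, j])
        names.append(f"{tag}drift_{j + 1}")
    cols.append(np.ones(n_volumes))
    names.append(f"{tag}mean")
    return cols, names


def build_condition_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    conditions: tuple[str, ...] = ("hit", "CR", "other"),
    motion: np.ndarray | None = None,
    hp_cutoff_s: float = DEFAULT_HP_CUTOFF_S,
) -> DesignMatrix:
    """One-run design with one regressor per condition plus nuisance.

    Trials whose outcome is not a named condition fall into ``"other"`` when
    present.  Empty conditions are dropped with a warning and recorded in
    ``dropped``.
    """
    cols, names, interest, dropped = [], [], [], []
    outcome = events["outcome"].to_numpy()
    mapped = np.where(np.isin(outcome, conditions), outcome, "other")
    for cond in conditions:
        onsets = events.loc[mapped == cond, "onset"].to_numpy(float)
        if onsets.size == 0:
            warnings.warn(f"condition {cond!r} has no events; column dropped")
            dropped.append(cond)
            continue
        cols.append(event_regressor(onsets, n_volumes, tr))
        names.append(cond)
        interest.append(True)
    if not any(interest):
        raise ValueError("no regressors of interest")
    ncols, nnames = _session_nuisance(n_volumes, tr, hp_cutoff_s, motion, "")
    cols += ncols
    names += nnames
    interest += [False] * len(ncols)
    return DesignMatrix(np.column_stack(cols), names, np.array(interest),
                        [n_volumes], dropped)


def condition_design_runs(
    events_by_run: list[pd.DataFrame],
    n_volumes: int | list[int],
    tr: float,
    conditions: tuple[str, ...] = ("hit", "CR", "other"),
    motion_by_run: list[np.ndarray] | None = None,
    hp_cutoff_s: float = DEFAULT_HP_CUTOFF_S,
) -> DesignMatrix:
    """Joint multi-run condition design: one regressor per condition spanning
    all runs (concatenated per-run regressors) plus per-session nuisance."""
    n_runs = len(events_by_run)
    nv = [n_volumes] * n_runs if np.isscalar(n_volumes) else list(n_volumes)
    total = sum(nv)
    cols, names, interest, dropped = [], [], [], []
    for cond in conditions:
        col = np.zeros(total)
        n_events = 0
        row0 = 0
        for ri, ev in enumerate(events_by_run):
            outcome = ev["outcome"].to_numpy()
            mapped = np.where(np.isin(outcome, conditions), outcome, "other")
            onsets = ev.loc[mapped == cond, "onset"].to_numpy(float)
            if onsets.size:
                col[row0:row0 + nv[ri]] = event_regressor(onsets, nv[ri], tr)
                n_events += onsets.size
            row0 += nv[ri]
        if n_events == 0:
            warnings.warn(f"condition {cond!r} has no events; column dropped")
            dropped.append(cond)
            continue
        cols.append(col)
        names.append(cond)
        interest.append(True)
    if not any(interest):
        raise ValueError("no regressors of interest")
    row0 = 0
    for ri in range(n_runs):
        motion = None if motion_by_run is None else motion_by_run[ri]
        ncols, nnames = _session_nuisance(nv[ri], tr, hp_cutoff_s, motion, f"run{ri + 1}_")
        for c, nm in zip(ncols, nnames):
            full = np.zeros(total)
            full[row0:row0 + nv[ri]] = c
            cols.append(full)
            names.append(nm)
            interest.append(False)
        row0 += nv[ri]
    return DesignMatrix(np.column_stack(cols), names, np.array(interest), nv, dropped)


def single_trial_design(
    events_by_run: list[pd.DataFrame],
    n_volumes: int | list[int],
    tr: float,
    motion_by_run: list[np.ndarray] | None = None,
    hp_cutoff_s: float = DEFAULT_HP_CUTOFF_S,
    id_column: str = "adjective",
) -> DesignMatrix:
    """Least-squares-all design over all runs of one phase: one regressor
    per trial (named by its unique trial id) plus per-session motion, drift
    and mean columns."""
    n_runs = len(events_by_run)
    nv = [n_volumes] * n_runs if np.isscalar(n_volumes) else list(n_volumes)
    ids = [str(t) for ev in events_by_run for t in ev[id_column]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial ids across runs")
    n_trials = len(ids)
    total = sum(nv)
    trial_cols = np.zeros((total, n_trials))
    nuis_cols, nuis_names = [], []
    row0, t0 = 0, 0
    for ri, ev in enumerate(events_by_run):
        onsets = ev["onset"].to_numpy(float)
        trial_cols[row0:row0 + nv[ri], t0:t0 + len(onsets)] = trial_regressor_matrix(
            onsets, nv[ri], tr
        )
        motion = None if motion_by_run is None else motion_by_run[ri]
        cols, names = _session_nuisance(nv[ri], tr, hp_cutoff_s, motion, f"run{ri + 1}_")
        for c, nm in zip(cols, names):
            full = np.zeros(total)
            full[row0:row0 + nv[ri]] = c
            nuis_cols.append(full)
            nuis_names.append(nm)
        row0 += nv[ri]
        t0 += len(onsets)
    matrix = np.column_stack([trial_cols] + nuis_cols) if nuis_cols else trial_cols
    names = ids + nuis_names
    interest = np.array([True] * n_trials + [False] * len(nuis_names))
    return DesignMatrix(matrix, names, interest, nv)


@dataclass
class GlmFit:
    """Fitted GLM: per-voxel betas plus residual summaries."""

    betas: np.ndarray  # n_regressors x n_voxels
    names: list[str]
    design: DesignMatrix
    df: int
    sigma2: np.ndarray  # residual variance per voxel
    mean_signal: np.ndarray  # per-voxel mean of the data
    rho: float | None = None

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


def _check_rank(X: np.ndarray, names: list[str]) -> int:
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        # identify a culprit set by greedy QR-style elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                keep.append(j)
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )
    return rank


def _ar1_whiten(M: np.ndarray, rho: float, session_lengths: list[int]) -> np.ndarray:
    out = M.astype(float).copy()
    row0 = 0
    for n in session_lengths:
        block = M[row0:row0 + n]
        out[row0 + 1:row0 + n] = block[1:] - rho * block[:-1]
        out[row0] = block[0] * np.sqrt(1.0 - rho**2)
        row0 += n
    return out


def estimate_ar1(resid: np.ndarray, session_lengths: list[int]) -> float:
    """Pooled lag-1 autocorrelation of residuals, within sessions."""
    num = den = 0.0
    row0 = 0
    for n in session_lengths:
        block = resid[row0:row0 + n]
        num += float(np.sum(block[1:] * block[:-1]))
        den += float(np.sum(block**2))
        row0 += n
    return 0.0 if den == 0 else float(np.clip(num / den, -0.99, 0.99))


def fit_glm(data: np.ndarray, design: DesignMatrix, whitening: str = "none") -> GlmFit:
    """Fit the GLM voxelwise by OLS; optional pooled single-rho AR(1)
    prewhitening (estimate rho from OLS residuals, whiten, refit).

    ``data`` is (n_volumes, n_voxels).
    """
    if whitening not in ("none", "ar1"):
        raise ValueError(f"unknown whitening {whitening!r}")
    # preserve float32 inputs (half the BLAS cost); contiguity matters too
    dtype = np.float32 if np.asarray(data).dtype == np.float32 else np.float64
    Y = np.ascontiguousarray(data, dtype)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("data and design disagree on number of volumes")
    rank = design.rank
    if rank < X.shape[1]:
        _check_rank(X, design.names)  # raises, naming collinear columns
    pinv = design.pinv.astype(dtype, copy=False)  # pinv itself in float64
    Xd = X.astype(dtype, copy=False)
    betas = pinv @ Y
    resid = Y - Xd @ betas
    rho = None
    if whitening == "ar1":
        rho = estimate_ar1(resid, design.session_lengths)
        Xw = _ar1_whiten(X, rho, design.session_lengths)
        Yw = _ar1_whiten(Y, rho, design.session_lengths)
        betas = np.linalg.pinv(Xw) @ Yw
        resid = Yw - Xw @ betas
    df = Y.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / max(df, 1)
    return GlmFit(
        betas=betas,
        names=list(design.names),
        design=design,
        df=df,
        sigma2=sigma2,
        mean_signal=Y.mean(axis=0),
        rho=rho,
    )


def percent_signal_change(fit: GlmFit, name: str) -> np.ndarray:
    """Scale a beta map to percent signal change.

    SPM-style convention: 100 * beta * (peak of the unit-event regressor,
    which is 1 for the peak-normalized HRF) / voxel mean signal.  Voxels with
    non-positive mean signal are returned as NaN.
    """
    beta = fit.beta(name)
    peak = 1.0  # canonical_hrf is peak-normalized; a unit event peaks at 1
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * beta * peak / fit.mean_signal
    psc = np.asarray(psc, float)
    psc[~(fit.mean_signal > 0)] = np.nan
    return psc


def contrast_map(fit: GlmFit, weights: dict[str, float] | np.ndarray) -> np.ndarray:
    """Weighted sum of betas per voxel; weights by regressor name or as a
    vector over the regressors of interest."""
    if isinstance(weights, dict):
        con = np.zeros(fit.betas.shape[1])
        for name, w in weights.items():
            con += w * fit.beta(name)
        return con
    weights = np.asarray(weights, float)
    inames = fit.design.interest_names
    if weights.size != len(inames):
        raise ValueError("weight vector length must match regressors of interest")
    con = np.zeros(fit.betas.shape[1])
    for name, w in zip(inames, weights):
        con += w * fit.beta(name)
    return con


def smooth_volumes(data: np.ndarray, fwhm_mm: float, voxel_size: float) -> np.ndarray:
    """Gaussian spatial smoothing of a 4D (x, y, z, t) array, per volume."""
    if fwhm_mm <= 0:
        return data
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    out = np.empty_like(data, dtype=float)
    for t in range(data.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(data[..., t], sigma_vox)
    return out
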