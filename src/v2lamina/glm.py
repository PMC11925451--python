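"""Block-design GLMs: canonical block regressor, design matrices, OLS fits.

The canonical block response is a boxcar convolved with a single-gamma
impulse response h(t) = (t/p)^q * exp(q - q*t/p) with p = 5 s, q = 4
(so h peaks at 1 for t = p), and the plateau of the convolved response is
normalised to 1 -- a smooth, plateau-normalised approximation to the block
regressors used in standard fMRI packages.  Betas are therefore in the
units of the data (percent signal change at the block plateau).

Two design-matrix modes are supported: ``per_condition`` (one regressor per
stimulus condition; used for selectivity analyses) and ``per_block`` (one
regressor per stimulus block within a single model; used to obtain
block-wise t-score patterns for decoding).  Nuisance regressors are an
intercept plus Legendre polynomial drift terms per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

HRF_PEAK_S = 5.0
HRF_POWER = 4.0
_FINE_DT = 0.05
_HRF_SUPPORT_S = 50.0


def hrf_gamma(t):
    """Single-gamma hemodynamic impulse response, peak-normalised to 1 at t=p."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / HRF_PEAK_S
    out[pos] = tp**HRF_POWER * np.exp(HRF_POWER - HRF_POWER * tp)
    return out


def _block_curve(block_duration_s):
    """Fine-grid convolved block response, plateau-normalised.

    Returns (time_grid, values); values are 0 at t <= 0 and approach 1 on
    the plateau of a sufficiently long block.
    """
    if block_duration_s <= 0:
        raise InputError("block_duration_s must be positive")
    t = np.arange(0.0, block_duration_s + _HRF_SUPPORT_S, _FINE_DT)
    h = hrf_gamma(t)
    box = (t < block_duration_s).astype(float)
    resp = np.convolve(box, h)[: t.size] * _FINE_DT
    resp /= np.trapezoid(hrf_gamma(np.arange(0, _HRF_SUPPORT_S, _FINE_DT)), dx=_FINE_DT)
    return t, resp


def canonical_block_response(block_duration_s, tr_s):
    """Canonical response to one block starting at t=0, sampled every TR.

    The returned vector covers the block plus the hemodynamic tail.
    """
    if tr_s <= 0:
        raise InputError("tr_s must be positive")
    tgrid, curve = _block_curve(block_duration_s)
    ts = np.arange(0.0, tgrid[-1], tr_s)
    return np.interp(ts, tgrid, curve)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # timepoint x regressor
    regressor_names: list
    condition_columns: dict = field(default_factory=dict)  # condition/block -> column

    @property
    def n_timepoints(self):
        return self.matrix.shape[0]

    @property
    def stimulus_columns(self):
        return sorted(self.condition_columns.values())

    @property
    def nuisance_columns(self):
        stim = set(self.condition_columns.values())
        return [j for j in range(self.matrix.shape[1]) if j not in stim]


def build_design_matrix(design, run_index, mode="per_condition", drift_order=2) -> DesignMatrix:
    """Design matrix for one run of a block design.

    Parameters
    ----------
    design : BlockDesign
    run_index : int
    mode : {"per_condition", "per_block"}
        One regressor per condition, or one per stimulus block (all blocks of
        the run in a single model).
    drift_order : int
        Highest Legendre polynomial order of the drift nuisance (0 keeps the
        intercept only).
    """
    if drift_order < 0:
        raise InputError("drift_order must be >= 0")
    if mode not in ("per_condition", "per_block"):
        raise InputError(f"unknown mode {mode!r}")
    onsets = design.block_onsets[run_index]
    starts = np.array([t for t, _ in onsets])
    if np.any(np.diff(np.sort(starts)) < design.block_duration_s - 1e-9):
        raise InputError("overlapping stimulus blocks")
    n_tr = design.n_timepoints
    times = np.arange(n_tr) * design.tr_s
    tgrid, curve = _block_curve(design.block_duration_s)

    cols, names, cond_cols = [], [], {}
    if mode == "per_condition":
        for cond in design.conditions:
            reg = np.zeros(n_tr)
            for onset, c in onsets:
                if c == cond:
                    reg += np.interp(times - onset, tgrid, curve, left=0.0, right=0.0)
            cond_cols[cond] = len(cols)
            names.append(cond)
            cols.append(reg)
    else:
        for b, (onset, c) in enumerate(onsets):
            reg = np.interp(times - onset, tgrid, curve, left=0.0, right=0.0)
            cond_cols[b] = len(cols)
            names.append(f"block{b:02d}_{c}")
            cols.append(reg)

    names.append("intercept")
    cols.append(np.ones(n_tr))
    if drift_order >= 1:
        x = np.linspace(-1.0, 1.0, n_tr)
        leg = np.polynomial.legendre.legvander(x, drift_order)
        for k in range(1, drift_order + 1):
            names.append(f"drift{k}")
            cols.append(leg[:, k])
    return DesignMatrix(np.column_stack(cols), names, cond_cols)


@dataclass
class GLMResult:
    """OLS fit of one run.

    ``betas`` holds the coefficients of the stimulus columns (voxel x
    stimulus-regressor, in design order); ``coefficients`` all regressors.
    ``block_t`` (per-block mode) holds the t score of each block regressor.
    """

    betas: np.ndarray
    coefficients: np.ndarray
    condition_columns: dict
    residuals: np.ndarray
    dof: int
    sigma2: np.ndarray  # per-voxel residual variance
    xtx_inv: np.ndarray
    block_t: np.ndarray | None = None

    def beta(self, condition):
        j = self.condition_columns[condition]
        return self.coefficients[:, j]

    def contrast_t(self, contrast):
        """t statistic of a linear contrast over the stimulus regressors.

        ``contrast`` maps condition/block keys to weights; unlisted
        regressors get weight 0.
        """
        c = np.zeros(self.coefficients.shape[1])
        for key, w in contrast.items():
            c[self.condition_columns[key]] = w
        num = self.coefficients @ c
        denom = np.sqrt(self.sigma2 * (c @ self.xtx_inv @ c))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, num / denom, np.nan)


def fit_glm(run_data, X: DesignMatrix) -> GLMResult:
    """Ordinary-least-squares fit of ``run_data`` (voxel x timepoint).

    Raises an error naming the collinear columns if the design is
    rank-deficient.
    """
    data = np.asarray(run_data, dtype=float)
    if data.ndim != 2 or data.shape[1] != X.n_timepoints:
        raise InputError(
            f"run_data has {data.shape[-1] if data.ndim == 2 else '?'} timepoints, "
            f"design has {X.n_timepoints}"
        )
    M = X.matrix
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        _, r = np.linalg.qr(M)
        bad = [X.regressor_names[j] for j in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise InputError(f"design matrix is rank-deficient; collinear columns: {bad}")
    xtx_inv = np.linalg.inv(M.T @ M)
    coef = data @ (M @ xtx_inv)  # (V x k)
    resid = data - coef @ M.T
    dof = M.shape[0] - rank
    sigma2 = (resid**2).sum(axis=1) / dof if dof > 0 else np.full(data.shape[0], np.nan)
    stim = sorted(X.condition_columns.values())
    result = GLMResult(
        betas=coef[:, stim],
        coefficients=coef,
        condition_columns=dict(X.condition_columns),
        residuals=resid,
        dof=dof,
        sigma2=sigma2,
        xtx_inv=xtx_inv,
    )
    block_keys = [k for k in X.condition_columns if isinstance(k, (int, np.integer))]
    if block_keys:
        se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, stim])
        with np.errstate(divide="ignore", invalid="ignore"):
            result.block_t = np.where(se > 0, coef[:, stim] / se, np.nan)
    return result
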