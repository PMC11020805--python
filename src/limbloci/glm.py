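"""Run-level GLM for block-design motor fMRI.

A run's design matrix holds one boxcar-convolved task regressor per 20 s
block (three per run), six rigid-body motion nuisance columns and Legendre
polynomial drift terms.  Per-voxel regression yields block-wise betas, the
across-block average beta (contrast [1/3, 1/3, 1/3]) and its t statistic,
which downstream stages use as the activation map.  Estimation is OLS with
optional AR(1) prewhitening (coefficient pooled over mask voxels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import HemiMask, VolumeGrid

__all__ = [
    "GLMError",
    "double_gamma_hrf",
    "DesignMatrix",
    "build_design",
    "BetaMaps",
    "fit_glm",
    "fit_subject",
    "rm_anova",
]


class GLMError(ValueError):
    pass


def double_gamma_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak normalised to 1.

    SPM convention: gamma density with shape ``peak_delay`` minus
    ``undershoot_ratio`` times a gamma density with shape ``undershoot_delay``
    (both scale ``dispersion`` seconds).
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    h = h - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay / dispersion, scale=dispersion
    )
    peak = h.max() if h.size and h.max() > 0 else 1.0
    return h / peak


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with named columns.

    Columns: ``n_task`` boxcar-convolved task regressors, 6 motion nuisance
    columns, then drift polynomials 0..order (drift_0 is the constant).
    """

    matrix: np.ndarray
    names: list[str]
    n_task: int
    tr: float
    onsets: list[tuple[float, float]]

    @property
    def task(self) -> np.ndarray:
        return self.matrix[:, : self.n_task]

    @property
    def zero_columns(self) -> list[str]:
        """Names of all-zero columns (e.g. a flat motion trace), flagged so the
        fit can drop them instead of failing on rank deficiency."""
        z = np.all(self.matrix == 0.0, axis=0)
        return [n for n, flag in zip(self.names, z) if flag]


_HRF_DT = 0.05  # s, oversampling step for boxcar convolution
_HRF_LEN = 32.0  # s, support of the sampled response


def build_design(
    onsets,
    n_volumes: int,
    tr: float,
    motion: np.ndarray | None,
    drift_order: int = 2,
) -> DesignMatrix:
    """Assemble the run design matrix.

    ``onsets`` is a list of (start_s, duration_s) task blocks; a zero duration
    is treated as a unit impulse.  Motion may be None (six zero columns,
    flagged for removal by the fit).  Drift columns are Legendre polynomials
    over the run, orders 1..``drift_order`` demeaned so only drift_0 carries
    the intercept.
    """
    if tr <= 0 or n_volumes < 2:
        raise ValueError("need tr > 0 and at least 2 volumes")
    run_end = n_volumes * tr
    onsets = [(float(a), float(d)) for a, d in onsets]
    for a, d in onsets:
        if d < 0 or a < 0 or a >= run_end:
            raise ValueError(f"block onset {a} s outside run of {run_end} s")

    t_hi = np.arange(0.0, run_end + _HRF_LEN, _HRF_DT)
    hrf = double_gamma_hrf(np.arange(0.0, _HRF_LEN, _HRF_DT))
    vol_t = np.arange(n_volumes) * tr
    cols, names = [], []
    for k, (a, d) in enumerate(onsets):
        box = np.zeros_like(t_hi)
        if d > 0:
            box[(t_hi >= a) & (t_hi < a + d)] = 1.0
            reg = np.convolve(box, hrf)[: len(t_hi)] * _HRF_DT
        else:  # impulse event
            box[np.searchsorted(t_hi, a)] = 1.0
            reg = np.convolve(box, hrf)[: len(t_hi)]
        cols.append(np.interp(vol_t, t_hi, reg))
        names.append(f"block_{k + 1}")
    n_task = len(cols)

    if motion is None:
        motion = np.zeros((n_volumes, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise ValueError(f"motion trace must be (n_volumes, 6), got {motion.shape}")
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j + 1}")

    x = np.linspace(-1.0, 1.0, n_volumes)
    for k in range(drift_order + 1):
        basis = np.polynomial.legendre.Legendre.basis(k)(x)
        if k > 0:
            basis = basis - basis.mean()  # keep drift terms orthogonal to the mean
        cols.append(basis)
        names.append(f"drift_{k}")

    return DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        n_task=n_task,
        tr=tr,
        onsets=onsets,
    )


@dataclass
class BetaMaps:
    """Per-voxel GLM estimates over the mask voxels (lexicographic order)."""

    block_betas: np.ndarray  # (n_task, V)
    avg_beta: np.ndarray  # (V,)
    t_blocks: np.ndarray  # (n_task, V)
    t_avg: np.ndarray  # (V,)
    sigma2: np.ndarray  # (V,) residual variance
    df: int
    mask_indices: np.ndarray  # (V, 3)
    grid: VolumeGrid
    ar1: float
    dropped_columns: list[str]

    def raster(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.grid.shape, fill, dtype=float)
        out[tuple(self.mask_indices.T)] = values
        return out


def _collinear_names(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns implicated in a rank deficiency (small R diagonal in QR)."""
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    _, r = np.linalg.qr(x / norms)
    bad = np.abs(np.diag(r)) < 1e-8
    return [n for n, b in zip(names, bad) if b]


def _whiten_matrix(n: int, rho: float) -> np.ndarray:
    w = np.eye(n)
    w[0, 0] = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        w[i, i - 1] = -rho
    return w


def fit_glm(
    run_data: np.ndarray,
    design: DesignMatrix,
    mask: HemiMask | np.ndarray,
    grid: VolumeGrid | None = None,
    ar1: float | str = 0.0,
) -> BetaMaps:
    """Per-voxel regression of a run inside the mask.

    ``run_data`` is a 4-D raster (x, y, z, t) or a (t, V) matrix already
    restricted to the mask voxels.  ``ar1`` may be a fixed coefficient or
    ``"auto"`` (estimated from pooled OLS residuals, then prewhitened refit);
    0 reduces exactly to OLS.
    """
    if isinstance(mask, HemiMask):
        region, grid = mask.region, mask.grid
    else:
        region = np.asarray(mask, dtype=bool)
        if grid is None:
            raise ValueError("grid required when mask is a plain raster")
    idx = np.argwhere(region)

    run_data = np.asarray(run_data, dtype=float)
    if run_data.ndim == 4:
        if run_data.shape[:3] != region.shape:
            raise ValueError("run raster does not match the mask grid")
        y = run_data[tuple(idx.T)].T  # (t, V)
    else:
        y = run_data
        if y.shape[1] != len(idx):
            raise ValueError("sample matrix does not match mask voxel count")

    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError("volume count mismatch between data and design")

    dropped = design.zero_columns
    keep = [i for i, n in enumerate(design.names) if n not in dropped]
    names = [design.names[i] for i in keep]
    x = x[:, keep]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_names(x, names)
        raise GLMError(f"design is rank deficient; collinear columns: {bad}")

    def solve(xw, yw):
        xtx_inv = np.linalg.inv(xw.T @ xw)
        beta = xtx_inv @ xw.T @ yw
        resid = yw - xw @ beta
        dof = xw.shape[0] - xw.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        return beta, resid, sigma2, dof, xtx_inv

    beta, resid, sigma2, dof, xtx_inv = solve(x, y)
    rho = 0.0
    if ar1 == "auto":
        num = (resid[1:] * resid[:-1]).sum()
        den = (resid**2).sum()
        rho = float(num / den) if den > 0 else 0.0
    elif ar1:
        rho = float(ar1)
    if rho != 0.0:
        w = _whiten_matrix(x.shape[0], rho)
        beta, resid, sigma2, dof, xtx_inv = solve(w @ x, w @ y)

    n_task = design.n_task
    t_blocks = np.empty((n_task, y.shape[1]))
    for k in range(n_task):
        c = np.zeros(x.shape[1])
        c[k] = 1.0
        denom = np.sqrt(sigma2 * (c @ xtx_inv @ c))
        t_blocks[k] = np.divide(
            beta[k], denom, out=np.zeros_like(beta[k]), where=denom > 0
        )
    c_avg = np.zeros(x.shape[1])
    c_avg[:n_task] = 1.0 / n_task
    avg_beta = c_avg @ beta
    denom = np.sqrt(sigma2 * (c_avg @ xtx_inv @ c_avg))
    t_avg = np.divide(avg_beta, denom, out=np.zeros_like(avg_beta), where=denom > 0)

    return BetaMaps(
        block_betas=beta[:n_task],
        avg_beta=avg_beta,
        t_blocks=t_blocks,
        t_avg=t_avg,
        sigma2=sigma2,
        df=dof,
        mask_indices=idx,
        grid=grid,
        ar1=rho,
        dropped_columns=dropped,
    )


def fit_subject(dataset, mask: HemiMask, drift_order: int = 2, ar1: float | str = 0.0):
    """Fit every run of a simulated/loaded subject; return per-task maps.

    Returns ``{(movement, side): BetaMaps}`` over the mask voxels.
    """
    out = {}
    for run in dataset.runs:
        design = build_design(
            run.onsets, run.data.shape[-1], run.tr, run.motion, drift_order
        )
        out[(run.movement, run.side)] = fit_glm(run.data, design, mask, ar1=ar1)
    return out


def save_beta_maps(bm: BetaMaps, design: DesignMatrix, prefix) -> None:
    """Write the average beta and t rasters as NIfTI with a JSON sidecar
    recording the design provenance (onsets, TR, drift order, contrast)."""
    import json
    from pathlib import Path

    from .grid import write_volume

    prefix = Path(prefix)
    write_volume(prefix.with_suffix(".beta.nii"), bm.raster(bm.avg_beta), bm.grid)
    write_volume(prefix.with_suffix(".t.nii"), bm.raster(bm.t_avg), bm.grid)
    sidecar = {
        "onsets_s": design.onsets,
        "tr_s": design.tr,
        "n_task_regressors": design.n_task,
        "drift_order": sum(n.startswith("drift_") for n in design.names) - 1,
        "contrast": [1.0 / design.n_task] * design.n_task,
        "ar1": bm.ar1,
        "df": bm.df,
        "dropped_columns": bm.dropped_columns,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def rm_anova(betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way repeated-measures ANOVA across tasks, vectorised over voxels.

    ``betas`` has shape (n_subjects, n_tasks, V): per-subject average-block
    beta per task.  Returns (F, p) arrays of length V; the error term is the
    subject x task interaction.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim == 2:
        betas = betas[:, :, None]
    n, k, _ = betas.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 tasks")
    grand = betas.mean(axis=(0, 1))
    task_means = betas.mean(axis=0)  # (k, V)
    subj_means = betas.mean(axis=1)  # (n, V)
    ss_task = n * ((task_means - grand) ** 2).sum(axis=0)
    resid = betas - task_means[None] - subj_means[:, None] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    # rounding floor: sums of squares that are numerically zero relative to
    # the data scale are treated as exactly zero (flat data => F = 0, p = 1)
    ss_total = ((betas - grand) ** 2).sum(axis=(0, 1))
    tol = 1e-12 * np.maximum(ss_total, 1e-300)
    ss_task = np.where(ss_task < tol, 0.0, ss_task)
    ss_err = np.where(ss_err < tol, 0.0, ss_err)
    df_task = k - 1
    df_err = (n - 1) * (k - 1)
    ms_task = ss_task / df_task
    ms_err = ss_err / df_err
    f = np.divide(ms_task, ms_err, out=np.zeros_like(ms_task), where=ms_err > 0)
    f = np.where((ms_err == 0) & (ms_task > 0), np.inf, f)
    p = stats.f.sf(f, df_task, df_err)
    p = np.where((ms_err == 0) & (ms_task == 0), 1.0, p)
    return np.squeeze(f), np.squeeze(p)
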