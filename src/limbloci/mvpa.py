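"""Searchlight MVPA: four-class movement decoding per sphere.

For every mask voxel the feature vector is the beta values inside its
searchlight sphere.  Classification uses an SVM (linear or RBF kernel) under
nested subject-wise cross-validation: five outer folds split subjects into
train/test, and one inner subject-wise split of the outer-training subjects
selects C (and gamma) from a decade grid.  The reported map is the mean test
accuracy over outer folds; chance for four balanced classes is 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import SVC

from .grid import HemiMask, neighborhood, sphere_offsets

__all__ = [
    "MvpaConfig",
    "AccuracyMap",
    "smooth_gaussian",
    "assemble_samples",
    "searchlight_classify",
    "scenario_sweep",
    "threshold_accuracy",
]

_DECADES = tuple(10.0**k for k in range(-4, 4))  # 1e-4 .. 1e3


@dataclass
class MvpaConfig:
    input_mode: str = "block"  # 'block' (3 maps/run) or 'average' (1 map/run)
    smoothing_fwhm_mm: float = 0.0
    radius_vox: int = 3
    kernel: str = "rbf"
    c_grid: tuple = _DECADES
    gamma_grid: tuple = _DECADES
    n_outer_folds: int = 5
    report_threshold: float = 0.65

    def __post_init__(self):
        if self.input_mode not in ("block", "average"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not self.c_grid or (self.kernel == "rbf" and not self.gamma_grid):
            raise ValueError("hyperparameter grids must be nonempty")
        if self.n_outer_folds < 2:
            raise ValueError("need at least 2 outer folds")
        if not 0.0 < self.report_threshold <= 1.0:
            raise ValueError("report threshold must be in (0, 1]")


@dataclass
class AccuracyMap:
    accuracy: np.ndarray  # (V,) mean test accuracy over outer folds
    fold_accuracy: np.ndarray  # (n_folds, V)
    chosen_c: np.ndarray  # (n_folds, V)
    chosen_gamma: np.ndarray  # (n_folds, V); nan for linear kernel
    folds: list[np.ndarray]  # subject ids per outer test fold
    subject_accuracy: pd.DataFrame  # per test subject: fraction correct
    mask: HemiMask
    config: MvpaConfig

    def raster(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.mask.grid.shape, fill, dtype=float)
        out[tuple(self.mask.indices.T)] = self.accuracy
        return out


def smooth_gaussian(raster: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2)) per axis."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return np.asarray(raster, dtype=float)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / np.asarray(voxel_size_mm, dtype=float)
    return ndimage.gaussian_filter(np.asarray(raster, dtype=float), sigma=sigma_vox)


def assemble_samples(
    subject_maps: dict,
    side: str,
    mask: HemiMask,
    input_mode: str = "block",
    smoothing_fwhm_mm: float = 0.0,
):
    """Build (features, labels, subjects) for one side's four movements.

    ``subject_maps`` maps subject id -> {(movement, side): BetaMaps}.  In
    'block' mode each run contributes its three block betas; in 'average'
    mode one across-block average map.  Smoothing, when requested, is applied
    to each full-grid beta raster before masking.
    """
    feats, labels, subjects = [], [], []
    vox = tuple(mask.indices.T)
    for sid in sorted(subject_maps):
        for (movement, s), bm in sorted(subject_maps[sid].items()):
            if s != side:
                continue
            maps = bm.block_betas if input_mode == "block" else [bm.avg_beta]
            for values in maps:
                if smoothing_fwhm_mm > 0:
                    raster = bm.raster(values)
                    values = smooth_gaussian(
                        raster, smoothing_fwhm_mm, mask.grid.voxel_size_mm
                    )[vox]
                feats.append(np.asarray(values, dtype=float))
                labels.append(movement)
                subjects.append(sid)
    return np.stack(feats), np.asarray(labels), np.asarray(subjects)


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _grid(config: MvpaConfig):
    if config.kernel == "linear":
        return [(c, None) for c in sorted(config.c_grid)]
    return list(product(sorted(config.c_grid), sorted(config.gamma_grid)))


def _svc(kernel: str, c: float, gamma):
    return SVC(kernel=kernel, C=c, gamma=(gamma if gamma is not None else "scale"))


def searchlight_classify(
    features: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    mask: HemiMask,
    config: MvpaConfig,
    seed: int = 0,
) -> AccuracyMap:
    """Mean nested-CV test accuracy per searchlight centre.

    Outer folds partition *subjects* (never samples), so train and test sets
    are always subject-disjoint; one inner subject-wise 4/1 split of the
    outer-training subjects drives the grid search.  Hyperparameter ties go
    to the smallest C, then the smallest gamma.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if features.shape[0] != len(labels) or len(labels) != len(subjects):
        raise ValueError("features, labels and subjects must align")
    classes = np.unique(labels)
    for sid in np.unique(subjects):
        have = np.unique(labels[subjects == sid])
        if len(have) < len(classes):
            raise ValueError(f"subject {sid!r} is missing classes; exclude it first")
    uniq = np.unique(subjects)
    if len(uniq) < config.n_outer_folds:
        raise ValueError(
            f"need >= {config.n_outer_folds} subjects for subject-wise folds"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds = [np.sort(f) for f in np.array_split(uniq[order], config.n_outer_folds)]

    # searchlight geometry
    idx = mask.indices
    col_of = np.full(mask.grid.shape, -1, dtype=int)
    col_of[tuple(idx.T)] = np.arange(len(idx))
    offs = sphere_offsets(config.radius_vox)
    neighborhoods = [
        col_of[tuple(neighborhood(center, offs, mask).T)] for center in idx
    ]

    n_v = len(idx)
    n_f = len(folds)
    fold_acc = np.zeros((n_f, n_v))
    chosen_c = np.full((n_f, n_v), np.nan)
    chosen_g = np.full((n_f, n_v), np.nan)
    subj_correct: dict = {}
    grid_pts = _grid(config)

    for fi, test_subj in enumerate(folds):
        test_rows = np.isin(subjects, test_subj)
        train_subj = np.setdiff1d(uniq, test_subj)
        inner = np.random.default_rng(seed + 1000 + fi).permutation(train_subj)
        n_val = max(1, int(round(len(train_subj) / 5.0)))
        val_subj = np.sort(inner[:n_val])
        fit_rows = np.isin(subjects, np.setdiff1d(train_subj, val_subj))
        val_rows = np.isin(subjects, val_subj)
        train_rows = np.isin(subjects, train_subj)

        y_fit, y_val, y_train, y_test = (
            labels[fit_rows],
            labels[val_rows],
            labels[train_rows],
            labels[test_rows],
        )
        for vi, cols in enumerate(neighborhoods):
            x = features[:, cols]
            xf, xv = _standardize(x[fit_rows], x[val_rows])
            best = (-1.0, np.inf, np.inf)  # (acc, c, gamma) with tie-breaks
            for c, g in grid_pts:
                clf = _svc(config.kernel, c, g)
                clf.fit(xf, y_fit)
                acc = float((clf.predict(xv) == y_val).mean())
                key = (acc, -c, -(g if g is not None else 0.0))
                ref = (best[0], -best[1], -best[2])
                if key > ref:
                    best = (acc, c, g if g is not None else np.nan)
            c_best, g_best = best[1], best[2]
            xt, xs = _standardize(x[train_rows], x[test_rows])
            clf = _svc(config.kernel, c_best, None if np.isnan(g_best) else g_best)
            clf.fit(xt, y_train)
            pred = clf.predict(xs)
            fold_acc[fi, vi] = float((pred == y_test).mean())
            chosen_c[fi, vi] = c_best
            chosen_g[fi, vi] = g_best
            for sid in test_subj:
                rows = subjects[test_rows] == sid
                ok, tot = subj_correct.get(sid, (0, 0))
                subj_correct[sid] = (
                    ok + int((pred[rows] == y_test[rows]).sum()),
                    tot + int(rows.sum()),
                )

    subject_accuracy = pd.DataFrame(
        [
            {"subject": sid, "accuracy": ok / tot}
            for sid, (ok, tot) in sorted(subj_correct.items())
        ]
    )
    return AccuracyMap(
        accuracy=fold_acc.mean(axis=0),
        fold_accuracy=fold_acc,
        chosen_c=chosen_c,
        chosen_gamma=chosen_g,
        folds=folds,
        subject_accuracy=subject_accuracy,
        mask=mask,
        config=config,
    )


def scenario_sweep(
    subject_maps: dict,
    side: str,
    mask: HemiMask,
    axes: dict,
    base_config: MvpaConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One accuracy map per scenario combination.

    ``axes`` maps any of input_mode / smoothing_fwhm_mm / radius_vox / kernel
    to a list of values; unlisted axes come from ``base_config``.  Returns a
    summary table of the within-mask accuracy distribution per condition
    (keyed like B/A x L/N x SM x RADIUS) and the maps themselves.
    """
    base = base_config or MvpaConfig()
    for key, vals in axes.items():
        if not len(vals):
            raise ValueError(f"empty scenario axis {key!r}")
    names = ["input_mode", "smoothing_fwhm_mm", "radius_vox", "kernel"]
    grids = [axes.get(n, [getattr(base, n)]) for n in names]
    rows, maps = [], {}
    for combo in product(*grids):
        cfg = replace(base, **dict(zip(names, combo)))
        feats, labels, subj = assemble_samples(
            subject_maps, side, mask, cfg.input_mode, cfg.smoothing_fwhm_mm
        )
        amap = searchlight_classify(feats, labels, subj, mask, cfg, seed=seed)
        key = "{}-{}-SM{:g}-R{}".format(
            "B" if cfg.input_mode == "block" else "A",
            "L" if cfg.kernel == "linear" else "N",
            cfg.smoothing_fwhm_mm,
            cfg.radius_vox,
        )
        maps[key] = amap
        acc = amap.accuracy
        rows.append(
            {
                "condition": key,
                "input_mode": cfg.input_mode,
                "kernel": cfg.kernel,
                "smoothing_fwhm_mm": cfg.smoothing_fwhm_mm,
                "radius_vox": cfg.radius_vox,
                "mean": acc.mean(),
                "median": float(np.median(acc)),
                "q1": float(np.quantile(acc, 0.25)),
                "q3": float(np.quantile(acc, 0.75)),
                "max": acc.max(),
                "fold_means": list(amap.fold_accuracy.mean(axis=1)),
                "subject_means": list(amap.subject_accuracy.accuracy),
            }
        )
    return pd.DataFrame(rows), maps


def threshold_accuracy(accuracy_map: AccuracyMap, threshold: float | None = None):
    """Binary raster of voxels with accuracy >= threshold (default 65%)."""
    thr = accuracy_map.config.report_threshold if threshold is None else threshold
    if not 0.0 <= thr <= 1.0 + 1e-12:
        raise ValueError("threshold must be in [0, 1]")
    out = np.zeros(accuracy_map.mask.grid.shape, dtype=bool)
    out[tuple(accuracy_map.mask.indices.T)] = accuracy_map.accuracy >= thr
    return out
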