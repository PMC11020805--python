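"""Head-motion summaries, block/subject exclusion rules and the
equipment-comparison statistics.

The per-volume motion score is the Euclidean norm of the backward difference
of the six rigid-body parameters (the scrubbing "enorm" convention), with
rotations converted to arc length on a configurable head radius.  A task
block fails when strictly more than 10% of its volumes exceed the strict
0.5 mm threshold; a subject is included only when every block of every run
passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "motion_norm",
    "block_volumes",
    "qc_blocks",
    "qc_subject",
    "compare_motion",
    "MotionSummary",
]

PARAM_NAMES = ("roll", "pitch", "yaw", "dS", "dL", "dP")
ROTATION_COLS = (0, 1, 2)  # degrees; translations in mm


def motion_norm(
    trace: np.ndarray,
    rotation_radius_mm: float = 50.0,
    mode: str = "diff",
) -> np.ndarray:
    """Per-volume Euclidean motion score in mm.

    ``mode='diff'`` (default) scores the framewise differential, with the
    first volume scored 0; ``mode='absolute'`` scores displacement from the
    first volume.  Rotations (columns 0-2, degrees) become arc length at
    ``rotation_radius_mm``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got shape {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 volumes")
    mm = trace.copy()
    mm[:, ROTATION_COLS] *= rotation_radius_mm * np.pi / 180.0
    if mode == "diff":
        delta = np.diff(mm, axis=0, prepend=mm[:1])
    elif mode == "absolute":
        delta = mm - mm[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.linalg.norm(delta, axis=1)


def block_volumes(onsets, tr: float, n_volumes: int) -> list[np.ndarray]:
    """Volume indices of each task block: acquisition onset within
    [block start, block end)."""
    t = np.arange(n_volumes) * tr
    return [np.flatnonzero((t >= a) & (t < a + d)) for a, d in onsets]


@dataclass
class MotionSummary:
    blocks: pd.DataFrame  # run, block, n_volumes, n_flagged, fraction, verdict
    include: bool  # subject verdict: every block of every run passed


def qc_blocks(
    norms: np.ndarray,
    onsets,
    tr: float,
    threshold_mm: float = 0.5,
    max_fraction: float = 0.10,
    run: str | int = 0,
) -> pd.DataFrame:
    """Per-block QC table for one run; a block fails iff the flagged
    fraction strictly exceeds ``max_fraction``."""
    norms = np.asarray(norms, dtype=float)
    rows = []
    for b, vols in enumerate(block_volumes(onsets, tr, len(norms))):
        if len(vols) == 0:
            raise ValueError(f"block {b} contains no volumes")
        flagged = int((norms[vols] > threshold_mm).sum())  # strict >
        frac = flagged / len(vols)
        rows.append(
            {
                "run": run,
                "block": b,
                "n_volumes": len(vols),
                "n_flagged": flagged,
                "fraction": frac,
                "verdict": "pass" if frac <= max_fraction else "fail",
            }
        )
    return pd.DataFrame(rows)


def qc_subject(
    dataset,
    threshold_mm: float = 0.5,
    max_fraction: float = 0.10,
    rotation_radius_mm: float = 50.0,
) -> MotionSummary:
    """QC every run of a subject; include iff all blocks of all runs pass."""
    tables = []
    for run in dataset.runs:
        norms = motion_norm(run.motion, rotation_radius_mm)
        tables.append(
            qc_blocks(
                norms,
                run.onsets,
                run.tr,
                threshold_mm,
                max_fraction,
                run=f"{run.movement}_{run.side}",
            )
        )
    blocks = pd.concat(tables, ignore_index=True)
    return MotionSummary(blocks=blocks, include=bool((blocks.verdict == "pass").all()))


def _tukey_kramer_p(t: np.ndarray, df: np.ndarray, k: int) -> np.ndarray:
    """Adjusted p from the studentized range with k groups (q = |t| sqrt(2))."""
    return stats.studentized_range.sf(np.abs(t) * np.sqrt(2.0), k, df)


def compare_motion(
    traces_with: list[np.ndarray],
    traces_without: list[np.ndarray],
    mode: str = "run",
    alpha: float = 0.05,
    k_groups: int = 2,
) -> pd.DataFrame:
    """Welch t-tests on the six motion parameters, with vs without equipment.

    ``mode='run'`` compares per-run summaries (mean absolute framewise change
    per parameter); ``mode='timepoint'`` compares each volume's parameter
    value across runs and requires equal run lengths.  Significance at
    ``alpha`` uses the Tukey-Kramer (studentized-range) adjustment.
    """
    a = [np.asarray(t, dtype=float) for t in traces_with]
    b = [np.asarray(t, dtype=float) for t in traces_without]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 traces per condition")
    for t in a + b:
        if t.ndim != 2 or t.shape[1] != 6:
            raise ValueError("each trace must be (volumes, 6)")

    rows = []
    if mode == "run":
        sa = np.stack([np.abs(np.diff(t, axis=0)).mean(axis=0) for t in a])
        sb = np.stack([np.abs(np.diff(t, axis=0)).mean(axis=0) for t in b])
        for j, name in enumerate(PARAM_NAMES):
            res = stats.ttest_ind(sa[:, j], sb[:, j], equal_var=False)
            rows.append({"parameter": name, "t": res.statistic, "df": res.df})
    elif mode == "timepoint":
        lengths = {t.shape[0] for t in a + b}
        if len(lengths) != 1:
            raise ValueError("timepoint mode requires equal run lengths")
        ta = np.stack(a)  # (runs, vols, 6)
        tb = np.stack(b)
        n_vols = ta.shape[1]
        for j, name in enumerate(PARAM_NAMES):
            res = stats.ttest_ind(ta[:, :, j], tb[:, :, j], axis=0, equal_var=False)
            for v in range(n_vols):
                rows.append(
                    {
                        "parameter": name,
                        "timepoint": v,
                        "t": res.statistic[v],
                        "df": res.df[v],
                    }
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = pd.DataFrame(rows)
    t = out["t"].to_numpy()
    df = out["df"].to_numpy()
    with np.errstate(invalid="ignore"):
        p_welch = 2.0 * stats.t.sf(np.abs(t), df)
        p_adj = _tukey_kramer_p(t, df, k_groups)
    out["p"] = np.where(np.isfinite(t), p_welch, 1.0)
    out["p_adj"] = np.where(np.isfinite(t), p_adj, 1.0)
    out["t"] = np.where(np.isfinite(t), t, 0.0)
    out["significant"] = out["p_adj"] < alpha
    return out
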