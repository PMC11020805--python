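"""Threshold-free laterality index (AveLI) over a chosen ROI definition.

AveLI avoids picking one activation threshold: every positive t value in the
two contralateral ROI extracts serves in turn as the threshold t_i, a
laterality index subLI_i = (Rt_i - Lt_i) / (Rt_i + Lt_i) is computed from
the sums of t-scores >= t_i on each side, and AveLI is the average of all VN
of them (VN = pooled count of positive-t voxels).  For healthy subjects the
two inputs are the contralateral-hemisphere t values of the right-side and
left-side movements; for stroke subjects the non-paretic-side movement plays
the R role and the paretic-side movement the L role.  AveLI is in [-1, 1];
+1 means activation exclusively with the first input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import HemiMask

__all__ = [
    "ave_li",
    "ave_li_stroke",
    "LateralityRecord",
    "roi_laterality",
    "compare_definitions",
]


def ave_li(t_right_move, t_left_move) -> tuple[float, int]:
    """AveLI of two contralateral t-value sets; returns (AveLI, VN).

    Thresholds are the pooled strictly-positive t values (ties counted with
    multiplicity); each threshold is inclusive (t >= t_i), so the threshold
    voxel itself always contributes and denominators stay positive.  With no
    positive t anywhere the index is undefined: (nan, 0).
    """
    r = np.asarray(t_right_move, dtype=float).ravel()
    l = np.asarray(t_left_move, dtype=float).ravel()
    pos = np.concatenate([r[r > 0], l[l > 0]])
    if pos.size == 0:
        return float("nan"), 0
    thr = pos[:, None]
    rt = np.where(r[None, :] >= thr, r[None, :], 0.0).sum(axis=1)
    lt = np.where(l[None, :] >= thr, l[None, :], 0.0).sum(axis=1)
    subli = (rt - lt) / (rt + lt)
    return float(subli.mean()), int(pos.size)


def ave_li_stroke(t_nonparetic_move, t_paretic_move) -> tuple[float, int]:
    """Stroke variant: non-paretic-side movement in the R role, paretic in L."""
    return ave_li(t_nonparetic_move, t_paretic_move)


@dataclass
class LateralityRecord:
    subject: str
    movement: str
    roi_definition: str  # 'pcl' or 'loci'
    variant: str  # 'healthy' (R vs L) or 'stroke' (NP vs P)
    ave_li: float  # nan when undefined
    vn: int
    reason: str = ""  # why undefined, when it is

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ave_li)


def _contra_extract(t_map: np.ndarray, moving_side: str, mask: HemiMask, roi):
    """t values of one movement's map in the hemisphere contralateral to the
    moving limb, restricted to ``roi`` (boolean raster or None for the whole
    hemisphere)."""
    hemi = "left" if moving_side == "right" else "right"
    sel = mask.hemisphere(hemi)
    if roi is not None:
        sel = sel & np.asarray(roi, dtype=bool)
    return np.asarray(t_map)[sel]


def roi_laterality(
    t_maps: dict,
    mask: HemiMask,
    movement: str,
    subject: str = "",
    variant: str = "healthy",
    loci: dict | None = None,
    loci_mode: str = "movement",
    paretic_side: str | None = None,
) -> LateralityRecord:
    """AveLI of one movement for one subject under a chosen ROI definition.

    ``t_maps`` maps (movement, moving_side) -> full-grid t raster.  With
    ``loci=None`` the ROI is the whole PCL hemisphere; otherwise ``loci``
    maps (movement, moving_side) -> boolean locus raster and the extract is
    restricted to the movement's own locus (``loci_mode='movement'``) or the
    union of all movements' loci (``'union'``).  For the stroke variant
    ``paretic_side`` decides which moving side takes the P role.
    """
    roi_definition = "pcl" if loci is None else "loci"

    def roi_for(move_side: str):
        if loci is None:
            return None
        if loci_mode == "movement":
            return loci.get((movement, move_side))
        if loci_mode == "union":
            out = None
            for r in loci.values():
                out = r if out is None else (out | r)
            return out
        raise ValueError(f"unknown loci_mode {loci_mode!r}")

    if variant == "healthy":
        first, second = "right", "left"  # R role, L role
    elif variant == "stroke":
        if paretic_side not in ("left", "right"):
            raise ValueError("stroke variant needs paretic_side")
        first = "right" if paretic_side == "left" else "left"  # non-paretic
        second = paretic_side
    else:
        raise ValueError(f"unknown variant {variant!r}")

    record = dict(
        subject=subject, movement=movement, roi_definition=roi_definition,
        variant=variant,
    )
    extracts = []
    for move_side in (first, second):
        if (movement, move_side) not in t_maps:
            return LateralityRecord(
                **record, ave_li=float("nan"), vn=0,
                reason=f"no t map for {(movement, move_side)}",
            )
        roi = roi_for(move_side)
        if loci is not None and (roi is None or not roi.any()):
            return LateralityRecord(
                **record, ave_li=float("nan"), vn=0,
                reason=f"no locus for {(movement, move_side)}",
            )
        vals = _contra_extract(t_maps[(movement, move_side)], move_side, mask, roi)
        if vals.size == 0:
            return LateralityRecord(
                **record, ave_li=float("nan"), vn=0,
                reason=f"empty contralateral ROI for {(movement, move_side)}",
            )
        extracts.append(vals)
    li, vn = ave_li(*extracts)
    reason = "" if np.isfinite(li) else "no positive t values"
    return LateralityRecord(**record, ave_li=li, vn=vn, reason=reason)


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "movement": r.movement,
                "roi_definition": r.roi_definition,
                "variant": r.variant,
                "ave_li": r.ave_li,
                "vn": r.vn,
                "reason": r.reason,
            }
            for r in records
        ]
    )


def compare_definitions(records) -> pd.DataFrame:
    """Paired t-test (loci vs PCL AveLI) per movement across subjects.

    ``records`` is an iterable of LateralityRecord or an equivalent
    DataFrame; subjects lacking either definition for a movement are dropped
    from that movement's pairing.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    rows = []
    for movement, grp in df.groupby("movement", sort=True):
        wide = grp.pivot_table(
            index="subject", columns="roi_definition", values="ave_li"
        ).dropna()
        if not {"loci", "pcl"} <= set(wide.columns) or len(wide) < 2:
            raise ValueError(f"movement {movement!r}: need >= 2 paired records")
        res = stats.ttest_rel(wide["loci"], wide["pcl"])
        diff = wide["loci"] - wide["pcl"]
        if np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "movement": movement,
                "n": len(wide),
                "df": len(wide) - 1,
                "mean_loci": wide["loci"].mean(),
                "mean_pcl": wide["pcl"].mean(),
                "t": t_stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
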