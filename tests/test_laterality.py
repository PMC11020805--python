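"""Threshold-free AveLI and the ROI-definition comparison."""

import numpy as np
import pytest

from limbloci import simulate as sim
from limbloci.laterality import (
    ave_li,
    ave_li_stroke,
    compare_definitions,
    records_frame,
    roi_laterality,
)


def brute_force_ave_li(t_r, t_l):
    """Independent oracle: explicitly materialise every subLI_i."""
    t_r = [float(v) for v in t_r]
    t_l = [float(v) for v in t_l]
    thresholds = [v for v in t_r + t_l if v > 0]
    if not thresholds:
        return float("nan"), 0
    sublis = []
    for ti in thresholds:
        rt = sum(v for v in t_r if v >= ti)
        lt = sum(v for v in t_l if v >= ti)
        sublis.append((rt - lt) / (rt + lt))
    return sum(sublis) / len(sublis), len(sublis)


def test_worked_example_two_thresholds():
    # thresholds {2, 1, 1}: subLI = 1, 0.5, 0.5 -> AveLI = 2/3
    li, vn = ave_li([2.0, 1.0], [1.0])
    assert li == pytest.approx(2.0 / 3.0)
    assert vn == 3


def test_stroke_worked_example():
    # NP {3}, P {1}: thresholds {3, 1}; subLI = 1 and (3-1)/(3+1) -> AveLI 0.75
    li, vn = ave_li_stroke([3.0], [1.0])
    assert li == pytest.approx(0.75)
    assert vn == 2


def test_one_sided_activation_gives_plus_one():
    li, _ = ave_li([2.0, 0.4, 1.1], [-0.5, -2.0])
    assert li == pytest.approx(1.0)


def test_mirror_symmetric_sets_give_zero():
    vals = [1.5, 0.7, 2.2]
    li, _ = ave_li(vals, vals)
    assert li == pytest.approx(0.0)


def test_no_positive_t_is_undefined():
    li, vn = ave_li([-1.0, -0.2], [-3.0])
    assert np.isnan(li)
    assert vn == 0


def test_antisymmetry_and_scale_invariance():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.normal(0.5, 1.0, size=rng.integers(1, 8))
        b = rng.normal(0.5, 1.0, size=rng.integers(1, 8))
        if not ((a > 0).any() or (b > 0).any()):
            continue
        li_ab, _ = ave_li(a, b)
        li_ba, _ = ave_li(b, a)
        assert li_ab == pytest.approx(-li_ba)
        li_scaled, _ = ave_li(3.7 * a, 3.7 * b)
        assert li_scaled == pytest.approx(li_ab)
        assert -1.0 <= li_ab <= 1.0


def test_matches_brute_force_oracle_on_random_inputs():
    rng = np.random.default_rng(1)
    n_checked = 0
    for _ in range(1000):
        a = rng.normal(0.3, 1.0, size=rng.integers(1, 9))
        b = rng.normal(0.3, 1.0, size=rng.integers(1, 9))
        got, vn_got = ave_li(a, b)
        want, vn_want = brute_force_ave_li(a, b)
        assert vn_got == vn_want
        if vn_want == 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)
            n_checked += 1
    assert n_checked > 800


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    t_sets = st.lists(
        st.floats(-3.0, 3.0, allow_nan=False, width=32), min_size=1, max_size=8
    )

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(a=t_sets, b=t_sets, scale=st.floats(0.125, 8.0))
    def test_ave_li_properties_hypothesis(a, b, scale):
        """Bounds, antisymmetry and positive-scale invariance hold for any
        pair of t-value sets."""
        li, vn = ave_li(a, b)
        if vn == 0:
            assert np.isnan(li)
            return
        assert -1.0 <= li <= 1.0
        assert ave_li(b, a)[0] == pytest.approx(-li, abs=1e-9)
        scaled = ave_li([scale * v for v in a], [scale * v for v in b])[0]
        assert scaled == pytest.approx(li, abs=1e-6)

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_ties_counted_with_multiplicity():
    li, vn = ave_li([1.0, 1.0], [1.0])
    # three identical thresholds, each with Rt=2, Lt=1 -> subLI = 1/3
    assert vn == 3
    assert li == pytest.approx(1.0 / 3.0)


@pytest.fixture(scope="module")
def lat_mask():
    return sim.make_pcl_mask()


def _t_maps(mask, right_amp, left_amp, rng=None, noise=0.0):
    """Movement t maps with hemisphere-specific amplitude + optional noise."""
    maps = {}
    for side, amp in (("right", right_amp), ("left", left_amp)):
        t = np.zeros(mask.grid.shape)
        hemi = "left" if side == "right" else "right"
        t[mask.hemisphere(hemi)] = amp
        if noise and rng is not None:
            t[mask.region] += rng.normal(0, noise, size=mask.n_voxels)
        maps[("toe_flexion", side)] = t
    return maps


def test_contra_only_signal_gives_positive_li(lat_mask):
    maps = _t_maps(lat_mask, right_amp=2.0, left_amp=1.0)
    rec = roi_laterality(maps, lat_mask, "toe_flexion", subject="s0")
    assert rec.defined
    assert rec.ave_li > 0
    assert rec.roi_definition == "pcl"


def test_identical_maps_give_zero_under_both_definitions(lat_mask):
    maps = _t_maps(lat_mask, right_amp=1.5, left_amp=1.5)
    pcl = roi_laterality(maps, lat_mask, "toe_flexion")
    truth = sim.make_ground_truth(lat_mask, sim.SimConfig())
    loci = {}
    for side in ("left", "right"):
        r = np.zeros(lat_mask.grid.shape, dtype=bool)
        r[tuple(truth.loci[("toe_flexion", side)].indices.T)] = True
        loci[("toe_flexion", side)] = r
    loc = roi_laterality(maps, lat_mask, "toe_flexion", loci=loci)
    assert pcl.ave_li == pytest.approx(0.0)
    assert loc.ave_li == pytest.approx(0.0)


def test_empty_locus_yields_undefined_record(lat_mask):
    maps = _t_maps(lat_mask, 1.0, 1.0)
    loci = {("toe_flexion", "right"): np.zeros(lat_mask.grid.shape, dtype=bool)}
    rec = roi_laterality(maps, lat_mask, "toe_flexion", loci=loci)
    assert not rec.defined
    assert rec.reason


def test_stroke_variant_swaps_roles(lat_mask):
    maps = _t_maps(lat_mask, right_amp=2.0, left_amp=0.5)
    a = roi_laterality(
        maps, lat_mask, "toe_flexion", variant="stroke", paretic_side="left"
    )
    b = roi_laterality(
        maps, lat_mask, "toe_flexion", variant="stroke", paretic_side="right"
    )
    assert a.ave_li == pytest.approx(-b.ave_li)


def test_loci_sharpen_laterality_with_focal_signal(lat_mask):
    """Focal contralateral signal + diffuse noise: locus ROIs give a larger
    |AveLI| than the whole PCL in the group mean."""
    rng = np.random.default_rng(3)
    truth = sim.make_ground_truth(lat_mask, sim.SimConfig())
    loci = {}
    for side in ("left", "right"):
        r = np.zeros(lat_mask.grid.shape, dtype=bool)
        r[tuple(truth.loci[("toe_flexion", side)].indices.T)] = True
        loci[("toe_flexion", side)] = r
    records = []
    for i in range(40):
        maps = {}
        for side in ("left", "right"):
            t = np.zeros(lat_mask.grid.shape)
            t[lat_mask.region] = rng.normal(0.0, 1.0, size=lat_mask.n_voxels)
            if side == "right":  # only right-side movement activates its locus
                t[loci[("toe_flexion", side)]] += 3.0
            maps[("toe_flexion", side)] = t
        records.append(
            roi_laterality(maps, lat_mask, "toe_flexion", subject=f"s{i}")
        )
        records.append(
            roi_laterality(maps, lat_mask, "toe_flexion", subject=f"s{i}", loci=loci)
        )
    df = records_frame(records)
    mean_abs = df.groupby("roi_definition").ave_li.apply(lambda s: s.abs().mean())
    assert mean_abs["loci"] > mean_abs["pcl"]
    table = compare_definitions(df)
    assert table.loc[0, "p"] < 0.05


def test_compare_definitions_identical_pairs():
    records = []
    for i, v in enumerate([0.1, 0.3, -0.2, 0.5]):
        for roi in ("pcl", "loci"):
            records.append(
                dict(
                    subject=f"s{i}", movement="toe_flexion", roi_definition=roi,
                    variant="healthy", ave_li=v, vn=10, reason="",
                )
            )
    import pandas as pd

    table = compare_definitions(pd.DataFrame(records))
    assert table.loc[0, "t"] == 0.0
    assert table.loc[0, "p"] == 1.0


def test_compare_definitions_hand_case():
    # paired differences {1,1,2,0,1}: mean 1, sd sqrt(0.5) -> t = 3.1623
    import pandas as pd

    rows = []
    pcl = [0.0, 0.1, 0.2, 0.3, 0.4]
    loci_v = [1.0, 1.1, 2.2, 0.3, 1.4]
    for i, (a, b) in enumerate(zip(pcl, loci_v)):
        rows.append(dict(subject=f"s{i}", movement="m", roi_definition="pcl",
                         variant="healthy", ave_li=a, vn=1, reason=""))
        rows.append(dict(subject=f"s{i}", movement="m", roi_definition="loci",
                         variant="healthy", ave_li=b, vn=1, reason=""))
    table = compare_definitions(pd.DataFrame(rows))
    assert table.loc[0, "t"] == pytest.approx(3.1623, abs=1e-4)
    assert table.loc[0, "df"] == 4


def test_compare_definitions_needs_pairs():
    import pandas as pd

    rows = [
        dict(subject="s0", movement="m", roi_definition="pcl", variant="healthy",
             ave_li=0.1, vn=1, reason=""),
        dict(subject="s0", movement="m", roi_definition="loci", variant="healthy",
             ave_li=0.2, vn=1, reason=""),
    ]
    with pytest.raises(ValueError):
        compare_definitions(pd.DataFrame(rows))
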