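"""Design-matrix construction and per-voxel GLM estimation."""

import numpy as np
import pytest
from scipy import stats

from limbloci import simulate as sim
from limbloci.glm import (
    GLMError,
    build_design,
    double_gamma_hrf,
    fit_glm,
    rm_anova,
)

THREE_BLOCKS = [(20.0, 20.0), (60.0, 20.0), (100.0, 20.0)]


def test_design_has_three_task_columns_and_expected_width():
    motion = np.random.default_rng(0).normal(size=(97, 6)) * 0.01
    d = build_design(THREE_BLOCKS, 97, 1.44, motion, drift_order=2)
    assert d.n_task == 3
    assert d.matrix.shape == (97, 3 + 6 + 3)
    # each task column has support only after its block onset
    t = np.arange(97) * 1.44
    for k, (onset, _) in enumerate(THREE_BLOCKS):
        col = d.task[:, k]
        assert np.allclose(col[t < onset], 0.0, atol=1e-9)
        assert col.max() > 0.1
        assert t[np.argmax(col)] > onset  # haemodynamic lag


def test_zero_motion_columns_are_flagged():
    d = build_design(THREE_BLOCKS, 97, 1.44, np.zeros((97, 6)), 2)
    assert set(d.zero_columns) == {f"motion_{j}" for j in range(1, 7)}


def test_impulse_regressor_equals_sampled_hrf():
    # direct evaluation of the double-gamma closed form as the oracle
    d = build_design([(0.0, 0.0)], 30, 1.0, None, drift_order=0)
    t = np.arange(30) * 1.0
    g = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    fine = np.arange(0, 32, 0.001)
    gf = stats.gamma.pdf(fine, 6) - stats.gamma.pdf(fine, 16) / 6.0
    oracle = g / gf.max()
    assert np.allclose(d.task[:, 0], oracle, atol=1e-3)
    assert abs(double_gamma_hrf(np.arange(0, 32, 0.05)).max() - 1.0) < 1e-12


def test_onset_beyond_run_end_rejected():
    with pytest.raises(ValueError):
        build_design([(200.0, 20.0)], 97, 1.44, None, 2)


@pytest.fixture(scope="module")
def noiseless_fit(mask_module, quiet_module):
    cfg, mask, truth = quiet_module
    subj = sim.simulate_subject(truth, cfg, "healthy", np.random.default_rng(5), "s0")
    run = subj.runs[0]
    design = build_design(run.onsets, run.data.shape[-1], run.tr, run.motion, 2)
    bm = fit_glm(run.data, design, mask)
    scale = 1.0 - subj.true_laterality if run.side == "left" else 1.0 + subj.true_laterality
    amp = truth.amplitude_map(run.movement, run.side, scale)
    return bm, amp[tuple(mask.indices.T)]


@pytest.fixture(scope="module")
def mask_module():
    return sim.make_pcl_mask()


@pytest.fixture(scope="module")
def quiet_module(mask_module):
    cfg = sim.SimConfig(
        noise_sd=0.0, drift_scale=0.0, spike_prob=0.0, motion_walk_sd=0.0,
        dtype="float64", seed=0,
    )
    return cfg, mask_module, sim.make_ground_truth(mask_module, cfg)


def test_noiseless_betas_recover_injected_amplitude(noiseless_fit):
    bm, amp = noiseless_fit
    assert np.abs(bm.avg_beta - amp).max() < 1e-8
    for k in range(3):
        assert np.abs(bm.block_betas[k] - amp).max() < 1e-8


def test_average_beta_is_mean_of_block_betas(noiseless_fit):
    bm, _ = noiseless_fit
    assert np.allclose(bm.avg_beta, bm.block_betas.mean(axis=0))


def test_intercept_shift_invariance(mask_module):
    rng = np.random.default_rng(2)
    n, v = 60, mask_module.n_voxels
    design = build_design([(10.0, 20.0)], n, 2.0, rng.normal(size=(n, 6)) * 0.01, 2)
    y = rng.normal(size=(n, v))
    b0 = fit_glm(y, design, mask_module).block_betas
    b1 = fit_glm(y + 7.5, design, mask_module).block_betas
    assert np.allclose(b0, b1, atol=1e-9)


def test_duplicated_motion_column_raises(mask_module):
    rng = np.random.default_rng(3)
    motion = rng.normal(size=(60, 6))
    motion[:, 5] = motion[:, 4]
    design = build_design([(10.0, 20.0)], 60, 2.0, motion, 1)
    y = rng.normal(size=(60, mask_module.n_voxels))
    with pytest.raises(GLMError, match="motion"):
        fit_glm(y, design, mask_module)


def test_ols_equals_whitened_fit_at_zero_ar(mask_module):
    rng = np.random.default_rng(4)
    design = build_design(THREE_BLOCKS, 97, 1.44, rng.normal(size=(97, 6)) * 0.01, 2)
    y = rng.normal(size=(97, mask_module.n_voxels))
    a = fit_glm(y, design, mask_module, ar1=0.0)
    b = fit_glm(y, design, mask_module, ar1=0.0)
    assert np.allclose(a.block_betas, b.block_betas)
    # whitening with an estimated coefficient near zero stays close to OLS
    c = fit_glm(y, design, mask_module, ar1="auto")
    assert abs(c.ar1) < 0.2
    assert np.allclose(a.block_betas, c.block_betas, atol=0.05)


def test_pure_noise_t_moments(mask_module):
    """t statistics on white noise follow Student's t: mean 0, var df/(df-2)."""
    rng = np.random.default_rng(5)
    design = build_design(THREE_BLOCKS, 97, 1.44, rng.normal(size=(97, 6)) * 0.01, 2)
    t_all = []
    for _ in range(4):
        y = rng.normal(size=(97, mask_module.n_voxels))
        t_all.append(fit_glm(y, design, mask_module).t_avg)
    t = np.concatenate(t_all)
    df = 97 - 12
    assert abs(t.mean()) < 0.05
    assert abs(t.var() - df / (df - 2)) < 0.1


def test_beta_map_sidecar_round_trip(tmp_path, mask_module, quiet_module):
    import json

    cfg, mask, truth = quiet_module
    subj = sim.simulate_subject(truth, cfg, "healthy", np.random.default_rng(8), "s0")
    run = subj.runs[0]
    design = build_design(run.onsets, run.data.shape[-1], run.tr, run.motion, 2)
    bm = fit_glm(run.data, design, mask)
    from limbloci.glm import save_beta_maps
    from limbloci.grid import read_volume

    save_beta_maps(bm, design, tmp_path / "map")
    data, grid = read_volume(tmp_path / "map.beta.nii")
    assert np.allclose(data[tuple(mask.indices.T)], bm.avg_beta, atol=1e-6)
    sidecar = json.loads((tmp_path / "map.json").read_text())
    assert sidecar["tr_s"] == run.tr
    assert sidecar["n_task_regressors"] == 3
    assert sidecar["contrast"] == [1 / 3, 1 / 3, 1 / 3]


def test_rm_anova_flat_data_gives_f_zero():
    betas = np.tile(np.random.default_rng(6).normal(size=(5, 1, 10)), (1, 4, 1))
    f, p = rm_anova(betas)
    assert np.allclose(f, 0.0)
    assert np.allclose(p, 1.0)


def test_rm_anova_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    data = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
    f, p = rm_anova(data[:, :, None])
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(6), 4),
            "task": np.tile(np.arange(4), 6),
            "y": data.ravel(),
        }
    )
    ref = pingouin.rm_anova(data=long, dv="y", within="task", subject="subject")
    assert np.isclose(float(f), ref["F"].iloc[0], rtol=1e-10)
    assert np.isclose(float(p), ref["p_unc"].iloc[0], rtol=1e-8)


def test_rm_anova_detects_strong_task_differences(mask_module, quiet_module):
    cfg, mask, truth = quiet_module
    cfg_noisy = sim.SimConfig(
        noise_sd=1.0, drift_scale=0.0, spike_prob=0.0, motion_walk_sd=0.0, seed=9
    )
    betas = []
    for i, child in enumerate(np.random.SeedSequence(21).spawn(6)):
        subj = sim.simulate_subject(
            truth, cfg_noisy, "healthy", np.random.default_rng(child), f"s{i}"
        )
        per_task = []
        for run in subj.runs:
            if run.side != "left":
                continue
            design = build_design(run.onsets, run.data.shape[-1], run.tr, run.motion, 2)
            per_task.append(fit_glm(run.data, design, mask).avg_beta)
        betas.append(np.stack(per_task))
    f, p = rm_anova(np.stack(betas))
    locus = truth.loci[("ankle_dorsiflexion", "left")]
    sel = np.zeros(mask.grid.shape, dtype=bool)
    sel[tuple(locus.indices.T)] = True
    in_locus = sel[tuple(mask.indices.T)]
    # strong injected differences: locus voxels overwhelmingly below p=.05
    assert (p[in_locus] < 0.05).mean() > 0.9
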