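"""RDM construction, rank-correlation mapping and permutation inference."""

import numpy as np
import pytest
from scipy import stats

from limbloci import simulate as sim
from limbloci.grid import HemiMask, VolumeGrid
from limbloci.rsa import SearchlightRSA, build_rdms, code_rdm, dissimilarity
from limbloci.rsa import permutation_threshold, rsa_map
from limbloci.rsa import test_retest_loci as retest_loci  # alias: not a test


def test_identical_patterns_score_zero():
    assert dissimilarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)


def test_negated_patterns_score_two():
    p = np.array([1.0, 2.0, 3.0])
    assert dissimilarity(p, -p) == pytest.approx(2.0)


def test_hand_computed_pair():
    # Pearson r of (1,2,3) and (1,3,2) is 0.5 -> dissimilarity 0.5
    assert dissimilarity([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)


def test_dissimilarity_bounds_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(2000):
        p = rng.normal(size=7)
        q = rng.normal(size=7)
        d = dissimilarity(p, q)
        assert 0.0 <= d <= 2.0


def test_length_mismatch_and_degenerate_inputs():
    with pytest.raises(ValueError):
        dissimilarity([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        dissimilarity([1, 2], [3, 4])
    # constant pattern: correlation undefined -> midpoint 1.0
    assert dissimilarity([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == pytest.approx(1.0)


def _block_labels():
    labels = []
    for side in ("left", "right"):
        for movement in sorted(sim.MOVEMENTS):
            for b in range(3):
                labels.append((movement, side, b))
    return labels


def test_code_rdm_structure():
    labels = _block_labels()
    code = code_rdm(labels, "toe_flexion", "left")
    assert code.shape == (24, 24)
    iu = np.triu_indices(24, 1)
    vals = code[iu]
    # C(3,2)=3 same-task pairs scored 0; 3*21 mixed pairs scored 1; rest excluded
    assert (vals == 0).sum() == 3
    assert (vals == 1).sum() == 63
    assert np.isnan(vals).sum() == len(vals) - 66
    scored_full = code_rdm(labels, "toe_flexion", "left", score_other_pairs=True)
    assert not np.isnan(scored_full[iu]).any()


def test_build_rdms_shapes_and_degenerate_sphere():
    rng = np.random.default_rng(1)
    labels = _block_labels()
    pair = build_rdms(rng.normal(size=(24, 10)), labels, "toe_flexion", "left")
    assert pair.neural.shape == (24, 24)
    assert np.allclose(pair.neural, pair.neural.T)
    assert np.allclose(np.diag(pair.neural), 0.0)
    assert ((pair.neural >= 0) & (pair.neural <= 2)).all()
    with pytest.raises(ValueError, match="degenerate sphere"):
        build_rdms(rng.normal(size=(24, 2)), labels, "toe_flexion", "left")


def test_identical_condition_patterns_give_zero_rdm():
    labels = _block_labels()
    patterns = np.tile(np.arange(8.0), (24, 1))
    pair = build_rdms(patterns, labels, "toe_flexion", "left")
    assert np.allclose(pair.neural, 0.0)


def _toy_mask(n=8):
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[0, 3] = -3.0 * n / 2 + 1.5
    grid = VolumeGrid(shape=(n, n, n), affine=affine)
    return HemiMask.from_region(np.ones(grid.shape, dtype=bool), grid)


def test_rho_is_one_when_neural_matches_code():
    """A neural RDM built to mirror the code RDM ranks gives rho = 1."""
    labels = _block_labels()
    code = code_rdm(labels, "toe_flexion", "left")
    neural = np.where(np.isnan(code), 0.5, code) * 1.7  # monotone in the code
    rdms = [np.stack([neural])]  # one subject, one "voxel"
    group, per = rsa_map(rdms, labels, "toe_flexion", "left")
    assert group[0] == pytest.approx(1.0)
    assert per.shape == (1, 1)


def test_rho_invariant_to_monotone_transform():
    rng = np.random.default_rng(2)
    labels = _block_labels()
    neural = np.abs(rng.normal(size=(24, 24)))
    neural = (neural + neural.T) / 2
    np.fill_diagonal(neural, 0.0)
    g1, _ = rsa_map([np.stack([neural])], labels, "toe_flexion", "left")
    g2, _ = rsa_map([np.stack([np.sqrt(neural)])], labels, "toe_flexion", "left")
    assert g1[0] == pytest.approx(g2[0])


def test_rho_matches_scipy_spearman():
    rng = np.random.default_rng(3)
    labels = _block_labels()
    code = code_rdm(labels, "toe_flexion", "left")
    neural = np.abs(rng.normal(size=(24, 24)))
    neural = (neural + neural.T) / 2
    np.fill_diagonal(neural, 0.0)
    group, _ = rsa_map([np.stack([neural])], labels, "toe_flexion", "left")
    iu = np.triu_indices(24, 1)
    sel = ~np.isnan(code[iu])
    ref = stats.spearmanr(neural[iu][sel], code[iu][sel]).statistic
    assert group[0] == pytest.approx(ref)


def test_noise_patterns_give_near_zero_group_map():
    rng = np.random.default_rng(4)
    labels = _block_labels()
    mask = _toy_mask(6)
    sl = SearchlightRSA(mask, radius_vox=1)
    rdms = [
        sl.subject_rdms(rng.normal(size=(24, mask.n_voxels))) for _ in range(6)
    ]
    group, _ = rsa_map(rdms, labels, "toe_flexion", "left")
    assert abs(group.mean()) < 0.02


def test_permutation_threshold_validates_n_perm():
    labels = _block_labels()
    rdms = [np.zeros((1, 24, 24))]
    with pytest.raises(ValueError):
        permutation_threshold(rdms, labels, "toe_flexion", "left", n_perm=50)
    with pytest.raises(ValueError):
        permutation_threshold(
            rdms, labels, "toe_flexion", "left", n_perm=100, alpha=0.001
        )


def test_null_rank_is_uniform_under_exchangeability():
    """With pure-noise RDMs, the observed max statistic ranks uniformly in
    its own permutation null (p-p straightness via a KS test)."""
    rng = np.random.default_rng(5)
    labels = _block_labels()
    pits = []
    for _ in range(60):
        neural = np.abs(rng.normal(size=(3, 24, 24)))
        neural = (neural + neural.transpose(0, 2, 1)) / 2
        for k in range(3):
            np.fill_diagonal(neural[k], 0.0)
        rdms = [neural[k][None] for k in range(3)]
        res = permutation_threshold(
            rdms, labels, "toe_flexion", "left", n_perm=120, alpha=0.05,
            seed=int(rng.integers(1 << 30)),
        )
        obs = res.observed.max()
        pits.append((res.null_max < obs).mean())
    assert stats.kstest(pits, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def injected_cohort():
    """Small cohort with known loci, GLM-fit and converted to RDM stacks."""
    from limbloci import glm
    from limbloci.rsa import condition_patterns

    cfg = sim.SimConfig(seed=20, spike_prob=0.0)
    mask = sim.make_pcl_mask()
    truth = sim.make_ground_truth(mask, cfg)
    sl = SearchlightRSA(mask, radius_vox=2)
    rdms, labels = [], None
    for i, child in enumerate(np.random.SeedSequence(20).spawn(8)):
        s = sim.simulate_subject(
            truth, cfg, "healthy", np.random.default_rng(child), f"s{i}"
        )
        pat, labels = condition_patterns(glm.fit_subject(s, mask))
        rdms.append(sl.subject_rdms(pat))
    return mask, truth, rdms, labels


def test_group_map_concentrates_on_true_locus(injected_cohort):
    """rho-weighted centre of mass of the top map voxels lands within two
    voxels of the injected locus centre, for every movement."""
    mask, truth, rdms, labels = injected_cohort
    for movement in sim.MOVEMENTS:
        group, _ = rsa_map(rdms, labels, movement, "left")
        top = group >= np.quantile(group, 0.95)
        mni = mask.grid.to_mni(mask.indices[top])
        w = group[top]
        com = (mni * w[:, None]).sum(axis=0) / w.sum()
        center = truth.loci[(movement, "left")].center_mni
        assert np.linalg.norm((com - center) / 3.0) <= 2.0


def test_injected_locus_is_significant_and_distant_voxels_not(injected_cohort):
    mask, truth, rdms, labels = injected_cohort
    res = permutation_threshold(
        rdms, labels, "knee_extension", "left", n_perm=300, alpha=0.01, seed=1
    )
    assert res.significant.any()
    locus = truth.loci[("knee_extension", "left")]
    near = np.zeros(mask.grid.shape, dtype=bool)
    near[tuple(locus.indices.T)] = True
    sig_mni = mask.grid.to_mni(mask.indices[res.significant])
    dists = np.linalg.norm(sig_mni - locus.center_mni, axis=1)
    # significant voxels concentrate around the injected locus
    assert np.median(dists) < 15.0


def test_alpha_monotonicity(injected_cohort):
    mask, truth, rdms, labels = injected_cohort
    loose = permutation_threshold(
        rdms, labels, "knee_extension", "left", n_perm=300, alpha=0.05, seed=2
    )
    strict = permutation_threshold(
        rdms, labels, "knee_extension", "left", n_perm=300, alpha=0.01, seed=2
    )
    assert (strict.significant <= loose.significant).all()


def test_retest_split_validation(injected_cohort):
    mask, truth, rdms, labels = injected_cohort
    with pytest.raises(ValueError, match="split"):
        retest_loci(
            rdms, labels, mask, "toe_flexion", "left", split=(5, 5), n_perm=100
        )


def test_retest_identical_subjects_give_all_or_nothing_counts(injected_cohort):
    mask, truth, rdms, labels = injected_cohort
    clones = [rdms[0]] * 8  # identical data in every subject
    res = retest_loci(
        clones, labels, mask, "ankle_rotation", "left", n_reps=3, split=(4, 4),
        n_perm=150, alpha=0.02, persistence_cutoff=3, seed=3,
    )
    assert set(np.unique(res.counts)) <= {0, 3}
    assert (res.sig_a == res.sig_b).all()


def test_retest_noise_only_cohort_yields_empty_loci():
    rng = np.random.default_rng(6)
    labels = _block_labels()
    mask = _toy_mask(6)
    sl = SearchlightRSA(mask, radius_vox=1)
    rdms = [
        sl.subject_rdms(rng.normal(size=(24, mask.n_voxels))) for _ in range(8)
    ]
    res = retest_loci(
        rdms, labels, mask, "toe_flexion", "left", n_reps=3, split=(4, 4),
        n_perm=200, alpha=0.01, persistence_cutoff=3, seed=4,
    )
    assert len(res.loci) == 0
    assert res.counts.max() == 0
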