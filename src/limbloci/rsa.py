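"""Searchlight representational similarity analysis (RSA) with permutation
FWE correction and test-retest persistence.

For every mask voxel a neural representational dissimilarity matrix (RDM) is
built over task x block conditions from the multivoxel beta patterns in a
3-voxel-radius sphere, with dissimilarity 1 - Pearson r (range [0, 2]).  A
binary code RDM singles out one movement of interest: pairs within that
movement score 0 (same task), pairs between it and any other task score 1,
and pairs among the other tasks are excluded from scoring (a switch scores
them 1 instead).  The movement-specificity map is the Spearman rank
correlation between the two RDMs, computed per subject and averaged.

Significance is family-wise corrected by a max-statistic permutation null:
the condition labels are shuffled (the same shuffle for every subject), the
group map recomputed and its mask-wide maximum recorded.  Final loci must
replicate: over repeated random splits of the cohort into two sub-groups,
only voxels whose significance overlaps in both halves more than a cutoff
number of repetitions survive, and surviving voxels are reported as clusters
of at least five voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grid import ClusterTable, HemiMask, extract_clusters, neighborhood, sphere_offsets

__all__ = [
    "dissimilarity",
    "code_rdm",
    "RDMPair",
    "build_rdms",
    "condition_patterns",
    "SearchlightRSA",
    "rsa_map",
    "permutation_threshold",
    "test_retest_loci",
    "identify_loci",
    "PersistenceResult",
]


def dissimilarity(p, q) -> float:
    """1 - Pearson correlation of two patterns: 0 identical, 2 opposite.

    A zero-variance (constant) pattern has no defined correlation; such pairs
    score 1.0, the uninformative midpoint.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("patterns must be 1-D vectors of equal length")
    if len(p) < 3:
        raise ValueError("patterns need at least 3 voxels")
    pc, qc = p - p.mean(), q - q.mean()
    denom = np.linalg.norm(pc) * np.linalg.norm(qc)
    if denom == 0:
        return 1.0
    return float(1.0 - (pc @ qc) / denom)


def _task_of(label) -> tuple:
    """(movement, side) part of a condition label (movement, side[, block])."""
    return tuple(label[:2])


def code_rdm(
    labels, movement: str, side: str, score_other_pairs: bool = False
) -> np.ndarray:
    """Binary code RDM for one movement of interest; excluded pairs are NaN.

    0 = both conditions belong to the movement of interest (same task),
    1 = one does and the other is any other task; pairs among other tasks
    are excluded unless ``score_other_pairs``.
    """
    interest = np.array([_task_of(l) == (movement, side) for l in labels])
    if interest.sum() < 2:
        raise ValueError(
            f"need >= 2 conditions of movement of interest {(movement, side)!r}"
        )
    n = len(labels)
    out = np.full((n, n), np.nan)
    ii = interest[:, None] & interest[None, :]
    mixed = interest[:, None] ^ interest[None, :]
    out[ii] = 0.0
    out[mixed] = 1.0
    if score_other_pairs:
        out[~(ii | mixed)] = 1.0
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class RDMPair:
    labels: list
    neural: np.ndarray
    code: np.ndarray  # NaN entries are excluded from scoring
    movement: str
    side: str


def _rdm_from_patterns(patterns: np.ndarray) -> np.ndarray:
    """(n_cond, k) pattern matrix -> (n_cond, n_cond) 1 - Pearson RDM.

    Zero-variance patterns correlate 0 with everything (dissimilarity 1).
    """
    x = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    r = (x @ x.T) / np.outer(safe, safe)
    r[norms == 0, :] = 0.0
    r[:, norms == 0] = 0.0
    rdm = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(rdm, 0.0)
    return rdm


def build_rdms(
    patterns: np.ndarray,
    labels,
    movement: str,
    side: str,
    score_other_pairs: bool = False,
) -> RDMPair:
    """Neural + code RDM pair for one searchlight sphere.

    ``patterns`` is (n_conditions, sphere_voxels), one multivoxel pattern per
    condition.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] != len(labels):
        raise ValueError("patterns must be (n_conditions, sphere_voxels)")
    if patterns.shape[1] < 3:
        raise ValueError("degenerate sphere: fewer than 3 voxels")
    return RDMPair(
        labels=list(labels),
        neural=_rdm_from_patterns(patterns),
        code=code_rdm(labels, movement, side, score_other_pairs),
        movement=movement,
        side=side,
    )


def condition_patterns(subject_maps: dict, mode: str = "block"):
    """Per-condition beta patterns over the mask voxels for one subject.

    ``subject_maps`` maps (movement, side) -> BetaMaps.  Block mode yields
    (movement, side, block) conditions (24 for a complete subject); run mode
    yields one average-beta condition per task.
    """
    labels, rows = [], []
    for (movement, side), bm in sorted(subject_maps.items()):
        if mode == "block":
            for b, beta in enumerate(bm.block_betas):
                labels.append((movement, side, b))
                rows.append(beta)
        elif mode == "run":
            labels.append((movement, side))
            rows.append(bm.avg_beta)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return np.stack(rows), labels


class SearchlightRSA:
    """Precomputed searchlight geometry + per-subject RDM stacks."""

    def __init__(self, mask: HemiMask, radius_vox: int = 3):
        self.mask = mask
        self.radius_vox = radius_vox
        idx = mask.indices
        col_of = np.full(mask.grid.shape, -1, dtype=int)
        col_of[tuple(idx.T)] = np.arange(len(idx))
        offs = sphere_offsets(radius_vox)
        self.neighborhoods = [
            col_of[tuple(neighborhood(center, offs, mask).T)] for center in idx
        ]

    def subject_rdms(self, patterns: np.ndarray) -> np.ndarray:
        """(n_cond, V_mask) betas -> (V_mask, n_cond, n_cond) neural RDMs."""
        patterns = np.asarray(patterns, dtype=float)
        n = patterns.shape[0]
        out = np.empty((len(self.neighborhoods), n, n))
        for vi, cols in enumerate(self.neighborhoods):
            out[vi] = _rdm_from_patterns(patterns[:, cols])
        return out


def _scored_pairs(interest: np.ndarray, iu, score_other_pairs: bool):
    ii = interest[iu[0]]
    jj = interest[iu[1]]
    within = ii & jj
    mixed = ii ^ jj
    sel = (within | mixed) if not score_other_pairs else np.ones_like(within)
    rows, cols = iu[0][sel], iu[1][sel]
    code = np.where(within[sel], 0.0, 1.0)
    return rows, cols, code


def _rho_stack(rdms: np.ndarray, rows, cols, code) -> np.ndarray:
    """Spearman rho per voxel between scored neural entries and the code.

    The code RDM is binary, so its ranks are an affine function of the values
    and the rank correlation reduces to Pearson(rank(neural), code).
    """
    vals = rdms[:, rows, cols]  # (V, m)
    ranks = rankdata(vals, axis=1)
    yc = code - code.mean()
    y_ss = float(yc @ yc)
    if y_ss == 0:
        raise ValueError("code RDM has no scored contrast")
    xc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * y_ss)
    num = xc @ yc
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


def _interest_vector(labels, movement, side) -> np.ndarray:
    v = np.array([_task_of(l) == (movement, side) for l in labels])
    if v.sum() < 2:
        raise ValueError(f"movement of interest {(movement, side)!r} has < 2 conditions")
    return v


def rsa_map(
    subject_rdms: list[np.ndarray],
    labels,
    movement: str,
    side: str,
    score_other_pairs: bool = False,
):
    """Group (mean over subjects) and per-subject movement-specificity maps."""
    n = len(labels)
    iu = np.triu_indices(n, 1)
    interest = _interest_vector(labels, movement, side)
    rows, cols, code = _scored_pairs(interest, iu, score_other_pairs)
    per_subject = np.stack([_rho_stack(r, rows, cols, code) for r in subject_rdms])
    return per_subject.mean(axis=0), per_subject


@dataclass
class SigResult:
    significant: np.ndarray  # (V,) bool
    observed: np.ndarray  # (V,) group rho
    threshold: float
    null_max: np.ndarray  # (n_perm,)


def _draw_interests(labels, movement, side, n_perm, rng):
    """Interest vectors under condition-label shuffles (same shuffle for all
    subjects): condition i takes the label of condition perm[i]."""
    base = _interest_vector(labels, movement, side)
    out = np.empty((n_perm, len(base)), dtype=bool)
    for p in range(n_perm):
        out[p] = base[rng.permutation(len(base))]
    return out


def permutation_threshold(
    subject_rdms: list[np.ndarray],
    labels,
    movement: str,
    side: str,
    n_perm: int = 10000,
    alpha: float = 0.01,
    seed: int = 0,
    score_other_pairs: bool = False,
) -> SigResult:
    """Max-statistic FWE threshold from condition-label permutations.

    A voxel is significant when its observed group rho exceeds the
    (1 - alpha) quantile of the permutation distribution of the mask-wide
    maximum group rho.
    """
    if n_perm < 100 or n_perm * alpha < 1:
        raise ValueError("n_perm too small for the requested alpha")
    n = len(labels)
    iu = np.triu_indices(n, 1)
    observed, _ = rsa_map(subject_rdms, labels, movement, side, score_other_pairs)
    rng = np.random.default_rng(seed)
    interests = _draw_interests(labels, movement, side, n_perm, rng)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        rows, cols, code = _scored_pairs(interests[p], iu, score_other_pairs)
        group = np.mean(
            [_rho_stack(r, rows, cols, code) for r in subject_rdms], axis=0
        )
        null_max[p] = group.max()
    threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    return SigResult(
        significant=observed > threshold,
        observed=observed,
        threshold=threshold,
        null_max=null_max,
    )


@dataclass
class PersistenceResult:
    counts: np.ndarray  # (V,) overlap persistence over repetitions
    overlaps: np.ndarray  # (n_reps, V) bool
    sig_a: np.ndarray  # (n_reps, V) significance in the test half
    sig_b: np.ndarray  # (n_reps, V) significance in the retest half
    loci: ClusterTable
    final_mask: np.ndarray  # (V,) bool: persistent voxels in >= cutoff reps
    persistence_cutoff: int
    movement: str
    side: str


def test_retest_loci(
    subject_rdms: list[np.ndarray],
    labels,
    mask: HemiMask,
    movement: str,
    side: str,
    n_reps: int = 10,
    split: tuple[int, int] = (10, 11),
    n_perm: int = 10000,
    alpha: float = 0.01,
    persistence_cutoff: int = 8,
    min_cluster: int = 5,
    seed: int = 0,
    score_other_pairs: bool = False,
) -> PersistenceResult:
    """Persistent movement loci over repeated random test/retest splits.

    Each repetition splits the cohort into two sub-groups, thresholds each
    half's group map with its own max-statistic null, and takes the voxelwise
    conjunction.  Voxels whose conjunction recurs in at least
    ``persistence_cutoff`` of ``n_reps`` repetitions (default 8/10, the
    strict reading of "more than seven times") form the final loci, as
    connected clusters of at least ``min_cluster`` voxels.

    One seeded pool of label permutations is shared across repetitions and
    halves; each half's null is the max over that half's subject-mean maps
    (permutations are exchangeable, so reuse is valid and lets per-subject
    permuted maps be computed once per permutation).
    """
    n_subj = len(subject_rdms)
    if sum(split) != n_subj:
        raise ValueError(f"split {split} does not sum to cohort size {n_subj}")
    if n_perm < 100 or n_perm * alpha < 1:
        raise ValueError("n_perm too small for the requested alpha")

    n = len(labels)
    iu = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(n_reps):
        order = rng.permutation(n_subj)
        halves.append((np.sort(order[: split[0]]), np.sort(order[split[0] :])))

    interest = _interest_vector(labels, movement, side)
    rows, cols, code = _scored_pairs(interest, iu, score_other_pairs)
    observed = np.stack([_rho_stack(r, rows, cols, code) for r in subject_rdms])

    interests = _draw_interests(labels, movement, side, n_perm, rng)
    null_max = np.zeros((n_reps, 2, n_perm))
    for p in range(n_perm):
        prows, pcols, pcode = _scored_pairs(interests[p], iu, score_other_pairs)
        per_subj = np.stack(
            [_rho_stack(r, prows, pcols, pcode) for r in subject_rdms]
        )
        for rep, (a, b) in enumerate(halves):
            null_max[rep, 0, p] = per_subj[a].mean(axis=0).max()
            null_max[rep, 1, p] = per_subj[b].mean(axis=0).max()

    n_vox = observed.shape[1]
    sig_a = np.zeros((n_reps, n_vox), dtype=bool)
    sig_b = np.zeros((n_reps, n_vox), dtype=bool)
    for rep, (a, b) in enumerate(halves):
        thr_a = np.quantile(null_max[rep, 0], 1.0 - alpha, method="higher")
        thr_b = np.quantile(null_max[rep, 1], 1.0 - alpha, method="higher")
        sig_a[rep] = observed[a].mean(axis=0) > thr_a
        sig_b[rep] = observed[b].mean(axis=0) > thr_b
    overlaps = sig_a & sig_b
    counts = overlaps.sum(axis=0)
    final = counts >= persistence_cutoff

    raster = np.zeros(mask.grid.shape, dtype=bool)
    raster[tuple(mask.indices.T)] = final
    stat = np.zeros(mask.grid.shape)
    stat[tuple(mask.indices.T)] = observed.mean(axis=0)
    loci = extract_clusters(
        raster, min_cluster, mask.grid, stat_map=stat, movement=movement, side=side
    )
    kept = np.zeros(mask.grid.shape, dtype=bool)
    for c in loci.clusters:
        kept[tuple(c.indices.T)] = True
    return PersistenceResult(
        counts=counts,
        overlaps=overlaps,
        sig_a=sig_a,
        sig_b=sig_b,
        loci=loci,
        final_mask=kept[tuple(mask.indices.T)],
        persistence_cutoff=persistence_cutoff,
        movement=movement,
        side=side,
    )


def identify_loci(
    subject_rdms: list[np.ndarray],
    labels,
    mask: HemiMask,
    movements,
    sides=("left", "right"),
    **kwargs,
) -> dict:
    """Run test-retest persistence for every movement x side."""
    return {
        (m, s): test_retest_loci(subject_rdms, labels, mask, m, s, **kwargs)
        for s in sides
        for m in movements
    }
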