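"""Synthetic block-design motor fMRI cohorts with known ground truth.

The generator emulates the study structure the analysis assumes: per subject,
eight runs (4 lower-limb movements x 2 sides), each 3 task blocks of 20 s
interleaved with 20 s rest; TR 1.44 s for healthy subjects and 2.0 s for the
stroke group; 3 mm isotropic voxels on a small paracentral-lobule (PCL)
fixture mask straddling the midline.  Each movement owns a Gaussian-profile
locus in the contralateral medial wall, ordered along the superior-inferior
axis following the cortical homunculus (toe most inferior, then ankle
dorsiflexion, ankle rotation, knee extension most superior, shifted slightly
posterior).  BOLD = baseline + (boxcar (x) canonical HRF) x amplitude map
+ polynomial drift + AR(1) noise; motion traces are slow random walks with
occasional one-volume spikes.

Healthy subjects draw a right-vs-left amplitude asymmetry (their true
laterality); stroke subjects draw a non-paretic-vs-paretic laterality that is
linearly coupled to a synthetic Fugl-Meyer (FMA) score on the paretic side,
so the downstream laterality/association stages have recoverable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .glm import build_design
from .grid import HemiMask, VolumeGrid

__all__ = [
    "MOVEMENTS",
    "SIDES",
    "SimConfig",
    "ConfigError",
    "make_grid",
    "make_pcl_mask",
    "Locus",
    "GroundTruth",
    "make_ground_truth",
    "Run",
    "SubjectDataset",
    "simulate_subject",
    "Cohort",
    "simulate_cohort",
]

# somatotopic order, inferior -> superior along the medial wall
MOVEMENTS = ("toe_flexion", "ankle_dorsiflexion", "ankle_rotation", "knee_extension")
SIDES = ("left", "right")
STROKE_SUBSET = ("ankle_dorsiflexion", "toe_flexion")  # movements all stroke subjects perform


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Cohort sizes, block design and TRs mirror the study setup; amplitude,
    noise and coupling values are the generator's calibrated defaults
    (documented in docs/methods.md).
    """

    n_healthy1: int = 21
    n_healthy2: int = 11
    n_stroke: int = 15
    n_stroke_complete: int = 6  # stroke subjects performing all four movements
    tr_healthy: float = 1.44
    tr_stroke: float = 2.0
    n_blocks: int = 3
    block_s: float = 20.0
    rest_s: float = 20.0
    baseline: float = 100.0
    amp_contra: float = 1.5
    amp_ipsi: float = 0.3
    noise_sd: float = 1.0
    ar1: float = 0.3
    drift_order: int = 2
    drift_scale: float = 0.5
    motion_walk_sd: float = 0.004  # mm (or deg) per volume, random-walk step
    spike_prob: float = 0.002  # per-volume probability of a one-volume spike
    spike_mm: tuple[float, float] = (0.6, 1.5)
    block_amplitudes: tuple | None = None  # per-block signal multipliers
    locus_sigma_mm: float = 3.0
    locus_radius_mm: float = 6.0
    knee_posterior_shift_mm: float = 3.0
    disjoint_loci: bool = False
    healthy_asym_mean: float = 0.12
    healthy_asym_sd: float = 0.25
    stroke_lat_range: tuple[float, float] = (-0.8, 0.8)
    fma_intercept: float = 17.0
    fma_slope: float = 10.0  # laterality -> paretic-side FMA coupling
    fma_noise_sd: float = 3.0
    fma_max: float = 34.0  # lower-extremity FMA range, clamped
    fma_nonparetic_mean: float = 33.0
    fma_nonparetic_sd: float = 1.0
    dtype: str = "float32"  # run-raster storage; float64 for exactness checks
    seed: int = 0

    def __post_init__(self):
        if min(self.block_s, self.rest_s, self.tr_healthy, self.tr_stroke) <= 0:
            raise ConfigError("all durations must be positive")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ConfigError("spike_prob must be a probability")
        if self.n_blocks < 1:
            raise ConfigError("need at least one task block")

    @property
    def onsets(self) -> list[tuple[float, float]]:
        """Task-block (start_s, duration_s), leading rest then alternation."""
        return [
            (self.rest_s + k * (self.block_s + self.rest_s), self.block_s)
            for k in range(self.n_blocks)
        ]

    @property
    def run_duration_s(self) -> float:
        return self.n_blocks * self.block_s + (self.n_blocks + 1) * self.rest_s

    def n_volumes(self, tr: float) -> int:
        return int(np.floor(self.run_duration_s / tr))


def make_grid(shape=(12, 12, 24), voxel_mm: float = 3.0) -> VolumeGrid:
    """Analysis grid with voxel centres on a half-voxel MNI lattice.

    The x origin is chosen so no voxel centre sits at x = 0: hemispheres are
    cleanly separated by the midline.
    """
    nx, ny, nz = shape
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[0, 3] = -voxel_mm * nx / 2 + voxel_mm / 2
    affine[1, 3] = -voxel_mm * ny / 2 + voxel_mm / 2 + 30.0
    affine[2, 3] = voxel_mm / 2 + 24.0
    return VolumeGrid(shape=shape, affine=affine)


def make_pcl_mask(
    grid: VolumeGrid | None = None,
    x_extent_mm: float = 8.0,
    y_extent_mm: tuple[float, float] = (21.0, 39.0),
    z_extent_mm: tuple[float, float] = (30.0, 90.0),
) -> HemiMask:
    """Fixture paracentral-lobule mask: a medial-wall slab on both sides of
    the midline, labelled 1 = left hemisphere, 2 = right."""
    grid = grid or make_grid()
    idx = np.indices(grid.shape).reshape(3, -1).T
    mni = grid.to_mni(idx)
    keep = (
        (np.abs(mni[:, 0]) <= x_extent_mm)
        & (mni[:, 1] >= y_extent_mm[0])
        & (mni[:, 1] <= y_extent_mm[1])
        & (mni[:, 2] >= z_extent_mm[0])
        & (mni[:, 2] <= z_extent_mm[1])
    )
    region = np.zeros(grid.shape, dtype=bool)
    region[tuple(idx[keep].T)] = True
    return HemiMask.from_region(region, grid)


@dataclass
class Locus:
    movement: str
    limb_side: str  # side of the moving limb; the locus is contralateral
    center_mni: np.ndarray
    indices: np.ndarray  # (k, 3) member voxels
    weights: np.ndarray  # (k,) Gaussian spatial profile, 1 at the centre


@dataclass
class GroundTruth:
    """True movement loci plus the injected amplitudes."""

    loci: dict[tuple[str, str], Locus]
    amp_contra: float
    amp_ipsi: float
    mask: HemiMask

    def centroid_z(self, movement: str, limb_side: str) -> float:
        loc = self.loci[(movement, limb_side)]
        return float(self.mask.grid.to_mni(loc.indices)[:, 2].mean())

    def amplitude_map(
        self, movement: str, limb_side: str, contra_scale: float = 1.0
    ) -> np.ndarray:
        """Spatial amplitude raster for one task: the contralateral locus at
        ``amp_contra * contra_scale`` plus a weaker mirror (ipsilateral)
        response at the same movement's opposite-limb locus."""
        amp = np.zeros(self.mask.grid.shape)
        contra = self.loci[(movement, limb_side)]
        amp[tuple(contra.indices.T)] += self.amp_contra * contra_scale * contra.weights
        other = "left" if limb_side == "right" else "right"
        ipsi = self.loci[(movement, other)]
        amp[tuple(ipsi.indices.T)] += self.amp_ipsi * ipsi.weights
        return amp


# fractions of the mask z-span at which each movement's locus centre sits
_Z_FRACTIONS = {
    "toe_flexion": 0.15,
    "ankle_dorsiflexion": 0.40,
    "ankle_rotation": 0.62,
    "knee_extension": 0.85,
}


def make_ground_truth(mask: HemiMask, config: SimConfig) -> GroundTruth:
    """Place the four loci per side along the superior-inferior axis of the
    contralateral medial wall (toe inferior ... knee superior-posterior)."""
    grid = mask.grid
    for side in SIDES:
        if mask.hemisphere(side).sum() < 40:
            raise ConfigError(f"{side} hemisphere of the mask has < 40 voxels")

    hemi_mni = {s: grid.to_mni(np.argwhere(mask.hemisphere(s))) for s in SIDES}
    hemi_idx = {s: np.argwhere(mask.hemisphere(s)) for s in SIDES}
    loci: dict[tuple[str, str], Locus] = {}
    for limb_side in SIDES:
        hemi = "right" if limb_side == "left" else "left"  # contralateral
        mni = hemi_mni[hemi]
        zlo, zhi = mni[:, 2].min(), mni[:, 2].max()
        if zhi - zlo < 4 * grid.voxel_size_mm[2]:
            raise ConfigError("mask z-span too small to order four loci")
        x_c = float(np.median(mni[:, 0]))
        y_c = float(np.median(mni[:, 1]))
        centers = {}
        for movement in MOVEMENTS:
            z_c = zlo + _Z_FRACTIONS[movement] * (zhi - zlo)
            y_m = y_c - (
                config.knee_posterior_shift_mm if movement == "knee_extension" else 0.0
            )
            centers[movement] = np.array([x_c, y_m, z_c])
        nearest = None
        if config.disjoint_loci:
            cen = np.stack([centers[m] for m in MOVEMENTS])
            nearest = np.argmin(
                ((mni[:, None, :] - cen[None]) ** 2).sum(axis=2), axis=1
            )
        for mi, movement in enumerate(MOVEMENTS):
            d2 = ((mni - centers[movement]) ** 2).sum(axis=1)
            member = d2 <= config.locus_radius_mm**2
            if nearest is not None:
                member &= nearest == mi
            if member.sum() < 1:
                raise ConfigError(
                    f"mask too small: empty locus for {movement}/{limb_side}"
                )
            loci[(movement, limb_side)] = Locus(
                movement=movement,
                limb_side=limb_side,
                center_mni=centers[movement],
                indices=hemi_idx[hemi][member],
                weights=np.exp(-d2[member] / (2 * config.locus_sigma_mm**2)),
            )
    truth = GroundTruth(
        loci=loci, amp_contra=config.amp_contra, amp_ipsi=config.amp_ipsi, mask=mask
    )
    for limb_side in SIDES:
        zs = [truth.centroid_z(m, limb_side) for m in MOVEMENTS]
        if not all(a < b for a, b in zip(zs, zs[1:])):
            raise ConfigError("locus centroids do not honour the somatotopic order")
    return truth


@dataclass
class Run:
    movement: str
    side: str
    data: np.ndarray  # 4-D (x, y, z, t) float32
    onsets: list[tuple[float, float]]
    tr: float
    motion: np.ndarray  # (t, 6): roll, pitch, yaw (deg), dS, dL, dP (mm)
    spike_volumes: np.ndarray  # ground truth: volumes carrying a motion spike


@dataclass
class SubjectDataset:
    subject_id: str
    group: str  # 'healthy' or 'stroke'
    dataset: str  # 'healthy1', 'healthy2' or 'stroke'
    runs: list[Run]
    true_laterality: float
    paretic_side: str | None = None
    fma: dict[tuple[str, str], float] = field(default_factory=dict)
    # fma keys: (movement, 'paretic'|'nonparetic')


def _motion_trace(n_vols: int, config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    walk = np.cumsum(rng.normal(0.0, config.motion_walk_sd, size=(n_vols, 6)), axis=0)
    spikes = np.zeros(n_vols, dtype=bool)
    if config.spike_prob > 0:
        spikes[1:] = rng.random(n_vols - 1) < config.spike_prob
    for v in np.flatnonzero(spikes):
        j = int(rng.integers(3, 6))  # spike mainly in a translation axis
        mag = rng.uniform(*config.spike_mm) * (1 if rng.random() < 0.5 else -1)
        walk[v, j] += mag
        walk[v, rng.integers(0, 3)] += 0.2 * mag  # small rotational component
    return walk, np.flatnonzero(spikes)


def _ar1_noise(shape, sd: float, rho: float, rng) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 1e-12)), size=shape)
    return lfilter([1.0], [1.0, -rho], innov, axis=0)


def _simulate_run(
    truth: GroundTruth,
    config: SimConfig,
    movement: str,
    side: str,
    tr: float,
    contra_scale: float,
    rng,
) -> Run:
    grid = truth.mask.grid
    n_vols = config.n_volumes(tr)
    motion, spike_vols = _motion_trace(n_vols, config, rng)
    design = build_design(config.onsets, n_vols, tr, None, config.drift_order)
    if config.block_amplitudes is None:
        task = design.task.sum(axis=1)  # equal amplitude in every block
    else:
        if len(config.block_amplitudes) != config.n_blocks:
            raise ConfigError("block_amplitudes must have one entry per block")
        task = design.task @ np.asarray(config.block_amplitudes, dtype=float)
    amp = truth.amplitude_map(movement, side, contra_scale).ravel()
    v = amp.size
    bold = config.baseline + task[:, None] * amp[None, :]
    if config.drift_scale > 0 and config.drift_order > 0:
        x = np.linspace(-1.0, 1.0, n_vols)
        basis = np.stack(
            [
                np.polynomial.legendre.Legendre.basis(k)(x)
                for k in range(1, config.drift_order + 1)
            ]
        )
        basis -= basis.mean(axis=1, keepdims=True)
        coef = rng.normal(0.0, config.drift_scale, size=(config.drift_order, v))
        bold += basis.T @ coef
    bold += _ar1_noise((n_vols, v), config.noise_sd, config.ar1, rng)
    data = np.moveaxis(bold.reshape(n_vols, *grid.shape), 0, -1).astype(config.dtype)
    return Run(
        movement=movement,
        side=side,
        data=data,
        onsets=config.onsets,
        tr=tr,
        motion=motion,
        spike_volumes=spike_vols,
    )


def simulate_subject(
    truth: GroundTruth,
    config: SimConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-00",
    dataset: str | None = None,
    paretic_side: str | None = None,
    complete: bool = True,
) -> SubjectDataset:
    """One subject's runs, motion and clinical metadata.

    Healthy subjects draw a right-vs-left contralateral-amplitude asymmetry
    ``lam``; their right-limb runs get contralateral amplitude scaled by
    (1 + lam), left-limb by (1 - lam).  Stroke subjects draw ``lam`` as the
    non-paretic-vs-paretic balance, and a paretic-side FMA score
    ``intercept + slope * lam + noise`` (clamped to [0, fma_max]); the
    non-paretic side scores near ceiling, uncoupled.
    """
    if group == "healthy":
        tr = config.tr_healthy
        lam = float(
            np.clip(
                rng.normal(config.healthy_asym_mean, config.healthy_asym_sd), -0.9, 0.9
            )
        )
        scale = {"right": 1.0 + lam, "left": 1.0 - lam}
        paretic_side = None
        fma = {}
        movements = MOVEMENTS
    elif group == "stroke":
        tr = config.tr_stroke
        if paretic_side is None:
            paretic_side = "left" if rng.random() < 0.5 else "right"
        lam = float(rng.uniform(*config.stroke_lat_range))
        nonparetic = "right" if paretic_side == "left" else "left"
        scale = {nonparetic: 1.0 + lam, paretic_side: 1.0 - lam}
        movements = MOVEMENTS if complete else STROKE_SUBSET
        fma = {}
        for movement in movements:
            fma[(movement, "paretic")] = float(
                np.clip(
                    config.fma_intercept
                    + config.fma_slope * lam
                    + rng.normal(0.0, config.fma_noise_sd),
                    0.0,
                    config.fma_max,
                )
            )
            fma[(movement, "nonparetic")] = float(
                np.clip(
                    rng.normal(config.fma_nonparetic_mean, config.fma_nonparetic_sd),
                    0.0,
                    config.fma_max,
                )
            )
    else:
        raise ValueError(f"unknown group {group!r}")

    runs = [
        _simulate_run(truth, config, movement, side, tr, scale[side], rng)
        for side in SIDES
        for movement in movements
    ]
    return SubjectDataset(
        subject_id=subject_id,
        group=group,
        dataset=dataset or group,
        runs=runs,
        true_laterality=lam,
        paretic_side=paretic_side,
        fma=fma,
    )


@dataclass
class Cohort:
    subjects: list[SubjectDataset]
    truth: GroundTruth
    config: SimConfig

    def metadata(self) -> pd.DataFrame:
        """Tab-separable per-subject x movement metadata table."""
        rows = []
        for s in self.subjects:
            movements = sorted({r.movement for r in s.runs})
            for movement in movements:
                rows.append(
                    {
                        "subject": s.subject_id,
                        "group": s.group,
                        "dataset": s.dataset,
                        "paretic_side": s.paretic_side or "",
                        "movement": movement,
                        "true_laterality": s.true_laterality,
                        "fma_paretic": s.fma.get((movement, "paretic"), np.nan),
                        "fma_nonparetic": s.fma.get((movement, "nonparetic"), np.nan),
                    }
                )
        return pd.DataFrame(rows)


def iter_cohort(config: SimConfig, mask: HemiMask | None = None, truth=None):
    """Yield subjects one at a time (memory-friendly form of the cohort)."""
    mask = mask or make_pcl_mask()
    truth = truth or make_ground_truth(mask, config)
    ss = np.random.SeedSequence(config.seed)
    plan = (
        [("healthy", "healthy1", True)] * config.n_healthy1
        + [("healthy", "healthy2", True)] * config.n_healthy2
        + [
            ("stroke", "stroke", i < config.n_stroke_complete)
            for i in range(config.n_stroke)
        ]
    )
    children = ss.spawn(len(plan))
    for i, ((group, dataset, complete), child) in enumerate(zip(plan, children)):
        yield simulate_subject(
            truth,
            config,
            group,
            np.random.default_rng(child),
            subject_id=f"sub-{i:02d}",
            dataset=dataset,
            complete=complete,
        ), truth


def simulate_cohort(config: SimConfig, mask: HemiMask | None = None) -> Cohort:
    """Materialise the full cohort (sizes from the config; defaults 21/11/15)."""
    mask = mask or make_pcl_mask()
    truth = make_ground_truth(mask, config)
    subjects = [s for s, _ in iter_cohort(config, mask, truth)]
    return Cohort(subjects=subjects, truth=truth, config=config)
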