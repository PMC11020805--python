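# Methods

`limbloci` re-creates, on synthetic data, a pipeline for locating
movement-specific cortical loci of four lower-limb movements (toe flexion,
ankle dorsiflexion, ankle rotation, knee extension) in the paracentral
lobule (PCL) from block-design motor fMRI, and for scoring how lateralised
each movement's activation is. This note documents the models, the
generator, the numerical choices and what the tests do and do not show.

## Synthetic data generator

The subject scans this kind of analysis is normally run on are not
publicly deposited, so the package ships a first-class simulator whose
defaults encode the study conditions:

* **Design.** Eight runs per subject (4 movements x 2 moving sides), each
  with three 20 s task blocks interleaved with 20 s rest and a leading rest
  block (140 s per run). TR is 1.44 s for healthy subjects (97 volumes) and
  2.0 s for the stroke group (70 volumes); voxels are 3 mm isotropic.
  Cohort sizes default to 21 (healthy dataset 1), 11 (healthy dataset 2)
  and 15 (stroke, of whom 6 perform all four movements and 9 only ankle
  dorsiflexion and toe flexion).
* **Geometry.** The PCL fixture mask is a medial-wall slab straddling the
  midline (|x| <= 8 mm, 720 voxels, 360 per hemisphere) on a 12 x 12 x 24
  grid whose voxel centres sit on the half-voxel MNI lattice, so no centre
  lies at x = 0 and the hemispheres partition the mask exactly. Each
  movement owns a Gaussian-profile locus (sigma 3 mm, support radius 6 mm)
  in the hemisphere contralateral to the moving limb, centred at 15%, 40%,
  62% and 85% of the mask's z span for toe, dorsiflexion, rotation and
  knee respectively; the knee locus is shifted 3 mm posterior. This encodes
  the somatotopic inferior -> superior ordering the study design assumes.
* **Signal.** BOLD = 100 (baseline) + HRF-convolved boxcar x amplitude map
  + Legendre drift (order 2, random coefficients, sd 0.5) + AR(1) noise
  (coefficient 0.3, marginal sd 1.0). The contralateral locus amplitude is
  1.5 signal units (1.5% signal change, a typical robust motor block
  response) with a 0.3-unit ipsilateral mirror response. This
  signal-to-noise ratio was calibrated once, during generator design: much
  above it the rank-based RSA statistic saturates at its combinatorial
  ceiling and max-statistic thresholding becomes degenerate; much below it
  half-cohorts of six subjects cannot clear the family-wise threshold.
* **Laterality and clinical coupling.** Each healthy subject draws an
  asymmetry lam ~ N(0.12, 0.25) (clipped to ±0.9); right-limb runs scale
  the contralateral amplitude by (1 + lam), left-limb by (1 - lam), so the
  cohort's true laterality has a positive (contralaterally dominant) mean.
  Stroke subjects draw lam ~ U(-0.8, 0.8) as the non-paretic vs paretic
  balance, and a per-movement paretic-side Fugl-Meyer (FMA) score
  17 + 10 x lam + N(0, 3), clamped to the lower-extremity range [0, 34];
  the non-paretic side scores N(33, 1) at ceiling, uncoupled. The FMA
  coupling strength and noise are the generator's own choices, made so the
  association stage has known recoverable structure.
* **Motion.** Traces are slow random walks (step sd 0.004) plus rare
  one-volume spikes (per-volume probability 0.002, magnitude 0.6-1.5 mm,
  mainly in one translation axis with a 20% rotational component). At these
  rates roughly half of simulated subjects pass the strict QC rule, echoing
  the high drop-out the rule produces on real data.

What the generator does **not** emulate: physiological noise, spatially
correlated noise, susceptibility artifacts, lesions, inter-subject
anatomical variability, or any uncertainty in locus placement across
subjects (all subjects share one truth geometry). Passing recovery tests
therefore shows the pipeline is correct and well-calibrated under its own
assumptions, not that it would perform identically on scanner data.

## GLM

Per run, the design holds three task regressors (boxcar convolved with the
canonical double-gamma HRF: response gamma shape 6, undershoot shape 16,
ratio 1/6, scale 1 s, peak normalised to 1), six motion nuisance columns
and Legendre drift terms up to order 2 (orders >= 1 demeaned). Estimation
is per-voxel OLS with optional AR(1) prewhitening (coefficient pooled from
OLS residuals); at coefficient 0 the two estimators coincide, and the
noiseless-simulation oracle pins the betas to the injected amplitudes at
1e-8. All-zero columns (for example a flat motion trace) are flagged and
dropped rather than failing the rank check; genuine collinearity raises an
error naming the offending columns. The per-task map consumed downstream
is the run-level t of the across-block average contrast [1/3, 1/3, 1/3].
The univariate baseline is a voxelwise one-way repeated-measures ANOVA
across the four movements of a side (error term: subject x task
interaction), cross-checked against pingouin.

## Motion QC

The per-volume score is the Euclidean norm of the backward difference of
the six parameters (scrubbing convention; an absolute-displacement mode is
available), with rotations converted to arc length at a 50 mm head radius.
A task block fails when strictly more than 10% of its volumes score
strictly above 0.5 mm; a subject is included only if every block of every
run passes. The equipment comparison applies Welch t-tests per parameter
(per-run summaries, or per timepoint for length-matched runs) with a
studentized-range (Tukey-Kramer) adjustment; with two conditions the
adjustment is the q = |t| sqrt(2) mapping.

## Searchlight MVPA

Four-class SVM decoding per searchlight sphere (radius 1-3 voxels),
features standardised with training statistics only. Cross-validation is
nested and subject-wise throughout: five outer folds partition subjects;
one inner 4/1 subject split of the outer-training subjects drives the grid
search over C (and gamma for the RBF kernel) on decade grids 1e-4..1e3.
Ties prefer the smallest C, then the smallest gamma. Multiclass handling
is one-vs-one voting. Scenario sweeps vary block-wise vs run-averaged
inputs, 0 vs 4 mm FWHM smoothing, radius and kernel, and report the
within-mask accuracy distribution per condition (plus per-fold and
per-subject accuracies, since either could be the distribution a box plot
summarises). Chance for balanced four-class decoding is 25%; label
permutations within subject reproduce it to within the sampling noise of
the reduced desk-scale setup.

## Searchlight RSA

Per voxel, the neural RDM over the 24 task x block conditions is
1 - Pearson r between sphere patterns (radius 3; 123 voxels when
untruncated). A constant pattern has no defined correlation; such pairs
score the uninformative midpoint 1.0. The code RDM marks pairs within the
movement of interest 0, pairs between it and any other task 1, and
excludes pairs among other tasks (a switch scores them 1 instead; with
run-level RDMs the within-movement cell would otherwise be empty, which is
why block-level conditions are the default). The map statistic is the
Spearman correlation between the scored upper-triangle entries, computed
per subject and averaged; because the code is binary, the rank correlation
reduces to Pearson(rank(neural), code), which the implementation exploits
and a scipy cross-check verifies.

Significance is family-wise corrected with a max-statistic null: the 24
condition labels are shuffled (the same shuffle applied to every subject,
preserving the subject-mean aggregation inside the null), the group map is
recomputed, and its mask-wide maximum recorded; a voxel is significant
when its observed value strictly exceeds the empirical (1 - alpha)
quantile ("higher" method) of the maxima. Shuffling at the condition level
gives C(24,3) = 2024 distinct interest sets, enough to support corrected
p < 0.01; shuffling whole tasks would give only eight. Final loci must
replicate: the cohort is split at random into two sub-groups (10/11 at
full scale), each half is thresholded with its own null, the conjunction
is taken, and only voxels persisting in at least 8 of 10 repetitions
(strict "more than seven"; configurable) survive, reported as 26-connected
clusters of at least five voxels with peak and centre-of-mass MNI
coordinates. Within one persistence analysis a single seeded permutation
pool is shared across repetitions and halves — permutations are
exchangeable, so reuse is statistically valid and lets each subject's
permuted maps be computed once.

Desk-scale study sizes (stated as the package's own choices): recovery
runs use 12 subjects split 6/6, 5 repetitions with persistence cutoff 4,
and 500 permutations; the full-scale defaults (21 subjects, 10/11, 10
repetitions, 10,000 permutations, cutoff 8) remain the function defaults.

## Laterality (AveLI)

AveLI is threshold-free: every strictly positive t value in the two
contralateral ROI extracts serves in turn as threshold t_i (ties counted
with multiplicity), subLI_i = (Rt_i - Lt_i)/(Rt_i + Lt_i) uses the sums of
t >= t_i (closed threshold, so the denominator is always positive), and
AveLI is the mean of the VN subLI values, VN being the pooled positive-t
count. Healthy variant: right-side movement in the R role, left-side in L,
each extracted from its contralateral hemisphere. Stroke variant:
non-paretic movement in R, paretic in L. With no positive t anywhere the
record is explicitly undefined (NaN with a reason), never 0. ROI
definitions: whole-PCL hemisphere, or the movement's own locus
(default; the union of all loci is a mode). The ROI comparison is a paired
t-test per movement.

## Association

OLS of FMA on AveLI; R^2 is the squared Pearson correlation. Significance
comes from permuting y against x with statistic R^2 (two-sided by
construction) and the add-one correction p = (1 + #{>= observed}) /
(n_perm + 1); for n! <= n_perm the p value is computed by exhaustive
enumeration instead. The confidence band is the pointwise percentile
interval of the refit line over case-resampling bootstrap draws; draws
with a constant predictor are skipped and counted, with a warning above
10%. Known limitation: percentile bands under-cover at small n (measured
~90% nominal-95% coverage at n = 15, ~95% by n = 80), so the calibration
test of the band runs at n = 80; at the stroke cohort's n = 15 the band
should be read as approximate.

## Numerical and tie-breaking conventions

Lexicographic ordering wherever ties could occur (sphere offsets, cluster
members, fold assembly); argmax/argmin take the first (lexicographically
smallest) index. Hemisphere labels come from the sign of the voxel-centre
MNI x coordinate; exact-midline voxels belong to neither hemisphere. All
randomness flows through `numpy.random.Generator` objects seeded from a
single integer via `SeedSequence.spawn`, so identical configurations give
bitwise-identical cohorts, folds, permutations and bootstrap draws.

One sweep-related caveat: on this generator run-averaged inputs decode at
least as well as block-wise inputs (signal is block-constant up to the
optional per-block multipliers, so averaging only reduces noise). Findings
that block-wise inputs win on real data point to block-level pattern
variability the generator does not emulate.
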