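# Methods

This note documents the models implemented in `sonoquant`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical conventions that matter for reproducing
its outputs.

## Concentration mapping

The mapping assumes fast-exchange linear relaxivity: the change in
longitudinal relaxation rate is proportional to local contrast-agent
concentration, `ΔR1 = r1·C`, with `r1 = 4.5 mM⁻¹s⁻¹` for Gd-DOTA at 3 T
(configurable). Inputs are co-registered quantitative T1 maps in
seconds; congruence (identical shape, affines equal to 1e-4 mm) is
checked, never assumed. Three conventions are deliberate:

* negative concentrations are **kept**: under symmetric noise they make
  ROI-minus-control differences unbiased, which the detection criterion
  relies on;
* voxels with nonpositive or missing T1 propagate as NaN and are
  counted, never silently set to 0 (which would dilute ROI quantities);
* no smoothing, decay or washout correction is applied.

## Beam geometry

All measurement regions hang off an `ImplantGeometry`: a skull entry
point and an inward unit axis. "15 × 55 mm cylindrical ROI" is read as
**diameter** 15 mm × length 55 mm — the transducer is 10 mm across, so
15 mm covers near-field beam spread — with both numbers overridable.
Voxel membership is a voxel-center test with flat end caps and no
partial-volume weighting; this is what the brute-force per-voxel oracles
in the tests check exactly. The contralateral control is the exact
world-space reflection of the beam across the mid-sagittal plane,
rasterized to nearest voxels (no interpolation of booleans), with any
identical tissue restriction applied on its own side.

The implant PET box (10 × 10 × 40 mm³ along the axis) supports three
restrictions: none, exclude-CSF, gray-matter-only. The same-hemisphere
distal comparator is an equal box translated 20 mm **within the coronal
plane** (default direction inferior): a posterior shift would leave the
coronal slices the comparator is supposed to share, so the shift
direction is constrained to have no anterior–posterior component. The
three comparator boxes are required to be pairwise disjoint; the beam
cylinder necessarily contains the implant box (both are anchored to the
same axis), so no disjointness is demanded between those two.

Pressure derating is the standard 1-D amplitude law
`p(d) = p0·10^(−α·f·d/20)`, `α = 0.6 dB/cm/MHz`, `f = 1 MHz`,
`p0 = 1.03 MPa` by default. It is strictly decreasing and multiplicative
over path segments; it is not a 3-D field simulation.

## Opening metrics and detection

Gd quantity sums signed concentrations over non-missing ROI voxels and
converts via voxel volume and molar mass. The mass basis is the
gadoterate **complex** (558.6 g/mol), isolated in one configurable
constant, since quantities could equally be expressed per elemental Gd.

The enhancement threshold is adapted on the control ROI: the smallest
observed control concentration such that strictly fewer than 5% of
control voxels exceed it (nearest-rank upper quantile; both the
strictness and the 5% are parameters). The same threshold is applied to
the beam ROI. Detection uses `Q_roi > Q_ctrl + 2·SD`, where SD is the
sample standard deviation (n−1) of control quantities pooled over all
supplied sessions — one cohort-wide criterion spread.

A property worth knowing: when the *only* variability is voxel noise,
`Q_roi − Q_ctrl` has standard deviation √2 times the SD of a single
control quantity, so the 2-SD rule has a one-sided null exceedance of
`1 − Φ(√2) ≈ 7.9%`, not ≈2.5%. In real cohorts the pooled control SD
also absorbs between-session and physiological variability, which pushes
the false-positive rate down; the synthetic null deliberately omits such
variability, so its measured null detection rate sits near 8%.

Similarly, the enhanced-volume difference `V_roi − V_ctrl` slightly
underestimates the planted volume under noise: the threshold admits
just-under-5% of control voxels, and the beam ROI has fewer *non-enhanced*
voxels available to clear the threshold than the control has, biasing
the difference low by a few percent of the ROI volume.

## PET SUVR

SUVR is the ratio of ROI means. Reference schemes: opposite-hemisphere
mirror, same-hemisphere distal box, bilateral parietal cortex, whole
cerebellum, and white matter eroded by 2 voxels on the 1-mm grid (the
erosion depth is a parameter; 2 mm clears the cortical partial-volume
rim in the phantom). Percent change is simple,
`100·(SUVR_t − SUVR_0)/SUVR_0`; annualized percent change divides by the
elapsed years (4 months = 1/3 yr), with a compounded variant available.
Amyloid positivity is strict: SUVR exactly 1.1 is negative, matching the
reading of a 1.11 case as "at the limit of positivity". The QC rule
flags any subject whose implant-distal region changes by more than 5%
(absolute, per interval, strict); the bound is a parameter, not a claim
about physiology.

## Control matching

Eligibility is same gender and |ΔMMSE| ≤ 2; among eligible candidates
the k = 5 nearest in |Δage| win, ties broken by |ΔMMSE| then id, which
makes the output deterministic and invariant to pool order. Diagnosis
can be required to match exactly (off by default, since the per-subject
rule names only age/gender/MMSE while diagnosis may merely filter the
pool). Matching is with replacement across cases by default; a greedy
without-replacement variant processes cases in id order.

## Group statistics

All hand-authored so small-sample behaviour is fully specified and
testable against enumeration oracles:

* **Wilcoxon signed-rank**: zero differences dropped (classic
  convention, not Pratt), mid-ranks for ties, W = sum of positive
  signed ranks. For n ≤ 25 the two-sided p is exact, via a
  convolution recurrence over doubled ranks (so mid-ranks stay
  integral); beyond that, a normal approximation with continuity and
  tie corrections. Two-sided throughout.
* **Kruskal–Wallis**: standard rank formula with tie correction,
  chi-square reference on (groups − 1) df.
* **Benjamini–Hochberg**: step-up adjusted p-values clipped at 1.

## Pattern analysis

Scans are divided by their in-mask mean (patterns are relative to the
whole brain), column-centered, and reduced by SVD to q PCs. CVA solves
`Sb w = λ Sw w` in PC space with `Sw` ridge-stabilized
(`λridge = 1e-6·trace(Sw)/q`) so duplicated scans cannot crash the
solve; canonical scores are normalized to unit pooled within-class
variance, and patterns are the weights back-projected to voxel space.
Pattern sign is arbitrary and fixed only by alignment.

Split-half resampling partitions **subjects** (each contributes one scan
per class, so class balance follows). Reproducibility is the
sign-aligned Pearson correlation of the halves' CV1 patterns; prediction
is nearest-centroid cross-classification accuracy averaged over both
directions. The number of splits (default 100), the PC count (default: a
grid search over q ∈ 2..min(15, rank−1) maximizing median prediction +
median reproducibility) and the classifier are deliberate parameters —
none is canonical in the split-half literature. Consensus patterns are
reproducibility-weighted (negatives clipped; unweighted fallback with a
warning if all splits are nonpositive), sign-aligned means, renormalized
to unit norm.

A scaling fact governs the recoverable regime: the alignment of the top
principal component with a planted spike degrades as voxels/scans grows
(`cos²θ ≈ (1 − c/λ²)/(1 + c/λ)` with `c = p/n`). The tests therefore
exercise the planted-effect conditions (separation 5 noise-SDs, 20
subjects, 3 classes) at 30 voxels, where reproducibility ≥ 0.9 genuinely
holds, rather than at whole-brain dimensionality.

## The synthetic phantom

The phantom is the simplest geometry that exercises every pipeline
branch: an ellipsoidal brain (semi-axes 65 × 80 × 55 mm on a
144 × 176 × 128 grid at 1 mm) with a 2-mm outer CSF shell, a 4-mm
cortical gray-matter shell, white matter inside, a cerebellar
compartment in the inferior-posterior brain, and a parietal subdivision
of the cortex. The head is adult-sized on purpose: the full 55-mm beam
must stay within one hemisphere for its mirrored control to be disjoint,
which a smaller grid cannot satisfy. Tissue T1 defaults are 3-T
literature values (GM 1.4 s, WM 0.9 s, CSF 4.0 s).

Enhancement is planted by inverting the relaxometry model inside a
sub-region of the beam (default: 10 mm × 10.3 mm cylinder ≈ 0.81 mL at
0.2 mM), so concentration mapping must recover the planted value exactly
at zero noise. Noise is additive Gaussian on T1 — the measured quantity —
independently in pre and post maps, truncated at 0.05 s to keep rates
physical (default sd 0.02 s). PET series assign regional means times
per-time-point change factors plus Gaussian noise; focal regions (e.g.
the implant box) multiply on top, so a planted 6.6% target decrease is
exact under an unchanged reference. All randomness flows from one
integer seed through a named generator per artifact; identical seeds
give bit-identical outputs. `PhantomFactory` builds the deterministic
anatomy once and resamples only noise across seeds, which is what the
multi-seed simulations use.

What the generator does **not** emulate: PET point-spread and partial
volume, MRI sequence physics, head motion (QC is tested by planting
out-of-range distal changes directly), spatially correlated noise, and
between-session physiological variability of the control ROI — the last
omission is why the measured null detection rate reflects pure voxel
noise (see above). Passing tests demonstrate correct recovery of planted
effects under these idealized conditions, not robustness to real-scanner
artifacts.

## Problem sizes

The test suite and the acceptance script run the quantification chain at
the full default grid (≈3.2 M voxels): 50 noisy seeds for quantity
recovery, 10 for volume recovery, 200 (tests) / 100 (script) null seeds
for detection characteristics; 10⁴ (tests) / 4·10³ (script) null
replicates for the Wilcoxon operating level at n = 9; 50 splits for the
pattern metrics at 20 subjects × 3 classes × 30 voxels; 500 random pools
for the matching oracle. These sizes make all Monte-Carlo margins small
relative to the tolerances they are checked against.
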