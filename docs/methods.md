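# Methods

This note documents the models and procedures implemented in `rai2ctbp`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions adopted where the underlying
analysis left them open.

## CTC marker calling (`rai2ctbp.ctc`)

qPCR quantification-cycle differences (ΔCq; lower = more transcript) for
*AR*, *KRT19* and *RAI2* are preprocessed against a healthy-donor reference
(n ≥ 2 donors per gene; 10 by default):

1. **Imputation.** Missing values become the gene-wise maximum observed ΔCq
   plus 2 cycles. The gene maximum is taken over all observed values of the
   combined run (donors + patients) before any replacement; it can be pinned
   to a fixed panel constant.
2. **Censoring.** Numeric values strictly greater than the donor
   mean + 1 SD are replaced by the same max + 2 sentinel. Both replacements
   represent expression indistinguishable from healthy background, which is
   why they share a sentinel; the operation is idempotent.
3. **Positivity.** A sample is positive for a gene iff ΔCq < donor mean
   (strict, matching the "below healthy expression" rule; the +1 SD margin
   is already consumed by censoring). Sentinels always call negative.
4. **CTC status.** Positive for *AR* or *KRT19* (or both) ⇒ CTC-positive.
   *RAI2* detection frequencies are reported with CTC-positive samples as
   the denominator.

Cohort frequencies are integer-rounded percentages. Fisher's exact test is
computed by full hypergeometric enumeration in log-space; two-sided p-values
use the probability-mass convention (sum over tables whose point probability
is ≤ the observed, relative tie tolerance 1e-7), which is the most common
convention but differs from mid-p and doubling variants. The odds ratio is
the conditional maximum-likelihood estimate. The ΔΔCT utility computes
2^(−ΔΔCT) with a caller-chosen reference gene.

**Boundary-noise caveat.** The synthetic generator draws negative samples at
the healthy mean plus Gaussian noise. Under the strict `< mean` rule, any
nonzero noise therefore pushes roughly half of the borderline negatives
below threshold. Exact ground-truth recovery consequently holds only in the
noise-free regime (the regime the recovery test uses); noisy synthetic runs
overestimate detection frequencies relative to the generating fractions.
Real data do not sit exactly at the healthy mean, so this is an artifact of
the emulation, not of the calling rules.

## Line-profile colocalization (`rai2ctbp.coloc`)

Profiles are two-channel intensity scans (default 3 µm at 0.03 µm/sample ≈
100 samples, 100 profiles) across foci. Alignment maximizes the
mean-subtracted, norm-normalized cross-correlation of the focus channel
against an arbitrarily chosen reference profile over integer shifts
|s| ≤ max_shift (default: a quarter of the profile length), evaluated on
the overlap only (no wraparound). Ties resolve to the smallest |s|, then to
the negative shift. The chosen shift is applied identically to the second
channel; shifted-out samples are masked, and mean ± SD profiles average
only contributing profiles (SD with n−1; undefined below 2 contributors).

**Efficiency score.** The source analysis reported efficiencies but not the
score's definition, so it is an explicit operationalization here: a profile
is colocalized iff the second channel's *mean* within ±0.25 µm of the
aligned focus-channel peak exceeds `tail_mean + 2·tail_sd` of that
profile's own second channel, tails being the outer 20% of samples. Window
and threshold factor are parameters. The window mean (rather than maximum)
is used because the maximum of ~17 noise samples exceeds a 2-SD threshold
~30% of the time, which would swamp the score's false-positive budget; with
the mean, the false-positive rate at zero coincidence is ≈ 0 and the score
tracks the true coincidence fraction within binomial error for peak
amplitudes ≥ 5× the noise SD.

## 3D foci quantification (`rai2ctbp.foci`)

Uniform background subtraction (`max(v − b, 0)`, with "auto" = intensity
histogram mode over 256 bins), thresholding (Otsu by default, since the
original segmentation was performed in a commercial package that does not
document its threshold), connected components at 26-connectivity (the most
permissive; 6/18 available), volume = voxel count × voxel volume, and an
**inclusive** lower volume cutoff at 0.1 µm³. Components are assigned to the
cell label under their centroid voxel. Per-cell counts include zero-count
cells; medians/quartiles use inclusive linear interpolation. The unpaired
t-test is Student's pooled-variance test by default (Welch behind a flag);
zero-variance degenerate inputs yield p = 1 (equal means) or p = 0 with a
warning (unequal means).

The synthetic image generator places hard spheres inside disjoint
rectangular "cells", with a two-voxel clearance between sphere surfaces so
rasterized foci remain separable as distinct components; rasterization is
by voxel-center-inside test, accepting partial-volume error at boundaries
(≤ 15% for a 0.4 µm sphere at 0.1 µm voxels). No optics (PSF, anisotropic
blur) are simulated, so passing recovery tests demonstrate correctness of
the segmentation arithmetic, not robustness to microscope blur.

## NMR titration metrics (`rai2ctbp.nmr`)

Chemical shift perturbation between reference and observed HSQC peaks:

    Δδ = sqrt( (δ_ref(¹H) − δ(¹H))² + (δ_ref(¹⁵N)/6.5 − δ(¹⁵N)/6.5)² )

with the ¹⁵N scale (6.5) configurable. Titration intensity ratios are
I(point)/I(ratio 0) per residue; missing peaks stay missing, zero-reference
residues are excluded and flagged. Heteronuclear NOE is I_sat/I_unsat and
may be negative (fast-motion signature of disordered residues). Peaks are
matched by residue number — assignment is assumed done upstream.

The titration generator attenuates intensities to a floor of 0.1 at
binding-site centers (tandem sites 316–320 and 342–346 by default, Gaussian
fall-off of 4 residues), reproducing the bilobal two-site pattern; CSPs grow
to 0.1 ppm at site centers. Real titrations add exchange-regime line-shape
effects the generator does not model.

## Filament geometry (`rai2ctbp.filament`)

Layer k of a filament is `R(k·angle)·P + k·rise·ẑ` applied to the layer
point cloud P. Defaults: 120°/5 nm (the 3₁ screw), six layers of a
9.5 × 9.5 × 5 nm tetramer-layer template. Layer spacings are successive
centroid differences projected on the axis (all equal to the rise for
screw-generated filaments). Filament length is the material extent
`(n − 1)·rise + thickness`, which makes six 5-nm layers exactly 30 nm; the
centroid span is also available. The unique unit is the smallest k with
k·angle ≡ 0 (mod 360°) within 1e-6° (searched to k = 1000; otherwise
"aperiodic"): 3 for 120°. Positive angles are right-handed screws about
+z; handedness is a flag. PDB export writes one chain per layer of
pseudo-atoms in Å (nm × 10) via gemmi; fixed-width PDB precision bounds
round-trips at ~1e-3 Å.

## Binding and scattering (`rai2ctbp.binding`)

**ITC forward model.** Single-site equilibrium with stoichiometry N:
`[MX] = ((N·Mt + Xt + Kd) − √((N·Mt + Xt + Kd)² − 4·N·Mt·Xt))/2`. Each
injection (default 10 µl into 1.4 ml) dilutes both totals by
`(1 − v/V₀)`; the heat of injection i is
`V₀·ΔH·([MX]_i − [MX]_{i−1}·(1 − v/V₀)) + offset`, i.e. the standard
perfusion correction for complex displaced from the cell, reported in µcal
(a kcal/mol-of-injectant converter is provided for conventional plots).
Default scheme mirrors the experimental setup: 10 µM macromolecule in the
cell, 100 µM titrant in the syringe, 30 injections.

**Fit.** Nonlinear least squares over (K_d, N) with (ΔH, offset) profiled
out linearly at every evaluation (variable projection): a coarse grid
(log-spaced K_d ∈ [0.01, 1000] µM × N ∈ [0.1, 4]) seeds a bounded
`least_squares` refinement at 1e-15 tolerances. Because fit and simulator
share the forward model, noise-free round trips recover parameters to
≤ 1e-6 relative error; with 2% (of max heat) Gaussian noise the median K_d
error stays below 10% in a well-determined design (Wiseman c ≈ 20). In the
shallow c ≈ 2 regime of the 10 µM/5 µM configuration, K_d uncertainty under
noise is substantially larger — an intrinsic identifiability limit, not a
fitting defect. Saturation short of the fitted N raises a warning; only the
single-site model is implemented (the multi-site case is out of scope).

**Guinier analysis.** Linear regression of ln I on s² iterated on the
window s ≤ 1.3/R_g until membership stabilizes; `R_g = √(−3·slope)`,
`I(0) = exp(intercept)`. Data generated exactly by the law invert to
machine precision; non-decaying input raises "no Guinier regime".

## Pipeline (`rai2ctbp.pipeline`, CLI)

A single integer seed fans out to per-stage child seeds by fixed offsets
(+1000 qPCR, +2000 coloc, +3000 foci, +4000 CSP, +6000 ITC), making whole
runs deterministic and hash-comparable. The run configuration is a plain
serializable dataclass (YAML round trip; unknown keys rejected), written
next to the outputs together with a manifest and a config hash. Stage
failures are recorded per stage without aborting independent stages.

Default cohort conditions emulate the study population sizes (HSPC 15,
CRPC 27, AVPC 57, NEPC 18; 10 healthy donors) with per-gene positive
fractions near the reported detection rates, a 6-cycle positive shift,
0.5-cycle noise and 5% missingness. Problem sizes throughout (image
20×128×128 voxels, 100 profiles × ~100 samples, 60 residues × 4 ratios,
30 injections) were chosen to exercise every code path at desk scale while
keeping the full test suite and analysis scripts fast.

## Known limitations

- No amplification-curve, preamplification, or gDNA (ValidPrime) modelling;
  the generator works directly at ΔCq level.
- No PSF simulation, nucleus segmentation from DAPI, or object splitting of
  merging foci; the published foci counts depend on real images and are not
  reproduction targets.
- No peak picking or assignment; no binding-constant fitting from CSP
  trajectories.
- No interface-area or contact analysis on deposited coordinates; the
  screw-geometry module operates on idealized point clouds.
- No SAXS shape reconstruction, p(r)/D_max analysis, or curve prediction
  from atomic models; only the Guinier regime is implemented.
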