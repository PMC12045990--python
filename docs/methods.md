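# Methods

This note documents the models implemented in `organoid_mech`, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic generators do and do not emulate, and
the known limitations.

## Micropipette-aspiration rheology (`sls`)

**Model.**  For small deformations of a half-space aspirated through a
pipette of inner radius Rp under constant suction ΔP, the creep
compliance is J(t) = 2π L(t) / (3 φ Rp ΔP), with L(t) the aspirated
tongue length and φ a dimensionless wall factor (default 2.1, the
standard value for thick-walled pipettes).  L and Rp must share a length
unit; ΔP in Pa then gives J in Pa⁻¹.  The standard linear solid —
spring k₁ in parallel with a Maxwell arm (spring k₂, dashpot μ) — has

    J_SLS(t) = (1/k_st)(1 − ((k₀ − k_st)/k₀) e^(−t/τ)),
    k₀ = k₁ + k₂,   k_st = k₁,   τ = μ(k₁ + k₂)/(k₁ k₂).

Its three signatures — an instantaneous elastic jump J(0⁺) = 1/k₀, a
transient with time scale τ, and a finite plateau 1/k_st — are exactly
what whole-organoid creep shows, which is why the minimal linear solid
model suffices.

**Fitting.**  Nonlinear least squares (Levenberg–Marquardt) over
θ = (ln k_st, ln k₂, ln τ) with k₂ = k₀ − k_st.  The log
parameterization enforces positivity and k₀ ≥ k_st structurally rather
than through active constraints, which keeps noisy fits off unphysical
boundaries.  Initialization is endpoint-based: k₀ from 1/J at the first
loaded sample, k_st from 1/J averaged over the final 10% of samples, τ
from the time J crosses the midpoint between those plateaus — this puts
the start point inside the convergence basin for any trace with a
visible rise.  R² is computed about the mean of J over the fitted
window.  A fit whose transient amplitude k₂ falls below 10⁻³·k_st is
flagged `degenerate_tau`: the response is purely elastic and τ is not
identified (deriving μ then raises an error, since the Maxwell arm is
absent).

**Suction onset.**  Recordings include a ~2 s unloaded lead-in.  By
default the onset is the first sample from which L exceeds the baseline
mean + 3 baseline SDs for three consecutive samples (single noise spikes
are ignored); a manual onset overrides this.  Time is re-zeroed at onset
and pre-onset samples kept as baseline metadata.

**Condition statistics.**  Pooled-variance two-tailed t (two groups) and
one-way ANOVA F (three or more), both from their closed forms with
p-values from the reference distributions; the module is therefore
self-contained and each statistic is unit-tested against hand values and
an independent implementation.

## Fiber-network microstructure model (`network`)

**Model.**  A W×H triangular lattice (default 8×8 = 64 nodes, rest
length l₀ = 1), periodic horizontally and open vertically.  Straight
lines of edges in each of the three principal directions are fibers.
The energy is

    E = (k_s/2) Σ_⟨ij⟩ p_ij (l_ij − l₀)²
      + (k_b/2) Σ_⟨ijk⟩ p_ij p_jk (θ_ijk − π)²
      + Σ_n λ q_n (A_n − A₀)²

with bending penalized only at consecutive collinear edge pairs of one
fiber (rest angle π; no bending at fiber crossings), and cells as
individual lattice triangles (q_n = 1) with rest area A₀ = √3/4·l₀² and
area stiffness λ.  Defaults follow the study configuration: 64 nodes,
N_c = 32 cells, stretch/bend ratio R = k_s/(k_b l₀²) = 10 with k_b = 1
(so k_s = 10) and λ = 1.  Numerically the bend term uses the turning
angle δ = atan2(a×b, a·b) between consecutive segment vectors, which
equals π − θ and is smooth at the straight rest state, where the
interior-angle form has a derivative discontinuity.

**Dilution.**  Random mode keeps each edge independently with
probability p.  Patterned mode removes the n = round((1−p)·E) edges
whose midpoints lie nearest the system center (distance ties broken by a
seeded shuffle) — equivalent to growing a circular removal region until
the realized occupied fraction matches the target within one edge; a
required radius exceeding the half-system size raises an error.  Bend
triples deactivate automatically through the occupancy product.
Dangling edges and floating clusters are retained; they carry no load
and keep the realized-p accounting exact.

**Compression and stiffness.**  Top and bottom rows are
displacement-controlled vertically (height change γ·H₀) and free to
slide horizontally; the box width is fixed.  Interior degrees of freedom
are relaxed by L-BFGS with the analytic gradient (gradient-tolerance
10⁻⁸, strain continuation in steps of ≤ 5·10⁻³ starting from the
previous minimized state).  Stiffness is the central second difference
K = (1/A_sys)[E(γ+Δ) − 2E(γ) + E(γ−Δ)]/Δ² at γ = 0.01 with Δ = 10⁻³,
normalized by the undeformed system area so K is intensive; the
evaluation strain sits in the near-linear regime (E is quadratic in γ to
within 1% there) and relative comparisons between conditions are
invariant to the normalization choice.

**Observed behavior.**  On the default configuration, with 20+ replicate
seeds, mean K falls monotonically as p decreases in both modes, and
going from patterned dilution at p = 0.85 to random dilution at p = 0.95
raises mean stiffness by ≈ 41% (stable to within a few points across
evaluation strains 0.002–0.05 and seed counts).  A known limitation: for
p ≲ 0.7 the single-central-hole patterned construction becomes *stiffer*
than random dilution at equal p — a plate with a hole keeps load paths
around the hole while random dilution approaches the rigidity threshold
— so the patterned ≤ random ordering holds only in the p ≳ 0.8 regime
where the patterned/random comparison is actually made.  Multiple
smaller removal regions would likely extend that ordering to lower p;
only the single-region construction is implemented.

## ADC pipeline (`adc`)

**Per-voxel fit.**  ln S(b) = ln S₀ − b·ADC by ordinary least squares
over all b-values (closed form, vectorized).  Voxels with any
non-positive intensity or a negative fitted ADC are excluded from the
mask and counted, never floored — exclusion counts keep audits possible.

**Segmentation.**  Tissue retains signal at the strongest diffusion
weighting while free medium does not, so the mask comes from automatic
Otsu thresholding of the highest-b image with small-object removal
(default minimum 9 voxels); a manual threshold is accepted.

**Distribution.**  The masked ADCs fill a 100-bin histogram over their
min–max range, normalized to unit sum (the maximal-likelihood position
is invariant to sum- versus area-normalization).  Denoising zeroes all
real-FFT components above `keep_modes` (default 10 of the 50 available)
and clips negative ripple at zero; the cutoff is a tunable, chosen to
remove bin-level noise while preserving the unimodal envelope.  The
maximal-likelihood position is the midpoint of the two linear
interpolated crossings of ⅔ of the denoised peak height nearest the
peak — a location estimate robust to the right-skew of tissue ADC
distributions; a profile truncated before crossing on either side raises
an error rather than guessing.

**Group comparison.**  With the same scans observed for all groups
(matched design), each scan contributes the relative deviation
(ADC_group − ADC_ref)/ADC_ref.  Because both groups share each scan's
multiplicative drift, the ratio cancels it exactly; the deviations are
summarized as mean ± SD in percent and tested against zero with the
closed-form paired t.

## Sholl radial profiling (`sholl`)

The organoid center and radius come either from a manually drawn widest
diameter (midpoint and half-length, the bench procedure) or
automatically from the mask centroid and maximal centroid-to-boundary
distance.  Circles at normalized radii 0.02, 0.04, …, 1.00 (increment
configurable) are sampled densely in angle — the sample count is a
multiple of 4 and rounding is floor(x+0.5), which makes the rasterized
circle map onto itself under quarter-turn rotations — and a contiguous
run of signal-positive pixels along a circle counts as one intersection
(wrap-around runs merged), the classic Sholl semantics.  Thresholding
defaults to Otsu within the mask.  For group comparison each counted
intersection contributes its normalized radius as one observation
(radius-weighted pooling, matching the exported distribution tables);
per-circle-count pooling is available as an option.  The Mann–Whitney U
uses midranks, full enumeration of the permutation distribution for
combined samples ≤ 20, and the tie-corrected continuity-corrected normal
approximation otherwise.

## Synthetic generators (`synth`)

All generators are pure functions of their arguments; identical
configuration and seed give bit-identical output, and every output
passes the input validation of its consuming module.

- **Creep traces**: L(t) inverted from the SLS compliance through the
  aspiration relation; defaults k₀ = 400 Pa, k_st = 250 Pa, τ = 2 s,
  ΔP = 2 kPa, Rp = 150 µm, 30 Hz sampling, 8 s loaded recording after a
  2 s unloaded lead-in.  Noise is multiplicative Gaussian on L (tracking
  error scales with tongue length), default 1% — the level at which
  individual-trace fit quality lands in the measured regime (R²
  typically above 0.98).
- **DWI phantoms**: disk-shaped wells on a 96×96 grid (0.1 mm in-plane
  voxels), six b-values 0–1200 s/mm², per-voxel ADC drawn log-normal
  (positive support, right-skewed, producing the asymmetric distribution
  the ⅔-peak rule is designed for) with group means ~10⁻³ mm²/s and CV
  0.15; Rician magnitude noise at SNR 30 at b = 0; per-scan
  multiplicative ADC drift (+2%/scan) common to all wells.
- **Collagen images**: a disk organoid (radius 100 px) with 150
  non-overlapping puncta (radius 1.5 px) either confined to an annulus
  at 0.8 of the organoid radius (width 0.06; 0.5 mimics an older,
  internalized ring) or scattered uniformly — the same punctum count and
  size in both modes matches total signal by construction, mirroring the
  observation that the phenotypes differ in organization, not amount.

**What the generators do not emulate**: image-based tongue tracking
(traces are already extracted L(t) series), k-space reconstruction,
registration or distortion artifacts in the MRI, partial-volume and
multi-compartment diffusion, microscopy point-spread functions, or
fiber-like (elongated) collagen morphology.  Passing tests therefore
demonstrate the correctness and statistical behavior of the analysis
chain under controlled conditions, not robustness to every artifact of
real acquisitions.

## Problem sizes and determinism

Replicate counts are chosen for tight means at interactive runtimes: 20
seeds per condition in the test suite's network sweeps and 80 in the
reproduction script (the patterned/random ratio's standard error is then
well under one percentage point); 50 traces for per-trace fit-quality
percentiles; 5-scan phantoms matching the repeated-scan design.  Every
stochastic step takes an explicit seed, and the pipeline runner derives
per-stage seeds from a single root seed, so reruns are byte-identical.
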