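# organoid-mech

Tissue-mechanics and imaging analysis for brain organoids: a Python
library that quantifies how extracellular-matrix (ECM) amount and
organization set the stiffness of organoid tissue, with four independent
analysis stages and seeded synthetic generators for every input modality.

The package is aimed at labs doing organoid mechanobiology: micropipette
aspiration (MPA) rheology of whole organoids, diffusion-weighted MRI of
organoid batches, immunofluorescence of collagen organization, and
lattice-based microstructure modeling that ties the observations together.

## What it computes

**SLS rheology** (`organoid_mech.sls`).  An MPA creep test records the
aspirated tongue length L(t) under constant suction ΔP through a pipette
of radius Rp.  The creep compliance

    J(t) = 2π L(t) / (3 φ Rp ΔP),          φ = 2.1 (wall factor)

is fitted with the standard linear solid (a spring k₁ in parallel with a
Maxwell arm k₂–μ):

    J_SLS(t) = (1/k_st) · [1 − ((k₀ − k_st)/k₀) · e^(−t/τ)]

giving the instantaneous stiffness k₀ = k₁ + k₂, steady-state stiffness
k_st = k₁ and response time τ = μ(k₁+k₂)/(k₁k₂).  Conditions are compared
with closed-form pooled-t / one-way-ANOVA statistics.

**Fiber-network microstructure model** (`organoid_mech.network`).  The ECM
is a diluted triangular lattice of semiflexible fibers with embedded
area-elastic cell triangles:

    E = (k_s/2) Σ p_ij (l_ij − l₀)² + (k_b/2) Σ p_ij p_jk (θ_ijk − π)²
        + Σ λ q_n (A_n − A₀)²

with edge occupancy p_ij ∈ {0,1}, fiber direction triples ⟨ijk⟩ and
stretch/bend ratio R = k_s/(k_b l₀²).  ECM *amount* is the occupied-edge
fraction p; ECM *organization* is the dilution mode — random (every edge
independently, mutant-like) versus patterned (a central circular region,
ring-like control).  Tissue stiffness K = (1/A) d²E_min/dγ² is extracted
by energy minimization under uniaxial compression (periodic horizontally,
clamped top/bottom rows).

**ADC pipeline** (`organoid_mech.adc`).  Multi-b diffusion-weighted
stacks (b = 0…1200 s/mm²) are reduced to per-voxel apparent diffusion
coefficients via the mono-exponential log-linear fit S(b) = S₀e^(−b·ADC),
the organoid tissue segmented on the highest-b image, the masked ADCs
binned into a normalized 100-bin distribution, Fourier-denoised, and
summarized by the ⅔·I_max maximal-likelihood position.  Groups are
compared scan-by-scan through relative deviations from a reference group
(cancelling longitudinal drift) with a matched t test.

**Sholl radial profiling** (`organoid_mech.sholl`).  A thresholded
collagen image is probed with concentric circles from the organoid
center; distinct signal arcs crossing each circle are counted, distances
normalized by organoid radius, and control/mutant radial distributions
compared with a Mann–Whitney U test (exact enumeration for small
samples).

**Synthetic data** (`organoid_mech.synth`).  Seeded generators emulate
every modality: SLS-shaped creep traces with tracking noise, disk-well
DWI phantoms with log-normal ADC heterogeneity, Rician noise and
per-scan drift, and ring versus scattered collagen images with matched
total signal.

## Worked example

`examples/02_fiber_network.py` compares an organized (patterned) matrix
at occupied fraction p = 0.85 against a disorganized (random) one at
p = 0.95, at the default 64-node, 32-cell, R = 10 configuration:

```
patterned p=0.85: K = 8.39 +/- 0.02
random    p=0.95: K = 11.60 +/- 0.55
relative increase: 38.1%
```

K is in simulation units (k_b = λ = l₀ = 1).  Even with *more* ECM
removed overall, the disorganized matrix is markedly stiffer than the
ring-organized one — organization, not just amount, sets tissue
stiffness.  `examples/03_adc_phantom.py` shows the drift-cancelling ADC
comparison recovering an injected 9% offset:

```
mutant vs control: 9.2 +/- 1.5 % (matched t = 13.86, p = 1.6e-04, n = 5 scans)
```

The other examples (`01_creep_rheology.py`, `04_collagen_sholl.py`) walk
through SLS fitting of two organoid populations and ring-vs-scattered
Sholl discrimination.  A thin CLI wraps the same library calls:
`organoid-mech demo --out runs/demo`, `organoid-mech network compare`,
`organoid-mech rheology fit`, `organoid-mech simulate <scenario>`.

## Layout

    src/organoid_mech/   library (sls, network, adc, sholl, synth, stats,
                         pipeline, cli)
    examples/            one narrative script per capability
    tests/               pytest suite incl. end-to-end acceptance checks
    scripts/acceptance.py  headline-number reproduction
    docs/methods.md      models, parameters, numerical choices, limitations
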