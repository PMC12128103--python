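# Methods

This note records the models implemented in `pyroepl`, the numerical
choices behind them, what the synthetic inputs do and do not emulate, and
the known limitations.

## Scope and division of labor

`pyroepl` computes *reactant-only* electron-density reactivity descriptors
on volumetric grids, aggregates them per pyrolysis reaction channel, and
evaluates/refits affine barrier models.  It deliberately performs no
electronic-structure computation: real wavefunctions enter as Gaussian cube
files (density and, optionally, a precomputed ELF field); geometry
optimization, transition-state searches, frequencies and thermal
corrections are upstream concerns.  The analytic Gaussian-orbital models in
`pyroepl.fixtures` stand in for wavefunctions wherever a field-level
computation must be verified end to end.

## Grids, fields and integration

All fields live on a `UniformGrid` (origin, three step vectors, shape),
positions in bohr, densities in e/bohr³.  Defaults: 0.2 bohr spacing and a
5 bohr margin beyond the molecular bounding box.  These were chosen once as
the coarsest settings at which the fixture-model descriptor values sit on
their convergence plateaus (refining to 0.15 bohr moves basin populations
and pair indices by under 2%, and a smooth two-electron Gaussian integral
by under 0.1% — both asserted in the suite).

Integration is a midpoint Riemann sum, `sum(values) · |det(axes)|`,
optionally restricted by a voxel mask.  No adaptive quadrature: the
descriptors are grid-converged plateaus, not high-precision quadratures,
and a constant-weight sum keeps masked integrals exactly additive — the
basin-closure identity then holds to machine precision *by construction*.

Cube I/O implements the standard Gaussian cube dialect (last index fastest,
six values per line, bohr positions; negative voxel counts flag Ångström
and are converted).  Non-orthogonal axes are accepted and flagged in the
field metadata.  The orbital basis is limited to s and p primitives — it
serves the fixtures; production densities arrive as cubes.

## ELF and basin populations

The electron localization function is computed as
η = 1/(1 + (τ_P/τ_H)²) with the Pauli kinetic-energy density
τ_P = ½·Σᵢ occᵢ·|∇ψᵢ|² − |∇ρ|²/(8ρ) and the Thomas–Fermi reference
τ_H = (3/5)(6π²)^{2/3} ρ^{5/3}.  Numerical choices:

* **Density floor ρ_min = 10⁻⁶ e/bohr³.**  Where ρ → 0 the ratio
  τ_P/τ_H degenerates to 0/0; voxels below the floor get η = 0 and are
  excluded from basins.  Their density is reported as an explicit
  "residue" in the closure summary, never silently dropped.
* **τ_P clamped at zero from below.**  The quantity is positive-definite
  in exact arithmetic; small negatives are cancellation noise.
* **Basin assignment** is an on-grid steepest ascent under 26-connectivity
  with deterministic tie-breaking (lowest flat-index neighbor wins).
  Plateaus are handled explicitly: η is quantized to 9 decimals so float
  dust cannot split a physical plateau; plateau voxels adopt an uphill
  path from their rim by geodesic propagation; a connected plateau with no
  higher rim is one attractor.  This matters because any
  *single-occupied-orbital* system has τ_P ≡ 0 and hence η ≡ 1 over the
  entire live region — the topologically degenerate but physically
  meaningful limit in which the whole region is one localization domain
  (asserted on the two-center two-electron fixture: one valence basin
  holding 2.00 e).  A field that is constant over a grid with *no*
  density-floor boundary carries no information at all and is rejected.
* **Attractor merging** fuses grid maxima closer than 0.3 bohr (finite
  spacing fragments one physical attractor into neighboring voxels).
* **Synaptic classification** is declared, not derived: an attractor
  within 0.35 bohr of a nucleus with Z > 2 marks a core basin; a valence
  basin is connected to every atom whose free-atom density at the
  attractor exceeds 5% of the promolecule density there; exactly two
  connected atoms make a disynaptic basin V(A,B).  Only C–O and C–C
  disynaptic populations are exported to descriptor tables, because those
  are the bonds the barrier models consume.

The basin populations realize the electron-count expectation value as the
plain density integral over each basin; populations plus the below-floor
residue equal the total density integral exactly, and the total matches
the electron count within 10⁻² e at the default grid on the fixture
models.

## Hirshfeld populations and condensed Fukui functions

Stockholder weights w_A = ρ_A^free / Σ_B ρ_B^free use packaged
single-exponential free-atom models ρ_Z(r) = Z·ζ³/(8π)·e^{−ζr} with one
tabulated ζ per element.  This is a deliberately crude radial model: only
density *ratios* enter the weights, and the exponential is strictly
positive, so the promolecule never vanishes.  It is not suitable for
quantitative free-atom energetics — it is not used for any.

Condensed Fukui functions are vertical finite differences of Hirshfeld
populations at fixed geometry: f⁺_A = N^A(N₀+1) − N^A(N₀),
f⁻_A = N^A(N₀) − N^A(N₀−1).  **Convention note:** the radical descriptor
is implemented as the half-sum f⁰ = (f⁺ + f⁻)/2 — the standard
finite-difference average.  A plain sum of the two neighboring-state
populations (which occasionally appears in print) is dimensionally
inconsistent with a Fukui function and is not offered as an option; the
convention is stated here rather than switched silently.  Negative
condensed values are retained, never clipped.  Sum rules ⟨Σf⁺⟩ = ⟨Σf⁻⟩ = 1
hold within 10⁻² at the default grid because the state integrals differ by
exactly one electron.

An opt-in `FukuiCache` reuses site values keyed by (site, substitution
state) — the refinement of freezing unsubstituted-site values at those of
the parent sugar.  Every reuse is logged; the cache is never on by
default.

## IGM pair index

δgᵖᵃⁱʳ(r) = |∇ρ_A| + |∇ρ_B| − |∇ρ_A + ∇ρ_B| ≥ 0 (triangle inequality,
asserted voxelwise) with atomic densities ρ_A = w_A·ρ — the actual-density
(Hirshfeld) variant; a promolecular variant is available for comparison.
Gradients of the stockholder products are taken by central differences on
the grid (index derivatives mapped through the inverse axes matrix, so
sheared grids are correct).  The gross index Δgᵖᵃⁱʳ integrates δgᵖᵃⁱʳ over
the **whole grid**: the integrand has compact support in the interatomic
region, so the full-grid integral realizes the interaction domain without
an arbitrary boundary — this choice is declared, since no cutoff
isosurface convention is universal.  No division by d_AB² and no H₂
normalization anywhere: the barrier models consume the unnormalized index.

## Reaction recipes and aggregation

Each channel's descriptor means are fixed token lists over the ring-label
convention (C1–C5 with C1 anomeric, ring oxygen O, hydroxyl oxygens O1–O4
numbered by carbon, protons H_Oi/Hi):

* ring opening: f̄ over {C1:f⁰, O:f⁻, O1:f⁻}; N̄ = V(C1,O);
  Δḡ over {C1–O, O1–H_O1};
* ring contraction, channel FF1: f̄ over {C1,C2,C3:f⁰; O1,O2:f⁻};
  N̄ = V(C1,O1); Δḡ over {C2–C3, C1–O1, O2–H_O2};
* ring contraction, channel FF2: f̄ over {C1,C2:f⁰; O,O1,O2:f⁻};
  N̄ = mean of V(C1,O), V(C2,O2); Δḡ over {C1–O, C2–O2, O1–H_O1};
* eliminations i = 1…7: index-arithmetic rules generating the two f⁰
  carbons, one f⁻ hydroxyl oxygen, the broken C–O bond and the
  proton-transfer C–H pair per channel.  Channel 6 pairs the C4–O4 bond
  with the C4–H4 proton — the same carbon — and is kept exactly as the
  published rule states it.

When a recipe's hydroxyl position carries an acetyl or methoxy group the
hydroxyl proton does not exist: an O_i–H_Oi pair is relabeled to the
oxygen–linkage-carbon pair and a `RecipeWarning` is emitted; elimination
channels (no hydroxyl-proton pair) warn that the leaving molecule becomes
the acid/alcohol.  Ambiguities surface as warnings, never silent rewrites.

## Barrier models, fitting and level maps

The four packaged coefficient sets are constants with provenance; refits
run through `fit_epl` (ordinary least squares on the three descriptors
plus intercept, rank-checked, n ≥ 5) and never overwrite them.  Metrics:
MAE, RMSE, and R²_adj = 1 − (1−R²)(n−1)/(n−p−1).  Standard errors come
from the usual OLS covariance s²(XᵀX)⁻¹.  Train/validation splitting is
seeded and optionally stratified by reaction class (per-class proportions
within one row).

Because the full descriptor/barrier training set behind the published
coefficients is not printed anywhere recoverable, those coefficients are
**not** re-derived here; the fitting pipeline is instead validated by
parameter recovery on synthetic data (exact at zero noise; within 3
standard errors in ≥95% of 100 seeded replicates at σ = 1 kcal/mol,
n = 200).  The packaged 30-reaction barrier table (three species × ten
channels × five levels × two temperatures) ships as a digest-locked TSV;
cells measured under relaxed SCF convergence carry an explicit flag, and
the one channel whose transition state never converged is stored as
missing, never as zero.

Level maps are affine (slope, intercept in kcal/mol); the six packaged
maps have slopes near +1 and are applied, inverted and refitted through
one code path.  The two-point CBS extrapolation solves the exponential
SCF channel (amplitude eliminated analytically) and the closed-form
power-law correlation channel; it is exact on data generated from those
model forms, and energies pass through unit-agnostic.  Packaged exponents
α = 4.42, β = 2.46 apply to the (2,3) cardinal pair only; other pairs
require user-supplied parameters.

## What the synthetic inputs do and do not show

The toy density suite (one-center 2e, homonuclear 2e, polar 4e, bent
three-center 2e; all unit-normalized s-contractions with vertical ±1e
occupation variants) exercises every field-level code path with known
closed-form behavior: normalization, ELF limits, basin closure, Fukui sum
rules, IGM locality.  It does **not** emulate shell structure, orbital
orthogonality effects, p/d anisotropy, or the size and conformational
flexibility of real sugars — so passing tests certify the numerics of the
descriptor machinery, not the chemical accuracy of any descriptor value
for a real xylopyranose.  Real-system accuracy rests on the upstream
quantum chemistry and enters through cube files.  Similarly, the species
builder does composition/electron bookkeeping (substituent group
arithmetic, condensation with loss of water) and deliberately carries no
3-D geometry: conformer selection is out of scope.

The synthetic regression generator samples descriptors uniformly over
f̄ ∈ [0.02, 0.12], N̄ ∈ [0.8, 1.8], Δḡ ∈ [0.2, 1.2] — windows bracketing
the magnitudes the real reaction channels produce — with Gaussian noise on
the barrier.  It validates estimator correctness, not the physical claim
that real barriers are affine in the descriptors.

## Degenerate inputs and tie-breaks (summary)

* empty orbital set, zero-atom cube, value-count mismatch, grid
  mismatches, out-of-range elimination channels, duplicate descriptor
  keys, underdetermined or collinear fits, singleton strata, X = Y
  cardinals: all raise with specific messages;
* steepest-ascent ties: lowest flat-index neighbor; plateau roots: lowest
  flat-index member; attractor-merge representative: highest η, then
  lowest flat index — partitions are bit-reproducible;
* missing barrier cells are `None`; negative Fukui values are retained.

## Known limitations

* Attractor positions are grid-resolution (no continuous refinement of
  maxima); adequate because basin populations, not attractor coordinates,
  feed the models.
* The single-exponential free-atom models have no shell structure; weights
  near heavy-atom cores are qualitative.  For the organic subset (H, C, O)
  driving the descriptors this does not change basin or pair assignments
  in the fixtures.
* ELF from cube input requires the user to supply the ELF field itself;
  it cannot be reconstructed from a density cube alone (the kinetic-energy
  ingredient is not recoverable).
* Problem sizes in the test and acceptance runs use the default 0.2 bohr
  spacing on toy systems (grids of roughly 50–70 points per axis), the
  package's standard desk-scale configuration.
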