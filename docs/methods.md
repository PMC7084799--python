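# Methods

## Scope and model

`ppimutscan` analyzes a fixed two-chain complex topology plus an ordered
coordinate ensemble (multi-model PDB; times in ps assigned as k·dt). Three
analyses share that substrate:

**Contact networks.** The contact predicate is a van der Waals overlap:
atoms are in contact when `r_i + r_j − d_ij > t` with threshold
`t = −0.4 Å` by default. The inequality is strict — an overlap of exactly
−0.4 Å is *not* a contact — which is measure-zero in floating point but
fixed for determinism. Residue pairs are linked in a frame when at least
one atom pair qualifies; over a frame window an edge records its
persistence (fraction of frames present) and mean atom-pair count with
zero-frames included. Degree counts distinct partners. Only inter-chain
contacts are collected by default (the networks of interest span the
interface; the graph is then bipartite and the two chains' degree sums both
equal the edge count). Hydrogens participate when present; a flag drops
them. The neighbour search is pruned with a k-d tree at cutoff
`2·max(r) − t` and is exactly equivalent to the all-pairs brute force
(property-tested on random fixtures).

**Binding energetics.** Single-trajectory MM/PBSA without an entropy term:

    ΔG_bind = ΔE_vdW + ΔE_elec + ΔG_polar + ΔG_nonpolar

Complex and unbound chains are evaluated on identical coordinates, so all
bonded and intra-chain nonbonded terms cancel exactly and the vacuum MM
part reduces to the cross-chain pair sums: Lennard-Jones 12-6 with
Lorentz–Berthelot combining (arithmetic σ, geometric ε) and Coulomb
`f·q_i·q_j / d` with `f = 1389.35458 kJ·mol⁻¹·Å·e⁻²`, no distance cutoff,
vacuum dielectric 1. Coincident atoms across chains (d < 1e−6 Å) are a
singularity error. The absence of a cutoff matters scientifically: charged
residues far from the interface still contribute through long-range
electrostatics, which is why per-residue values of charged residues must be
read with care (see Limitations).

**Geometry.** Kabsch superposition by SVD with the reflection branch
excluded (rotations are always proper; <3 points or collinear selections
are errors). RMSD series fit each frame to a reference frame over a fit
selection (default backbone N/CA/C/O; all atoms when no backbone names
exist) and measure over a possibly different selection. RMSF is computed
about the time-average structure: frames are fitted first to the raw
coordinate mean and then refitted to the fitted mean (two passes). Starting
from the raw mean makes the result exactly invariant to frame order.
`group_by_chain` fits each chain independently so rigid inter-chain motion
does not inflate per-protein fluctuations; both modes are exposed because
"per protein" reporting is ambiguous between them. Weights are uniform
(no mass weighting).

## The Poisson–Boltzmann solver

Polar solvation comes from an in-repo finite-difference solver of the
linearized PB equation on a uniform node grid:

    ∇·(ε(x) ∇φ) − λ(x) φ = −4π f ρ(x)

with φ in kJ/mol/e, ε the relative dielectric, and λ = ε_solv·κ² nonzero
only in solvent (κ from the Debye–Hückel expression for 1:1 salt at the
configured ionic strength and temperature; ~8 Å Debye length at 150 mM,
310.15 K).

Numerical choices, in order of consequence:

- **Dielectric boundary.** Solute = union of atomic vdW spheres. Each
  finite-difference *face* between adjacent nodes is classified
  solute/solvent by its midpoint (sharp assignment). This was chosen over
  node-centred harmonic averaging because the sharp face classification
  converges monotonically on the Born-ion benchmark (errors +11.6% → +3.6%
  → +1.4% at 0.8/0.4/0.25 Å spacing) whereas the averaged variant
  oscillates around the analytic value. An optional harmonic sub-sampled
  smoothing of face dielectrics remains available (`boundary_smoothing`),
  off by default.
- **Charges** spread to the eight surrounding nodes with trilinear weights;
  potentials are read back by trilinear interpolation.
- **Boundary condition.** Dirichlet, from the Debye-screened Coulomb sum of
  all charges in the exterior dielectric.
- **Linear solve.** The 7-point system is symmetric positive definite and
  is solved by conjugate gradients with a Jacobi preconditioner to relative
  residual 1e−6 (configurable); non-convergence raises with the residual.
- **Self-energy cancellation.** G_polar = ½Σ q_i(φ_solv − φ_ref)(x_i) where
  the reference solve uses the solute dielectric everywhere and κ = 0 on
  the *identical* grid, cancelling the (spacing-dependent) grid self-energy
  of the spread charges. A system with all charges zero short-circuits to
  exactly 0.
- **Shared grids.** For binding, complex and isolated chains are all solved
  on the complex-extent grid. The uniform-dielectric reference operator is
  linear in the charges, so the complex reference is the superposition of
  the per-chain references; five solves per frame cover all six states.
  Tests verify this against the naive six-solve route.

Defaults: solute dielectric 2 (the choice made for the reference
calculations this pipeline mirrors), solvent 80, ionic strength 150 mM,
temperature 310.15 K, grid spacing 0.5 Å, padding 10 Å. The 0.8 Å "fast"
spacing used in the test suite and pipeline `--fast` mode keeps the
Born-ion error near 12% — adequate for the qualitative variant orderings
the synthetic suite probes, not for converged absolute energies.

**Nonpolar term.** `G_nonpolar = γ·SASA + c` with SASA from a Shrake–Rupley
implementation using deterministic golden-spiral quadrature points (default
512/atom, probe 1.4 Å; an isolated sphere is exact by construction, cluster
totals agree with an independent latitude–longitude quadrature within 2%).
Default γ = 0.0226778 kJ·mol⁻¹·Å⁻² with offset 0 so that far-separated
neutral chains have exactly zero binding energy; a preset with the
g_mmpbsa-style offset 3.84928 kJ/mol is provided for compatibility.

**Uncertainty.** Per-component bootstrap standard error of the ensemble
mean (default 1000 resamples, seeded). Frames are treated as independent;
no autocorrelation correction is attempted.

## Decomposition conventions

Each cross-chain pair's full MM value is booked to the residue on its *own*
chain. Consequences, both asserted in tests: each chain's ledger is
complete (chain-A rows sum to ΔE_MM, chain-B rows do too), and summing both
chains double-counts. Halving conventions were rejected because combined
domain rows should equal the plain sum of their parts. Per-residue polar
contributions reuse the per-atom potential differences of the
already-solved grids (no extra PB solves); nonpolar contributions are
per-atom SASA differences times γ. In this scheme the solvation rows of one
chain sum exactly to the binding totals; decomposition schemes in other
tools do not guarantee that, so cross-tool row-level comparisons should be
qualitative. Domain aggregation is partition-invariant (refining a domain
into two leaves the summed rows unchanged), and unmapped residues pool
under `other`.

A default domain map for PCSK9/LDLR crystal-structure numbering ships with
the I/O layer (prodomain 31–152, C-terminal 450–682, LDLR L7 / EGF(A) /
EGF(B) / β-propeller). The catalytic-domain boundary 153–449 is inferred
from its flanking domains rather than an authoritative annotation, and is
labelled as such in the docstring.

## Frame selection

Windows are inclusive at both endpoints with frames at
`start, start+stride, … ≤ end`; each requested time maps to the nearest
stored frame, ties to the earlier frame. An on-grid window therefore
selects `⌊(end−start)/stride⌋ + 1` frames — the canonical protocols (final
50 ns of a 500 ns run stored every 100 ps) give 101 frames at a 500 ps
stride and 251 at 200 ps. A stride finer than the stored sampling warns,
and raises if it would select a frame twice.

## What the synthetic generator emulates — and what it does not

The generator builds bead-level chains (three beads per residue: two
backbone-like, one side bead) on a regular geometry: residues every 6 Å,
chains 16 Å apart, declared interface pairs pointing side beads at each
other at ≈3 Å (overlap +0.4 Å) while every other cross-chain residue pair
keeps > 8 Å clearance (validated at construction; infeasible requests
raise). A five-element parameter table gives neutral LJ beads plus charged
side-bead residue types (±0.5 e, ±1.0 e), applied through the same
`assign_parameters` path as real input. Ensembles add isotropic Gaussian
jitter (default σ = 0.25 Å, per-residue overrides available); planted
contacts are clamped back inside the criterion in a configurable fraction
of frames (`persistence_target`, default 1.0) and deliberately swung out of
contact in the rest. Everything is seeded and bit-reproducible.

The standard variant suite plants three effects on a 10+10-residue complex:
a charged interface hotspot (±1 e pair at residue A:3/B:3, dominating its
chain's per-residue ledger), a *contact-gain* variant (residue A:5 acquires
two oppositely-charged partners B:4/B:6 — degree rises by 2 and the mean
binding energy becomes more favorable), and a *charge-edit* variant
(identical coordinates to wild type; only the side-bead charge of
non-interface residue A:9 shifts by −1 e, so the network is exactly
unchanged while the cutoff-free electrostatics move by tens of kJ/mol).

What passing these tests shows: the pipeline recovers contact gains,
energetic orderings, long-range charge effects and localized flexibility
*when they are present by construction*. What it does not show: anything
about real protein geometry — beads have no amino-acid shape, no rotamers,
no hydrogen-bond directionality, no calcium sites, no β-propeller fold; the
jitter is uncorrelated white noise with none of the collective motions of
real trajectories; and the MM/PBSA magnitudes on beads say nothing about
absolute binding affinities of real complexes.

## Problem sizes

The test suite runs the variant suite at 6 frames (40 for the
charge-edit statistics, where only the cheap vacuum terms are needed) with
the 0.8 Å PB grid; the Born-ion benchmark uses 0.8/0.4/0.25 Å spacings; the
RMSF closed-form check uses 1000 frames. `scripts/acceptance.py` uses the
same sizes. These are the package's validation scales; production analyses
of real ensembles would use the 0.5 Å default grid and the 101/251-frame
protocols.

## Known limitations

- Linearized PB only; no nonlinear term, no Stern (ion-exclusion) layer,
  and the dielectric boundary is the vdW union, not a molecular (rolled)
  surface — reaction-field energies for deeply buried charges are
  systematically less accurate.
- Per-frame PB solves are the cost center (~2–3 s/frame on the toy systems
  at 0.8 Å); per-residue decomposition re-evaluates frames independently of
  the ensemble-energy pass.
- No entropy estimate; reported ΔG values are end-state enthalpic/solvation
  scores, comparable between variants, not absolute affinities.
- Insertion codes and altlocs in PDB input are unsupported (error), and
  residue identity is (chain, residue number) only.
- Bootstrap SEs assume independent frames; correlated trajectories will
  look more certain than they are.
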