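# Methods

This note documents the models, numerical choices and limitations
behind pgpflex, in the order the pipeline runs them.

## Structural ensembles and selections

An ensemble is F frames × N atoms of coordinates in Å with shared atom
metadata; multi-MODEL PDB is the interchange format (fixed 8.3 columns,
hence 10⁻³ Å round-trip precision). Residue numbering follows the
file's author numbering, so selections can be written with the residue
labels used in the literature (e.g. Walker A of Pgp's NBD1 is
`resid 423-431 and name CA`, nine Cα atoms). The selection grammar is
deliberately small — `chain`, `resid` (single, list, range), `name`,
joined by `and` — and resolution is deterministic, ordered by file
position; an empty match is an error rather than an empty selection, so
a typo cannot silently produce a zero-atom analysis. Element masses
come from the IUPAC standard atomic weights; an unknown element falls
back to carbon with a logged warning rather than aborting, because CoM
analyses of protein selections are insensitive to rare exotic atoms.

## Distance traces and population histograms

CoM distances default to mass weighting; an unweighted (geometric) mode
exists because published analyses do not always state their weighting,
and for a Cα-only selection the two differ negligibly. Histograms use
0.1 Å bins anchored at integer multiples of the width (floor
convention; a sample exactly on an edge belongs to the upper bin) and
are normalized to unit mass; the pooled mean is the mean of the
concatenated samples, not the mean of per-trace means, which matters
when traces differ in length. An equilibration-discard option drops a
fixed number of leading frames per trace, with a helper to convert a
time in ns to frames when frame times are present.

## Superposition, r.m.s.f. and theoretical B-factors

Fluctuations are measured after removing global rigid-body motion: each
frame is least-squares fitted (rotation + translation, no scaling;
SVD-based) onto a reference using a fit selection (all Cα by default).
The default reference is the ensemble mean structure obtained by a
two-pass iterative fit — first onto frame 0, then onto the resulting
mean — which removes the arbitrariness of any single reference frame at
negligible cost. r.m.s.f. is the root of the time-averaged squared 3-D
displacement about each atom's mean position; for isotropic Gaussian
jitter of per-coordinate σ it converges to σ√3. The theoretical
temperature factor is θ = (8π²/3)·r.m.s.f.², the isotropic harmonic
relation between a crystallographic B-factor and a mean-square
displacement; the conversion is exact by construction and tested to
10⁻¹². RMSD against an external template uses optimal (Kabsch)
superposition with positional atom correspondence, so it is invariant
under any rigid motion of either side and never exceeds the
unsuperposed RMSD.

## Hydrogen-bond occupancy and helical defects

The published record rarely states the geometric hydrogen-bond
criterion behind an occupancy map, so it is explicit and configurable
here: the default is the heavy-atom convention d(N,O) ≤ 3.5 Å
(inclusive at the boundary), with an N–H···O angle ≥ 120° added only
when amide hydrogens are present and requested. Occupancy is the
fraction of frames in which the i(C=O)···(i+4)(N–H) bond is formed,
keyed to the acceptor residue i; pairs missing backbone atoms are
skipped with a warning, not an error, because chain termini and
non-standard residues are normal in real structures.

A helical defect is called where the bond is absent in strictly more
than 30% of frames (occupancy < 0.7). The sentence "fails to persist
for more than 30% of the time" admits a second reading — persists less
than 30% (occupancy < 0.3) — selectable via `strict_persistence`; the
default follows the grammar of the first reading. The comparison uses a
10⁻⁹ guard so that exactly 30% absent is never called (1 − 0.7 exceeds
0.3 by one ulp in binary floating point). A per-residue aggregate view
marks residue r defective when any pair with acceptor in r−4..r is
defective, for structure coloring.

## DEER forward model

For an isotropically oriented pair of nitroxide labels at distance r
(nm), the powder-averaged dipolar signal is K(t, r) = ∫₀¹ cos[(3x² − 1)
ω t] dx with ω = 2πD/r³ and D = 52.04 MHz·nm³ (nitroxide g ≈ g_e; the
constant is overridable). The kernel is evaluated in closed form
through Fresnel integrals,

  K = √(π/6φ)·[cos φ·C(q) + sin φ·S(q)], q = √(6φ/π), φ = ωt,

with the φ → 0 limit handled explicitly (K → 1). An independent
fixed-order Gauss–Legendre route exists for cross-validation; the
default order is 512 because the integrand completes ~185 oscillations
at the fastest (t = 4 µs, r = 1.5 nm) corner of the default grids, and
512 nodes reach 10⁻¹⁴ agreement with the closed form (64 nodes do not).

The measured signal model is V(t) = [1 − λ + λ·(K P Δr)]·exp(−k·t^(d/3)),
with modulation depth λ, background rate k (µs^(−d/3)) and background
dimensionality d = 3 by default; simulated noise is additive Gaussian
and always requires an explicit seed (no global random state). Traces
are normalized to V(0) = 1, including the noise at t = 0 — exactly as a
normalized experimental trace would be — which is why the inversion
must tolerate small offset and scale errors (below).

Noise convention: SNR is quoted relative to the dipolar modulation, so
a trace at SNR 30 with λ = 0.3 carries σ = λ/30 = 0.01 on the
normalized echo amplitude.

## Tikhonov inversion

Background correction first fits ln V over the tail window
(t ≥ 0.6·t_max by default, ≥ 10 points required) to ln(1−λ) − k·t^(d/3)
and divides out the pure stretched exponential, giving a form factor
with ff(0) = 1 and asymptote 1 − λ.

The inversion then fits the form factor directly as

  min over q ≥ 0, c₀ ≥ 0 of ‖c₀ + K q Δr − ff‖² + α²‖L₂ q‖²,

solved by non-negative least squares on the stacked system, where
q = λ·P(r) and c₀ absorbs the unmodulated fraction. The modulation
depth falls out as λ = Σq Δr/(c₀ + Σq Δr) and P = q/Σq Δr. Fitting
with a free intercept rather than pre-rescaling by an estimated λ makes
the recovered distribution exactly invariant to constant offsets and
overall scale errors in the form factor — the two artefacts produced by
normalizing at a single noisy t = 0 point — which otherwise appear as
spurious mass at the grid edges.

L₂ is the second-difference operator with zero boundary (P pinned
softly to zero at both grid edges). A reflective-boundary variant was
evaluated and rejected: its null space contains the constant vector, so
a flat pedestal across the whole grid is unpenalized and realistic
noise deposits unphysical mass at the far edge, biasing the recovered
mean by up to ~0.2 nm. The zero-boundary operator encodes the physical
expectation that the grid brackets the distribution.

α is chosen at the L-curve corner: maximum curvature of the parametric
(log residual, log roughness) curve over a log-spaced α grid (14 points
over 10⁻³…10², ≥ 8 required). A degenerate curve (no positive
curvature) falls back to the mid-grid α with a warning.

The background rate is refined against the full trace: the residual of
the joint model as a function of k is L-shaped — underestimating k is
cheap because the leftover decay is absorbed by spurious
short-distance mass, while overestimating it is penalized sharply —
so the refined k is the largest rate whose residual stays within a
relative tolerance (default 0.01) of the profile minimum, located by a
coarse bracket, bounded scalar minimization, and root-finding on the
tolerance contour. The tolerance was calibrated once on a dedicated
synthetic calibration set (40 seeds disjoint from the test suite's
seeds) by minimizing the mean recovery error of the distribution mean;
on noiseless data the contour collapses and k is recovered exactly.
With this pipeline a single Gaussian (4.0 nm, sd 0.3 nm) at SNR 30 is
recovered with a typical mean error of ~0.03 nm; the per-replicate
probability of exceeding 0.1 nm is about 2–3%, so a 20-replicate batch
typically lands at 19–20/20. Two equal Gaussians at 4.0 and 5.5 nm
(sd 0.25 nm) are resolved as two modes at SNR 50 with t_max = 4 µs.

The default distance grid is 1.5–8.0 nm in 256 points, bracketing the
25–60 Å range relevant to inter-NBD measurements with margin; the time
grid is taken from the input trace. Excluded-volume and
orientation-selection effects are ignored (isotropic powder average),
and spin-label rotamers are not modelled, so recovered P(r) describes
label-label, not backbone-backbone, distances.

## Sequence composition

Gly/Pro counting runs over half-open, 0-based alignment-column spans;
gaps are excluded from the residue count, ambiguity codes (B, Z, X, and
U/O) count as residues but never as G or P, and any character outside
the amino-acid alphabet plus gap is an error naming the character.
Group comparison uses a seeded percentile bootstrap (10,000 resamples
by default) on the difference of mean counts; the implementation is
plain numpy indexing so that fixed seeds reproduce CI endpoints
bit-exactly.

## Synthetic data: what it emulates and what it does not

The hinged-trajectory generator builds two rigid pseudo-domain clouds
on arms of equal length meeting at a hinge, with the opening angle set
per frame so that the noise-free CoM separation equals
base + amplitude·sin(2πf/period) exactly (defaults 40 ± 20 Å over a
50-frame period, 100 frames, 0.3 Å per-atom thermal noise). Two ideal
α-helical linkers ride on the arms, so the separation signal is
produced by hinge bending rather than free translation, and designated
(i, i+4) pairs on the first linker are geometrically broken — the
carbonyl O displaced 4 Å directly away from the partner amide N — in
exactly round(fraction·F) seeded frames. The manifest records the
planted distance trace, broken pairs, frames and seed.

The ideal helix is built from internal coordinates (NeRF chain
extension) at (φ, ψ) = (−57°, −47°) with standard backbone bond lengths
and angles, giving d(O_i, N_{i+4}) ≈ 3.09 Å — comfortably inside the
3.5 Å criterion for every pair.

These generators reproduce the statistical structure each analyzer
assumes — rigid domains, sinusoidal separation, isotropic noise,
Gaussian P(r), i.i.d. residue draws — not the physics of a membrane
transporter. Passing closure tests therefore demonstrates that the
analyzers measure what they claim on data of known ground truth; it
does not validate force fields, sampling convergence, spin-label
behaviour, or any biological claim about real trajectories.

## Problem sizes

Defaults are sized for interactive use: 100-frame ensembles of a few
hundred atoms, 200-point DEER traces on a 256-point distance grid, 20
inversion replicates for recovery statistics, 500-sequence groups for
composition power checks. All scale linearly (ensembles) or with the
NNLS cost (inversion, ~O(n_r³) worst case) and run comfortably on one
CPU.

## Known limitations

- No mmCIF input; no binary trajectory formats (the multi-MODEL PDB
  contract is the single interchange point; a DCD/XTC adapter could sit
  behind it).
- The hydrogen-bond criterion is geometric only; no DSSP/STRIDE
  secondary-structure assignment, side-chain bonds, or bifurcated-bond
  bookkeeping.
- The DEER background model is a single stretched exponential; strongly
  structured intermolecular backgrounds (e.g. oligomers) are out of
  scope, and comparisons to measured distributions remain qualitative
  because label rotamers are not modelled.
- Domain boundaries (e.g. NBD1/NBD2 residue ranges) are user-supplied;
  the package does not guess them.
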