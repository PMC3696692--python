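# pgpflex

Quantitative analytics for the conformational flexibility of ABC
transporters such as P-glycoprotein (Pgp), built around the two
complementary views of inter-domain motion: structural ensembles
(e.g. molecular-dynamics trajectories stored as multi-MODEL PDB) and
pulsed-EPR double electron-electron resonance (DEER) distance
measurements between spin-labelled sites.

An ABC exporter couples ATP binding and hydrolysis in its two
nucleotide-binding domains (NBDs) to alternating access of its
transmembrane domains (TMDs). In the inward-facing state the NBDs are
separated, and how widely that separation fluctuates — and where in the
TMD helices the flexibility originates — is the scientific question this
package quantifies.

## What it computes

**Ensemble geometry** — center-of-mass (CoM) distance time traces
between atom selections (e.g. the two NBDs, or opposing Walker A /
LSGGQ ATP-binding motifs), pooled into population distributions on a
0.1 Å grid; per-atom root-mean-square fluctuation after iterative
rigid-body superposition, converted to theoretical temperature factors
via

&nbsp;&nbsp;&nbsp;&nbsp;θ = (8π²/3) · (r.m.s.f.)²  [Å²];

minimal RMSD against an external template (Kabsch superposition); and
per-frame contact counts of a probe selection against a site selection
(e.g. lipid-tail carbons entering the TMD lumen).

**Helical-defect mapping** — occupancy of each backbone i(C=O)···(i+4)(N–H)
hydrogen bond over the ensemble (heavy-atom criterion d(N,O) ≤ 3.5 Å,
optional N–H···O angle term), with a helical defect called where the
bond is absent in more than 30% of frames. Defects mark candidate
kink/unwinding hinges in the transmembrane helices.

**DEER** — forward simulation of 4-pulse DEER dipolar signals from a
distance distribution P(r) through the powder-averaged dipolar kernel

&nbsp;&nbsp;&nbsp;&nbsp;K(t, r) = ∫₀¹ cos[(3x² − 1) ω(r) t] dx, ω(r) = 2π·D/r³, D = 52.04 MHz·nm³,

with modulation depth λ and stretched-exponential background
exp(−k·t^(d/3)); and the inverse problem — recovering P(r) from a
measured trace — solved by Tikhonov regularization (second-difference
roughness penalty, non-negativity constraint, L-curve choice of the
regularization weight α, full-trace refinement of the background rate).

**Sequence composition** — glycine/proline counts over annotated TMD
spans of aligned ABC-exporter sequence sets (Pfam-style FASTA or
Stockholm), with joint histograms and seeded bootstrap comparisons
between groups. Gly/Pro content is a sequence-level proxy for helix
malleability.

**Synthetic data** — seeded generators that emulate each input with a
machine-readable ground-truth manifest: a hinge-bending two-domain
trajectory with a planted separation signal, ideal α-helices with
planted hydrogen-bond failures, DEER traces from Gaussian-mixture
P(r), and sequence sets with controlled Gly/Pro frequencies. The whole
pipeline is testable without any external download.

## Worked example

Simulate a DEER trace from a single-Gaussian P(r) (mean 4.0 nm,
sd 0.3 nm, λ = 0.3, background k = 0.05 µs⁻¹, noise at SNR 30) and
invert it back:

```bash
$ pgpflex simulate deer --out deersim --seed 7
$ pgpflex deer deersim/deer_trace.dat --out pr.tsv
{"alpha": 2.894, "bg_k": 0.0484, "fwhm_nm": 0.776, "lambda": 0.306,
 "mean_nm": 3.977, "mode_nm": 3.998, "residual_norm": 0.133, ...}
```

The inversion recovers the planted mean distance to 0.02 nm
(3.977 vs 4.0), the modulation depth to 0.006 (0.306 vs 0.3) and the
background rate to 3% (0.0484 vs 0.05); the full width at half maximum
(0.776 nm vs the true 0.707 nm) carries the expected regularization
broadening.

Generate a hinge-bending two-domain trajectory (planted separation
40 + 20·sin Å) and measure the inter-domain CoM distance distribution:

```bash
$ pgpflex simulate trajectory --out traj --seed 7
$ pgpflex distances traj/trajectory.pdb --sel-a "chain A" --sel-b "chain B" --out d.csv
# pooled mean 40.01 A, support 40.10 A
```

The pooled mean matches the planted 40 Å base and the histogram support
spans the full 40 Å peak-to-peak range of the planted signal.

Library use mirrors the CLI:

```python
from pgpflex import deer, geometry, synthetic

trace, truth, manifest = synthetic.make_synthetic_deer(
    synthetic.DeerSimConfig(noise_sigma=0.01, seed=7))
result = deer.invert_trace(trace)
mean, mode, fwhm, support = deer.distribution_stats(result.p_hat)
```

A multi-stage run (distances, histogram, r.m.s.f., H-bonds, DEER,
Gly/Pro) is driven by a single YAML config through `pgpflex run
config.yaml`; every output directory carries a `summary.json` with the
config hash, and a rerun with the same inputs and seed is
byte-identical.

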