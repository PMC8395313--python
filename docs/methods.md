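# Methods

`helimem` analyses how short cationic helical peptides (anticancer /
antimicrobial peptides, 12–40 residues) associate with planar lipid
bilayers.  It has two halves: sequence-level amphipathicity profiling, and
trajectory-level structural metrics feeding a binding-mode classifier.  All
trajectory inputs here are synthetic — the generator fabricates geometry
with known ground truth; it performs no molecular dynamics.

## Sequence metrics

**Net charge** at neutral pH uses the integer convention Lys/Arg +1,
Asp/Glu −1, His 0, free N-terminus +1, free-acid C-terminus −1 (0 when
amidated).  Terminal chemistry is an explicit flag on every
`PeptideSequence`, never inferred, because synthetic peptides in this family
are usually C-terminally amidated and the flag shifts the charge by one.
No pKa-based fractional-charge model is attempted.

**Mean hydrophobicity `<H>`** scores each residue on the Fauchère–Pliska
octanol/water partition scale (stored at the published 2-decimal precision,
Gly = 0.00), averages over every contiguous 11-residue window, then averages
the window values.  A sequence shorter than the window is a single window.
This window-averaging convention is the one used by the HELIQUEST web
server, and it reproduces published reference values for these peptides to
2 decimals.

**Mean hydrophobic moment `<muH>`** is the Eisenberg moment per window:

    muH = (1/W) * | sum_k H_k * exp(i * k * delta) |,   delta = 100°

with `k` indexing residues inside the window and 100° the per-residue twist
of an ideal α-helix; window values are averaged the same way.  The helical
wheel projection places residue `k` at azimuth `(k·delta) mod 360` and the
hydrophobic-face arrow is the argument of the same complex sum, so the face
magnitude equals `muH` recomputed with window = sequence length (asserted in
tests).  Published comparisons round half-up to 2 decimals.

Known edge: for the 37-residue cathelicidin in the bundled fixture the
printed reference charge is +6 while the stated convention with an amidated
C-terminus gives +7; the package reports the convention's value and leaves
the flag to the caller.  Two of the published 12-residue segment values for
that peptide (the 13–24 moment and the 25–36 hydrophobicity) differ from
this procedure by 0.01–0.02 after rounding; the tests assert only the values
that reproduce.

## Secondary structure and helicity

Helicity is assigned from backbone geometry by the Kabsch–Sander
hydrogen-bond criterion.  Amide hydrogens are always reconstructed (1.0 Å
from N, anti-parallel to the preceding C=O; residue 1 and prolines get
none) unless a trust-input flag is set — deterministic placement beats
trusting heterogeneous input files.  The bond energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

is evaluated in Å (internal coordinates are nm; the conversion happens at
the call boundary) and a bond is called at E < −0.5 kcal/mol, with a 0.5 Å
clash guard that rejects malformed geometry.  Two consecutive i→i+4
hydrogen-bonded turns promote residues i..i+3 to `H`; the reduced alphabet
is {H, T, C} because only α-helicity feeds the downstream analysis (3₁₀/π
helices and strands are deliberately not distinguished; counting 3₁₀ toward
helicity is switchable only by editing the assignment, a documented
limitation).  The helicity fraction is `#H / (L − 2)`: the two terminal
residues can never satisfy the two-turn rule and are counted as inherent
coil.  On ideal generated helices the label strings agree exactly with an
independent DSSP implementation (mdtraj), which the test suite uses as an
external oracle.

## Membrane geometry

The bilayer is reduced to its phosphorus atoms.  Leaflets are split about
the median P z-coordinate (ties to the lower leaflet; a point cloud with no
0.5 nm gap is rejected as "no bilayer"), and each leaflet's phosphate plane
is the mean z of its P atoms.  The membrane normal is fixed to z — a
flat-bilayer assumption matching the generator; no curvature handling, no
periodic-boundary unwrapping (inputs must be whole molecules).

* **Surface distance**: |z_COM(peptide) − z_COM(nearer leaflet P)|, with a
  mass-weighted COM over all peptide atoms (standard atomic masses; the
  side-chain pseudo-atom carries its residue's lumped side-chain mass).
  Hydrogens are included when present, toggleable.
* **Tilt**: the helix axis is the largest-variance principal direction of
  the CA positions of the longest helical run (all CAs when that run is
  shorter than 5 residues), oriented N→C; tilt is the angle to z folded to
  [0°, 90°] (90° = lying in-plane, 0° = standing), so it is invariant to
  the axis sign.  The in-plane azimuth of the same axis is kept for the
  swing analysis.
* **Insertion depth**: per residue, the signed z offset of the side-chain
  centroid (CA for Gly) from the nearer phosphate plane; negative means
  buried toward the membrane interior.  For the lower leaflet the raw z
  difference is sign-flipped so that "negative = inserted" holds for both
  leaflets; only the upper leaflet occurs in generated data.  Side-chain
  centroids are a deliberate heuristic — depths are read from a single
  pseudo-atom, not a rotamer model.
* **Smoothing**: exponential averaging `y_t = α·x_t + (1−α)·y_{t−1}` with
  default α = 0.05 (a config knob; the raw, unsmoothed traces feed the
  classifier).

## Binding-mode classifier

Three recurring association geometries are distinguished, plus unbound:

| mode | picture | rule (over the final third of the trajectory) |
|------|---------|-----------------------------------------------|
| I    | carpet: helix flat on the surface | mean helicity ≥ 0.6 and median tilt ≥ 60° |
| II   | partial helix + buried anchor | 0.2 ≤ mean helicity < 0.6 and some residue's mean depth < −0.1 nm |
| III  | antenna: standing helix, N-terminal tether | mean helicity ≥ 0.6, median tilt < 45°, COM above the phosphate plane, one of the first three residues below it |
| unbound | — | fewer than half the frames have distance < 1.2 nm |

The cuts are quantitative stand-ins for qualitative descriptors ("highly
helical", "perpendicular"); they live in one `ClassifierThresholds` block
and are chosen to separate the generator's regimes cleanly.  When no rule
fires the classifier returns the nearest rule by its worst normalised
margin, flagged `low_confidence` — classification is total on valid input.
Azimuth circular variance (the "swing" signature of mode III) and the
xy-projected convex-hull footprint area are reported as evidence, not
gated on, since only simulations demonstrate them.  Mixture populations are
out of scope; a single mode plus evidence scores is always reported.

**LD band signs.** Flow linear dichroism (LD = A∥ − A⊥ of flow-aligned
vesicles) reports helix orientation: the π→π* transition moment (~210 nm)
lies along the helix axis, the n→π* moment (~222 nm) perpendicular to it.
With the perpendicular moment averaged over rotation about the axis, its
effective orientation factor is −(3cos²θ−1)/2 against the axis's 3cos²θ−1,
so the two band signs are always opposite, both nulling within ±1° of the
magic angle (54.74°).  Signs only — predicting LD magnitudes would require
the flow cell's orientation parameter, which is out of scope.

## Synthetic generator

The generator emulates, at toy scale, a simulation setup in which a helical
peptide starts near a planar bilayer.  Defaults (the fixed study
conditions): phosphate planes at ±2.0 nm, 36 P atoms per leaflet on a
0.8 nm xy grid with Gaussian z-jitter σ = 0.03 nm; 100 frames at 1 ns
spacing (echoing a 100-point trace of a long production run); bound
peptides ride 0.3 nm above the phosphate plane; anchors bury 0.4 nm below
it; unbound peptides stay 3.2 nm above; mode III stands at 20° tilt with a
15°/frame azimuth random walk about the anchor point.

Backbones are built by forward kinematics from standard bond
lengths/angles with φ = −57°, ψ = −47° (ideal α-helix: 1.5 Å rise, 100°
twist, CA–CA 3.8 Å, i→i+4 H-bonds), one pseudo-atom per side chain at the
residue's average centroid distance.  Partial folding re-samples φ/ψ in a
chosen interval uniformly from the extended/PPII coil basin and rebuilds
the chain, leaving the upstream segment bit-identical.  Each frame is a
rigid placement of the base conformation (rigid-body jitter only, no
per-atom noise — this keeps the generated helicity an exact ground truth);
mode III additionally rotates about z through the anchor.  All randomness
flows from the single spec seed, so equal specs give byte-identical PDB
files.

What the generator does **not** emulate: force-field energetics, water,
lipid chains, peptide flexibility beyond the fixed conformation, binding
kinetics (every frame is already in the target state), curvature, or
periodic boundaries.  Passing recovery tests therefore shows that the
*measurement and classification* chain is correct on clean geometry, not
that the classifier would resolve ambiguous real simulations.

## Numerical choices

* Rounding for published-table comparison: 2 decimals, half away from zero.
* Helix-axis fit: SVD principal component; degenerate below 5 CAs (rejected).
* Footprint: scipy convex hull of the xy projection; collinear input → 0.
* Tie-breaks: leaflet split ties to the lower leaflet, nearer-leaflet
  distance ties to the upper; classifier rule order unbound → I → II → III.
* PDB round trip is exact to the format's 3-decimal Å columns (1e-3 Å);
  trajectory frame times ride in a `REMARK 250 TIMESTEP_PS` line.

## Problem sizes

Test and acceptance runs use 13–37-residue peptides, 36 P per leaflet,
trajectories of 30–100 frames, and 100 seeded trajectories (25 per mode)
for the recovery rate — sizes chosen so the whole suite runs in well under
a minute on one core while every code path is exercised at the same
geometry the metrics assume.
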