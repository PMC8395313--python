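# helimem

Analysis toolkit for **helical membrane-active peptides** — the short
cationic anticancer/antimicrobial peptides (ACPs/AMPs) that fold into
amphipathic α-helices at lipid bilayers.  It answers two questions a
peptide biophysicist asks constantly:

1. **From the sequence alone** — how amphipathic is this peptide?
   Net charge at neutral pH, windowed mean hydrophobicity `<H>`
   (Fauchère–Pliska octanol/water scale) and the Eisenberg mean hydrophobic
   moment `<muH>`, plus helical-wheel coordinates with the hydrophobic-face
   arrow.  Per window of 11 residues:

   `muH = (1/W) |Σ_k H_k · exp(i·k·100°)|`

2. **From a peptide + bilayer trajectory** — how is it bound?
   Kabsch–Sander helicity per frame, peptide–surface distance from the
   phosphate planes, helix tilt against the membrane normal, per-residue
   insertion depths — classified into one of three binding modes:
   **I** carpet-like (highly helical, lying flat on the surface),
   **II** partially helical with a side chain anchored below the phosphate
   plane, **III** antenna-like (standing helix tethered by its N-terminal
   residues, free to swing), or **unbound**.  Helix tilt also predicts the
   signs of the two flow linear-dichroism bands (~210 nm π→π* along the
   axis, ~222 nm n→π* perpendicular; opposite signs, both nulling at the
   magic angle 54.7°).

A seeded synthetic-trajectory generator builds ideal/partial helices over
virtual phosphorus planes with controllable mode, tilt, depth and disorder —
ground-truth inputs for testing the whole measurement chain.  See
`docs/methods.md` for models, assumptions and limitations.

## Worked example

Profile the five bundled study peptides:

```
$ helimem profile
id        length  net_charge  mean_H  mean_muH  window  scale
LasioIII  15      6           0.54    0.77      11      fauchere_pliska
Macro1    13      4           0.57    0.54      11      fauchere_pliska
TempoLa   13      3           0.49    0.73      11      fauchere_pliska
FK-16     16      5           0.32    0.78      11      fauchere_pliska
LL-37     37      7           0.13    0.65      11      fauchere_pliska
```

`mean_H`/`mean_muH` are the 11-residue-window averages described above: high
`muH` (LasioIII 0.77, FK-16 0.78) marks strongly amphipathic helices; net
charge counts K/R − D/E plus a free N-terminus, with the amidated C-terminus
contributing 0.

Generate a synthetic "antenna" (mode III) trajectory and classify it back:

```
$ helimem simulate --sequence LLRHVVKILEKYL --mode III --seed 3 --frames 100 --out sim
sim/traj_III_seed3.pdb
$ helimem analyze sim/traj_III_seed3.pdb --out sim
III
```

`analyze` writes four trace tables (`*_helicity.tsv`, `*_distance.tsv`,
`*_tilt.tsv`, `*_depths.tsv`) and a JSON mode call whose evidence block
shows *why*: mean helicity 1.0, median tilt ≈ 22° (standing), COM ≈ 0.7 nm
above the phosphate plane with the N-terminal residues anchored ≈ 0.25 nm
below it, and a large azimuth spread (the swing).  Same seed, same outputs —
trajectories and calls are byte-reproducible.

The same works from Python:

```python
from helimem import SyntheticSpec, generate_mode_trajectory, analyze_trajectory

spec = SyntheticSpec(sequence="VNWKKILGKIIKVVK", mode="II", seed=7,
                     disorder_range=(1, 7))   # disordered N-term, Trp3 anchor
result = analyze_trajectory(generate_mode_trajectory(spec))
print(result.call.mode)                        # 'II'
print(result.call.evidence["anchor_depth_min"])  # ~ -0.4 nm (buried Trp)
```

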