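# ploopflex

Conformational comparison and enzyme kinetics for P-loop phosphatases.

Protein tyrosine phosphatases (PTPs) carry an invariant signature motif,
HCxxGxxR, whose backbone forms the phosphate-binding loop (P-loop). Whether
the enzyme is catalytically competent depends on a subtle backbone property:
in the active conformation the main-chain amide N–H groups of the central
motif residues all point into the active-site pocket, creating the positive
electrostatic cradle that binds the substrate phosphate and lowers the pKa
of the catalytic cysteine; in inactive conformations they point away. Some
phosphatases — notably thermophilic archaeal enzymes carrying a tandem
glycine (GG) pair at motif positions 4–5 — can switch between these two
states, flipping individual peptide bonds and re-wiring the hydrogen-bond
network between the P-loop and the neighbouring α4−α5 loop.

`ploopflex` implements the complete analysis chain used to characterise such
a switch from crystal structures and activity assays:

- **Structure I/O** — PDB/mmCIF reading (via gemmi) into a uniform
  hierarchy, altloc resolution, atom selection, sequence extraction.
- **Geometry** — closed-form least-squares (Kabsch) superposition,
  fixed-frame region RMSDs, signed torsion angles, and sequence-guided
  structural alignment with iterative outlier trimming ("N structurally
  aligned residues").
- **Conformation** — per-residue φ/ψ/ω tables, glycine-aware Ramachandran
  region classification, peptide-bond flip detection between conformers,
  P-loop active/inactive classification from amide orientations, and
  normalized 10°-bin dihedral histograms over multi-model ensembles.
- **Interactions** — geometric hydrogen-bond detection on heavy atoms,
  hydrogen-bond network differencing between conformers, and side-chain
  carbon–carbon packing-contact counts (the standard packing correlate of
  thermostability).
- **Kinetics** — initial velocities from fluorogenic progress curves
  (least-squares slope over a 2–10 min window) and Michaelis–Menten fitting,

      v = Vmax · S / (KM + S),    kcat = Vmax / [E],

  by nonlinear least squares or Lineweaver–Burk, with catalytic-efficiency
  (kcat/KM) fold-change comparison.
- **Synthetic data** — deterministic generators for all of the above: toy
  peptides built to prescribed dihedrals, known rigid motions, constructed
  peptide flips, controlled P-loop fixtures, and simulated plate assays.

## Worked example

`examples/05_kinetics_fit.py` simulates a DiFMUP-style assay at the
published wild-type parameters for 20 °C and 60 °C (product read every
2 min for 10 min at 50–1500 µM substrate, 10 nM enzyme, 2% read noise),
refits the rate law, and compares efficiencies:

```
20C: kcat =   4.69 1/s   KM = 0.705 mM   kcat/KM =    6.65 1/(s mM)
60C: kcat =  29.58 1/s   KM = 0.263 mM   kcat/KM =  112.38 1/(s mM)
catalytic efficiency at 60C / 20C = 16.9-fold
```

The fits recover the generating parameters (4.74 s⁻¹ / 0.719 mM and
30.0 s⁻¹ / 0.276 mM) to within the simulated read noise, and the
temperature activation of the enzyme comes out as a ~16–17-fold gain in
kcat/KM. The other scripts in `examples/` each demonstrate one capability
(conformer comparison and flip detection, P-loop state calls, H-bond
network differencing, packing contacts, ensemble histograms) and print a
line explaining what the numbers mean.

A thin CLI mirrors the library:

```sh
ploopflex compare formI.pdb formII.pdb --region 92-99 --motif-start 92 --json
ploopflex contacts formII.pdb --residue 2 --cutoff 4.5
ploopflex kinetics fit assay.csv --method nonlinear
```

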