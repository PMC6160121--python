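# cormbind

Analysis pipeline for characterizing how CO-releasing molecules (CORMs)
— prodrug metal carbonyl complexes such as the molybdenum piano-stool
complex [Mo(η⁵-Cp)(CH₂COOH)(CO)₃] — interact non-covalently with serum
albumin, the plasma protein that would carry them in circulation. The
package is aimed at researchers combining fluorescence titrations,
far-UV circular dichroism and multi-copy ligand molecular-dynamics
ensembles to answer four questions: does the ligand quench the
protein's tryptophan fluorescence, and by a dynamic or static
mechanism? does binding perturb secondary structure? which residues and
which ligand moieties mediate binding? and do the binding sites carry
over to the human protein?

## What it computes

**Quenching** (`cormbind.quenching`). Stern-Volmer, I₀/I = 1 + K_sv[Q],
and Lehrer, I/I₀ = (1 − f_b) + f_b/(1 + K_sv[Q]), fits with inner-filter
correction, bounded multistart nonlinear least squares and
variance-stabilized residuals. f_b is the fraction of emission
accessible to the quencher: for albumin's two buried tryptophans,
f_b ≈ 0.5 means the quencher reaches exactly one. Welch's t-test on
replicate (or bootstrap) K_sv at two temperatures classifies the
mechanism: K_sv rising with temperature ⇒ dynamic (collisional),
falling ⇒ static (complex formation).

**CD** (`cormbind.cd`). Mean residue molar ellipticity
MRME = θ/(10·C·N·d), location of the α-helix 208/222 nm double
minimum, and a change test on the maximum MRME deviation relative to
the spectral dynamic range.

**Contacts** (`cormbind.contacts`). Per-residue ligand occupancy
(fraction of frames with any ligand copy within 0.4 nm heavy-atom
distance), binding residues at strictly > 30% occupancy,
moiety-resolved interaction probabilities (Cp ring / carbonyls /
carboxyl), geometric hydrogen-bond detection, Kabsch RMSD and radius of
gyration, and a tryptophan report predicting f_b = (#binding Trp)/(#Trp)
for direct comparison with the fluorescence fit.

**Site mapping** (`cormbind.sites`). Global BLOSUM62 alignment with
identity/similarity percentages, conservation classification of
interacting residues across species, and three-way overlap with
reference residue sets such as albumin's seven fatty-acid sites.

**Synthetic data** (`cormbind.synthetic`). Seeded generators for all of
the above — Lehrer titrations, helix/coil CD spectra, and kinematic
trajectory ensembles around a coarse self-avoiding protein with planted
binding hotspots of known expected occupancy — so the entire pipeline
runs and is tested without any external data.

## Worked example

Generate a synthetic study and run every stage (`cormbind --help` lists
the subcommands):

```sh
cormbind simulate --out run/data --seed 11
cormbind quench --low run/data/titration_25C.csv \
                --high run/data/titration_37C.csv --out run --seed 1
cormbind cd --spectra run/data/cd_0_BSA.csv --spectra run/data/cd_1_BSA_10uM.csv \
            --spectra run/data/cd_2_BSA_25uM.csv --spectra run/data/cd_3_BSA_50uM.csv --out run
cormbind contacts --traj run/data/trajectories --out run
cormbind report --run-dir run
```

prints

```
mechanism: dynamic (p=9.32e-88)
unchanged
binding residues (> 30% occupancy): [5, 14, 30]
modules present: cd, contacts, quench
quenching: mechanism=dynamic, fitted fb=0.5070252954715581
cross-check: |fitted fb - Trp-predicted fb| = 0.007
binding residues: [5, 14, 30]
CD: unchanged
```

Reading the output: the synthetic titrations were generated at
K_sv = 0.038 µM⁻¹ (25 °C) and 0.058 µM⁻¹ (37 °C) with accessible
fractions 0.49/0.53; the fits recover K_sv = 0.035 ± 0.007 and
0.050 ± 0.006 µM⁻¹, and since K_sv rises with temperature the mechanism
is called **dynamic**. The fitted f_b ≈ 0.51 says half the emission is
quenchable. The trajectory ensemble planted three hotspots (residues 5,
14, 30, one of which — 14 — is a tryptophan; the second tryptophan at
22 is not a site): occupancy analysis recovers exactly those residues
above the 30% criterion, so the Trp report predicts f_b = 1/2 — within
0.007 of the fluorescence fit, reproducing the consistency check
between the two experiments. The moiety profile for the same run is
ring 0.44 / carbonyl 0.46 / carboxyl 0.11: binding is dominated by the
hydrophobic ring and carbonyl faces. The CD spectra differ only by
noise, so the protein's secondary structure is reported unchanged.

See `docs/methods.md` for model details, parameter conventions and the
limitations of the synthetic generators.

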