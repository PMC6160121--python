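# Methods

This note documents the models implemented in `cormbind`, the choices
made where the design was genuinely open, and what the synthetic data
generators do and do not emulate.

## Fluorescence quenching

A quencher Q titrated into a protein solution reduces the intrinsic
tryptophan emission intensity I read at the emission maximum. Two models
are fit to each titration:

* **Stern-Volmer** (homogeneous, collisional): I0/I = 1 + Ksv [Q].
* **Lehrer** (partial accessibility): I/I0 = (1 - fb) + fb / (1 + Ksv [Q]),
  where fb is the fraction of emission from fluorophores the quencher can
  reach. At fb = 1 the Lehrer curve is the Stern-Volmer inverse; as
  [Q] grows it plateaus at 1 - fb. For a protein with m equal-yield
  fluorophores of which k are accessible, fb = k/m; serum albumin's two
  buried tryptophans with one accessible give the diagnostic fb ≈ 0.5.

Concentrations are fixed in µM so Ksv is reported in µM⁻¹.

**Inner-filter correction.** When absorbances at the excitation and
emission wavelengths are recorded, intensities are multiplied by
`10**((A_ex + A_em)/2)`, the standard cuvette-midpoint correction,
before fitting. Without absorbances the series passes through unchanged
with a logged notice.

**Fitting.** The Lehrer fit is nonlinear least squares on the I/I0 scale
for the q > 0 points (the q = 0 point defines I0 and is satisfied
identically). Residuals are *relative* — divided by the model
prediction — because fluorimeter noise scales with the signal;
unweighted fitting of such data visibly biases Ksv upward at a 12-point,
2%-noise design, while the variance-stabilized objective removes most of
that bias. Fits are bounded (Ksv > 0, 0 < fb ≤ 1) and started from a
4 × 4 multistart grid, Ksv ∈ {0.001, 0.01, 0.1, 1} µM⁻¹ ×
fb ∈ {0.25, 0.5, 0.75, 1}; the lowest-cost solution wins and cost ties
resolve toward the smaller Ksv. Standard errors come from the
Gauss-Newton covariance of the weighted problem; the reported `rss` is
the plain residual sum of squares on I/I0 so nested models remain
comparable. The Stern-Volmer fit is the one-parameter regression of
I0/I - 1 on q through the origin (the intercept is exact by
construction); a non-positive slope is clipped to zero and flagged.

**Mechanism classification.** Ksv rising with temperature indicates
diffusion-controlled (dynamic) quenching; falling Ksv indicates static,
ground-state-complex quenching. `compare_ksv` runs Welch's
unequal-variance t-test on replicate Ksv estimates at two temperatures
and calls `dynamic`/`static` only when the difference is significant at
α (default 0.05) and in the corresponding direction, otherwise
`inconclusive`. When only one titration exists per temperature,
replicate spread is supplied by seeded residual-resampling bootstrap
(default 200 refits): the published ± uncertainties do not state a
replicate structure, so the bootstrap is the package's way of attaching
a sampling distribution to a single curve.

## Circular dichroism

Raw far-UV ellipticity θ (mdeg) on a 195–260 nm grid is normalized to
mean residue molar ellipticity

    MRME(λ) = θ(λ) / (10 · C · N · d)   [deg·cm²·dmol⁻¹]

with molar protein concentration C, residue count N (583 for the mature
bovine serum albumin chain, overridable) and path length d in cm. This
is the residue-count form of the convention; the mean-residue-weight
form differs only through the definition of N.

Band minima are located after light Savitzky-Golay smoothing (window 7,
order 2) by a strict discrete local-minimum test, restricted to the
204–212 and 218–226 nm windows around the canonical α-helix double
minimum; only the deepest minimum per window is reported.

`spectra_change` resamples every spectrum onto the reference grid
(linear interpolation), converts to MRME and reports the maximum
absolute deviation normalized by the reference's dynamic range
(max − min). The default tolerance is 5% of that range — the published
observation being qualitative ("no alteration"), the threshold is a
package choice sized to sit well above instrument noise and well below
any real secondary-structure transition.

## Trajectory contact analysis

All coordinates are nm, residue numbering 1-based.

* **Contact criterion:** residue r contacts ligand copy ℓ when the
  minimum heavy-atom pair distance is ≤ 0.4 nm (4 Å, the common
  contact-map convention; configurable). Hydrogens are excluded.
* **Occupancy:** a residue is "in contact" in a frame when *any* ligand
  copy touches it. Per-replicate frame fractions are averaged across
  replicates by default (`per_replicate_mean`; replicates are
  independent simulations); a `pooled` mode lumps frames for
  single-replicate use. For equal-length replicates the two coincide.
* **Binding residues:** occupancy strictly greater than the threshold
  (default 0.30) — strict because the criterion is "more than 30% of
  the simulation time", so a residue at exactly 0.30 is excluded.
* **Moiety profile:** for each (frame, copy) pair that is in protein
  contact at all, each moiety (ring / carbonyl / carboxyl) scores when
  at least one of its atoms is within the cutoff. Probabilities are
  conditioned on the copy being bound, because the question is which
  moiety mediates binding rather than how often copies diffuse nearby;
  an unconditional mode is available. The metal `center` atom counts
  toward contact detection but belongs to no moiety.
* **Hydrogen bonds:** with explicit hydrogens, donor–acceptor distance
  ≤ 0.35 nm and donor–H–acceptor angle ≥ 120°; in coarse mode (no
  hydrogens) a distance-only criterion at 0.32 nm, with each unordered
  atom pair reported once since donor/acceptor roles are ambiguous.
  Donors/acceptors come from templates: ligand carboxyl oxygens donate
  and accept, carbonyl oxygens accept; protein side, any N/O atom in
  atomistic topologies, or the bead of a polar residue
  (S/T/Y/N/Q/D/E/K/R/H/W) in one-bead-per-residue topologies.
* **Structure metrics:** per-frame RMSD to the first frame after
  optimal least-squares (Kabsch) superposition of the protein atoms —
  rigid motions score zero to ≤ 1e-6 nm — and unit-mass radius of
  gyration. Raw (non-superposed) RMSD is available for closed-form
  checks.
* **Trp report:** predicted accessible fraction = (# binding Trp) /
  (# Trp) under the equal-quantum-yield assumption, directly comparable
  with the fitted Lehrer fb.

## Binding-site mapping

Global pairwise alignment is Needleman–Wunsch with affine gaps
(BLOSUM62, open 10, extend 0.5 — common defaults; the published
alignment states no method). Identity is the fraction of identical
columns over the aligned span *excluding terminal-gap columns*; this
denominator choice matters for cross-species identity figures and is
therefore explicit. Similarity counts non-identical columns whose
residues share a physicochemical class; the default partition is
{AVLIM} {FWY} {ST} {NQ} {DE} {KRH} {C} {G} {P}, configurable.
Site conservation classifies each interacting residue through the
alignment column map as conserved / similar / nonconserved / unaligned
(gap partner); fractions sum to 1. Site sets are compared as an exact
three-way partition (only-A / both / only-B), with cross-species sets
first mapped through the column map (gap-aligned residues dropped and
counted). Reference residue lists such as the seven fatty-acid sites
are user-supplied configuration, not shipped data.

## Synthetic data generators

The generators define the study conditions for every test; they are
seeded and bit-reproducible.

* **Titrations:** Lehrer curves with multiplicative Gaussian noise
  (relative SD, default 2%) on the q > 0 points; the q = 0 point
  defines I0 noiselessly. Default design: 12 points, q ∈ [0, 50] µM,
  parameters (0.038 µM⁻¹, 0.49) and (0.058 µM⁻¹, 0.53) at 25 °C and
  37 °C respectively.
* **CD spectra:** fixed Gaussian-mixture basis shapes — helix with a
  positive band at 192 nm and minima at 208/222 nm (σ = 4.5 nm), coil
  with a deep 197 nm minimum — mixed by helix fraction (default 0.65,
  an albumin-like helicity), scaled to machine units for 3 µM protein,
  583 residues, 1 mm path, plus mdeg-level Gaussian noise.
* **Protein:** a compact self-avoiding random walk, one bead per
  residue, step 0.38 nm, minimum separation 0.34 nm, spherical
  confinement radius ∝ n^(1/3); random residue names with two TRP
  placed at ~23% and ~36% of the chain (echoing the albumin Trp pair,
  one inside a planted site and one outside). Placement failure within
  the retry cap raises.
* **Ligand:** an idealized four-legged piano-stool: metal center, a
  5-carbon ring 0.26 nm below it, three C–O carbonyl legs splayed
  upward and a carboxymethyl leg (CH2 + COOH) reaching highest. Bond
  lengths are free parameters — only contact geometry matters — and the
  faces are deliberately well separated so that orientation determines
  which moiety touches.
* **Trajectories:** kinematic, not physical MD (MD engines are out of
  scope). One ligand copy is dedicated to each hotspot residue and
  follows a two-state bound/free Markov chain with continuation
  probability `hotspot_dwell_prob`, entry probability solved from the
  stationary condition so the expected occupancy equals
  `hotspot_occupancy`, and the initial state drawn from the stationary
  distribution — expected occupancy is exact from frame 0, and when
  dwell probability equals the target occupancy the frames are
  independent, making binomial sampling error exact for tests. Dwell 0
  disables planting (a zero-length dwell is no binding), leaving
  hotspots at background level. While bound, the copy presents a moiety
  face drawn from `face_weights` (default ring 0.45 / carbonyl 0.45 /
  carboxyl 0.10, encoding hydrophobically dominated binding) anchored
  0.26 nm from the hotspot bead along the local outward surface normal.
  Free copies jump-diffuse in a shell around the protein and
  occasionally graze the surface, providing unspecific background
  contacts; unbound designated copies park farther out, beyond contact
  range. The protein vibrates with 0.01 nm isotropic jitter about its
  reference coordinates.

**Desk-scale defaults** are 5 replicates × 400 frames × 5 ligand copies
around a 60-residue chain with hotspots at residues 5, 14 (a TRP) and
30. The full-scale published configuration (50 replicates, 25 copies,
583 residues) is reachable by overriding `GeneratorConfig`; analyses
are O(frames × protein atoms × ligand atoms) and scale linearly.

**What the generator does not emulate:** real energetics and kinetics
(no force field, water, electrostatics or periodic boundaries), side
chains and packing of a real protein, ligand flexibility, correlated
binding of multiple copies to one site, and binding-site formation by
tertiary structure. Tests passing on these data therefore validate the
*analysis operations* — contact detection, occupancy statistics, moiety
attribution, model fitting — not any claim about real albumin
trajectories.

## Numerical notes and limitations

* Lehrer fit non-convergence from all 16 starts raises with
  diagnostics; fb at its upper bound is flagged (homogeneous
  population).
* Welch's test on two zero-variance identical replicate sets is defined
  as p = 1 (inconclusive).
* `spectra_change` requires a nonzero reference dynamic range.
* PDB output stores Å to 3 decimals, so ensemble round-trips are exact
  to 5e-5 nm; occupancy/moiety results are invariant to this rounding
  in practice, but bitwise coordinate equality across a PDB round-trip
  is not guaranteed.
* The bootstrap mechanism test treats refits of one curve as replicates;
  it quantifies fit uncertainty, not between-experiment variability, and
  will overstate significance relative to true biological replicates.
* Single-sequence FASTA inputs are assumed for site mapping; the first
  record is used.
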