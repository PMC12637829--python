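# Methods

`fibrilkit` quantifies three aspects of amyloid fibril polymorphs — helical
geometry, solvation-based stabilization energetics, and chaperone-site
accessibility — and analyzes single-molecule force-extension curves of a
protein tethered between dsDNA handles. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Fibril models and helical geometry

A fibril model is a finite stack of protein chains, one per layer. Chains
are ordered by projecting their Cα centroids on the fibril axis, which is
itself the least-squares line through the per-layer centroids, oriented from
the first to the last layer. The central chain (lower of the two middle
layers for even stacks) is the representative layer for all single-layer
analyses, because edge chains lack neighbors on one side.

**Rise and twist.** For each consecutive layer pair the optimal rigid
transform is computed (Kabsch superposition over all matched heavy atoms);
the twist is the rotation angle about the screw axis, signed by the
right-hand rule about the axis direction, and the rise is the centroid
displacement along it. Values are averaged over pairs; their standard
deviation is reported as a quality metric. The sign convention makes a
+3.95°/layer fibril right-handed. The crossover — the length over which the
twisted fibril completes a half turn — is `rise × 180 / |twist|` for a
1-start helix and is undefined at zero twist.

**Warping RMSD.** Layer non-planarity is the RMS deviation of the core
residues' Cα atoms of the central chain from a reference plane. Two
references are reported: the plane normal to the fibril axis through the Cα
centroid, and the least-squares best-fit plane (smallest principal direction
of the centered point cloud). The best-fit value can never exceed the
normal-plane value. Degenerate (collinear) Cα sets raise an error rather
than returning an arbitrary plane. Note a subtlety of true least-squares
planes: for a point set whose in-plane spread is smaller than its
out-of-plane alternation, the optimal plane can be *perpendicular* to the
intuitive layer plane; the tests document this with an alternating-ring
example.

## Stabilization energy

The per-layer stabilization free energy is an atomic-solvation-parameter
(ASP) model:

    ΔG_stab(chain) = Σ_atoms ASP(class) × [A_fibril(atom) − A_reference(atom)]

with solvent-accessible areas in Å² and ASP values in kcal/(mol·Å²).
Negative totals mean a stabilized fibril. Default parameters are
Eisenberg–McLachlan-class values: apolar C +0.016, uncharged N/O −0.006,
carboxylate O⁻ −0.024, protonated N⁺ −0.050, S +0.021. Charged classes
cover Asp/Glu carboxylates, the C-terminal OXT, Lys NZ and the Arg
guanidinium; His is treated neutral at pH 7.4. A calibration helper fits a
single least-squares scale factor mapping computed ΔG values onto a
user-supplied reference table, for comparing against legacy parameterizations
whose exact constants are not published.

**SASA.** Areas come from a deterministic Shrake–Rupley engine: 960
golden-spiral (Fibonacci-lattice) test points per probe-expanded sphere
(probe 1.4 Å), an atom's area being the unoccluded point fraction times
`4π(r+probe)²`. No random numbers are used, so results are bit-reproducible;
the residual quadrature error is below ~0.5% and orientation-dependent at
the ~0.2% level. Radii are a Chothia-style united-atom table (C 1.87,
N 1.50, O 1.40, S 1.85 Å); hydrogens are excluded. The engine is
cross-checked in the tests against closed-form one- and two-sphere areas and
against an independent implementation given identical radii.

**Reference state.** The default reference is the *extended chain*: the
chain rebuilt with ideal backbone geometry (N–Cα 1.458, Cα–C 1.525,
C–N 1.329 Å) at φ = −140°, ψ = +135°, ω = 180°, with each residue's side
chain transplanted rigidly from the deposited conformation via its local
(N, Cα, C) frame — i.e. the observed rotamer is kept, which preserves the
exact per-atom correspondence the area difference requires. This reference
makes both intra-layer side-chain packing and inter-layer burial count
toward stability, which matters for polymorphs whose instability stems from
missing intra-layer contacts. An *isolated chain* reference (deposited
conformation, partners removed) is available and isolates pure inter-layer
burial.

**Context.** The scored chain must be interior (≥2 neighbors on each side).
Shorter stacks are extended to 5 layers by the model's helical symmetry
before scoring; scoring an edge chain without known symmetry is an error.
Per-residue energies are the atom terms grouped by residue and sum exactly
to the chain total; subunit decomposition either sums those per-residue
terms within spans (`in_context`, additive) or rebuilds the stack with only
one subunit present in every layer (`alone`). For display, per-residue
values are clipped to ±2.5 kcal/mol.

## Chaperone accessibility

Fibril fragmentation by the Hsp104/Ssa1/Sis1 machinery requires chaperone
binding to residues 143–164 of Sup35NM; the binding-site span is
configurable and residue identities are taken from the input, not
hard-coded. The headline metric is *sequence* separation: 0 if any ordered
core span overlaps the site, else the number of residues strictly between
the nearest boundaries — matching the landscape axis it feeds; a 3D
minimum-heavy-atom-distance variant is provided as a complement. Site
exposure is classified per model: `absent_from_model`, or ordered and
either contacting the rest of the core (any heavy-atom pair < 5 Å,
`ordered_overlapping_core`) or not (`ordered_adjacent`). The landscape
table is purely descriptive — one row per polymorph with ΔG, gap, abundance
and handedness, sorted by ΔG with name tie-breaks; fractions within one
preparation must sum to ≤ 1. No phenotype is predicted.

## Force spectroscopy

The tether is a series of worm-like chains at equal tension: two 2,000 bp
dsDNA handles (combined contour 2 × 2000 × 0.338 nm = 1352 nm, persistence
45 nm) plus, after unfolding, a polypeptide WLC growing by 0.365 nm per
unfolded residue (persistence 0.65 nm), at 298 K. The Marko–Siggia
interpolation relates force and fractional extension; its inverse is solved
by 80-step bisection (error < 2⁻⁸⁰). The folded end-to-end offset defaults
to 0 nm (no subtraction); all of these constants live in `TetherModel` and
are configurable, since force-spectroscopy conversions are sensitive to
them and published analyses rarely print them.

**Simulation.** Pulls are quasi-static: the ramp coordinate sweeps the
tether extension (optionally plus `force/trap_stiffness` bead displacement)
between the extensions bounding a 2–35 pN force window; each programmed
segment adds its residues to the unfolded contour when the noiseless force
first crosses its rupture force, producing the classic sawtooth. Gaussian
force noise (default σ = 0.2 pN) is seeded; sampling defaults to 5
samples/nm (≈500 Hz at the instrument's 100 nm/s pulling speed). The relax
branch keeps everything unfolded — refolding rips are rare in practice and
are not analyzed. The simulator is deterministic given its seed.

**Rip detection.** A rip is a force drop exceeding `max(4σ, 0.5 pN)` while
the trap advances. The drop height at each sample is measured with a
slope-corrected matched filter: straight-line fits over 10 samples on
either side, extrapolated to the candidate point, with a one-sample
persistence check so a single noise outlier cannot mimic a level shift.
This window was sized so the smallest physically meaningful rips (a
20-residue structure at 12 pN produces only a ~1.3 pN drop through the
compliant handles) remain above threshold at σ = 0.2–0.3 pN. The rupture
force is a quadratic fit of the 30 pre-drop samples extrapolated half a
sample past the last pre-drop point (the loading curve is gently convex, so
a straight line biases low). Contour-length gains come from fitting each
inter-rip branch's unfolded contour length — a closed-form weighted least
squares, since the tether model is linear in Lc; weights are the inverse
squared handle compliance, because at low force a 0.2 pN error moves the
predicted extension by tens of nm. Residue counts are `round(ΔLc/0.365)`.
Verified recovery at σ = 0.2: no count errors over 400 simulated pulls,
sizes within ±2 residues, rupture forces within ±0.4 pN.

## Synthetic fibrils

The generator emulates cross-β stacks at known ground truth: a Cα trace on
a 2D path (straight strand, U-bend, or S-fold serpentine; 3.8 Å spacing,
4.8 Å turn radius), backbone N/C/O and Cβ placed with ideal bond lengths
and an alternating cross-β pleat, side chains beyond Cβ omitted, layers
generated by exact helical symmetry, optional sinusoidal out-of-plane warp
`a·sin(2πi/period)` applied per residue before stacking, and seeded
Gaussian coordinate noise after stacking. Every dataset carries a
machine-readable ground-truth record (rise, twist, warp displacement field
and its RMS, seed); downstream tests compare against it, never against
copied numbers. Synthetic models are written in the same mmCIF dialect the
reader consumes, exercising the I/O path.

What the generator does *not* emulate: full side-chain rotamers and steric
zipper chemistry, sequence-dependent backbone geometry, protofilament
pairing, fuzzy-coat disorder, and map-level noise. Passing tests therefore
demonstrate correctness of the geometric and energetic machinery on ideal
stacks, not model-building accuracy on real reconstructions; energies of
Cβ-truncated poly-Ala stacks are internally consistent but not comparable
to values for real deposited cores.

A note on the warp oracle: on a U-bend path a *full-period* sinusoid is
partially absorbed by tilting the best-fit plane (the sine's sign
correlates with the strand separation axis), so the analytic identity
`best-fit RMSD = a/√2` is exercised with a two-period sinusoid, which is
orthogonal to all plane tilts on that path.

## Numerical choices and limitations

- SASA point count (960) trades ~0.3% quadrature error for speed;
  tolerance-critical comparisons in the tests raise it to 4000.
- Layer-pair twist extraction fails gracefully at twist → 0 (pure
  translation: twist 0, axis from centroids).
- `measure_rise_twist` requires identical residue composition across layers
  and averages over consecutive pairs; coordinate noise of σ = 0.05 Å leaves
  twist errors below 0.05°.
- Altloc handling keeps the highest-occupancy conformer; insertion codes
  are rejected (not expected in fibril depositions).
- Problem sizes in the test-suite and acceptance-script simulations (5–7
  layer stacks of 12–64 residues, 100-pull cohorts) were chosen as the
  smallest sizes at which every statistic stabilizes well inside its
  tolerance.
- The energy model contains no electrostatics or entropy terms beyond
  implicit solvation, and the simulator has no Bell–Evans loading-rate
  kinetics: rupture forces are programmed constants, appropriate for
  reproducing quasi-static size/force scatter but not for kinetic analyses.
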