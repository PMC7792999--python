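# Methods

This note records the models, conventions and defaults behind
`peroxosite`, the choices made where more than one reasonable design
exists, and what the synthetic-data tests do and do not establish about
real data.

## Coordinate model and conventions

Structures are read and written through gemmi (PDB v3.3, optionally
mmCIF) into a light in-memory model of atom sites. Three conventions
matter:

* **Deuterium is hydrogen.** Atoms with element "D" keep their identity
  on I/O but play the hydrogen role everywhere in geometry — as the H of
  a donor group, as the H of an X—H⋯π contact. They are never renamed.
* **Blank altloc is shared.** An atom with a blank alternate-location
  tag belongs to every conformer of its residue; expanding conformer "A"
  yields the blank atoms plus the A-tagged ones. Analyses never average
  across conformers silently: any quantity touching an atom with
  alternates is reported once per tag.
* **Author numbering is authoritative.** Residues are identified by
  (chain, author residue number, insertion code); no sequence alignment
  is attempted. Main-chain RMSD pairs residues this way, drops missing
  atoms pairwise, superposes on the paired set, and only then measures —
  "common main-chain atoms" means pair-then-fit.

Coordinates are written at the fixed 3-decimal PDB precision; internal
computation is full double precision. Symmetry expansion is out of
scope: analyses that span a crystallographic interface expect a
pre-expanded input file.

Torsions follow the IUPAC sign convention (viewing along the b→c bond,
clockwise rotation of d relative to a is positive), reported on
(−180°, 180°]. Note that an IUPAC torsion is *invariant* under reversing
the atom order and changes sign under mirror reflection; the property
tests assert exactly that. Ring planes are total-least-squares fits (the
smallest singular direction of the centered coordinates); the inter-plane
tilt is always the acute angle, and ω of a π contact is reported acute in
[0°, 90°], since a deposited model carries no meaningful side convention.

## Interaction geometry

A hydrogen-bond donor is any N/O/S heavy atom with an explicitly
resolved H/D within 1.3 Å; acceptors are N/O. Defaults — d(H⋯A) ≤ 2.5 Å
and ∠(D—H⋯A) ≥ 120° — follow common neutron-structure practice; they are
configuration, echoed into every report header, not claims. Donors
without a resolved hydrogen are skipped and logged, never guessed.
Because the printed literature is often ambiguous about whether a quoted
contact is H⋯acceptor or heavy-atom⋯acceptor, each detected bond carries
both distances.

X—H⋯π contacts use the classical triple (d<sub>X⋯m</sub>, ω(X),
∠(X—H⋯m)) against the fitted ring plane. Default classification
thresholds d ≤ 4.3 Å, ω ≤ 30°, ∠ ≥ 120° bracket the values typical of
peptide N—H⋯π statistics; classification is a pure, monotone predicate
over the stored parameters. The six-membered ring of the ligand is the
default π system; any ring selection can be supplied, and a contact to a
single ring *atom* (rather than the midpoint) is reported as a plain
distance.

## Circular statistics

Torsion traces are circular data; all densities use von Mises kernels.
When no kernel concentration is given, a plug-in rule fits a reference
von Mises of concentration κ̂ (Fisher's inverse-A approximation to the
mean resultant length) and takes the AMISE-optimal kernel concentration
ν = [3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²)]^{2/5}, computed with scaled Bessel
functions so degenerate samples do not overflow. Reference rules
oversmooth multimodal data mildly; the concentration used is recorded in
every output, and callers can override it. Grids default to 1° (circle)
and 2° (torus); sample sizes above a few thousand are binned at grid
resolution and convolved by FFT (error far below the grid scale), and
the result is renormalized exactly, so densities integrate to 1 within
1e−9. Modes are strict local maxima of the periodic grid, ordered by
height with ties broken by angle; maxima below 1e−6 of the global
maximum are discarded as floating-point ripple.

Two-dimensional clustering is density-peak labeling on the smoothed
toroidal density: every grid cell follows steepest ascent (8-neighbor,
periodic, strictly uphill so plateaus cannot cycle) to a local maximum,
frames inherit the basin of their cell, and basins below a population
floor (1%) or frames below a density floor (5% of the maximum) stay
unassigned. The procedure is deterministic and seed-free, which matches
the visual semantics of reading clusters off a contour plot. Cluster
centers are circular means of members, which are more stable than the
peak cell itself. A mixture-fit alternative was considered and dropped:
the density-peak method needs no component count and cannot fail to
converge.

Internally angles live on (−180°, 180°]; outputs that are conventionally
printed on [0°, 360°) (e.g. side-chain cluster centers) are wrapped for
display only.

## Water-site coordinates and residence

The catalytic water is tracked in radial coordinates relative to the
ligand frame: r = |C5—O_w| and θ = torsion(C4, C5, O_w, midpoint(H1, H2)).
The hydrogen midpoint defines θ; there is deliberately no heavy-atom
fallback, since the orientation of the water is the point of a
hydrogen-resolved analysis. The residence trace thresholds r at 4.0 Å by
default — between the bound state's typical 3.1–4.0 Å range and the
displaced state's 4.2–4.4 Å maximum — and reports the exact in-fraction,
run-length dwell segments, and, against a cluster labeling, the 2×k
contingency table with an odds ratio (largest cluster vs rest, flagged
rather than smoothed when a cell is zero) and Cramér's V.

## The synthetic generators

The generators exist so that every analysis stage can be verified
against exact ground truth.

The **toy active site** builds a planar bicyclic ligand (ideal 1.39 Å
six-ring bonds, fused five-ring, a ring-bound deuteron), a Thr-like
hydroxyl, a Lys-like ammonium, an Asn-like amide in two conformations at
75:25 occupancy, and three waters. Quantities are *planted*: the
hydroxyl deuteron is placed on the intersection circle of the two
distance spheres that constrain it (2.16 Å to the water oxygen, 2.77 Å
to the ring N7) with its torsion built in by natural-extension
placement; the water realizes (r, θ) = (3.47 Å, 6°) by construction and
its plane tilt (45°) by a bounded one-dimensional solve over the spin
angle; a separate water realizes the π triple (3.64 Å, 23.8°, 141°)
exactly from the law of sines in the O–H–m triangle. Ideal bond lengths
and angles are documented scaffolding, not chemistry claims. Requested
geometry that is infeasible (non-intersecting spheres, unreachable tilt)
raises rather than approximating. The manifest records every planted
value; construction is exact to 1e−6 before file rounding, and the
acceptance tests re-measure everything through the full pipeline.

The **ensemble generator** couples a hidden two-state Markov chain
(major/minor, persistence 0.99/0.97, stationary ratio 75:25 — persistent
because conformational states in simulations are temporally persistent,
which makes dwell-segment statistics non-trivial) to three observables,
all realized through actual 3D coordinates so analysis never
short-circuits to the manifest:

* a hydroxyl torsion channel sampled from 0.8·vM(−72°, κ=12) +
  0.2·vM(−135°, κ=20), giving the broad asymmetric profile with a
  dominant mode and a shoulder;
* an amide torsion pair from four von Mises components (κ = 40 ≈ 9°
  spread) centred at (179°, 192°), (60°, 210°), (330°, 330°) and
  (272°, 81°), the last exclusive to the minor state — the first and
  last are the crystallographic conformations, the middle two are
  additional rotamer basins placed well-separated on the torus;
* a water (r, θ) distribution per state: bound ≈ (N(3.6 Å, 0.18 Å),
  vM(10°, κ=80)); displaced ≈ (N(4.3 Å, 0.07 Å), vM(240°, κ=12)), i.e.
  the 225–255° band.

Water internal geometry is O–H 0.96 Å, H–O–H 104.5°, with a free spin
angle about the θ-defining axis. All randomness flows through one seeded
NumPy generator; identical seeds give identical bytes, including for the
fixture corpus written by `write_fixture_set`.

**What passing tests show, and what they do not.** The generator
produces exactly the statistical structure the analysis assumes:
independent von Mises mixtures, Gaussian radial spread, a clean two-state
chain, small isotropic jitter elsewhere. Recovery under these conditions
verifies the analysis code — estimator consistency, torus topology
handling, coupling bookkeeping — but says nothing about force-field
accuracy, sampling convergence of a real trajectory, correlated
multi-channel motions, or crystallographic model error. Ensemble sizes
in the tests (2·10⁴ shared fixture, 10⁵ for the acceptance suite) were
chosen so mode- and center-recovery tolerances (±3°, ±8°) sit well above
Monte-Carlo noise.

## Degenerate inputs and numerical edges

Collinear atoms make angles (zero arm) and torsions undefined and raise;
plane fits require three non-collinear points; superposition requires
three non-degenerate pairs and never returns a reflection (the smallest
singular direction is flipped when det = −1). Constant torsion series
produce a sharp single-mode density (the plug-in κ is capped at 10⁶);
a one-frame ensemble analyzes fine but is flagged degenerate. Odds
ratios with empty cells report infinity with a degeneracy flag. The
basin-ascent labeler moves only strictly uphill, so exact plateaus are
their own peaks instead of cycling.

## Known limitations

* No symmetry expansion, no reflection data, no map handling, no
  anisotropic displacement math.
* No protonation-state inference: hydrogens must be in the model.
* The plug-in bandwidth oversmooths strongly multimodal circular data;
  for very close modes pass an explicit concentration.
* Cluster centers are grid-free but assignment is grid-based (2°
  default); sub-degree basin boundaries are not resolved.
* The frame-table ensemble dialect infers elements from atom names and
  assumes a constant atom set across frames.
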