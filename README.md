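# peroxosite

Active-site geometry analysis for hydrogen/deuterium-resolved crystal
structures and conformational ensembles.

Neutron crystallography resolves the hydrogen (and deuterium) atoms that
X-ray structures usually miss, which turns questions about enzyme
mechanism — who donates which hydrogen bond, where a catalytic water
points, which rotamer a side chain adopts — into questions of plain
geometry. `peroxosite` packages that geometry for the kind of active
site found in urate oxidase: a planar heteroaromatic ligand stacked
under a catalytic water in the positively charged "peroxo hole", flanked
by a Lys–Thr dyad and a flexible Asn amide with alternate conformations.
It is aimed at structural biologists and simulators who want the same
numbers out of a deposited model and out of an MD ensemble.

## What it computes

* **Hydrogen bonds from explicit H/D positions** — donor, hydrogen,
  acceptor, d(H⋯A), d(D⋯A) and ∠(D—H⋯A), with configurable criteria
  (default d(H⋯A) ≤ 2.5 Å, ∠ ≥ 120°) echoed into every report.
* **X—H⋯π interactions**, in the classical parametrization: the distance
  *d*<sub>X⋯*m*</sub> from the donor heavy atom X to the ring midpoint
  *m*, the angle ω(X) between the X⋯*m* line and the ring normal, and
  the angle ∠(X—H⋯*m*) at the hydrogen. Ring planes are least-squares
  fits; classification thresholds are configuration, not ground truth.
* **Exact vector geometry** — distances, angles, IUPAC-signed torsions,
  ring-plane fitting, and Kabsch superposition with main-chain RMSD
  (pair by author numbering, fit, then measure).
* **Circular statistics of torsion ensembles** — von Mises kernel
  densities on the circle and the torus with a plug-in concentration
  rule, mode finding, and deterministic density-peak clustering of
  angle pairs (the computational analogue of reading clusters off a 2D
  contour plot).
* **Catalytic-water bookkeeping** — the radial coordinates
  (*r*, θ) = (|C5—O<sub>w</sub>|, torsion C4–C5–O<sub>w</sub>–midpoint(H1,H2))
  per frame, residence traces against an *r* threshold, dwell segments,
  and the association (odds ratio, Cramér's V) between side-chain
  cluster and water displacement.
* **Synthetic data with exact ground truth** — a toy active site whose
  hydrogen-bond distances, torsions, water coordinates, plane tilt and
  π triple are *planted* to requested values, and coupled ensembles
  driven by a hidden two-state Markov chain, so every analysis stage is
  verifiable end to end without downloading anything.

## Worked example

```python
from peroxosite import (build_toy_active_site, detect_hbonds,
                        characterize_pi_contact, water_site_coordinates)
from peroxosite.ensemble import (TorsionSpec, torsion_series,
                                 circular_density_1d, density_modes,
                                 cluster_torsions_2d, residence_trace)
from peroxosite.synthetic import EnsembleSpec, generate_ensemble

site, manifest = build_toy_active_site()
for hb in detect_hbonds(site)[:3]:
    print(f"{hb.label():48s} d(H...A) = {hb.d_h_acceptor:.2f} A, "
          f"angle = {hb.angle_dha:.0f} deg")

ring = [site.atom("A", 400, n) for n in ("N1", "C2", "N3", "C4", "C5", "C6")]
pi = characterize_pi_contact(site.atom("S", 603, "O"),
                             site.atom("S", 603, "D1"), ring)
print(f"O-H...pi: d(O..m) = {pi.d_xm:.2f} A, omega = {pi.omega:.1f} deg, "
      f"angle(O-H..m) = {pi.angle_xhm:.0f} deg")

ens, truth = generate_ensemble(EnsembleSpec(n_frames=100_000, seed=1))
thr = torsion_series(ens, TorsionSpec("thr", (("B", 57, "CA"), ("B", 57, "CB"),
                                              ("B", 57, "OG1"), ("B", 57, "DG1"))))
modes = density_modes(circular_density_1d(thr))
print(f"hydroxyl torsion: mode at {modes[0][0]:.0f} deg, "
      f"shoulder at {modes[1][0]:.0f} deg")

chi1 = torsion_series(ens, TorsionSpec("chi1", (("B", 254, "N"), ("B", 254, "CA"),
                                                ("B", 254, "CB"), ("B", 254, "CG"))))
chi2 = torsion_series(ens, TorsionSpec("chi2", (("B", 254, "CA"), ("B", 254, "CB"),
                                                ("B", 254, "CG"), ("B", 254, "ND2"))))
for c in cluster_torsions_2d(chi1, chi2):
    print(f"cluster {c.cluster_id}: center ({c.center[0] % 360:.0f}, "
          f"{c.center[1] % 360:.0f}) deg, population {c.population:.2f}")

w = water_site_coordinates(ens, ("A", 400, "C4"), ("A", 400, "C5"),
                           ("S", 601, "O"), ("S", 601, "D1"), ("S", 601, "D2"))
tr = residence_trace(w, r_threshold=4.0)
print(f"water residence: occupancy {tr.occupancy:.2f}, "
      f"mean dwell {tr.mean_inside_segment:.0f} frames")
```

prints

```
<A/AZA400/N9>-D9...<S/DOD602/O>                  d(H...A) = 1.84 A, angle = 180 deg
<S/DOD603/O>-D1...<B/ASN254/N>                   d(H...A) = 1.89 A, angle = 125 deg
<B/LYS10/NZ>-DZ1...<B/THR57/OG1>                 d(H...A) = 1.97 A, angle = 172 deg
O-H...pi: d(O..m) = 3.64 A, omega = 23.8 deg, angle(O-H..m) = 141 deg
hydroxyl torsion: mode at -72 deg, shoulder at -134 deg
cluster 0: center (179, 192) deg, population 0.44
cluster 1: center (272, 81) deg, population 0.26
cluster 2: center (330, 330) deg, population 0.15
cluster 3: center (60, 210) deg, population 0.14
water residence: occupancy 0.73, mean dwell 43 frames
```

The first block is crystal-style geometry: planted hydrogen bonds
reported back at their exact values, and a textbook O—H⋯π contact
(3.64 Å to the ring midpoint, 23.8° off the normal, 141° at the
deuteron). The second block is ensemble-style: the hydroxyl torsion's
broad asymmetric profile with its dominant mode near −72° and shoulder
near −135°; four amide-torsion clusters on the torus, the major
crystallographic conformation at (179°, 192°) and the minor one at
(272°, 81°) in an approximate 75:25 ratio; and a catalytic water that
sits inside the pocket (r ≤ 4 Å) about 73% of the time, in long dwell
segments because the hidden conformational state is persistent, not
i.i.d.

A command-line interface mirrors the library:

```sh
peroxosite fixtures --out fixtures          # write the synthetic corpus
peroxosite simulate --n-frames 10000 --seed 1 --out sim
peroxosite analyze-structure --config roles.json --input model.pdb --out report
peroxosite analyze-ensemble  --config roles.json --input sim/frames.csv --out summary
peroxosite compare ref.pdb mobile.pdb       # main-chain RMSD
peroxosite deuteration 1803 1820            # -> 99.1
```

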