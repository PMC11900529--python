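# utopioid

Standard-free structural identification of positional isomers of U-type
synthetic opioids ("utopioids").

## The problem

Forensic and drug-checking laboratories routinely receive new psychoactive
substances for which no certified reference standard exists. For the
benzyl-type U-opioids this is acute: U-48800 and U-51754 share the
molecular formula C17H24Cl2N2O and the same scaffold — a
1,2-*trans*-cyclohexane-diamine linked through an amide carbonyl to a
dichlorinated benzyl group — and differ only in which aromatic carbons
carry the chlorines (C-4/C-6 versus C-5/C-6). Their EI mass spectra are
essentially identical, so library search alone cannot tell them apart.

This package implements the three-stage desk workflow that resolves such
cases without standards:

1. **EI-MS arithmetic** (`utopioid.ms`): nominal/monoisotopic masses,
   chlorine isotope patterns, and halogen-count inference. A cluster of
   peaks 2 Da apart with abundances following the binomial
   (3/4 + 1/4)^n — 3:1 for one chlorine, 9:6:1 for two — fixes the
   chlorine count; fragment formulas are matched to peaks by mass.
2. **NMR bond-path compatibility** (`utopioid.nmr` + `utopioid.graph`):
   an HMBC cross-peak links a proton to a carbon 2–3 bonds away, and
   4-bond correlations are normally invisible. Candidate structures are
   molecular graphs with explicit hydrogens; every observed correlation
   is turned into a shortest-path query and candidates are ranked by
   violation count. For this isomer pair a single cross-peak is
   decisive: the aromatic ortho-doublet proton is 3 bonds from the
   benzylic methylene carbon in U-48800 but 4 bonds in U-51754.
3. **Conformer-ensemble geometry** (`utopioid.geometry`,
   `utopioid.ensemble`): given an ensemble of 3-D conformers, align on
   the ring carbons, cluster by pairwise RMSD (agglomerative, average
   linkage, with a medoid-distance merge), classify each ring as
   chair/boat/twist-boat from its puckering coordinates (Q, θ, φ), and
   call every ring proton axial or equatorial from the signed angle
   between its C–H bond and the least-squares ring plane. A seeded
   synthetic generator (`utopioid.synth`) emulates the statistical
   structure of an MD ensemble — mixtures of chairs and boats with
   thermal noise, and a bimodal exocyclic dihedral — so the whole chain
   is testable offline with exact ground truth.

## Worked example

Chlorine count from the printed isotope pair:

```
$ utopioid halogen-count --cluster "110:1500,112:500"
{ "n_chlorine": 1, "residual": 0.0, "verdict": "accepted", ... }
```

The 1500:500 abundances are an exact 3:1 pattern, so one chlorine
explains the 110/112 pair with zero residual.

Isomer discrimination against the built-in key HMBC correlation set:

```
$ utopioid nmr-discriminate --candidates U-48800,U-51754
{ ..., "best": "U-48800",
  "ranking": [ {"candidate": "U-48800", "violated": 0, "satisfied": 24, ...},
               {"candidate": "U-51754", "violated": 3, ...} ] }
```

U-48800 satisfies all 24 key correlations; U-51754 violates three —
including the decisive ortho-doublet ↔ methylene cross-peak, whose
bond path is 4 in that structure.

Conformer analysis of a synthetic 1000-frame ensemble:

```
$ utopioid synth-ensemble --n-frames 1000 --seed 1 --out ens.xyz
$ utopioid conf-analyze --ensemble ens.xyz --out conf.json --csv-out conf.csv
```

yields three clusters (fractions 0.874 chair, 0.113 flipped chair,
0.013 boat for this seed) and, for the dominant chair, per-proton angle
statistics such as

```
C1 H-1   86.12 ± 2.14  axial        C2 H-2   19.62 ± 3.01  equatorial
C2 H-1  -86.60 ± 1.81  axial        C3 H-1  -19.58 ± 3.10  equatorial
```

i.e. the familiar chair signature: six axial protons near ±90° to the
ring plane and four equatorial ones near ±19°, alternating in sign
around the ring (the sign convention is the right-hand rule on the ring
traversal order; see `docs/methods.md`).

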