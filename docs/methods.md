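# Methods

## Molecular graphs and bond-path logic

Candidate structures are undirected labelled graphs with explicit
hydrogen nodes. Making hydrogens explicit is a deliberate convention:
the bond count from a proton to a carbon then includes the proton's own
C–H bond, which is how multiple-bond NMR reach is counted in practice
(an HMBC cross-peak spans 2–3 such bonds). Bond order is stored
(single/double/aromatic) but ignored by path queries — long-range
correlation reach does not depend on bond order. Shortest paths are
breadth-first searches delegated to networkx.

Atom labels follow the positional numbering used in the NMR assignment
of the two built-in compounds (C-1 carbonyl, C-2 benzylic methylene,
C-3…C-8 aromatic, C-1′…C-9′ cyclohexane/amine region); a unicode prime,
an ASCII apostrophe and a trailing `p` are accepted interchangeably.
Proton labels such as `H-9'` resolve collectively to all protons of the
named carbon, because methyl/methylene protons are path-equivalent.

The minimal SMILES dialect covers exactly what candidate structures in
this compound class need (C/N/O/Cl, aromatic lowercase, branches, ring
closures, charges, multiple bonds). Implicit hydrogens fill the default
valence, with aromatic atoms consuming one extra unit for the ring π
system. The serialiser is non-canonical DFS; round-trip preserves
formula and degree sequence, which is what the tests check.

## Mass-spectrometric arithmetic

Two isotope models are offered. The `rounded` default treats C/H/N/O as
monoisotopic and chlorine as an exact 35:37 = 3:1 doublet, so Cl_n
clusters are exactly the binomial (3/4 + 1/4)^n with term k at offset
+2k Da — 3:1 and 9:6:1 as an analyst quotes them. The `natural` model
convolves full natural-abundance distributions at nominal-mass
resolution. Halogen inference normalises a binned cluster to its
tallest peak, compares against each rounded Cl_n template by least
squares over the union of offsets (residual normalised by the observed
sum of squares), and flags the verdict `ambiguous` when the runner-up
residual is within 10% of the best. Nominal masses ignore the electron
for cations (far below integer resolution); monoisotopic masses
subtract one electron mass per positive charge.

## NMR compatibility scoring

Verdicts per correlation: path 1 → `excluded` (one-bond territory,
evidence for neither side); path within the window (default 2–3) →
`compatible`; COSY additionally accepts 4-bond paths as
`weak-compatible` when a small recorded coupling (≤ 3 Hz, meta/W-type)
justifies it; anything else → `incompatible`. The 2–3 window is the
standard long-range reach; it is configurable for exotic 4-bond HMBC
work but the default deliberately excludes them, which is precisely
what makes the isomer discrimination decisive.

Observations may be keyed by spectral tags rather than atom labels,
because the same multiplet maps onto different positions in different
isomers: the ortho-only aromatic doublet is H-8 in U-48800 but H-7 in
U-51754. Per-candidate label maps resolve the tags; a map entry may
list alternatives (for assignments marked interchangeable), and the
least-violating alternative counts — so an honest uncertainty in the
assignment never manufactures a violation. The built-in key correlation
set gives the U-51754 hypothesis the full quaternary-carbon alternative
set, the most generous reading possible; it still accumulates three
violations where U-48800 accumulates none. Candidates are ranked by
(violations ↑, satisfactions ↓, name ↑); the name tiebreak makes
reports reproducible.

One printed table cell was corrected when building the fixture: the
HMBC partner lists of the two 134.x-ppm quaternary carbons and of the
134.2-ppm methine include a 3.09-ppm proton (the amide N-methyl), which
would require a 5–6-bond correlation in either isomer; the prose
assignment names the second methylene proton (3.94 ppm) instead, and
the fixture follows the prose.

## Ring geometry

The ring plane is the orthogonal least-squares plane of the six ring
carbons (smallest principal direction of the centred coordinates). Its
normal sign is fixed by the right-hand rule on the ring traversal
order. This convention determines the sign of every reported C–H angle;
a reversed traversal flips all signs globally, so angle patterns are
meaningful up to a global flip per cluster, and reports state the
convention. The signed C–H/plane angle is 90° minus the angle to the
normal, in [−90°, +90°]. Axial/equatorial calls use |mean angle| ≥ 45°
(boundary inclusive, configurable) — midway between the chair's ideal
axial (90°) and equatorial (19.47°) magnitudes and comfortably between
the empirical ranges of real chair ensembles.

Puckering uses the standard amplitude-phase decomposition for
six-membered rings: out-of-plane displacements z_j (in the mean-plane
frame whose two lowest Fourier components vanish) give a pseudorotation
pair (q2, φ) and an alternating amplitude q3, with Q² = q2² + q3² and
θ = atan2(q2, q3). Classification: planar when Q < 0.05 Å; chair when
θ < 30° or > 150°; otherwise boat when φ is within 15° of a multiple of
60° and twist-boat when within 15° of 30° + a multiple of 60°. The two
phase windows tile the wheel, so every non-chair puckered ring receives
a class. Dihedrals follow the IUPAC sign convention (clockwise positive
looking from the second to the third atom), range (−180°, 180°].

## Ensemble analysis

Frames are aligned once to frame 0 on the ring carbons (single pass, no
iterative mean-structure refinement). The pairwise RMSD matrix is
computed over the ring carbons plus all atoms bonded to them (bonding
inferred from the first frame by a 1.8 Å cutoff); by default every pair
is optimally superposed with proper rotations only, evaluated in closed
form (RMSD² = (T_i + T_j − 2·max_R tr(R·C_ij))/m) with batched 3×3
SVDs, so a 3000-frame matrix takes tens of seconds on one core. A
`superpose=False` mode measures deviations in the common pre-aligned
orientation instead.

Clustering is average-linkage agglomerative (scikit-learn) on the
precomputed matrix into an initial 14 groups, followed by a transitive
merge of groups whose medoid-to-medoid RMSD is below 0.3 Å. The merge
threshold automates what would otherwise be a visual merging of
near-duplicate clusters; both k_init and the threshold are configurable
and logged in every report. Final clusters are relabelled by descending
population. Per-cluster statistics are means ± SD (ddof = 1) of the
signed C–H angles over member frames, the positional call on the mean,
and the modal pucker class. Frames are weighted equally.

The dihedral route is independent and cheap: the signed torsion of four
named atoms per frame, cut at 0° (a frame exactly at the cutoff goes to
the positive cluster — a stated tie rule, relevant only for constructed
inputs since the sampled law is continuous).

## The synthetic generator

The generator stands in for an enhanced-sampling MD trajectory of the
flexible rings. What it emulates: a categorical mixture of ring
conformers (dominant chair, its ring-flip partner, rare boats — default
weights 0.8725/0.1134/0.0141 matching the dominant/secondary/rest split
of the motivating chair-chair-boat ensemble), Gaussian thermal noise on
the puckering angles (default SD 6°, chosen so that per-proton angle
SDs come out in the 2–7° range typical of a single conformer basin),
independent Cartesian jitter (0.03 Å), and random rigid placement of
every frame so that the alignment stage does real work. Ring carbons
sit on a regular projected hexagon whose radius is shrunk so the mean
squared 3-D bond length equals the nominal C–C bond (1.54 Å); for the
ideal chair amplitude Q = b/√6 this reproduces exactly tetrahedral ring
angles, which is what makes the 90°/19.47° axial/equatorial oracle
exact. Hydrogens are placed by local tetrahedral construction
(bisector ± perpendicular of the adjacent ring bonds, C–H 1.09 Å).

The two substituted carbons (C-1′ amide side, C-6′ amine side) carry a
nitrogen stub in a fixed hydrogen slot (lower slot at C-1′, upper at
C-6′). Fixing the slot rather than the axial/equatorial character is
the physically faithful choice: under a ring flip the substituents
change from equatorial to axial exactly as a real trans-diamine does,
which is also why the flipped-chair component is geometrically
distinguishable from the dominant chair despite identical ring-carbon
positions. Hydrogen slot numbering (H-1 = lower, H-2 = upper in the
construction frame) is what makes the dominant chair's axial set come
out as {C-1′-H-1, C-2′-H-1, C-3′-H-2, C-4′-H-1, C-5′-H-2, C-6′-H-1}.

The exocyclic-dihedral generator draws torsions from a mixture of
wrapped normals (default modes ±85°, circular SD 20–25°). Only the sign
structure and mode separation matter downstream; the true MD torsional
law is not modelled.

What the generator does *not* emulate — force-field energetics,
solvent, temperature ladders, correlated intramolecular motion, or
realistic boat/twist-boat interconversion pathways. Passing tests
therefore demonstrate that the analysis chain recovers known mixture
structure from geometrically realistic, thermally noisy ensembles; they
do not validate conformer populations of any real molecule.

## Problem sizes and numerical choices

Stochastic checks run at n = 3000 frames (mixture-fraction recovery
within three binomial standard errors; clustering label recovery with
adjusted Rand index ≥ 0.95), with smaller n in unit tests; these sizes
give comfortably powered checks at interactive runtimes. Exact oracles
(masses, isotope ratios, bond paths, ideal-chair angles, pucker
round-trips) use tolerances of 1e-6 or tighter. Degenerate inputs —
collinear rings, zero-length bonds, empty ensembles or clusters, rings
too puckered for the requested bond length — raise typed errors rather
than returning approximations. All randomness flows through
numpy `default_rng` seeds carried in the configuration objects; reports
embed a key-order-independent configuration hash, and fixed seed plus
fixed configuration reproduces every report byte for byte.

## Known limitations

- The SMILES dialect is intentionally minimal (no stereochemistry,
  wildcards or disconnected fragments); candidates outside C/H/N/O/Cl
  chemistry are rejected.
- Isotope patterns are nominal-mass; fine isotopic structure and
  resolution effects are out of scope.
- Axial/equatorial labels are strictly angle-threshold calls; for
  strongly distorted boats the labels describe geometry relative to the
  mean plane, not NMR-observable character.
- Chemical-shift prediction is out of scope: mapping observed shifts to
  atom labels (or spectral tags) is the caller's responsibility, with
  the built-in label maps provided for the two bundled compounds.
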