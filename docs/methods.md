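# Methods

This note documents the models, conventions, and numerical choices
behind each analysis in `cypmd`, and what the synthetic-data generators
do and do not emulate.

## Atom roles and units

All analyses operate on four atom roles assigned once at the I/O
boundary from atom-name/residue-name patterns: protein α-carbons
(`CA` of standard amino acids), the four porphyrin nitrogens of the
heme (`NA/NB/NC/ND` of `HEM`), POPC C1 carbons (the leaflet reference
plane), and ligand heavy atoms (non-hydrogen atoms of configured ligand
residue names). Atoms matching no rule are `OTHER`; the roles partition
the atom set. Residue numbers are taken verbatim from the PDB field
(1-based author numbering) — the conservation module maps sites through
an alignment, never through raw numbering, so no renumbering is needed
or performed.

Units are fixed throughout: coordinates and distances in Å, times in
ps, energies in kcal/mol. Hills files are whitespace-delimited with
four mandatory columns (time, CV center, width, height); extra columns
are ignored so both PLUMED-style `HILLS` files and exported tables
parse. Trajectories are read as DCD/XTC (via MDAnalysis) or
multi-model PDB. Frames are used as stored; no periodic-boundary
unwrapping is applied — the geometric metrics below depend only on
intra-frame centroids and a whole-protein minimum image would be a
no-op for the synthetic systems; real trajectories should be
pre-imaged around the protein.

## Conservation of the H1 site

The H1 allosteric site is the ordered list of 18 CYP2D6 residues
S137, T138, L139, R140, N141, L142, G143, L144, G145, K146, L149,
L189, P268, R269, D270, L271, A274, A277. Site columns are located in
an aligned FASTA by walking the reference's ungapped sequence; the
expected one-letter codes are verified and any mismatch is an error
naming the position, so a mis-indexed alignment cannot silently shift
the site.

Pair scoring: identical residues 1.0; non-identical residues in the
same physicochemical group 0.5; all other pairs 0. Gaps score 0
against anything, including another gap — a gap carries no conserved
residue. The default group partition is aliphatic {A,V,L,I,M,C},
aromatic {F,W,Y}, polar {S,T,N,Q}, basic {K,R,H}, acidic {D,E},
special {G,P}; published schemes differ in detail, so the partition is
a constructor argument, and any quantity depending only on exact
identity is scheme-independent. The conservation matrix entry c[i,j]
is the mean pair score over the 18 site positions of sequences i and j
(the per-pair site mean; an alternative — averaging per position over
the panel first — would yield a column profile, not a pairwise
matrix). Percent identity over the same columns is reported alongside;
the two are linked by `ident ≤ c ≤ ident + 0.5·(1 − ident)` with
identity on the 0–1 scale, which the property tests assert.

## Membrane-model geometry

* **Heme tilt angle.** The plane through the four porphyrin nitrogens
  is fit by least squares (the singular vector with the smallest
  singular value; exact for coplanar atoms, error for collinear ones).
  The reported angle is between that plane and the membrane normal
  (z-axis), i.e. 90° − ∠(normal, z), folded into [0°, 90°]. This
  convention makes a heme lying in the membrane plane read 90° and
  matches the experimental 38–78° window; the complementary
  normal-versus-normal convention is available via an argument.
* **Burying depth.** |z̄(Cα) − z̄(C1)|: the z-projection of the
  centroid separation, not the 3D distance — the metric is defined
  relative to the membrane plane, and a lateral offset of the leaflet
  centroid would contaminate a 3D distance (switchable to 3D). The
  "mass center considering α-carbons" is implemented as the unweighted
  Cα centroid (equal masses); the radius of gyration is likewise
  Cα-based and unweighted, √(mean|r − r̄|²).
* **RMSD/RMSF.** RMSD optionally removes the optimal least-squares
  rotation+translation (Kabsch, via scipy's `Rotation.align_vectors`)
  first. RMSF superposes all frames on frame 0, forms the mean
  structure, re-superposes on that mean, and measures fluctuations
  about it; rigidly moving trajectories therefore give zero RMSF.
* **Validation gates.** Mean tilt ∈ [38°, 78°] and mean depth ∈
  [26, 44] Å (35 ± 9), bounds inclusive.

## Association hotspots and occupancy grids

The association score of residue r is
Σ_frames |{ligand heavy atoms within 5 Å of Cα_r}| / N_heavy, with
N_heavy the total over all ligand copies (multiple copies are pooled —
the normalization is to the *total* number of ligand heavy atoms).
Contacts are counted with a per-frame k-d tree; a brute-force
double-loop recount is the test oracle. The score is additive over
trajectory concatenation, invariant under frame reordering, and
monotone in the cutoff.

Occupancy grids superpose each frame's Cα set on the first frame and
apply the same rigid transform to the probes before binning into
1 Å voxels over the protein bounding box plus a 5 Å margin. The voxel
z-score is (count − mean)/sd with mean and sd over *all* voxels of
that box — the operational definition of the "basal level of
occupancy", which is otherwise underdetermined. Zero-variance grids
are returned with the z-scores flagged undefined rather than raising.
A caveat for sparse data: with expected counts far below one per
voxel, a single coincidence of two observations already produces a
large z-score, so σ-isolevel displays are meaningful only when the
occupancy is well sampled at the chosen voxel size.

## Tunnels

CAVER's own Voronoi-based tunnel computation is out of scope; its
per-frame bottleneck output is parsed from CSV (columns frame,
tunnel/cluster id, bottleneck radius; duplicated (frame, tunnel) rows
are an error, never averaged — silent averaging would bias the n used
by the t-test). Bottleneck radii between two conditions are compared
with the Welch test below: "+"/"−" when the first condition's mean is
significantly larger/smaller at α = 0.1, "=" otherwise, "n/a" when the
tunnel is absent in either condition.

The grid bottleneck finder is a deliberately simple geometric
stand-in, not a CAVER re-implementation (no Voronoi diagram, no
inter-frame clustering; simulation-side parameters such as the 4.5
clustering threshold are metadata only). On a clearance field
(distance to nearest protein atom minus probe radius) it runs a
widest-path priority search over 6-connected voxels: Dijkstra with
`min` in place of `+`, keyed on the largest bottleneck seen. Face
adjacency is the conservative connectivity (diagonal moves would pass
through corners narrower than either voxel's clearance). Absence of a
positive-clearance path is a result value, not an exception. The test
oracle is threshold connectivity — the maximin value is the largest w
for which the start reaches a goal through voxels with clearance ≥ w —
plus literal simple-path enumeration on small corridor grids.

Egress pathways are classified by the nearest tunnel anchor (Euclidean)
to the ligand center at the first surface-crossing frame, defined as
the first frame whose ligand-center-to-protein minimum distance exceeds
5 Å — the same criterion the dissociation detector uses, so the two
readouts are consistent. Ties break lexicographically on the tunnel id
for determinism. Anchor coordinates are configuration, not hard-coded
structure-specific truth.

## Metadynamics readouts

The deposited bias is V(s, t) = Σ_{tᵢ ≤ t} hᵢ exp(−(s − sᵢ)²/(2σᵢ²));
the stated default width 0.05 Å is interpreted as σ (the PLUMED
convention), with an FWHM interpretation switchable per call. Heights
are summed as deposited — no well-tempered rescaling. V is
non-negative and non-decreasing in t at every s.

Dissociation time ΔT: visual calls are not reproducible, so the
automated criterion is the first frame opening a run of ≥ k
consecutive frames (default k = 10) with ligand-to-protein minimum
distance > 5 Å. Single-frame excursions are ignored; a trailing
above-threshold run shorter than k does not count; absence of egress
is a value (some replicas never dissociate), not an error. Both the
threshold and the persistence are exposed.

P_max is the maximum of V(s, ΔT) over a uniform CV grid on [0, 45 Å]
(the wall enters only as the grid's upper bound; wall forces are
simulation-side). The grid spacing defaults to a quarter of the
narrowest deposited σ and refuses to exceed σ/2, so no Gaussian peak
can fall between grid points at relevant accuracy; a 10× finer grid is
the test oracle. An alternative definition — the maximum bias actually
experienced along the trajectory, max_t V(s(t), t) — is provided as
`p_max_along_path`; it is bounded above by the grid maximum at final
time. For non-egressing replicas P_max is evaluated at the final frame
time and flagged.

Group comparison labels each metric by the condition with the lower
mean ("H1" when the allosteric-ligand group dissociates faster or
cheaper, "WAT" otherwise) with a Welch p-value; only replicas that
actually egressed contribute to the ΔT comparison.

## Statistics and accounting

All tests are Welch two-sided t-tests from summary statistics (mean,
sample sd with ddof = 1, n) at α = 0.1, with Welch–Satterthwaite
degrees of freedom, delegated to `scipy.stats.ttest_ind_from_stats`;
an independent textbook evaluation of the formulas is the test oracle.
The degenerate both-groups-zero-variance case is p = 1 for equal means
and an error otherwise. No multiple-testing correction is applied, and
none is offered.

Outcome tables mark an enzyme significant when *either* egress metric
(ΔT or P_max) is below α — the convention evident from outcome rows
where a single sub-α metric suffices. Simulation-plan accounting
multiplies duration × replicas × enzymes per row; the default
nine-enzyme plan totals 5 415 ns per enzyme and 48 735 ns overall, and
the per-enzyme cosolvent bookkeeping (3 probe species × 10 replicas,
15 ns equilibration + 5 ns sampling each) gives 30 simulations and
600 ns.

## Synthetic systems: what they emulate and what they do not

The generators produce the *geometry and bookkeeping* of a
membrane-CYP study, not its physics:

* `make_membrane_system` — Cα beads quasi-uniformly on a jittered
  sphere shell (centroid exactly at the origin), a 2 Å-radius
  porphyrin-N square rotated about x so the plane-versus-z angle
  equals the target exactly, and a C1 lattice exactly at
  z = bury_depth. Defaults (tilt 60°, depth 37 Å, 120 residues, 50
  lipids, 10 frames at 50 ps) sit inside the experimental windows and
  at the recording interval of the study design; noise is isotropic
  Gaussian jitter, the simplest model whose effect on the metrics
  propagates analytically: SE(depth) = σ√((1/n_res + 1/n_lip)/n_frames)
  and SE(tilt) ≈ σ√2/(2a√n_frames) radians for the a = 2 Å square.
  Recovery tests assert 5 propagated SEs. Exact recovery at zero noise
  is a construction guarantee, not a statistical statement.
* `make_ligand_walk` — pre-egress frames hug the innermost Cα (so the
  ligand is in contact and association scores register); from the
  scripted egress frame the ligand recedes along the exit-anchor
  direction, cleared beyond the dissociation cutoff by a configurable
  margin; an optional single-frame excursion exercises the persistence
  filter. No binding energetics, no tunnel geometry en route.
* `make_alignment` — ungapped alignments where every non-reference
  sequence realizes a per-position plan (identical / same-group /
  different) against the reference and non-reference sequences are
  mutually identical, which fixes the whole expected conservation
  matrix in closed form. Gapped cases are exercised by hand-built
  alignments in the tests, not by this generator.
* `make_tunnel_grid` — corridors carved into a walled grid, disjoint
  except at the shared start voxel and touching the boundary only at
  their ends; under those constraints every start-to-boundary path
  must traverse one full corridor, so the true maximin bottleneck is
  max over corridors of each corridor's minimum clearance.

Consequently, passing tests demonstrate correctness of the *analyses*
(geometry, counting, search, statistics) under controlled conditions;
they say nothing about force-field accuracy, sampling convergence, or
membrane realism of any particular simulation. Problem sizes
throughout the suite (hundreds of atoms, tens of frames, grids up to
6×6×4, 50–200 statistical repeats) are chosen so every oracle — brute
force enumeration included — runs comfortably; all analyses scale to
real trajectory sizes through the same code paths.

## Known limitations

* The alignment itself is consumed, never computed; a poor upstream
  alignment propagates directly into the conservation matrix.
* The occupancy "basal level" definition (all voxels of the padded
  bounding box) differs from tools that restrict to solvent-accessible
  voxels; absolute σ levels are therefore not comparable across tools.
* The grid bottleneck finder ignores probe deformability and reports
  voxel-resolution paths; it is a stand-in for testing and teaching,
  not a replacement for CAVER on real structures.
* ΔT detection depends on the 5 Å / persistence parameters; for
  ligands that linger at the surface the automated call can differ
  from a visual one.
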