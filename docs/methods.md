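# Methods

## The scoring model

`pairdock` scores a protein–protein configuration with knowledge-based,
distance-dependent atom-pair potentials.  For a receptor atom *p* of Sybyl
type *T_p* and a ligand atom *b* of type *T_b* at distance *d*, the score is

    ΔW = Σ_{p,b : d_{p,b} < 5 Å}  ΔW(T_p, T_b, d_{p,b})

with lower ΔW more favorable.  The per-pair terms are inverse-Boltzmann
log-ratios of an observed inter-partner distance density g_ab over a
reference density g_ref, binned at 0.1 Å over [0, 5) Å:

    ΔW(a, b, d) = −ln [ g_ab(d) / g_ref(d) ]

Each potential is shifted so that its value in the last bin (at the 5 Å
cutoff) is zero, making the score continuous at the cutoff.

**Atom types.** An 11-label alphabet (C.2, C.3, C.ar, N.3, N.am, N.ar,
N.pl3, O.2, O.3, O.co2, S.3) covering every heavy atom of the 20 canonical
amino acids; 121 ordered (66 unordered) pair potentials.  The
residue/atom → type table ships as an editable TSV
(`src/pairdock/data/atom_types.tsv`); the alphabet is a reconstruction of
standard Sybyl typing and deliberately configurable, since reasonable typing
schemes differ in a few places (e.g. Trp NE1, Lys NZ).

**Reference state.** Two strategies are built in: *type-averaged* (the
distance density pooled over all pairs — the classic convention and the
default) and *uniform* (flat over the bins).  The uniform reference is the
right tool when a synthetic knowledge base plants one shared contact law for
every pair: a type-averaged reference would cancel it identically.

**Pseudo-counts.** One count per bin before normalization.  This keeps
log-ratios finite in empty bins and gives the potentials a positive plateau
of ≈ ln(N_pair / n_bins) at distances the knowledge base never realizes —
the same behaviour a real knowledge base shows below van der Waals contact.

**Significance.** A pair potential is flagged statistically significant when
its interaction count is ≥ 500 (≈10 observations per 0.1 Å bin).

**Short-range repulsion.** For docking, a Gaussian term
`height · exp(−d²/(2σ²))` (height 280 000 at d = 0, σ = 0.8 Å by default) is
added to all bins below the first interior maximum of each pair potential
plus 0.1 Å; if no interior maximum precedes the global minimum, the onset
falls back to one bin before the global minimum.  The height is the
published parameterization and pairs with wells of order −4000; potentials
derived from the synthetic knowledge bases here have wells of order −2, so
the fixture helper `make_redock_potentials` scales the height by the same
height-to-well-depth ratio (280000/4314 ≈ 65) to keep the repulsive and
attractive regimes consistent.  σ is configuration, not constant: the 0.8 Å
default decays below 0.1% of the height by ~3 Å.

## Grids and the docking search

One rectangular potential grid per atom type is precomputed over the
receptor: each node accumulates ΔW(receptor type, grid type, node–atom
distance) for receptor atoms within 5 Å.  The box is centered at the
receptor center of mass and leaves a 5 Å margin beyond the receptor on every
face, so any atom outside the box is provably outside the interaction shell
and scores zero.  (A box sized extent + 5 Å in total would leave only 2.5 Å
per face and clip real interactions; the full margin is the consistent
choice.)  Node lookups are piecewise-constant in the containing bin, exactly
as in the derivation; grid sampling is trilinear by default, nearest-node as
an option (the two coincide on lattice-aligned coordinates, which is the
exact-equivalence test surface).

Rotations are sampled on a deterministic super-Fibonacci spiral over the
quaternion sphere.  The sample count is N = ⌈C/δ³⌉ with δ the resolution in
radians and C = 65, chosen so that the covering radius stays below the
nominal resolution (verified by Monte-Carlo) and that δ = 5.6° gives ~70 000
rotations, the order of magnitude an exhaustive rigid search uses at that
resolution.  The whole set is right-translated so its first element is the
identity — the metric is bi-invariant, so uniformity and covering are
unchanged, and the coarse limit (180°) contains the identity as required.

The translational scan runs on the grid lattice (default step 1 Å = grid
spacing).  Per rotation, the ligand atoms (rotated about their center of
mass) are spread trilinearly onto a local density grid per atom type and the
score at *every* lattice offset is obtained as a cross-correlation of the
receptor grids with those densities, computed via FFT with cached receptor
transforms.  By the spreading/interpolation duality this equals trilinear
grid scoring at each lattice pose to rounding error (asserted in the tests).
The best translation per rotation is retained (configurable k) and the
per-rotation winners merge into a global ranking; ties break by generation
order.  A knowledge-driven search restricts the lattice to a sphere around a
reference point; reference points are drawn within 5 Å of hinted interface
residues, pairwise ≥ 5 Å apart.

**Clustering** is greedy leader clustering in rank order: a solution joins
the first leader within the rmsd threshold (ligand backbone rmsd for docking
output at 5 Å; all-atom rmsd for externally supplied decoys at 2.5 Å),
otherwise it becomes a new leader — so each cluster's representative is its
best-scored member by construction.  Clusters are ordered by representative
score (docking protocol) or by size (decoy protocol).  This stands in for
the kclust algorithm, which is unavailable as a specification; a brute-force
O(n²) reconstruction validates it in the tests.

## Evaluation

CAPRI-style conventions: a residue is interfacial if any heavy atom is
within 10 Å of the partner; residue–residue contacts use 5 Å.  f_nat is the
fraction of reference contacts reproduced; f_not the fraction of the
prediction's contacts absent from the reference.  l_rmsd superposes the
receptors on all backbone atoms and measures the ligand backbone without
refit; i_rmsd fits and measures on the backbone of reference-interface
residues.  Quality classes follow the printed thresholds verbatim; the
boundaries f_nat = 0.3 and 0.5 appear in two classes as printed, resolved by
the precedence high > medium > acceptable > incorrect (a dense property
sweep asserts exactly one class fires per triple).  With several reference
binding modes, the best class (ties → lowest i_rmsd) is reported together
with the matched mode index.  Difficulty classes (easy/medium/difficult)
use the Cα interface rmsd between bound and superposed-unbound forms plus
f_not, at the published thresholds.

Random-selection baselines are binomial tails P(X ≥ k), X ~ B(n, p), with p
the acceptable fraction of the decoy pool; they are reported both raw and as
integer percent.  Funnel shape is quantified by the Spearman rank
correlation between scores and rmsds (positive = funnel-like).

**SASA** is Shrake–Rupley: golden-spiral sampling (960 points per atom by
default, probe 1.4 Å) over spheres of radius (vdW + probe), with an
element-wise vdW table (C 1.70, N 1.55, O 1.52, S 1.80 Å).  A_rel divides
the measured area by the folded-protein expectation c·M^e with c = 6.3,
e = 0.73 (Miller-type power law; M is the heavy-atom mass sum in Da — the
same convention molecular_weight uses, so numerator and denominator are
consistent).  The constants ship as configuration; the success rule —
predict success iff both partners have A_rel strictly below 1.1 — is
calibrated against them.

## Synthetic study conditions

The fixture module generates everything the tests need; no downloads.

**Toy complexes** are built from idealized residue templates (pods): a small
helical ligand (6 residues by default) and a receptor molded around it — 28
contact pods slide inward along directions covering a 120° spherical cap
until they sit at a 3.5 Å surface gap, backed by a filler shell of glycine
pods 4.8–9.5 Å from the ligand surface.  The filler gives the receptor wall
thickness: without it a rigid search can "farm contacts" by threading the
ligand through a one-residue-thick wall, a geometry no packed protein
exhibits.  Guarantees: ≥ 20 inter-chain atom pairs below 5 Å, no pair below
2.0 Å, receptor strictly larger, byte-identical output per seed.  The
templates have no Ramachandran realism — nothing downstream assumes backbone
plausibility, only typed heavy atoms and distances — and that is the main
gap between these fixtures and real data: passing tests demonstrate the
machinery (scoring, search, evaluation) is correct, not that the potentials
derived from real crystal structures would rank real decoys equally well.

**Decoy ensembles** are rigid ligand perturbations with targets ramped over
a requested rmsd range (default 0–20 Å); each decoy records its exact
all-atom rmsd recomputed from the perturbed coordinates.

**Knowledge bases** plant atom pairs on a 12 Å lattice (so only intended
pairs fall inside the counting shell) with inter-partner distances drawn
from declared laws.  Sampling is randomized-stratified through the inverse
CDF: a ground-truth generator should embody its law, so per-bin deviations
are O(1) rather than O(√n), while remaining a pure function of the seed.
The redocking potentials derive from a shared contact law — a Gaussian peak
at 3.6 Å (σ 0.2) over a uniform floor supported on (3.1, 5) Å — against the
uniform reference.  The floor starts at 3.1 Å because heavy-atom non-bonded
contacts below that distance are essentially unobserved in crystal
structures; letting the floor extend lower would legitimize physically
impossible packing and destroy the excluded-volume behaviour of the derived
potential.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script, chosen as
desk-scale versions of the method's operating points: 10 self-redocking
cases at 15°/1 Å (≈3600 rotations each, a few hundred receptor atoms),
knowledge bases of 2·10⁴ samples per pair for potential shape (10⁵ for the
flatness check), 50 complexes for the scoring-oracle equivalence, grids at
2.0/1.0/0.5 Å for the convergence study.  Ties everywhere break by earlier
generation order; all generators take explicit seeds and never wall-clock
defaults.  Degenerate inputs (empty interfaces, all-zero potentials,
constant funnel inputs) either score zero with zero pairs or raise a typed
error, as documented per operation.

## Known limitations

* The exact reference-state normalization and any distance-volume correction
  of the original published derivation live in prior work; the reference
  here is a pluggable strategy with the type-averaged default.
* Derived log-ratio potentials are O(1) while the published plots are
  O(1000); an overall scale does not affect rankings, but mixing the printed
  repulsion height with O(1) wells would — hence the ratio-preserving
  height scaling described above.
* The rigid-body search has no flexibility, refinement, or long-range
  electrostatics; unbound docking with conformational change is out of its
  scope by construction.
* Greedy leader clustering is order-dependent (documented, deterministic);
  it is a stand-in for kclust, not a reimplementation.
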