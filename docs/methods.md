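# Methods

This note documents the models, conventions and numerical choices behind
`shp2meta`, and what the synthetic test conditions do and do not establish
about real data.

## The system and the collective variables

SHP2 toggles between an autoinhibited closed conformation, with the N-SH2
domain blocking the PTP catalytic site, and an open conformation in which
C-SH2 has rotated and N-SH2 occupies a different PTP surface.  Five
collective variables (CVs) span the transition; their reference values are
measured on the closed (wild-type) and open (E76K) crystal structures:

| CV | definition | closed | open |
|----|------------|--------|------|
| `dist1_np` | Cα CoM of I54–G86 vs Cα CoM of Q255–Q257, R465–G467, Q495–V497, E508–Y511 | 16.1 Å | 37.9 Å |
| `dist2_np` | Cα CoM of I54–G86 vs Cα CoM of A224–I226, I479–K482, H520–I522 | 35.1 Å | 18.4 Å |
| `dih_ncpp` | pseudo-dihedral over Cα of S44, T168, V497, Q510 | −59.5° | 66.4° |
| `psi_t218` | backbone ψ: T218 N, Cα, C and T219 N | 13.4° | 154.5° |
| `dist_k76_r265` | Cβ(76)–Cβ(265) distance | 9.9 Å | 47.9 Å |

Residue ranges are inclusive, author numbering, single chain.  CoMs use unit
weights (all anchors are Cα carbons, so this equals mass weighting).
Torsions follow the IUPAC atan2 convention and live in (−180°, 180°]; note
that a torsion is *symmetric* under reversing the atom chain
(`dihedral(a,b,c,d) = dihedral(d,c,b,a)`), which the property tests assert.

**State classification** is this package's own rule (visual FES annotation
is not reproducible): a conformation is `closed` when every CV lies within
`threshold_fraction × |open_ref − closed_ref|` of its closed reference
(circular distance for angles), `open` symmetrically, else `intermediate`.
Default `threshold_fraction = 0.25`; any value in (0, 0.5) keeps the two
reference points correctly labelled, which the tests check.

## RMSD conventions and the domain partition

"Backbone heavy atoms" means {N, CA, C, O}.  Atoms are paired across
structures by (chain, residue id, atom name), intersected over residues
resolved in both; unpaired atoms are dropped with a logged count.  Rather
than patching unresolved crystal residues from other structures, all
cross-structure comparisons are restricted to the shared residue set — this
is simpler and reproducible, and it is why the cross-structure RMSD checks
carry a ±0.5 Å band.

The domain partition defaults to N-SH2 = 3–103, C-SH2 = 112–216,
PTP = 221–524 with the C-SH2/PTP linker annotated as 217–246.  The
boundaries follow the standard SHP2 architecture and are config-overridable
because domain-wise RMSD values depend on them.  The linker annotation
deliberately overlaps the PTP range: it tags the hinge region, not a fourth
disjoint domain.

Superposition is the Kabsch SVD solution with the determinant correction
(reflections excluded); degenerate (rank < 2) configurations are rejected.

## Hydrogen bonds

A bond is counted when the donor–acceptor distance is ≤ 3.5 Å and the
D–H···A arrangement deviates from linearity by ≤ 20°.  Explicit hydrogens
are required; structures without them are rejected rather than guessed at.
The side-chain scan enumerates N/O donors (with an attached hydrogen,
inferred by a 1.25 Å covalent criterion) against N/O acceptors across two
residue groups in both directions, excluding backbone amide/carbonyl atoms.
Occupancy is the percentage of frames in which a given donor→acceptor pair
passes the criterion.

## Nonbonded inter-domain energies

The 12-6 Lennard-Jones term `ε[(Rmin/r)¹² − 2(Rmin/r)⁶]` and direct Coulomb
`k·q_iq_j/(ε_r·r)` (k = 332.0636 kcal·Å/mol·e²) are combined with
Lorentz–Berthelot rules in the CHARMM Rmin convention (`ε_ij = √(ε_iε_j)`,
`Rmin_ij = Rmin½_i + Rmin½_j`).  Forces are tapered with an atom-based
switching function between r_on = 10 Å and r_off = 12 Å; the energy is the
analytic integral of the switched force from r_off inward (termwise
antiderivatives of `S(r)·F(r)`, including the logarithmic term the Coulomb
power produces), so energy and force are continuous everywhere and exactly
zero beyond r_off.  Below r_on the plain potential applies, shifted for
continuity — hence at the LJ minimum the well depth is −ε plus the constant
switch shift (exactly −ε with switching disabled).

Two scope decisions: Coulomb is evaluated directly, without Ewald
summation, because a pairwise interaction-energy decomposition between two
atom groups is not an Ewald-defined quantity; and no force-field parameter
library is redistributed — parameter tables (ε, Rmin/2, q per atom key) are
user-supplied CSV, and the shipped tests use toy parameter sets.
Consequently the mean inter-domain energies of the microsecond all-atom
ensembles (e.g. −166.5 kcal/mol for N-SH2/PTP in the closed wild type) are
documented reference points, not reproducible targets; the machinery is
instead verified against brute-force pair summation to 1e-10.

## Well-tempered metadynamics engine

Dynamics are overdamped Langevin (Euler–Maruyama) directly in CV space on an
analytic landscape U(s):

    s' = s − (D·dt/k_BT)·∇(U+V)(s) + √(2·D·dt)·ξ

with reflective walls at the CV box and periodic wrap for angular CVs.  This
is a deliberate reduction: the engine's correctness surface is algorithmic
(bias bookkeeping, FES reconstruction, basin thermodynamics), not all-atom
force evaluation, so the protein's actual ΔG values are generator settings
here, never measurements.

Every `stride` steps a Gaussian kernel is deposited at the current position
with the well-tempered height `w = w₀·exp(−V(s)/k_BΔT)`, `ΔT = (γ−1)T`.
Heights at any revisited point are therefore non-increasing; as γ→∞ the
rule degenerates to standard metadynamics (constant w₀) and as γ→1⁺ heights
collapse after the first kernels.  The FES is `F(s) = −γ/(γ−1)·V(s)`,
min-shifted to zero.  Basin free energies use Boltzmann sums of the gridded
FES over disjoint regions (interval boxes or center+radius):
`ΔG_{a→b} = −k_BT ln(Z_b/Z_a)`.

Numerical choices:

- **Grid.** The bias and its gradient are accumulated on a regular grid
  (default spacing σ/4 per CV); Gaussian support is truncated at 6σ; angular
  dimensions use minimum-image distances and wrapped windows.  Grid
  interpolation is (bi)linear and is validated against direct kernel
  summation to 1%.
- **Force tables.** The run loop interpolates the total force from the same
  grid: the landscape gradient is tabulated once at start-up and every
  kernel patch increments both the bias and the force tables, making the
  per-step cost independent of the kernel count.  `langevin_step` exposes
  the per-step update with the analytic landscape gradient; a test confirms
  the two routes agree to the grid-interpolation error.
- **Uncertainty.** ΔG block errors replay the deposition log and recompute
  ΔG at five cumulative checkpoints spanning the second half of the run; the
  population standard deviation of those estimates is reported.  (The
  uncertainty protocol is this package's choice; enhanced-sampling papers
  rarely state theirs.)
- **Determinism.** A single `numpy` Generator seeded per run drives the
  noise; runs are bit-reproducible for fixed seed and parameters, and the
  HILLS-style log regenerates byte-identically.

Default biasing parameters (config-exposed): w₀ = 0.3 kcal/mol, σ = 1.0 Å
per distance CV (10° per angle), stride = 500 steps, γ = 10, T = 298 K.
The published simulations' exact Gaussian parameters are not publicly
tabulated, so these defaults are conventional choices of order k_BT/2 height
and sub-well width.

## Synthetic study conditions

**Two-basin landscapes.**  Inverted Gaussian wells (width 3 Å) at the
closed (16.1, 35.1) Å and open (37.9, 18.4) Å coordinates of the two
distance CVs, inside quartic confining walls; wells this far apart put the
saddle at the plateau level, so the closed-well depth *is* the
closed→open barrier.  When a target ΔG is requested the open-well depth is
tuned by Brent root-finding until Boltzmann quadrature over the two basin
regions (radius 0.45× the center separation) matches the target to
1e-4 kcal/mol; the tuner covers targets in [−12, +20] kcal/mol.  The barrier
rule for targeted landscapes is |ΔG| + 5 kcal/mol, keeping the transition
barrier a fixed margin above the asymmetry.

**ΔG-recovery protocol.**  Runs of 1.5×10⁶ steps (σ = 1.5 Å, w₀ = 0.5
kcal/mol, stride 100, γ = 20, D·dt = 0.125 Å²) recover tuned ΔG values of
−8.2 and +18.4 kcal/mol — the open-favoring (mutant-like) and
closed-favoring (wild-type-like) settings — within a few tenths of a
kcal/mol in ≈15 s each on one CPU.  Identical biasing parameters are used
for both settings.

**Reference double-well run.**  A 5×10⁵-step run on U(x) = 4(x²−1)²
kcal/mol (σ = 0.1, w₀ = 0.25, stride 200, γ = 10) reconstructs the landscape
with RMS error ≈ 0.13 kcal/mol over the thermally relevant region (F ≤ 6
kcal/mol) and recovers ΔG ≈ 0 between the symmetric basins.

**Toy proteins.**  One pseudo-Cα bead per residue needed by the CV suite
plus filler beads, with SHP2 residue numbering so the real CV machinery runs
unmodified.  The N-SH2 CoM is triangulated from the two distance targets
against fixed PTP surface patches (30 Å apart); torsion anchors are placed
by internal-coordinate construction; the Cβ pair is placed at the exact
target distance.  Both poses therefore hit all ten reference values
(distances exactly, torsions to float precision).  Domain-internal offsets
are drawn once per seed and shared between states, so closed/open frames
pair atom-by-atom for RMSD and clustering work.

**What this does and does not show.**  The generators emulate the *geometry*
of the conformational switch and the *statistics* of interface events, not
protein energetics: beads have no sterics or connectivity, landscapes are
two Gaussians, and hydrogen-bond series are i.i.d. Bernoulli draws (real
occupancy series are autocorrelated).  Passing tests therefore certify the
analysis and sampling machinery — CV evaluation, alignment conventions,
occupancy bookkeeping, FES/ΔG reconstruction — on inputs with known ground
truth; they say nothing about force-field accuracy or the convergence of
all-atom enhanced sampling, and quantities that require microsecond
trajectories (mean interaction energies, experimental-system occupancies,
backbone-ψ ensemble parameters, the protein's ΔG) are out of scope by
design.

## Ensemble analytics

Circular statistics use the directional mean and the circular standard
deviation `√(−2 ln R̄)` (delegated to scipy's implementations), which is the
appropriate convention for angle samples near the ±180° wrap and reduces to
the ordinary standard deviation for concentrated samples.  Mode detection
histograms angles periodically (5° bins), keeps strict local maxima at least
60° apart, and reports modes holding ≥ 10% of the sample within ±30°; all
three thresholds are arguments.  An exactly flat histogram has no strict
maxima, hence no modes.

Clustering is leader-style on pairwise aligned RMSD (default cutoff 3 Å,
alignment on PTP): frames join the first cluster whose medoid is within the
cutoff, else found a new one; a single refinement pass then moves each
medoid to the member minimizing summed in-cluster RMSD (which provably never
increases that sum).  The algorithm trades sophistication for determinism
and auditability — cluster identity depends only on frame order.

## Known limitations

- The engine supports 1–2 CVs only (matching its purpose); no
  multiple-walker or bias-exchange variants.
- Linear grid interpolation bounds bias accuracy at ~1% of the local bias
  scale; halve the grid spacing for tighter work.
- The hydrogen-bond scan infers donor hydrogens geometrically (1.25 Å), so
  unusual protonation states should be checked by the caller.
- PDB support covers single-model, single-conformer protein chains (first
  altloc kept, heteroatoms ignored); no mmCIF.
- Cross-structure analyses use shared resolved residues; numbers for
  structure pairs with large unresolved regions will differ from analyses
  performed on completed (patched) models.
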