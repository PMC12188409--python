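# Methods

## Scope and model system

The package implements the analysis and biasing machinery for studying how
the inhibitor protein IF₁ makes F₁-ATPase rotation direction-dependent:
a conformational landscape over αβ catalytic pairs, a rotary-angle
algorithm for γ, a mean-angle biasing scheme with nonequilibrium work and
torque accounting, per-frame trajectory metrics, and the torque→pmf
energetic bookkeeping.  All dynamic components run on a coarse-grained
rotary-motor simulator; no all-atom engine is involved, and no quantitative
claim about the real protein's dynamics is made from the toy runs.

## Conformational PCA

Each F₁ head contributes three αβ pairs.  The analyzed coordinates are Cα
atoms over fixed residue subsets chosen to be resolved across the
crystallographic ensemble — α 24–401, 413–483, 494–509 (465 residues) and
β 10–126, 129–310, 312–387, 396–464 (444 residues), 909 atoms per pair.
A batch "intersect" mode recomputes these subsets as the residues present
in *every* structure of a given batch, which is how ranges of this kind are
obtained in the first place.

Superposition iterates to the mean: all pairs are first aligned to the
first pair (or a named reference), then repeatedly re-aligned to the
running mean until the mean shifts by < 10⁻⁶ nm RMS (≤ 20 sweeps; the
iteration is a fixed-point refinement, so the result is insensitive to the
initial reference).  Rigid fits are least-squares optimal rotations with
det = +1 enforced (scipy's `Rotation.align_vectors`).

The covariance of the flattened coordinate vectors uses 1/M normalization
over M pairs; the explained-fraction statistic λₖ/Σλ is invariant to the
1/M vs 1/(M−1) choice.  Diagonalization goes through SVD of the centered
data matrix (numerically equivalent to the covariance eigenproblem and
better conditioned); modes are sorted by eigenvalue and sign-fixed so each
mode's largest-magnitude component is positive, making projections
bit-reproducible for a fixed input order.  Unweighted coordinates: with a
Cα-only, single-atom-type vector, mass weighting would only rescale the
metric uniformly.

The conformational-progress statistic is the unclipped linear position of
a trajectory's PC2 value between a start and a target value, in percent.
Defaults take the start from the trajectory's first frame and the target
from a user-supplied cluster centroid, since the analysis itself does not
prescribe the endpoints.

## Rotary angle

The stator frame is built from the β N-terminal domains (Cα of residues
10–82): the origin is the centroid of the three per-chain centers of mass,
z is the unit normal of the plane through them (oriented so the γ
C-terminal half — the protruding part — has positive z), and the frame is
rotated about z so the β_DP N-domain center lies on +x.  Which β chain is
"DP" is an input: it comes from nucleotide annotations or a prior landscape
classification, not from this module.

Given two frame-aligned structures, the γ subset (Cα of residues 1–30 and
221–270) of the model is superposed onto the reference's by an unweighted
least-squares fit (translation + proper rotation); the rotary angle is
atan2(y′, x′) of the rotated unit x axis projected on the xy plane.
Convention: CCW about the frame z axis — the hydrolysis direction — is
positive; a `sign` flag flips it.  Exact on rigid z rotations; antisymmetric
under exchanging model and reference.

## Mean-angle rotor bias

The collective variable is the in-plane Procrustes angle

θ\*(x) = atan2(Σᵢ wᵢ (xᵢʳ yᵢ − yᵢʳ xᵢ), Σᵢ wᵢ (xᵢʳ xᵢ + yᵢʳ yᵢ)),

the single rotation about z best fitting the current in-plane positions to
a reference in the weighted least-squares sense.  It is exact on rigid
rotations, closed-form, and differentiable; with S and C the two sums,
∂θ\*/∂xᵢ = wᵢ(−yᵢʳC − xᵢʳS)/(S²+C²) and ∂θ\*/∂yᵢ = wᵢ(xᵢʳC − yᵢʳS)/(S²+C²).
Only this average is restrained — individual atoms move freely as long as
the optimal mean rotation tracks the target.  Frame-to-frame
nearest-image unwrapping makes protocols beyond 360° accumulate correctly.

The bias is V = ½κ(θ−θ₀(t))² with θ₀(t) = θ₀ + s·ω·t (s = +1 CCW, −1 CW;
the ½ prefactor is this package's convention for quoting κ).  Work is
target-displacement (external) work: dW = V(θ, t+dt) − V(θ, t) at fixed
coordinates, accumulated per step.  The applied-torque estimator is the
windowed mean of κ(θ₀−θ), logged per step *before* the target moves so a
trajectory that tracks the target exactly logs zero torque; 1 kcal/mol =
6.9477 pN·nm converts to single-molecule units.

For an overdamped coordinate with rotational friction γ (= Σᵢ γᵢ rᵢ² for a
bead group) dragged at rate Ω, the steady state has lag θ₀−θ = γΩ/κ and
work rate γΩ²; these closed forms are the oracles for the work/torque
tests.  A caveat the test suite encodes: for a *2-D* bead realization at
finite temperature and large lag, radial drift changes the effective γ, so
the oracle tests pin the bead to its ring with a stiff radial tether,
leaving the angle as the only soft coordinate.

## Toy motor (synthetic data)

The simulator reproduces the statistical architecture the analyses assume,
not the enzyme's energetics.  Components and defaults (Å, kcal/mol, ns;
all toy-scale choices):

| parameter | default | meaning |
|---|---|---|
| `n_core`, `r_core` | 8 beads, 5 Å | buried rotor ring |
| `n_prot`, `r_prot` | 12 beads, 10 Å | protruded rotor ring (bias target) |
| `k_ring`, `k_radial` | 20 | ring elastic network / radial+axial tether |
| `kappa_tw` | 200 rad⁻² | core↔protruded torsion spring |
| `n_inh`, `k_bond`, `k_contact` | 8, 50, 5 | inhibitor chain and contacts |
| `contact_offset_deg` | 15° | chiral skew of the inhibitor linkage |
| `gate_barrier`, `k_gate_couple` | 2, 10 | gate double well and target coupling |
| `switch_angle_deg` | 60° | rotor angle flipping gate targets (+120°/unit) |
| `kbt`, `gamma_bead`, `gamma_gate` | 0.6, 1, 1 | temperature and frictions |

Rings are elastic networks (neighbor springs + radial/axial tethers) whose
soft mode is overall rotation; the torsion spring couples the two rings'
mean angles through the CV and its gradient, so under torque the core lags
the protruded ring as the real γ core does.  Stator gates are scalar double
wells (open ≈ 0, closed ≈ 1, barrier `gate_barrier`·16g²(1−g)²) whose
harmonic target flips once the unwrapped rotor angle passes
`switch_angle + j·120°` for unit j — the 3-fold architecture — or at
explicit protocol times, mirroring nucleotide-state replacement after 120°
steps.  The gate coupling reads the rotor angle but exerts no reaction
torque on the beads (one-way; a deliberate simplification that keeps the
gate thermodynamics exactly solvable for the occupancy test).

The inhibitor chain runs from the rotor core to stator unit 1; its
core-side end is skewed by `contact_offset_deg` about z while the
stator-side anchors are not, making the linkage chiral: with the positive
default offset, CW rotation costs measurably more work than CCW.  This
directional asymmetry is a *construction*, exercised as a regression test —
it shows the analysis pipeline resolves such asymmetries, nothing more.

Dynamics are Euler–Maruyama overdamped Langevin steps,
dx = −(dt/γ)∇U + √(2k_BT dt/γ)ξ, stable for dt < 2γ/k_max (k_max ≈ 50
bond springs at defaults; dt = 0.002 ns is the working default, and the
stiff-bias runs at κ = 10⁵–10⁶ rad⁻² need dt below 2·Σγr²/κ).  All
randomness flows from one protocol seed through named
`numpy.random.SeedSequence` children — one stream per coordinate block,
drawn in a fixed order — so trajectories are bitwise reproducible.
RMSD steering applies ½k(RMSD−ρ(t))² on the generalized coordinate vector
(beads + gates) with ρ shrinking linearly to zero, the desk analogue of
targeted MD.

What the generator does *not* emulate: chemistry (nucleotide binding,
hydrolysis), explicit solvent, realistic spring constants or barrier
heights, hydrodynamics, and any quantitative work/torque magnitude of the
real enzyme.  Tests passing on the toy therefore validate the *operators*
(CV, work ledger, PCA, metrics) — not predictions about F₁.

## Trajectory metrics

Helicity uses a dihedral-window criterion: a residue is helical when its
defined backbone dihedrals fall in φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°]
(terminal residues are judged on the dihedral they have).  The criterion is
pluggable — on ideal fixtures any reasonable secondary-structure assignment
agrees, which is the accuracy class this package needs.  Contacts count
residue pairs with any heavy-atom distance ≤ 4.5 Å (configurable), reported
relative to an equilibrium baseline as percent, optionally block-averaged
over non-overlapping half-open windows (e.g. 30 ns).  The long-helix
bending angle is the interior angle at the middle Cα of the 21/38/45
triplet.  χ1 (N–Cα–Cβ–Xγ, γ-atom per residue-type table) is reported in
[0°, 360°) to match the 200°/300° rotamer labels; the two-state assignment
uses ±40° windows (configurable; the defaults cannot overlap) with an
explicit "unassigned" category.

## Energetics

pmf [mV] = 1000·(τ·10⁻²¹ J·2π/n)/e with e = 1.602176634×10⁻¹⁹ C exactly;
rounding to integer mV happens only at presentation, so the inverse map is
an exact round trip.  The ejection torque scales the 40 pN·nm/rad baseline
by the inhibited state's 20% excess-work fraction, giving 48 pN·nm/rad and
235 mV at 8 protons/turn.  Torque is treated as angle-independent;
angle-resolved torque profiles are out of scope.

## Numerical conventions and edge cases

* Å for coordinates, nm for PCA, ns for time; degrees at every user
  interface, radians internally; kcal/mol for energies.
* Canonical atom order is ascending (chain, residue, atom name); all
  selection outputs follow it, so record shuffling cannot change results.
* Alternate locations collapse to a single conformer by occupancy;
  residue numbers are author numbering.
* Missing residues in a requested range are an error listing every gap;
  the batch "intersect" mode is the opt-in alternative.
* PDB writing refuses coordinates outside the fixed-width %8.3f field
  rather than truncating; round-trips are exact in labels and to 10⁻³ Å in
  coordinates.
* Degenerate inputs raise rather than warn: collinear coordinates in
  superposition, on-axis rotor groups, zero PC2 span in the progress
  statistic, coincident bending-angle points, identical residues in a
  minimum distance.

## Known limitations

* Pair-role assignment (E/TP/DP) is by user label or chain order; inferring
  roles from nucleotide occupancy or γ orientation across arbitrary
  deposited entries is not automated.
* The mean-angle CV is this package's documented contract for "restrain
  only the average rotation"; other realizations of that idea (e.g.
  torque-on-quaternion schemes) would differ in detail.
* The two acceptance tests against the real crystallographic ensemble
  require the deposited PDB entries on local disk; they are not bundled.
* The helicity criterion is dihedral-based, not hydrogen-bond-based; on
  frayed real helices the two can differ by a residue at the ends.
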