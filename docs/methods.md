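# Methods

This note documents the models, conventions, and numerical choices behind
`abensemble`, and what the synthetic-ensemble tests do and do not
establish about real trajectory data.

## Domain model

A `Conformation` is one frame: parallel per-atom arrays (peptide id,
1-based residue index, 1-letter residue code, atom name, element, van der
Waals radius, mass) plus coordinates in Å and a frame time in ps. An
`Ensemble` groups frames into trajectories sharing one topology, with a
recording interval and an analysis window that is half-open at the start
— a frame at time t belongs to the window iff t_start < t ≤ t_end. With
50 ns trajectories recorded every 50 ps and a (20, 50] ns window, this
convention yields exactly 600 analysis frames per trajectory, the only
choice consistent with the bookkeeping (44 trajectories ↔ 26,400
conformations per condition).

The alloform registry fixes Aβ42 as
`DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA` and Aβ40 as the same
sequence minus the final IA. Positive residues are R5, K16, K28; negative
residues D1, E3, D7, E11, E22, D23 (six, matching the propensity tables;
D1 contributes its side-chain carboxylate only). Van der Waals radii
(Bondi) and masses come from a fixed internal element table so results are
not installation-dependent.

## Statistical convention

One rule everywhere: the trajectory is the independent sampling unit.
Frames within a trajectory are autocorrelated, so every mean is a mean of
per-trajectory means and every SEM is `std(trajectory means, ddof=1)/√n`.
A single trajectory yields a mean but a flagged-unavailable (NaN) SEM.

## Analyses

**Contacts.** Two residues are in contact when their Cα atoms are
*strictly* below the cutoff (ties count as non-contact). The default
cutoff is 7.5 Å with 8.0 Å as the second value of the two-cutoff
robustness check; both are config entries and are surrogate defaults, not
externally fixed values. Intra(tertiary) maps pool both peptides of a
dimer; inter(quaternary) maps are symmetrized over peptide labeling so
results are invariant to chain order in the input file.

**Salt bridges.** A bridge exists when the minimum over side-chain N
(R: NE/NH1/NH2, K: NZ) × side-chain O (D: OD1/OD2, E: OE1/OE2) distances
is below the cutoff (default 4.0 Å, a standard criterion and likewise a
declared surrogate). Backbone N/O and the charged termini are excluded.
Dimer occurrences on either peptide pool into one intrapeptide statistic.
TOTAL rows sum the six unrounded pair propensities of a positive residue
(they may exceed 100% since distinct bridges coexist); Average TOTAL is
the mean of the three TOTALs; display rounding is round-half-up, applied
after aggregation — the published tables are reproducible only under
pre-rounding aggregation.

**SASA.** Deterministic Shrake–Rupley: each atom's sphere (vdW + 1.4 Å
probe) is sampled with a fixed 960-point Fibonacci set; a point is
exposed if outside every other atom's expanded sphere. The fixed point
set makes areas exactly reproducible at the cost of a ≤0.5% rotation
dependence, which bounds the tolerance of the rotation-invariance test.
Per-residue areas are reported in nm²; the hydrophobic reaction
coordinate sums residues of type {A, V, L, I, M, F} by default (G and Y
excluded as the conservative choice; the set is config-overridable).

**PMF.** `F_i = −ln(N_i/N)` over a 2D histogram (default 40×40 bins
spanning the data range, last bin right-closed), shifted so the global
minimum is 0 kT. Empty bins are masked as "not sampled", never given a
large finite value, which would fabricate barriers. Basin selection takes
frames within a depth (default 0.5 kT) of the minimum; representative
structures are the centroid of the largest GROMOS cluster (iterative
neighbor counting on pairwise Cα RMSD after Kabsch superposition, cutoff
default 0.3 nm, ties resolved to the lowest frame index so the result is
permutation-invariant).

**Water RDFs.** Distances from each water oxygen to the nearest heavy
atom of the residue, binned in spherical shells; the bulk density is
estimated from the outer 20% of the radial range (falling back to the
outermost populated shells when r_max extends past the data), which
tolerates irregular solvation shells better than box-volume
normalization. First-shell occupancy integrates raw counts to the first
local minimum of g(r) after its first maximum; structureless profiles
fall back to 3.5 Å and are flagged. The two-profile difference
classification quantifies the visual SEM-overlap convention: with
Δ = |g_a − g_b| and s = sem_a + sem_b at the shared first-shell peak bin,
s < Δ ≤ 1.1·s is "touching" (*), Δ > 1.1·s is "well separated" (**); the
10% band makes the otherwise-ambiguous boundary algorithmic.

**Convergence.** Per-residue statistics are evaluated at increasing time
windows or trajectory counts; convergence means the last two curves agree
within tolerance (default 0.5 Å for distance-from-CM) at every residue.
The RMSD series uses frame 0 as the reference (the natural choice when
trajectories start from distinct seed conformations). Secondary-structure
propensities are aggregated from an external assigner's per-frame label
stream (one line per frame, one of T/E/H/C per residue); implementing the
assignment algorithm is out of scope.

## Coarse-grained reconstruction

Four-bead chains (N, Cα, C′ backbone beads plus one side-chain bead per
non-Gly residue) become united-atom structures in two stages. Grafting
takes backbone heavy atoms from the beads, adds the carbonyl O at ideal
geometry (1.23 Å from C′ along the bisector away from Cα and the next N),
and centers a rigid united-atom side-chain template on the side-chain
bead, oriented deterministically along Cα → bead. Template geometry is an
idealized 1.5 Å-spaced zigzag — a surrogate sufficient for clash relief,
not a rotamer library. Clash relief is Metropolis Monte Carlo on a
soft-sphere energy `Σ max(0, σ_ij − d_ij)²`, σ_ij = 0.9·(r_i + r_j),
over non-bonded pairs (same-residue and adjacent backbone–backbone pairs
excluded); phase 1 moves side chains rigidly, phase 2 jitters backbones,
mirroring their separate optimization. Any move whose mapped bead
positions (N/Cα/C′ directly, side-chain bead as the side-chain centroid;
no re-superposition) exceed the bead-RMSD bound (default 2.0 Å) is
rejected outright, and the returned structure is the best-energy state
visited, so the bound is a hard constraint and the final energy never
exceeds the initial one. The default schedule is 2000 proposed moves per
phase at acceptance temperature 0.05; both are config entries. Hydrogen
placement is delegated to external tools.

## Synthetic ensembles

The generator produces the statistical structure the analyses assume, not
physical dynamics:

- **Monomers** — self-avoiding Cα walks (bond 3.8 Å, non-bonded pairs
  ≥ 4.0 Å) with one pseudo side-chain atom per non-Gly residue, per-frame
  Gaussian jitter (σ 0.3 Å) and optional rescaling to a target radius of
  gyration; targets below close packing error out. Charged residues'
  pseudo-atoms carry the side-chain N/O names, so the salt-bridge
  detector runs unmodified.
- **Dimers** — two chains with the N-terminal five residues scaled
  outward and residues 30+ scaled inward about the chain centroid,
  N-termini rotated to face away from the partner, then separated along
  an axis by bisection until the interpeptide contact count hits the
  target ± 2; an optional repair pass nudges residues until no cross
  pair lies inside the [7.5, 8.0) Å cutoff gap, which makes the
  two-cutoff robustness check hold by construction.
- **Telegraph salt bridges** — a two-state Markov chain per specified
  pair with prescribed stationary occupancy and mean dwell (default 5
  frames); the ON state pins the minimal N–O distance to cutoff − 1 Å,
  OFF to cutoff + 3 Å, with the same state on every peptide so the pooled
  intrapeptide propensity equals the occupancy.
- **Water shells** — Poisson-distributed uniform oxygens in a cubic box,
  rejected within 2.6 Å of solute heavy atoms; expected counts above
  2×10⁶ are refused rather than sampled unboundedly.
- **Four-bead chains** — idealized backbone bead geometry (N at 1.46 Å
  toward the previous Cα, C′ at 1.52 Å toward the next) with side-chain
  beads at 1.5–2.5 Å from Cα.

All generators derive one RNG per trajectory from seed + trajectory
index, so trajectory subsets are reproducible and different seeds
decorrelate.

What passing tests show — and do not. The synthetic ensembles exercise
the estimators against known ground truth (occupancies, contact targets,
planted clusters, uniform densities) and the operators against printed
table inputs. They do not validate force fields, water models, or
sampling adequacy of real simulations; conclusions about real Aβ
ensembles require real trajectories.

## Problem sizes and tolerances

Test and acceptance runs use deliberately small ensembles chosen to make
the statistical checks sharp rather than expansive: telegraph recovery
uses 10 trajectories × 600 frames (the per-condition window size of one
trajectory), the Gaussian PMF check uses 10⁵ samples on a 30×30 grid and
compares only well-populated bins (≥1000 counts, where per-bin sampling
error is ~0.03 kT) against the 0.15 kT tolerance, oracle equivalence uses
100 random dimers, and the reconstruction batch uses 50 chains at a
200-move schedule — the contract (composition conservation, monotone best
energy, hard bead-RMSD bound) is schedule-independent. Superposition
implementations (Kabsch SVD vs quaternion eigenvalue) agree to 10⁻⁸;
geometry invariances hold to 10⁻⁸ under random rigid motions; histogram
densities integrate to 1 within 10⁻⁹.

## Known limitations

- Side-chain templates are surrogates; reconstructed rotamers are not
  chemically idealized beyond clash avoidance.
- SASA uses spherical-shell normalization and a fixed point set; areas
  carry ~0.5% orientation noise.
- The water RDF reference point (nearest heavy atom) and bulk
  normalization are declared conventions — alternative definitions
  (residue centroid, box-volume density) shift g(r) for large residues.
- Several numeric parameters (contact cutoff, salt-bridge cutoff, PMF bin
  count, cluster cutoff, bead-RMSD bound) are declared defaults exposed
  in config and logged on every run; they are choices of this package,
  not externally fixed constants.
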