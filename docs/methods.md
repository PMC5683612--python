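# Methods

This note documents the models and procedures `cgkit` implements, the
defaults and units, the numerical choices, what the synthetic generators do
and do not emulate, and known limitations.  Units are nm, kJ/mol, K, amu and
e throughout; the gas constant is R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹.

## Interaction scaling

Martini-style force fields tabulate Lennard-Jones pairs over a discrete
ladder of well depths, ε from 2.0 (repulsive floor) to 5.6 kJ/mol, with
σ = 0.47 nm for most pairs, 0.62 nm for the super-repulsive level, and ring
("small") beads at σ = 0.43 nm with ε reduced by 25%.  Protein–protein
attraction is weakened by the linear map

ε_scaled = ε_rep + (1 − α)(ε_orig − ε_rep),  α ∈ [0, 1], ε_rep = 2.0 kJ/mol.

Properties that follow directly and are enforced by tests: the map is
non-increasing in α, preserves the ordering of levels for α < 1, never
produces a value below the floor, contracts the ladder spread by exactly
(1 − α), and collapses everything onto ε_rep at α = 1.  The floor is
configurable because tables with different conventions (e.g. polarizable
variants) have a different weakest level.

**Strategy U (uniform).**  Every bead type the protein uses — polar and
charged types included — is duplicated under a deterministic `sc` suffix.
Mutual pairs among duplicated types get scaled ε; every pair involving at
least one non-duplicated type keeps the original value, and σ, masses and
charges are copied verbatim.  Duplication rather than in-place editing is
what guarantees that lipid–lipid, water–water, protein–lipid and
protein–water interactions are bitwise untouched.  A name collision between
the suffixed name and an existing type is an error, never a silent rename.

**Strategy W (water-contacting beads only).**  Residues are classified by
counting bead–bead contacts (minimum image, cut-off 0.6 nm) of each protein
residue against water beads and against lipid beads, summed over the
retained frames of a short unbiased simulation; the first 5% of frames are
discarded as equilibration (configurable).  A residue qualifies when its
water count *strictly* exceeds its lipid count — ties do not qualify, which
is the conservative reading of "more contacts with water than with lipids".
Counts are summed bead–bead events rather than per-frame booleans, which is
robust to the number of frames analysed.  Only the bead types of qualifying
residues are duplicated and mutually scaled; interactions between scaled and
unscaled protein beads stay at their standard values.

**Small (ring) beads.**  Their pair table sits at 75% of the normal ladder
and can fall below a single table-wide floor.  `scale_epsilon` rejects
ε_orig < ε_rep by default (scaling such a pair toward the floor would
*increase* its attraction); when applying the map to a whole table the
`on_below_floor="scale"` policy is used instead, which pulls sub-floor
values up toward the floor and preserves the exact α = 1 fixed point.  The
single-floor choice keeps the map well defined across the whole table; a
per-class floor can be emulated by scaling the small-bead block separately
with `eps_repulsive = 1.5`.

## WHAM and bootstrap

Each umbrella window holds scalar reaction-coordinate samples collected
under a harmonic bias w_i(r) = k_i/2 (r − r₀_i)², typically
k = 400 kJ mol⁻¹ nm⁻² for helix–helix centre-of-mass umbrellas.  The
standard self-consistent equations

p(r_k) ∝ n_k / Σ_i N_i exp(f_i/RT) exp(−w_i(r_k)/RT),
exp(−f_i/RT) = Σ_k exp(−w_i(r_k)/RT) p(r_k)

are iterated with the bias evaluated at bin centres, until the largest
change in any f_i drops below 10⁻⁷ RT (at most 10⁵ iterations; failure to
converge raises, carrying the last residual).  G(r) = −RT ln p(r) is
reported up to an additive constant and is NaN on bins that received no
samples — undefined, not ±∞, and downstream operations must handle that
explicitly.  The default bin width is 0.01 nm.  No Jacobian or entropy
correction is applied to G(r): the two-dimensional geometry of membrane
dimerization enters only through the explicit π∫ r exp(−G/RT) dr of the
association constant, so applying a radial correction here *and* there
would double-count it.

Errors come from a Bayesian bootstrap of complete histograms: each replicate
multiplies every window's histogram by an independent Exp(1) weight
(normalized to mean one) and re-solves WHAM.  Resampling whole windows
rather than individual observations is deliberate — samples within a window
are strongly autocorrelated, and observation-level resampling would
underestimate the error.  Replicates are aligned to the full-data profile by
a least-squares constant offset before the per-bin standard deviation is
taken, making the spread invariant to the arbitrary PMF zero.  A replicate
that fails to converge is excluded with a warning.  One replicate yields a
spread of zero by convention.

## Dimerization free energy

The profile is first shifted so that G(2.75 nm) = 0 (linear interpolation
between the bracketing defined bins); 2.75 nm sits on the flat tail of
typical transmembrane-dimer profiles.  Then

K_a = π ∫₀^{r_max} r exp(−G(r)/RT) dr,  ΔG_DIM = −RT ln(K_a / A₀),

with r_max = 2.0 nm, T = 303 K and A₀ = 1 nm² per receptor (the standard
state of FRET dimerization assays) as defaults.  Since the logarithm's
argument must be dimensionless, the standard-state area appears explicitly
as K_a/A₀; with A₀ = 1 nm² it is numerically invisible but keeps the units
honest.  Quadrature is trapezoidal on the defined bin centres, extended to
the lower edge of the first defined bin and to r_max with the boundary G
values, so a flat profile integrates exactly to π r_max²/2; higher-order
rules would gain nothing on piecewise-binned data.  Undefined bins below the
first defined one are treated as hard core (zero Boltzmann weight);
undefined bins *inside* the integration region are an error.  Increasing
r_max on a profile that is flat beyond 2 nm changes ΔG_DIM negligibly only
when the bound well dominates K_a — the toolkit's invariant test uses a
realistically deep (−30 kJ/mol) well for exactly that reason.

For error propagation each bootstrap replicate is independently shifted,
integrated and converted; the reported spread is the standard deviation of
the replicate ΔG values and the point estimate always comes from the
full-data profile.  Per-replicate shifting keeps the result invariant to any
constant offset in the input profiles.

## Structure metrics

* **Backbone mapping:** one bead per residue at the Cα position, for
  comparing against atomistic (e.g. NMR) reference models.
* **RMSD:** Kabsch superposition (proper rotations only; the reflection case
  gets the standard sign correction).  The RMSD is computed from the
  transformed coordinates rather than from the SVD residual, which loses
  about eight significant digits to cancellation for near-identical sets.
  The dimer metric superposes both peptides *jointly* — a single rigid
  transform for the whole dimer — because the quantity of interest is the
  dimer geometry, not per-helix structure.  Homodimer chain-pairing
  ambiguity is resolved by taking the minimum over the two assignments.
  Motif-only alignment (fit on the dimerization-motif residues of peptide 1,
  transform applied to both peptides) is a separate operation intended for
  visual interface comparison.
* **Crossing angle:** arccos |u·v| of the first principal axes (SVD of the
  centered backbone beads of the contact-helix residue ranges, sign fixed
  first→last residue).  The absolute value discards handedness, so the
  result lives in [0°, 90°] and parallel/antiparallel both give 0°.
* **Contacts:** backbone bead pairs across peptides within 0.8 nm, minimum
  image, closed boundary (a pair at exactly the cut-off counts).
* **Trajectory summary:** per-frame RMSD, |Δ crossing angle| and signed
  contact-count deviation over the trailing window (default: last half, e.g.
  the last 20 of 40 μs), summarized per replica with an across-replica mean.
  The conventional acceptability rule — mean RMSD ≤ 1 nm and mean angle
  deviation ≤ 10° — is exposed as a pure threshold.

## Oligomer clustering

Peptide centres of mass are mass-weighted means computed after unwrapping
each peptide's beads by minimum image relative to its first bead (valid
while the peptide diameter is under half the box; the anchor choice is then
irrelevant).  Clusters are connected components of the graph joining COMs
within 2.5 nm (minimum image in all three dimensions, closed boundary);
labels are deterministic (lowest member index).  The per-frame average
oligomer size is number-averaged by default — total peptides divided by the
number of clusters — with the weight-averaged convention available, since
cluster-size tools report either.  The size histogram pools per-cluster
sizes over the trailing window (default: last quarter, e.g. the last 10 of
40 μs) and is normalized to frequencies.

## Synthetic generators

* **Interaction matrix:** 11 bead types across protein/water/lipid/ion
  categories.  A pair's level is `ladder[max(rank_i, rank_j)]` on a
  documented 9-level ladder (5.6, 5.0, 4.5, 4.0, 3.5, 3.1, 2.7, 2.3,
  2.0 kJ/mol); charged–apolar pairs get the super-repulsive level
  (ε = 2.0, σ = 0.62 nm); small–small pairs get 75% ε at σ = 0.43 nm.  Only
  the ladder endpoints, the σ values and the 25% rule are anchored facts —
  the interior spacing and the rank assignment are fixture choices.
* **Helices:** regular helix with standard α-helix backbone defaults
  (0.15 nm rise, 100° twist, 0.23 nm radius).  A finite helix's principal
  axis tilts slightly off the geometric axis (the winding phase does not
  cancel exactly), so the generated bead set is rigidly rotated to place
  its *measured* principal axis exactly on the requested one; crossed-dimer
  fixtures therefore realize their nominal crossing angle to machine
  precision, which is what makes them usable as oracles.
* **Umbrella sampler:** Gaussian random-walk Metropolis per window,
  vectorized across windows.  Step sizes are tuned during burn-in toward a
  30–60% acceptance band, the burn-in (10% of the production length, at
  least 200 steps) is discarded, and every 5th production state is retained
  so kept samples are nearly independent.  For a harmonic target the sample
  moments match the closed forms (mean r₀, variance RT/(k_true + k_bias)),
  which the tests check across seeds.
* **Double-well PMF:** exponential repulsive core (height 25 kJ/mol, onset
  0.4 nm, decay 0.05 nm) plus Gaussian wells of 7 kJ/mol at 1.0 nm
  (width 0.12 nm) and 3 kJ/mol at 1.7 nm (width 0.15 nm); flat within
  ~10⁻³ kJ/mol beyond 2.2 nm, so the 2.75 nm shift convention is exact for
  practical purposes.  Its reference ΔG_DIM comes from adaptive quadrature
  of the defining integral, independent of the histogram pipeline.
* **Cluster configurations:** chains with member spacing 0.8× the cut-off
  laid out on a grid with ≥ 2× cut-off separation between clusters, small
  seeded jitter, and shuffled peptide indices; the generator verifies its
  own partition before returning.

The WHAM recovery tests use 12 windows at centers 0.6–2.8 nm with
k = 400 kJ mol⁻¹ nm⁻² and 20,000 retained samples per window — enough for a
shift-aligned RMS error comfortably below 0.3 kJ/mol on a 0.01 nm grid, and
for the end-to-end free energy to land within 0.5 kJ/mol of the closed-form
value.  Smaller window sets (4,000 samples) back the cheaper unit tests.

### What the generators do not emulate

Synthetic windows are drawn from the exact biased Boltzmann density of a
one-dimensional PMF.  Real umbrella trajectories carry slowly decaying,
structured autocorrelation (lipid rearrangement, helix tilting), orthogonal
degrees of freedom that can be insufficiently sampled, and window-to-window
hysteresis; passing the recovery tests therefore validates the estimator
implementations, not the convergence of any particular simulation.
Similarly the geometric fixtures are ideal rigid helices — they exercise
the metric conventions, not the conformational variability of real
peptides.

## Known limitations

* Running molecular dynamics is out of scope; the toolkit prepares scaled
  parameter files and analyses existing output.  Reported free energies of
  real transmembrane dimers require μs-scale simulations in an external
  engine.
* Orthorhombic boxes only; triclinic input is rejected explicitly.
* Topology handling covers nonbonded sections only (no bonds, angles,
  elastic networks); zero C6/C12 entries cannot be converted to σ–ε form
  and are rejected.
* Per-amino-acid (type-specific) scaling calibration is not provided; the
  machinery stops at uniform and water-contact selections.
* WHAM is plain binned self-consistency: no MBAR, no autocorrelation-based
  inefficiency weighting, no 2-D reaction coordinates.
* The ITP writer's round-trip contract is 6 significant digits.
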