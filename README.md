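# cgkit

Coarse-grained protein interaction scaling and membrane-dimer analysis.

Coarse-grained force fields of the Martini family are known to over-stabilize
protein–protein contacts: umbrella-sampling estimates of transmembrane-helix
dimerization free energies come out roughly twice as large as FRET
measurements, and spontaneously formed dimers over-aggregate.  A pragmatic
remedy is to weaken the protein–protein Lennard-Jones well depths while
leaving protein–lipid, protein–water and all other interactions untouched.
`cgkit` implements that modification and the complete analysis stack needed
to evaluate it.

## What it does

**Interaction scaling.**  Martini describes nonbonded interactions with a
ladder of nine well depths, ε ∈ [2.0, 5.6] kJ/mol.  Every scaled pair is
moved toward the repulsive floor:

    ε_scaled = ε_repulsive + (1 − α) (ε_original − ε_repulsive)

with α ∈ [0, 1] and ε_repulsive = 2.0 kJ/mol, so no well depth ever drops
below the floor and at α = 1 the whole ladder collapses onto it.  Two
strategies are provided: **U** (uniform — all bead types used by the protein,
including P4, Qa and Qd) and **W** (only beads of residues that contact water
more than lipids, classified with a 0.6 nm bead-contact cut-off).  Scaled
beads are emitted as duplicated types in a standard GROMACS-dialect
nonbonded-parameter file, so nothing outside the selected protein–protein
block changes.

**Free energies.**  Umbrella-sampling windows (harmonic bias, typically
k = 400 kJ mol⁻¹ nm⁻²) are combined by self-consistent WHAM into a potential
of mean force G(r) along the helix–helix centre-of-mass distance, with
Bayesian-bootstrap error bars (100 replicates by default).  The profile is
shifted to zero at r = 2.75 nm and converted to a two-dimensional
association constant and dimerization free energy:

    K_a = π ∫₀^{r_max} r exp(−G(r)/RT) dr ,   ΔG_DIM = −RT ln(K_a / A₀)

with r_max = 2.0 nm and the FRET standard state A₀ = 1 nm² per receptor.

**Structure and aggregation metrics.**  Backbone-bead RMSD against a
coarse-grained reference dimer (joint Kabsch superposition), helix crossing
angles from the principal axes (SVD) of the contact-helix beads, inter-peptide
backbone contacts at 0.8 nm, and oligomer-size statistics from single-linkage
clustering of peptide centres of mass at 2.5 nm — all periodic-boundary aware.

**Synthetic fixtures.**  Every analysis has a generator with exactly known
ground truth: a Martini-like interaction matrix, ideal helices and crossed
dimers with prescribed crossing angles, Metropolis samples from a known PMF,
and centre-of-mass configurations with a known cluster partition.

## Worked example

```python
import numpy as np
from cgkit import (scale_epsilon, apply_uniform_scaling, wham,
                   bootstrap_pmf, dgdim_with_error)
from cgkit.synthetic_fixtures import (martini_like_matrix, TruePMF,
                                      metropolis_umbrella_sampler, true_dgdim)

# scaling the strongest interaction level
print(scale_epsilon(5.6, alpha=0.9))   # 2.36  (kJ/mol, near the 2.0 floor)
print(scale_epsilon(5.6, alpha=0.1))   # 5.24  (the mild 10% reduction)

# a U-0.1 force field: only protein-protein pairs change
table = martini_like_matrix()
ff = apply_uniform_scaling(table, table.types_of_category("protein"), alpha=0.1)
print(f"{len(ff.audit)} protein pairs rescaled; "
      f"P4-P4: {table.eps('P4','P4')} -> {ff.scaled.eps('P4sc','P4sc'):.2f} kJ/mol")
# 28 protein pairs rescaled; P4-P4: 5.6 -> 5.24 kJ/mol

# umbrella sampling -> WHAM -> dimerization free energy, on a known PMF
pmf = TruePMF.double_well()
windows = metropolis_umbrella_sampler(pmf, np.linspace(0.6, 2.8, 12),
                                      k=400.0, n_samples=20000, seed=1)
edges = np.arange(0.6, 2.8001, 0.01)
profile = wham(windows, bin_edges=edges, T=303.0)
_, replicates = bootstrap_pmf(windows, n_boot=100, seed=1, bin_edges=edges)
result = dgdim_with_error(profile, replicates, r_max=2.0)
print(f"dG_DIM = {result.dG:.2f} +/- {result.std:.2f} kJ/mol "
      f"(K_a = {result.K_a:.1f} nm^2); truth: {true_dgdim(pmf):.2f} kJ/mol")
# dG_DIM = -7.38 +/- 0.09 kJ/mol (K_a = 18.7 nm^2); truth: -7.40 kJ/mol
```

The last two lines are the full pipeline: biased samples are generated from a
known double-well profile, WHAM reconstructs the profile, the bootstrap
provides the spread, and the association-constant integral converts it to a
free energy that lands within the error bar of the closed-form value.

A `cgkit` console script exposes the same operations on files
(`cgkit scale-ff`, `cgkit classify-water`, `cgkit wham`, `cgkit dgdim`,
`cgkit dimer-metrics`, `cgkit clustersize`, `cgkit convert-ff`,
`cgkit make-fixtures`); run `cgkit --help` for details.

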