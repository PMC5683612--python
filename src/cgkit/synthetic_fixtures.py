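"""Synthetic inputs with known ground truth for every analysis stage.

This module generates: a Martini-like 9-level interaction matrix (printed
anchor values only — the endpoints 2.0 and 5.6 kJ/mol, the 0.47/0.62 nm
sigmas, and the 25% small-bead reduction — are fixed; the intermediate
ladder is a documented default), ideal coarse-grained helices and crossed
dimers with exactly known principal axes and crossing angles, Metropolis
samples from biased Boltzmann densities over a known PMF (the WHAM oracle),
and peptide-COM configurations with a known single-linkage partition.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from cgkit.constants import DEFAULT_TEMPERATURE, GAS_CONSTANT_KJ
from cgkit.io_formats import NonbondedTable
from cgkit.pmf_wham import UmbrellaWindow
from cgkit.structure_metrics import DimerFrame, PeptideBackbone, principal_axis

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureMatrixSpec",
    "TruePMF",
    "martini_like_matrix",
    "ideal_helix",
    "make_crossed_dimer",
    "metropolis_umbrella_sampler",
    "make_oligomer_config",
    "true_dgdim",
]

#: Default 9-level epsilon ladder, kJ/mol, strongest to weakest.  Only the
#: endpoints are anchored facts; the interior spacing is a fixture choice.
DEFAULT_LADDER = (5.6, 5.0, 4.5, 4.0, 3.5, 3.1, 2.7, 2.3, 2.0)

#: name, category, polarity rank (0 = most polar), mass (amu), charge (e), small
DEFAULT_TYPES = (
    ("P4", "protein", 0, 72.0, 0.0, False),
    ("P1", "protein", 2, 72.0, 0.0, False),
    ("Nda", "protein", 3, 72.0, 0.0, False),
    ("C1", "protein", 5, 72.0, 0.0, False),
    ("Qa", "protein", 1, 72.0, -1.0, False),
    ("Qd", "protein", 1, 72.0, 1.0, False),
    ("SC4", "protein", 5, 45.0, 0.0, True),
    ("W", "water", 0, 72.0, 0.0, False),
    ("C1L", "lipid", 5, 72.0, 0.0, False),
    ("PO4", "lipid", 1, 72.0, -1.0, False),
    ("Qion", "ion", 1, 72.0, 1.0, False),
)


@dataclass
class FixtureMatrixSpec:
    """Recipe for the Martini-like fixture matrix.

    The well depth of a pair is ``ladder[max(rank_i, rank_j)]`` except for
    charged-apolar pairs, which get the weakest (super-repulsive) level with
    sigma = 0.62 nm.  All other pairs use sigma = 0.47 nm, and pairs of two
    small (ring) beads use sigma = 0.43 nm with epsilon reduced by 25%.
    """

    ladder: tuple[float, ...] = DEFAULT_LADDER
    types: tuple = DEFAULT_TYPES
    sigma_normal: float = 0.47
    sigma_super_repulsive: float = 0.62
    sigma_small: float = 0.43
    small_eps_factor: float = 0.75

    def __post_init__(self):
        if len(self.ladder) != 9:
            raise ValueError("the fixture ladder has exactly 9 interaction levels")
        if any(e1 <= e2 for e1, e2 in zip(self.ladder, self.ladder[1:])):
            raise ValueError("ladder must be strictly decreasing")


def martini_like_matrix(spec: FixtureMatrixSpec | None = None) -> NonbondedTable:
    """Completed symmetric Lennard-Jones table per the fixture recipe.

    Anchors: maximal epsilon 5.6 and minimal 2.0 kJ/mol over normal pairs;
    super-repulsive pairs at sigma 0.62 nm; small-small pairs at 75% of the
    corresponding normal epsilon and sigma 0.43 nm.
    """
    spec = spec or FixtureMatrixSpec()
    table = NonbondedTable(dialect="sigma-eps")
    ranks: dict[str, int] = {}
    for name, category, rank, mass, charge, small in spec.types:
        table.add_type(name, mass=mass, charge=charge, small=small, category=category)
        ranks[name] = rank
    names = [t[0] for t in spec.types]
    for i, a in enumerate(names):
        for b in names[i:]:
            ba, bb = table.meta[a], table.meta[b]
            charged_apolar = (
                (ba.charge != 0.0 and ranks[b] >= 5)
                or (bb.charge != 0.0 and ranks[a] >= 5)
            )
            if charged_apolar:
                eps = spec.ladder[-1]
                sigma = spec.sigma_super_repulsive
            else:
                eps = spec.ladder[max(ranks[a], ranks[b])]
                sigma = spec.sigma_normal
            if ba.small and bb.small:
                eps *= spec.small_eps_factor
                sigma = spec.sigma_small
            table.set_pair(a, b, eps, sigma)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Geometric fixtures
# ---------------------------------------------------------------------------

def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation matrix mapping unit vector u exactly onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    axis = np.cross(u, v)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * math.acos(c)).as_matrix()


def ideal_helix(
    n_res: int,
    rise: float = 0.15,
    twist: float = 100.0,
    radius: float = 0.23,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    peptide_id: int = 1,
    start_resid: int = 1,
) -> PeptideBackbone:
    """Regular helix of one bead per residue with an exactly known principal axis.

    The defaults (0.15 nm rise, 100 degree twist, 0.23 nm radius) are standard
    alpha-helix backbone values.  A raw finite helix has a principal axis that
    tilts slightly off the geometric axis (the phase of the winding does not
    average out exactly), so after construction the bead set is rigidly
    rotated to place its measured principal axis exactly on the requested
    one; the centroid sits at ``origin``.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("degenerate (zero) axis")
    axis = axis / norm
    i = np.arange(n_res)
    theta = np.radians(twist) * i
    raw = np.column_stack([
        radius * np.cos(theta),
        radius * np.sin(theta),
        rise * i,
    ])
    raw -= raw.mean(axis=0)
    resids = start_resid + i
    bb = PeptideBackbone(coords=raw, resids=resids, peptide_id=peptide_id)
    measured = principal_axis(bb)
    R = _rotation_between(measured, axis)
    coords = (R @ raw.T).T + np.asarray(origin, dtype=float)
    return PeptideBackbone(coords=coords, resids=resids, peptide_id=peptide_id)


def make_crossed_dimer(
    angle: float,
    separation: float = 0.8,
    n_res: int = 26,
    **helix_kwargs,
) -> DimerFrame:
    """Two ideal helices whose principal axes subtend exactly ``angle`` degrees.

    Peptide 1 lies along z through the origin; peptide 2 is tilted by the
    requested angle in the x-z plane and offset along y so the closest
    approach of the two axes equals ``separation`` nm.
    """
    if not 0.0 <= angle <= 90.0:
        raise ValueError(f"angle must lie in [0, 90], got {angle}")
    a = math.radians(angle)
    p1 = ideal_helix(n_res, axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0),
                     peptide_id=1, **helix_kwargs)
    p2 = ideal_helix(n_res, axis=(math.sin(a), 0.0, math.cos(a)),
                     origin=(0.0, separation, 0.0), peptide_id=2, **helix_kwargs)
    return DimerFrame(peptides=(p1, p2), box=None)


# ---------------------------------------------------------------------------
# Umbrella-sampling oracle
# ---------------------------------------------------------------------------

@dataclass
class TruePMF:
    """A known free-energy profile G(r) (kJ/mol) on (r_min, r_max]."""

    g: Callable[[np.ndarray], np.ndarray]
    r_min: float = 0.05
    r_max: float = 3.2

    def __call__(self, r):
        return self.g(np.asarray(r, dtype=float))

    @classmethod
    def double_well(
        cls,
        core_height: float = 25.0,
        core_onset: float = 0.4,
        core_decay: float = 0.05,
        depth1: float = 7.0,
        center1: float = 1.0,
        width1: float = 0.12,
        depth2: float = 3.0,
        center2: float = 1.7,
        width2: float = 0.15,
    ) -> "TruePMF":
        """Repulsive core plus two Gaussian wells; flat (about 0) beyond 2.2 nm."""

        def g(r):
            r = np.asarray(r, dtype=float)
            core = core_height * np.exp(-(r - core_onset) / core_decay)
            w1 = depth1 * np.exp(-((r - center1) ** 2) / (2 * width1**2))
            w2 = depth2 * np.exp(-((r - center2) ** 2) / (2 * width2**2))
            return core - w1 - w2

        return cls(g=g)


def metropolis_umbrella_sampler(
    true_pmf: TruePMF,
    centers: Sequence[float],
    k: float = 400.0,
    n_samples: int = 5000,
    T: float = DEFAULT_TEMPERATURE,
    seed: int | None = None,
    thin: int = 5,
    burn_in_frac: float = 0.1,
    step: float | None = None,
) -> list[UmbrellaWindow]:
    """Markov-chain samples from the biased density of each umbrella window.

    Each window's target is ``exp(-[G_true(r) + k/2 (r - r0)^2] / RT)``.  A
    symmetric Gaussian random-walk Metropolis chain is run per window
    (vectorized across windows); the step size is tuned during burn-in toward
    a 30-60% acceptance rate, the burn-in (``burn_in_frac`` of the production
    length) is discarded, and every ``thin``-th production state is retained
    so that the kept samples are close to independent.  Reproducible given
    ``seed``; post-burn-in acceptance rates are logged and attached to each
    window as ``acceptance_rate``.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("need at least one window center")
    if np.any((centers < true_pmf.r_min) | (centers > true_pmf.r_max)):
        raise ValueError("window centers must lie inside the PMF domain")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if k < 0:
        raise ValueError("spring constant must be >= 0")
    rt = GAS_CONSTANT_KJ * T
    rng = np.random.default_rng(seed)
    n_win = len(centers)

    def energy(r: np.ndarray) -> np.ndarray:
        e = true_pmf(r) + 0.5 * k * (r - centers) ** 2
        out_of_domain = (r <= true_pmf.r_min) | (r > true_pmf.r_max)
        return np.where(out_of_domain, np.inf, e)

    if step is None:
        span = true_pmf.r_max - true_pmf.r_min
        step0 = 2.0 * math.sqrt(rt / k) if k > 0 else 0.2 * span
    else:
        step0 = step
    steps = np.full(n_win, step0)

    state = centers.copy()
    e_state = energy(state)
    if not np.all(np.isfinite(e_state)):
        raise ValueError("zero density at a window center")

    n_prod = n_samples * thin
    n_burn = max(200, int(burn_in_frac * n_prod))
    tune_block = 200
    acc_block = np.zeros(n_win)
    samples = np.empty((n_samples, n_win))
    accepted = np.zeros(n_win)
    kept = 0
    for it in range(n_burn + n_prod):
        prop = state + steps * rng.standard_normal(n_win)
        e_prop = energy(prop)
        log_alpha = -(e_prop - e_state) / rt
        accept = np.log(rng.random(n_win)) < log_alpha
        state = np.where(accept, prop, state)
        e_state = np.where(accept, e_prop, e_state)
        if it < n_burn:
            acc_block += accept
            if (it + 1) % tune_block == 0:
                rate = acc_block / tune_block
                steps = np.where(rate < 0.3, steps * 0.8,
                                 np.where(rate > 0.6, steps * 1.25, steps))
                acc_block[:] = 0.0
        else:
            accepted += accept
            if (it - n_burn + 1) % thin == 0:
                samples[kept] = state
                kept += 1
    rates = accepted / n_prod
    windows = []
    for j, r0 in enumerate(centers):
        w = UmbrellaWindow(center=float(r0), k=k, samples=samples[:, j].copy())
        w.acceptance_rate = float(rates[j])
        windows.append(w)
        logger.info("window r0=%.3f nm: acceptance %.2f, step %.3f nm",
                    r0, rates[j], steps[j])
    return windows


def true_dgdim(
    true_pmf: TruePMF,
    r_max: float = 2.0,
    T: float = DEFAULT_TEMPERATURE,
    r_ref: float = 2.75,
    A0: float = 1.0,
) -> float:
    """Closed-form (dense quadrature) dimerization free energy of a known PMF.

    Shifts G_true to zero at ``r_ref``, integrates
    ``pi r exp(-G/RT)`` from 0 to ``r_max`` adaptively, and applies
    ``-RT ln(K_a / A0)``.  Serves as the end-to-end oracle for the
    sampler -> WHAM -> integration chain.
    """
    rt = GAS_CONSTANT_KJ * T
    g_ref = float(true_pmf(r_ref))

    def integrand(r):
        return math.pi * r * math.exp(-(float(true_pmf(r)) - g_ref) / rt)

    ka, _ = quad(integrand, 0.0, r_max, limit=200)
    return -rt * math.log(ka / A0)


# ---------------------------------------------------------------------------
# Clustering oracle configurations
# ---------------------------------------------------------------------------

def make_oligomer_config(
    n: int,
    cluster_spec: Sequence[int],
    box: Sequence[float],
    seed: int | None = None,
    cutoff: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Peptide COMs whose single-linkage partition at ``cutoff`` is known exactly.

    Each cluster is laid out as a chain with bead spacing 0.8 x cutoff (so
    consecutive members are linked but the chain is not compact), clusters
    are separated by at least 2 x cutoff, and small seeded jitter is added.
    Peptide indices are shuffled so cluster membership is not contiguous.

    Returns ``(coms (n, 3), expected_labels)`` where each expected label is
    the lowest peptide index of its cluster (the convention of
    :func:`cgkit.oligomer_clustering.single_linkage_clusters`).
    Raises if the requested clusters cannot be packed into the box.
    """
    cluster_spec = list(cluster_spec)
    if sum(cluster_spec) != n:
        raise ValueError(f"cluster sizes {cluster_spec} do not sum to n={n}")
    if any(s < 1 for s in cluster_spec):
        raise ValueError("cluster sizes must be >= 1")
    box = np.asarray(box, dtype=float)
    spacing = 0.8 * cutoff
    gap = 2.0 * cutoff
    jitter_mag = 0.04 * cutoff
    margin = 0.5 * cutoff
    max_len = (max(cluster_spec) - 1) * spacing
    pitch = max_len + gap  # grid pitch between cluster origins
    if max_len + 2 * margin > box[0]:
        raise ValueError("box x-dimension too small for the largest cluster chain")
    n_cols = max(1, int((box[0] - 2 * margin - max_len) // pitch) + 1)
    n_rows = -(-len(cluster_spec) // n_cols)  # ceil division
    if (n_rows - 1) * gap + 2 * margin > box[1]:
        raise ValueError("box y-dimension too small for the requested cluster count")
    rng = np.random.default_rng(seed)
    coords = []
    groups: list[list[int]] = []
    idx = 0
    for ci, size in enumerate(cluster_spec):
        members = []
        x0 = margin + (ci % n_cols) * pitch
        y = margin + (ci // n_cols) * gap
        z = box[2] / 2.0
        for m in range(size):
            x = x0 + m * spacing
            pos = np.array([x, y, z]) + rng.uniform(-jitter_mag, jitter_mag, 3)
            coords.append(pos % box)
            members.append(idx)
            idx += 1
        groups.append(members)
    coords = np.asarray(coords)
    perm = rng.permutation(n)
    coords = coords[np.argsort(perm)]  # peptide perm[i] gets old coordinate i
    expected = np.empty(n, dtype=int)
    for members in groups:
        new_ids = [perm[m] for m in members]
        lowest = min(new_ids)
        for nid in new_ids:
            expected[nid] = lowest

    # defensive self-check: the construction must reproduce the partition
    from cgkit.oligomer_clustering import single_linkage_clusters

    got = single_linkage_clusters(coords, cutoff=cutoff, box=box)
    if not np.array_equal(got, expected):
        raise RuntimeError("fixture construction failed to realize the partition")
    return coords, expected
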