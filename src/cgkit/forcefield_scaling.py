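"""Downscaling of protein-protein Lennard-Jones well depths in a Martini-style table.

Two strategies are provided.  Uniform scaling (``U``) rescales the mutual
interactions of *all* bead types used by the protein, including the polar and
charged backbone/side-chain types (P4, Qa, Qd).  Water-contact scaling (``W``)
first classifies residues by whether they touch water more than lipids (bead
contact cut-off 0.6 nm) and rescales only the mutual interactions of beads
belonging to those residues; interactions between scaled and unscaled protein
beads remain at their standard values.

In both strategies the well depth of a scaled pair is moved toward the
repulsive floor of the interaction ladder:

    eps_scaled = eps_repulsive + (1 - alpha) * (eps_original - eps_repulsive)

with 0 <= alpha <= 1 and eps_repulsive = 2.0 kJ/mol by default, so no scaled
epsilon ever drops below the floor and alpha = 1 collapses the whole protein
ladder onto it.  Scaled beads are emitted as *duplicated* types so that
protein-lipid, protein-water and all non-protein interactions are untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from MDAnalysis.lib.distances import distance_array

from cgkit.constants import EPSILON_REPULSIVE
from cgkit.io_formats import Frame, NonbondedTable

__all__ = [
    "ScalingSpec",
    "ScaledForceField",
    "scale_epsilon",
    "apply_uniform_scaling",
    "apply_water_scaling",
    "classify_water_contacting_residues",
    "SCALED_TYPE_SUFFIX",
]

#: Deterministic suffix appended to duplicated (rescaled) bead-type names.
SCALED_TYPE_SUFFIX = "sc"


@dataclass
class ScalingSpec:
    """Declarative description of one scaling run.

    For strategy ``U`` the selection is a set of bead-type names used by the
    protein; for strategy ``W`` it is a set of ``(peptide_id, resid)`` pairs
    whose beads are to be rescaled.
    """

    strategy: str  # 'U' or 'W'
    alpha: float
    eps_repulsive: float = EPSILON_REPULSIVE
    selection: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strategy not in ("U", "W"):
            raise ValueError(f"strategy must be 'U' or 'W', got {self.strategy!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.eps_repulsive <= 0.0:
            raise ValueError("eps_repulsive must be positive")
        if self.alpha > 0.0 and not self.selection:
            raise ValueError("non-trivial scaling requires a non-empty selection")
        self.selection = frozenset(self.selection)

    @property
    def label(self) -> str:
        return f"{self.strategy}-{self.alpha:g}"


@dataclass
class ScaledForceField:
    """Result of a scaling run: original and emitted tables plus bookkeeping."""

    original: NonbondedTable
    scaled: NonbondedTable
    type_map: dict[str, str]  # original type -> duplicated (scaled) type
    audit: list[tuple[tuple[str, str], float, float]]  # (pair, eps_original, eps_scaled)

    def changed_pairs(self) -> list[tuple[str, str]]:
        """Pairs whose epsilon differs from the corresponding original value."""
        return [pair for pair, e0, e1 in self.audit if not math.isclose(e0, e1)]


def scale_epsilon(
    eps_original: float,
    alpha: float,
    eps_repulsive: float = EPSILON_REPULSIVE,
    on_below_floor: str = "error",
) -> float:
    """Move a Lennard-Jones well depth toward the repulsive floor.

    Returns ``eps_repulsive + (1 - alpha) * (eps_original - eps_repulsive)``,
    which interpolates linearly between the original value (alpha = 0) and the
    floor (alpha = 1) and never drops below the floor.

    Parameters
    ----------
    eps_original : float
        Unscaled well depth, kJ/mol.  Normally at or above the floor.
    alpha : float
        Fractional reduction of the attraction above the floor, in [0, 1].
    eps_repulsive : float
        The repulsive floor of the ladder, kJ/mol (> 0).
    on_below_floor : {'error', 'scale'}
        Small ring beads carry well depths at 75% of the normal ladder and can
        sit *below* a single table-wide floor; ``'error'`` rejects such input
        (scaling would then increase the attraction), ``'scale'`` applies the
        same linear map, which pulls the value up toward the floor and still
        satisfies the alpha = 1 fixed point.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if eps_repulsive <= 0.0:
        raise ValueError("eps_repulsive must be positive")
    if eps_original < eps_repulsive:
        if on_below_floor == "error":
            raise ValueError(
                f"eps_original={eps_original} < eps_repulsive={eps_repulsive}: "
                "scaling would increase the attraction"
            )
        elif on_below_floor != "scale":
            raise ValueError(f"unknown on_below_floor={on_below_floor!r}")
    return eps_repulsive + (1.0 - alpha) * (eps_original - eps_repulsive)


def _duplicate_and_scale(
    table: NonbondedTable,
    types_to_scale: Iterable[str],
    alpha: float,
    eps_repulsive: float,
    suffix: str,
    small_bead_policy: str,
) -> ScaledForceField:
    """Shared machinery of the U and W strategies.

    Every type in ``types_to_scale`` is duplicated under ``name + suffix``.
    Pairs among duplicated types get scaled epsilons; every pair involving at
    least one non-duplicated type keeps the corresponding original epsilon.
    Sigma, masses and charges are copied verbatim.
    """
    types_to_scale = sorted(set(types_to_scale))
    for t in types_to_scale:
        if t not in table.meta:
            raise KeyError(f"unknown bead type {t!r}")
    if alpha > 0.0 and not types_to_scale:
        raise ValueError("alpha > 0 with an empty scaling selection")
    if not table.is_complete():
        raise ValueError(f"input table incomplete; missing pairs: {table.missing_pairs()}")

    out = table.copy()
    type_map: dict[str, str] = {}
    for t in types_to_scale:
        new = t + suffix
        if new in table.meta:
            raise ValueError(
                f"duplicated type name {new!r} collides with an existing type; "
                "choose a different suffix"
            )
        bt = table.meta[t]
        out.add_type(new, mass=bt.mass, charge=bt.charge, small=bt.small,
                     category=bt.category)
        type_map[t] = new

    audit: list[tuple[tuple[str, str], float, float]] = []
    new_types = [type_map[t] for t in types_to_scale]
    # cross pairs new-old: copy the original cross value (also new-vs-unscaled-protein)
    for t, new in type_map.items():
        for other in table.types:
            eps, sigma = table.pairs[table._key(t, other)]
            # if the partner is itself duplicated, map it to its duplicate's
            # original: handled in the scaled block below; here pair new type
            # with every *original* type name
            out.set_pair(new, other, eps, sigma)
    # mutual pairs among duplicated types: Eq-style scaled epsilon
    for i, ti in enumerate(types_to_scale):
        for tj in types_to_scale[i:]:
            eps0, sigma = table.pairs[table._key(ti, tj)]
            eps1 = scale_epsilon(eps0, alpha, eps_repulsive,
                                 on_below_floor=small_bead_policy)
            out.set_pair(type_map[ti], type_map[tj], eps1, sigma)
            audit.append(((type_map[ti], type_map[tj]), eps0, eps1))
    out.validate()
    return ScaledForceField(original=table, scaled=out, type_map=type_map, audit=audit)


def apply_uniform_scaling(
    table: NonbondedTable,
    protein_types: Iterable[str],
    alpha: float,
    eps_repulsive: float = EPSILON_REPULSIVE,
    suffix: str = SCALED_TYPE_SUFFIX,
    small_bead_policy: str = "scale",
) -> ScaledForceField:
    """Strategy U: duplicate every protein bead type and scale all mutual pairs.

    The selection must contain *all* bead types the protein uses — including
    the polar/charged ones — since the point of uniform scaling is to weaken
    protein-protein attraction across the board while the duplicated types'
    interactions with water, lipids and ions stay at their standard values.
    """
    protein_types = set(protein_types)
    if alpha > 0.0 and not protein_types:
        raise ValueError("alpha > 0 requires a non-empty protein_types set")
    return _duplicate_and_scale(table, protein_types, alpha, eps_repulsive,
                                suffix, small_bead_policy)


def apply_water_scaling(
    table: NonbondedTable,
    classified_residues: Iterable[tuple[int, int]],
    residue_types: Mapping[tuple[int, int], str | Iterable[str]],
    alpha: float,
    eps_repulsive: float = EPSILON_REPULSIVE,
    suffix: str = SCALED_TYPE_SUFFIX,
    small_bead_policy: str = "scale",
) -> ScaledForceField:
    """Strategy W: duplicate only the bead types of water-contacting residues.

    ``residue_types`` maps ``(peptide_id, resid)`` to the bead type name(s)
    that residue uses.  Mutual pairs among the duplicated types are scaled;
    pairs between a duplicated type and anything else — including unscaled
    protein beads — keep the original cross values.
    """
    classified = set(classified_residues)
    types: set[str] = set()
    for key in classified:
        if key not in residue_types:
            raise KeyError(f"no bead-type mapping for residue {key}")
        entry = residue_types[key]
        if isinstance(entry, str):
            types.add(entry)
        else:
            types.update(entry)
    if alpha > 0.0 and classified and not types:
        raise ValueError("classified residues map to no bead types")
    if not classified:
        # nothing to rescale: emitted table is the original
        return ScaledForceField(original=table, scaled=table.copy(),
                                type_map={}, audit=[])
    return _duplicate_and_scale(table, types, alpha, eps_repulsive,
                                suffix, small_bead_policy)


def classify_water_contacting_residues(
    frames: Sequence[Frame],
    cutoff: float = 0.6,
    skip: float = 0.05,
) -> set[tuple[int, int]]:
    """Classify protein residues by water-vs-lipid bead contacts.

    For every protein residue, bead-bead contacts (minimum-image distance
    within ``cutoff`` nm) against water beads and against lipid beads are
    counted and summed over the retained frames; a residue is classified as
    water-contacting when its water count strictly exceeds its lipid count
    (ties are *not* classified).  The first ``skip`` fraction of frames is
    discarded as equilibration.

    Returns the set of ``(peptide_id, resid)`` keys of classified residues.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not 0.0 <= skip < 1.0:
        raise ValueError("skip must be a fraction in [0, 1)")
    n_skip = int(round(skip * len(frames)))
    retained = frames[n_skip:]
    if not retained:
        raise ValueError("no frames left after equilibration skip")

    water_counts: dict[tuple[int, int], int] = {}
    lipid_counts: dict[tuple[int, int], int] = {}
    for frame in retained:
        prot = frame.select("protein")
        water = frame.select("water")
        lipid = frame.select("lipid")
        if len(water) == 0 or len(lipid) == 0:
            raise ValueError("classification requires both water and lipid beads")
        box = np.array([*(frame.box * 1.0), 90.0, 90.0, 90.0])
        pc = np.ascontiguousarray(frame.coords[prot], dtype=np.float64)
        dw = distance_array(pc, np.ascontiguousarray(frame.coords[water]), box=box)
        dl = distance_array(pc, np.ascontiguousarray(frame.coords[lipid]), box=box)
        nw = (dw <= cutoff).sum(axis=1)
        nl = (dl <= cutoff).sum(axis=1)
        for i, gidx in enumerate(prot):
            key = (int(frame.peptide_ids[gidx]), int(frame.resids[gidx]))
            water_counts[key] = water_counts.get(key, 0) + int(nw[i])
            lipid_counts[key] = lipid_counts.get(key, 0) + int(nl[i])
    return {key for key in water_counts
            if water_counts[key] > lipid_counts.get(key, 0)}
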