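"""Dimer structure quality metrics for coarse-grained transmembrane peptides.

Three criteria judge a simulated dimer against a coarse-grained reference
structure (e.g. a Calpha-mapped NMR model): the backbone-bead RMSD after
joint Kabsch superposition of both peptides, the deviation of the helix
crossing angle (angle between the first principal axes of the contact-helix
backbone beads, handedness discarded, range [0, 90] degrees), and the
deviation in the number of inter-peptide backbone-bead contacts (cut-off
0.8 nm, closed boundary).  A summary over the tail window of a trajectory,
per replica, supports the usual "deviations up to 10 degrees and 1 nm are
acceptable" reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PeptideBackbone",
    "DimerFrame",
    "DimerReference",
    "DimerDeviationSummary",
    "map_atomistic_to_cg_backbone",
    "kabsch_superpose",
    "backbone_rmsd",
    "principal_axis",
    "crossing_angle",
    "interpeptide_contacts",
    "dimer_deviation_summary",
    "replica_summary_table",
    "in_acceptable_region",
    "motif_align",
]


@dataclass
class PeptideBackbone:
    """Ordered backbone bead coordinates (nm) for one peptide."""

    coords: np.ndarray
    resids: np.ndarray
    peptide_id: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.resids) != len(self.coords):
            raise ValueError("resids length mismatch")
        if len(self.coords) >= 2 and not np.all(np.diff(self.resids) > 0):
            raise ValueError("residue ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.coords)

    def residue_slice(self, first: int, last: int) -> np.ndarray:
        """Coordinates of residues with ``first <= resid <= last`` (inclusive)."""
        mask = (self.resids >= first) & (self.resids <= last)
        if not np.any(mask):
            raise ValueError(f"no residues in range [{first}, {last}]")
        return self.coords[mask]


@dataclass
class DimerFrame:
    """Two peptide backbones plus the (orthorhombic) box, nm."""

    peptides: tuple[PeptideBackbone, PeptideBackbone]
    box: np.ndarray | None = None
    time: float = 0.0  # ns, optional trajectory timestamp

    def __post_init__(self):
        if len(self.peptides) != 2:
            raise ValueError("a dimer frame holds exactly two peptides")
        self.peptides = tuple(self.peptides)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")


@dataclass
class DimerReference:
    """Reference dimer with contact-helix ranges and target metric values.

    ``helix_ranges`` gives the (first, last) residue ids defining the contact
    helix of each peptide, used for the crossing-angle axes.  The reference
    angle and contact count are the values the trajectory metrics are
    compared against; ``motif_range`` optionally marks the dimerization motif
    on peptide 1 for motif-based alignment.
    """

    peptides: tuple[PeptideBackbone, PeptideBackbone]
    helix_ranges: tuple[tuple[int, int], tuple[int, int]]
    crossing_angle: float
    n_contacts: int
    motif_range: tuple[int, int] | None = None
    contact_cutoff: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.crossing_angle <= 90.0:
            raise ValueError("reference crossing angle must lie in [0, 90] degrees")
        for pep, (lo, hi) in zip(self.peptides, self.helix_ranges):
            if lo > hi or lo < pep.resids.min() or hi > pep.resids.max():
                raise ValueError(f"helix range ({lo}, {hi}) outside residue span")

    @classmethod
    def from_frame(
        cls,
        frame: DimerFrame,
        helix_ranges: tuple[tuple[int, int], tuple[int, int]],
        motif_range: tuple[int, int] | None = None,
        contact_cutoff: float = 0.8,
    ) -> "DimerReference":
        """Build a reference from a frame, measuring its own angle and contacts."""
        angle = crossing_angle(frame, helix_ranges)
        n = interpeptide_contacts(frame, cutoff=contact_cutoff)
        return cls(peptides=frame.peptides, helix_ranges=helix_ranges,
                   crossing_angle=angle, n_contacts=n, motif_range=motif_range,
                   contact_cutoff=contact_cutoff)


def map_atomistic_to_cg_backbone(pdb_text: str, chain: str) -> PeptideBackbone:
    """One backbone bead per residue at the Calpha position (nm) of one chain.

    This is the coarse-grained backbone mapping used to compare simulation
    frames against atomistic (NMR) reference models.  Missing Calpha atoms
    raise, naming the residue.
    """
    from Bio.PDB import PDBParser
    import io as _io

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ref", _io.StringIO(pdb_text))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise ValueError(f"chain {chain!r} not found (available: {chain_ids})")
    coords, resids = [], []
    for residue in model[chain]:
        if residue.id[0].strip():  # skip heteroatoms/water
            continue
        if "CA" not in residue:
            raise ValueError(f"residue {residue.id[1]} ({residue.resname}) has no CA atom")
        coords.append(residue["CA"].coord / 10.0)  # Angstrom -> nm
        resids.append(residue.id[1])
    if not coords:
        raise ValueError(f"chain {chain!r} contains no standard residues")
    order = np.argsort(resids)
    return PeptideBackbone(coords=np.asarray(coords)[order],
                           resids=np.asarray(resids)[order],
                           peptide_id=chain_ids.index(chain) + 1)


def kabsch_superpose(
    mobile: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile points onto the
    reference frame; ``R`` is always a proper rotation (det +1, standard sign
    correction when a reflection would fit better).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {ref.shape}")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points for superposition")
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    # rmsd from the transformed coordinates, not the SVD residual: the latter
    # loses ~8 digits to cancellation for near-identical point sets
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def backbone_rmsd(frame: DimerFrame, ref: DimerReference) -> float:
    """Minimized backbone RMSD (nm) of the dimer against the reference.

    Both peptides are superposed *jointly* (one rigid transform for the whole
    dimer).  For homodimers the chain pairing is ambiguous; the minimum over
    the two assignments is returned.
    """
    fa, fb = frame.peptides
    ra, rb = ref.peptides
    candidates = []
    if len(fa) == len(ra) and len(fb) == len(rb):
        candidates.append((fa, fb))
    if len(fa) == len(rb) and len(fb) == len(ra):
        candidates.append((fb, fa))
    if not candidates:
        raise ValueError(
            f"bead count mismatch: frame ({len(fa)}, {len(fb)}) vs "
            f"reference ({len(ra)}, {len(rb)})")
    best = np.inf
    refc = np.vstack([ra.coords, rb.coords])
    for p1, p2 in candidates:
        mob = np.vstack([p1.coords, p2.coords])
        _, _, rmsd = kabsch_superpose(mob, refc)
        best = min(best, rmsd)
    return best


def principal_axis(backbone: PeptideBackbone,
                   residue_range: tuple[int, int] | None = None) -> np.ndarray:
    """First principal axis (unit vector) of the backbone beads via SVD.

    Coordinates are centered and the first right-singular vector taken; the
    sign is fixed so the axis has positive projection on the first-to-last
    residue direction.
    """
    coords = (backbone.coords if residue_range is None
              else backbone.residue_slice(*residue_range))
    if len(coords) < 3:
        raise ValueError("need at least 3 beads for a principal axis")
    centered = coords - coords.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("zero spread: coincident beads have no principal axis")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    direction = coords[-1] - coords[0]
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def crossing_angle(
    frame: DimerFrame,
    ranges: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> float:
    """Crossing angle (degrees, in [0, 90]) between the two helix axes.

    ``arccos(|u . v|)`` of the first principal axes of the contact-helix
    residue ranges; the absolute value discards handedness, so parallel and
    antiparallel helices both give 0.
    """
    p1, p2 = frame.peptides
    r1, r2 = ranges if ranges is not None else (None, None)
    u = principal_axis(p1, r1)
    v = principal_axis(p2, r2)
    cosang = np.clip(abs(float(np.dot(u, v))), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _min_image_diff(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def interpeptide_contacts(frame: DimerFrame, cutoff: float = 0.8) -> int:
    """Number of backbone bead pairs (one per peptide) within ``cutoff`` nm.

    The boundary is closed (a pair at exactly the cut-off counts).  Distances
    use the minimum image when the frame carries a box; without a box the
    coordinates are taken as unwrapped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a, b = frame.peptides
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    if frame.box is None:
        span = np.concatenate([a.coords, b.coords])
        extent = span.max(axis=0) - span.min(axis=0)
        # no way to undo wrapping without a box; refuse if it looks wrapped
        if np.any(extent > 50.0):
            raise ValueError("coordinates look wrapped but the frame has no box")
    diff = _min_image_diff(diff, frame.box)
    d = np.linalg.norm(diff, axis=-1)
    return int(np.count_nonzero(d <= cutoff))


@dataclass
class DimerDeviationSummary:
    """Tail-window averages of the three dimer-quality metrics for one replica."""

    mean_rmsd: float
    std_rmsd: float
    mean_abs_dangle: float
    std_abs_dangle: float
    mean_dcontacts: float
    std_dcontacts: float
    n_frames: int


def dimer_deviation_summary(
    frames: Sequence[DimerFrame],
    ref: DimerReference,
    window_frac: float = 0.5,
) -> DimerDeviationSummary:
    """Per-replica metric averages over the trailing ``window_frac`` of frames.

    Per frame: joint-dimer backbone RMSD, ``|theta - theta_ref|`` of the
    crossing angle, and the *signed* contact-count deviation
    ``N_frame - N_ref``.  The default window uses the last half of the
    trajectory (e.g. the last 20 of 40 microseconds).
    """
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must lie in (0, 1]")
    n = len(frames)
    n_window = max(1, int(round(window_frac * n))) if n else 0
    window = frames[n - n_window:]
    if not window:
        raise ValueError("empty analysis window")
    rmsds, dangles, dcontacts = [], [], []
    for fr in window:
        rmsds.append(backbone_rmsd(fr, ref))
        theta = crossing_angle(fr, ref.helix_ranges)
        dangles.append(abs(theta - ref.crossing_angle))
        dcontacts.append(interpeptide_contacts(fr, ref.contact_cutoff) - ref.n_contacts)
    rmsds, dangles, dcontacts = map(np.asarray, (rmsds, dangles, dcontacts))
    return DimerDeviationSummary(
        mean_rmsd=float(rmsds.mean()), std_rmsd=float(rmsds.std()),
        mean_abs_dangle=float(dangles.mean()), std_abs_dangle=float(dangles.std()),
        mean_dcontacts=float(dcontacts.mean()), std_dcontacts=float(dcontacts.std()),
        n_frames=len(window),
    )


def replica_summary_table(
    replicas: Sequence[Sequence[DimerFrame]],
    ref: DimerReference,
    window_frac: float = 0.5,
):
    """Summaries for several replica trajectories plus the across-replica mean.

    Returns a pandas DataFrame with one row per replica and a final ``mean``
    row averaging the per-replica means.
    """
    import pandas as pd

    rows = []
    for i, frames in enumerate(replicas, start=1):
        s = dimer_deviation_summary(frames, ref, window_frac)
        rows.append({"replica": str(i), "mean_rmsd": s.mean_rmsd,
                     "std_rmsd": s.std_rmsd, "mean_abs_dangle": s.mean_abs_dangle,
                     "std_abs_dangle": s.std_abs_dangle,
                     "mean_dcontacts": s.mean_dcontacts,
                     "std_dcontacts": s.std_dcontacts, "n_frames": s.n_frames})
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns="replica").mean(numeric_only=True)
    mean_row["replica"] = "mean"
    return pd.concat([df, mean_row.to_frame().T], ignore_index=True)


def in_acceptable_region(
    summary: DimerDeviationSummary,
    rmsd_tol: float = 1.0,
    angle_tol: float = 10.0,
) -> bool:
    """Rule-of-thumb classifier: mean RMSD <= 1 nm and mean |dangle| <= 10 deg."""
    return summary.mean_rmsd <= rmsd_tol and summary.mean_abs_dangle <= angle_tol


def motif_align(frame: DimerFrame, ref: DimerReference) -> tuple[DimerFrame, float]:
    """Superpose the whole dimer on the dimerization motif of peptide 1.

    Used for visual comparison of the dimer interface: the rigid transform is
    fitted on the motif residues of peptide 1 only and applied to both
    peptides.  Returns the transformed frame and the motif RMSD (nm).
    """
    if ref.motif_range is None:
        raise ValueError("reference has no motif range")
    lo, hi = ref.motif_range
    mob = frame.peptides[0].residue_slice(lo, hi)
    tgt = ref.peptides[0].residue_slice(lo, hi)
    R, t, rmsd = kabsch_superpose(mob, tgt)
    new_peps = tuple(
        PeptideBackbone(coords=(R @ p.coords.T).T + t, resids=p.resids.copy(),
                        peptide_id=p.peptide_id)
        for p in frame.peptides
    )
    return DimerFrame(peptides=new_peps, box=frame.box, time=frame.time), rmsd
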