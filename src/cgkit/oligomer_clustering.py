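"""Oligomer-size statistics from single-linkage clustering of peptide COMs.

Peptides whose centre-of-mass distance (minimum image) is within a cut-off
(2.5 nm by default, where the COM-COM radial distribution function of
transmembrane peptides decays to zero) are joined into one cluster; cluster
sizes over the trajectory give the average oligomer size time series and the
size histogram over a trailing window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "ComTrajectory",
    "ClusterTimeSeries",
    "compute_peptide_coms",
    "single_linkage_clusters",
    "cluster_size_stats",
]


@dataclass
class ComTrajectory:
    """Per-frame peptide centre-of-mass coordinates (nm) with boxes and times."""

    coms: np.ndarray          # (n_frames, n_peptides, 3)
    boxes: np.ndarray         # (n_frames, 3)
    times: np.ndarray         # (n_frames,) ns

    def __post_init__(self):
        self.coms = np.asarray(self.coms, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coms.ndim != 3 or self.coms.shape[2] != 3:
            raise ValueError("coms must be (n_frames, n_peptides, 3)")
        if self.boxes.shape != (len(self.coms), 3) or np.any(self.boxes <= 0):
            raise ValueError("boxes must be (n_frames, 3) positive lengths")
        if self.times.shape != (len(self.coms),):
            raise ValueError("times length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.coms)

    @property
    def n_peptides(self) -> int:
        return self.coms.shape[1]


@dataclass
class ClusterTimeSeries:
    """Cluster labels per frame, mean-size series, and a windowed size histogram."""

    labels: np.ndarray        # (n_frames, n_peptides) int
    mean_size: np.ndarray     # (n_frames,)
    times: np.ndarray         # (n_frames,) ns
    hist_sizes: np.ndarray    # distinct cluster sizes in the window
    hist_freq: np.ndarray     # frequencies (sum to 1) over the window

    def __post_init__(self):
        n = self.labels.shape[1]
        for row in self.labels:
            sizes = np.bincount(row, minlength=0)
            if sizes.sum() != n:
                raise ValueError("labels do not partition the peptides")


def compute_peptide_coms(
    coords: np.ndarray,
    groups: Sequence[np.ndarray],
    masses: np.ndarray,
    box: np.ndarray,
) -> np.ndarray:
    """Mass-weighted peptide centres of mass with per-peptide unwrapping.

    Each peptide's beads are unwrapped by the minimum image relative to its
    first bead before averaging, so a peptide straddling the periodic
    boundary gets a physical COM; the result is wrapped back into the box.
    Valid whenever each peptide's diameter is below half the box.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    coms = np.empty((len(groups), 3))
    for gi, idx in enumerate(groups):
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"peptide group {gi} is empty")
        pts = coords[idx]
        m = masses[idx]
        anchor = pts[0]
        diff = pts - anchor
        diff -= box * np.round(diff / box)
        unwrapped = anchor + diff
        com = (m[:, None] * unwrapped).sum(axis=0) / m.sum()
        # double modulo: a tiny negative COM would otherwise wrap to exactly box
        coms[gi] = (com % box) % box
    return coms


def single_linkage_clusters(
    coms: np.ndarray,
    cutoff: float = 2.5,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Single-linkage cluster labels at the given COM-COM distance cut-off.

    Clusters are the connected components of the graph joining peptide pairs
    within ``cutoff`` nm (minimum image when a box is given, closed boundary).
    Labels are deterministic: every member carries the lowest peptide index
    of its cluster.
    """
    coms = np.asarray(coms, dtype=float)
    if coms.ndim != 2 or coms.shape[1] != 3 or len(coms) == 0:
        raise ValueError("coms must be a non-empty (n, 3) array")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coms[:, None, :] - coms[None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        diff -= box * np.round(diff / box)
    d = np.linalg.norm(diff, axis=-1)
    adj = csr_matrix(d <= cutoff)
    _, comp = connected_components(adj, directed=False)
    labels = np.empty(len(coms), dtype=int)
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        labels[members] = members.min()
    return labels


def cluster_size_stats(
    traj: ComTrajectory,
    cutoff: float = 2.5,
    hist_window_frac: float = 0.25,
    average: str = "number",
) -> ClusterTimeSeries:
    """Per-frame average oligomer size and a size histogram over the tail window.

    ``average='number'`` counts every cluster equally (total peptides divided
    by the number of clusters); ``'weight'`` weights clusters by their size
    (the alternative convention of GROMACS cluster-size tools).  The histogram
    pools per-cluster sizes over the last ``hist_window_frac`` of frames
    (default: last quarter, e.g. the last 10 of 40 microseconds) and is
    normalized to frequencies.
    """
    if average not in ("number", "weight"):
        raise ValueError("average must be 'number' or 'weight'")
    if not 0.0 < hist_window_frac <= 1.0:
        raise ValueError("hist_window_frac must lie in (0, 1]")
    n_frames, n = traj.n_frames, traj.n_peptides
    if n_frames == 0:
        raise ValueError("empty trajectory")
    labels = np.empty((n_frames, n), dtype=int)
    mean_size = np.empty(n_frames)
    all_sizes: list[np.ndarray] = []
    for i in range(n_frames):
        lab = single_linkage_clusters(traj.coms[i], cutoff=cutoff, box=traj.boxes[i])
        labels[i] = lab
        _, counts = np.unique(lab, return_counts=True)
        if average == "number":
            mean_size[i] = n / len(counts)
        else:
            mean_size[i] = (counts * counts).sum() / n
        all_sizes.append(counts)
    n_window = max(1, int(round(hist_window_frac * n_frames)))
    pooled = np.concatenate(all_sizes[n_frames - n_window:])
    sizes, freq = np.unique(pooled, return_counts=True)
    return ClusterTimeSeries(labels=labels, mean_size=mean_size, times=traj.times,
                             hist_sizes=sizes, hist_freq=freq / freq.sum())
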