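"""Weighted-histogram analysis of umbrella-sampling windows.

Each window carries scalar reaction-coordinate samples (peptide-peptide
centre-of-mass distance, nm) collected under a harmonic bias
``w_i(r) = k_i/2 (r - r0_i)^2``.  The self-consistent WHAM equations

    p(r_k) ∝ n_k / sum_i N_i exp(beta f_i) exp(-beta w_i(r_k))
    exp(-beta f_i) = sum_k exp(-beta w_i(r_k)) p(r_k)

are iterated to convergence on the per-window free-energy constants f_i, and
the potential of mean force is reported as G(r_k) = -RT ln p(r_k), defined
only on bins that received at least one sample and known only up to an
additive constant.  No radial (Jacobian) correction is applied: the
two-dimensional geometry of membrane dimerization enters later, through the
explicit ``pi * integral r exp(-G/RT) dr`` of the association constant.

Error bars come from a Bayesian bootstrap of complete histograms: each
replicate re-runs WHAM with the windows' histograms multiplied by random
exponential weights, which respects the strong autocorrelation of samples
within one window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cgkit.constants import GAS_CONSTANT_KJ

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "WhamError",
    "wham",
    "bootstrap_pmf",
    "shift_to_zero",
]


class WhamError(RuntimeError):
    """WHAM failure (empty histograms or non-convergence)."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias centre, spring constant, samples.

    ``center`` in nm, ``k`` in kJ mol^-1 nm^-2, ``samples`` in nm.  ``k = 0``
    denotes an unbiased window.
    """

    center: float
    k: float
    samples: np.ndarray
    sampling_interval: float = 1.0  # ps, bookkeeping only

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.k < 0:
            raise ValueError("spring constant must be >= 0")
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.any(self.samples < 0):
            raise ValueError("reaction-coordinate samples must be >= 0")

    def bias(self, r: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(r, dtype=float) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free-energy curve G(r) on a radial grid, with optional bootstrap spread.

    ``G`` is NaN on bins that received no samples (undefined, not infinite);
    downstream operations must handle those explicitly.
    """

    r: np.ndarray
    G: np.ndarray
    std: np.ndarray | None = None
    T: float = 303.0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)
            if self.std.shape != self.r.shape:
                raise ValueError("std shape mismatch")
            if np.any(self.std[np.isfinite(self.std)] < 0):
                raise ValueError("std must be >= 0")
        if self.r.shape != self.G.shape:
            raise ValueError("r and G shape mismatch")
        if len(self.r) > 1 and not np.all(np.diff(self.r) > 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.G)

    def interpolate(self, r_ref: float) -> float:
        """Linearly interpolated G at ``r_ref`` using the bracketing defined bins."""
        mask = self.defined
        r_def, g_def = self.r[mask], self.G[mask]
        if len(r_def) == 0 or not (r_def[0] <= r_ref <= r_def[-1]):
            raise ValueError(
                f"r_ref={r_ref} outside the defined region "
                f"[{r_def[0] if len(r_def) else np.nan}, "
                f"{r_def[-1] if len(r_def) else np.nan}]"
            )
        return float(np.interp(r_ref, r_def, g_def))


def _wham_core(
    hist: np.ndarray,
    n_eff: np.ndarray,
    bias_matrix: np.ndarray,
    rt: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Iterate the WHAM equations on pre-binned (possibly re-weighted) histograms.

    ``hist``: (n_windows, n_bins) counts; ``n_eff``: per-window totals;
    ``bias_matrix``: biases w_i(r_k) in kJ/mol.  Returns the unbiased bin
    probabilities (NaN where the pooled count is zero).
    """
    c = np.exp(-bias_matrix / rt)  # (n_win, n_bins)
    n_k = hist.sum(axis=0)
    sampled = n_k > 0
    if not np.any(sampled):
        raise WhamError("no samples fell into any bin")
    f = np.zeros(len(n_eff))  # free-energy constants, kJ/mol
    for _ in range(max_iter):
        denom = (n_eff * np.exp(f / rt)) @ c  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sampled, n_k / denom, 0.0)
        p = p / p.sum()
        f_new = -rt * np.log(c @ p)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f)) / rt
        f = f_new
        if delta < tol:
            break
    else:
        raise WhamError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {delta:.3e})",
            residual=float(delta),
        )
    denom = (n_eff * np.exp(f / rt)) @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sampled, n_k / denom, np.nan)
    p = p / np.nansum(p)
    return p


def wham(
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray | None = None,
    T: float = 303.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bin_width: float = 0.01,
) -> PMFProfile:
    """Self-consistent WHAM estimate of G(r) from umbrella windows.

    When ``bin_edges`` is omitted a uniform grid of width ``bin_width`` nm
    covering the pooled sampled range is used.  Convergence is declared when
    the largest change of any window free-energy constant drops below
    ``tol * RT``.  G is reported up to an additive constant and is NaN on
    empty bins.
    """
    if len(windows) == 0:
        raise ValueError("need at least one umbrella window")
    if T <= 0:
        raise ValueError("temperature must be positive")
    rt = GAS_CONSTANT_KJ * T
    all_samples = np.concatenate([w.samples for w in windows])
    if bin_edges is None:
        lo, hi = all_samples.min(), all_samples.max()
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        bin_edges = lo + bin_width * np.arange(n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 2 or not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin_edges must be an increasing grid")
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    hist = np.stack([np.histogram(w.samples, bins=bin_edges)[0] for w in windows])
    n_eff = hist.sum(axis=1).astype(float)
    bias_matrix = np.stack([w.bias(centers) for w in windows])
    p = _wham_core(hist, n_eff, bias_matrix, rt, tol, max_iter)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = -rt * np.log(p)
    G -= np.nanmin(G)
    return PMFProfile(r=centers, G=G, T=T)


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 100,
    seed: int | None = None,
    bin_edges: np.ndarray | None = None,
    T: float = 303.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, list[PMFProfile]]:
    """Bayesian bootstrap of complete histograms around :func:`wham`.

    Each replicate draws one exponential weight per window (mean 1), scales
    that window's histogram by it, and re-solves WHAM.  Replicates are
    shift-aligned to the full-data profile (least-squares constant offset on
    the commonly defined bins) before the per-bin standard deviation is taken,
    so the spread is invariant to the arbitrary PMF zero.  Replicates that
    fail to converge are excluded with a warning.

    Returns ``(per-bin std, list of aligned replicate profiles)``.
    """
    full = wham(windows, bin_edges=bin_edges, T=T, tol=tol, max_iter=max_iter,
                bin_width=bin_width)
    rt = GAS_CONSTANT_KJ * T
    if bin_edges is None:
        # rebuild the same grid wham used
        half = np.diff(full.r).mean() / 2 if len(full.r) > 1 else bin_width / 2
        bin_edges = np.concatenate([full.r - half, [full.r[-1] + half]])
    bin_edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    hist = np.stack([np.histogram(w.samples, bins=bin_edges)[0] for w in windows]).astype(float)
    bias_matrix = np.stack([w.bias(centers) for w in windows])

    rng = np.random.default_rng(seed)
    profiles: list[PMFProfile] = []
    n_failed = 0
    for _ in range(n_boot):
        weights = rng.exponential(size=len(windows))
        weights *= len(windows) / weights.sum()
        h = hist * weights[:, None]
        try:
            p = _wham_core(h, h.sum(axis=1), bias_matrix, rt, tol, max_iter)
        except WhamError:
            n_failed += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            G = -rt * np.log(p)
        common = np.isfinite(G) & full.defined
        if not np.any(common):
            n_failed += 1
            continue
        G -= np.mean(G[common] - full.G[common])
        profiles.append(PMFProfile(r=centers, G=G, T=T))
    if n_failed:
        warnings.warn(f"{n_failed} of {n_boot} bootstrap replicates failed to "
                      "converge and were excluded")
    if not profiles:
        raise WhamError("all bootstrap replicates failed")
    if len(profiles) == 1:
        std = np.zeros_like(full.G)  # single replicate: spread 0 by convention
    else:
        stack = np.stack([p.G for p in profiles])
        counts = np.sum(np.isfinite(stack), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            std = np.where(counts >= 2, np.nanstd(stack, axis=0, ddof=1), np.nan)
    std = np.where(full.defined, std, np.nan)
    return std, profiles


def shift_to_zero(profile: PMFProfile, r_ref: float = 2.75) -> PMFProfile:
    """Shift the profile so that the (interpolated) G at ``r_ref`` is exactly zero.

    The default reference of 2.75 nm sits on the flat tail of typical
    transmembrane-dimer PMFs.  Shifting is idempotent, and the bootstrap
    spread is unaffected by the shift convention.
    """
    offset = profile.interpolate(r_ref)
    return PMFProfile(r=profile.r.copy(), G=profile.G - offset,
                      std=None if profile.std is None else profile.std.copy(),
                      T=profile.T)
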