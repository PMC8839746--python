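"""Post-processing of biased-sampling (umbrella) data.

The unbinding free-energy analysis consumes per-window reaction
coordinate samples produced elsewhere (the pulling and umbrella
simulations themselves are out of scope) and provides:

* :func:`wham` — the self-consistent weighted-histogram estimator of the
  unbiased potential of mean force (PMF) along the coordinate,
* :func:`pmf_delta_g` — the binding free energy as the difference
  between the PMF minimum in the bound region and the plateau where the
  ligand has lost contact with the protein,
* :func:`count_hbonds` — geometric hydrogen-bond counting with the
  standard distance/angle criterion (donor–acceptor distance <= 0.35 nm
  and hydrogen–donor–acceptor angle <= 30 degrees by default).

WHAM solves the coupled equations

    p_j  =  ( sum_i n_ij ) / ( sum_i N_i exp[(f_i - w_i(x_j)) / kT] )
    f_i  =  -kT ln sum_j p_j exp[-w_i(x_j) / kT]

for the unbiased bin probabilities p_j and per-window offsets f_i, where
w_i(x) = k_i (x - x0_i)^2 / 2 is the harmonic bias, iterating from all
offsets zero until the largest offset change drops below tolerance.
The PMF is -kT ln p, shifted so its minimum over occupied bins is zero;
unoccupied bins are reported as NaN, never silently interpolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KB_KJ_MOL_K",
    "UmbrellaWindow",
    "PMFProfile",
    "HBondCriteria",
    "HBondFrame",
    "WhamError",
    "wham",
    "pmf_delta_g",
    "count_hbonds",
]

#: Molar gas constant in kJ mol^-1 K^-1.
KB_KJ_MOL_K = 8.31446261815324e-3


class WhamError(RuntimeError):
    pass


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased window: harmonic bias parameters plus its samples."""

    bias_center: float  # nm
    spring_constant: float  # kJ mol^-1 nm^-2
    temperature: float  # K
    samples: np.ndarray  # nm

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.spring_constant < 0:
            raise ValueError(f"spring constant must be >= 0, got {self.spring_constant}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if samples.size < 1:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("non-finite reaction-coordinate samples")

    def bias(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_constant * (np.asarray(xi) - self.bias_center) ** 2


@dataclass(frozen=True)
class PMFProfile:
    """PMF on an ordered grid of bin centres (kJ/mol; NaN where unsampled)."""

    grid: np.ndarray  # nm, strictly increasing bin centres
    free_energy: np.ndarray  # kJ/mol, min over occupied bins = 0
    counts: np.ndarray  # total samples per bin
    temperature: float  # K

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond cutoffs (nm, degrees)."""

    distance_cutoff: float = 0.35
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if not self.distance_cutoff > 0 or not self.angle_cutoff > 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


@dataclass(frozen=True)
class HBondFrame:
    """Donor (heavy atom + bonded hydrogen) and acceptor coordinates in nm."""

    donors: tuple[tuple[np.ndarray, np.ndarray], ...]
    acceptors: tuple[np.ndarray, ...]

    @classmethod
    def from_arrays(
        cls,
        donor_xyz: np.ndarray,
        hydrogen_xyz: np.ndarray,
        acceptor_xyz: np.ndarray,
    ) -> "HBondFrame":
        donor_xyz = np.atleast_2d(np.asarray(donor_xyz, dtype=float))
        hydrogen_xyz = np.atleast_2d(np.asarray(hydrogen_xyz, dtype=float))
        acceptor_xyz = np.atleast_2d(np.asarray(acceptor_xyz, dtype=float))
        if donor_xyz.shape != hydrogen_xyz.shape:
            raise ValueError("donor and hydrogen arrays must have matching shapes")
        for arr in (donor_xyz, hydrogen_xyz, acceptor_xyz):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite coordinates in hydrogen-bond frame")
        dh = np.linalg.norm(hydrogen_xyz - donor_xyz, axis=1)
        if np.any(dh >= 0.15):
            raise ValueError(
                "hydrogen not bonded to its donor (D-H distance >= 0.15 nm)"
            )
        donors = tuple((d, h) for d, h in zip(donor_xyz, hydrogen_xyz))
        acceptors = tuple(a for a in acceptor_xyz)
        return cls(donors=donors, acceptors=acceptors)


def count_hbonds(frame: HBondFrame, criteria: HBondCriteria | None = None) -> int:
    """Count donor–acceptor pairs satisfying the geometric criterion.

    A pair bonds when the donor–acceptor distance is <= the distance
    cutoff AND the hydrogen–donor–acceptor angle (vertex at the donor
    heavy atom, the convention of the MD tool the cutoffs come from) is
    <= the angle cutoff. Each (donor, acceptor) pair counts at most once.
    """
    criteria = criteria or HBondCriteria()
    if not frame.donors or not frame.acceptors:
        return 0
    donor_xyz = np.array([d for d, _ in frame.donors])
    hyd_xyz = np.array([h for _, h in frame.donors])
    acc_xyz = np.array(list(frame.acceptors))
    # pairwise donor->acceptor vectors, shape (n_donors, n_acceptors, 3)
    da = acc_xyz[None, :, :] - donor_xyz[:, None, :]
    da_dist = np.linalg.norm(da, axis=2)
    dh = hyd_xyz - donor_xyz
    dh_norm = np.linalg.norm(dh, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = np.einsum("ijk,ik->ij", da, dh) / (da_dist * dh_norm[:, None])
    cos_angle = np.clip(cos_angle, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_angle))
    # a donor sitting on top of an acceptor has an undefined angle; exclude
    ok = (da_dist <= criteria.distance_cutoff) & (da_dist > 0)
    ok &= angle <= criteria.angle_cutoff
    return int(np.count_nonzero(ok))


def _check_overlap(windows: Sequence[UmbrellaWindow], on_no_overlap: str) -> None:
    ordered = sorted(windows, key=lambda w: w.bias_center)
    for a, b in zip(ordered, ordered[1:]):
        if a.samples.max() < b.samples.min() or b.samples.max() < a.samples.min():
            msg = (
                f"no histogram overlap between windows at "
                f"{a.bias_center:g} and {b.bias_center:g} nm"
            )
            if on_no_overlap == "error":
                raise WhamError(msg)
            warnings.warn(msg, UserWarning, stacklevel=3)


def wham(
    windows: Sequence[UmbrellaWindow],
    bins: int | np.ndarray = 200,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    on_no_overlap: str = "warn",
) -> PMFProfile:
    """Weighted-histogram estimate of the PMF from umbrella windows.

    ``bins`` is either a bin count over the pooled sample range or an
    explicit strictly-increasing array of bin edges. ``tolerance`` is the
    convergence threshold (kJ/mol) on the largest change of any window
    offset between iterations.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one umbrella window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"all windows must share one temperature, got {sorted(temps)}")
    if on_no_overlap not in ("warn", "error"):
        raise ValueError("on_no_overlap must be 'warn' or 'error'")
    if len(windows) > 1:
        _check_overlap(windows, on_no_overlap)

    kt = KB_KJ_MOL_K * windows[0].temperature
    pooled = np.concatenate([w.samples for w in windows])
    if isinstance(bins, (int, np.integer)):
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:  # degenerate: all samples identical
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("explicit bins must be strictly increasing edges")
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_win = len(windows)
    n_bins = centers.size
    counts = np.empty((n_win, n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    n_samples = counts.sum(axis=1)  # samples landing inside the grid
    total_counts = counts.sum(axis=0)

    # Boltzmann factors of each window's bias on the grid
    log_bias = np.array([-(w.bias(centers)) / kt for w in windows])  # (n_win, n_bins)

    f = np.zeros(n_win)  # offsets in kJ/mol, deterministic start
    occupied = total_counts > 0
    log_total = np.where(occupied, np.log(np.maximum(total_counts, 1)), -np.inf)

    from scipy.special import logsumexp

    converged = False
    for _ in range(int(max_iterations)):
        # log denominator per bin: logsumexp over windows of
        # ln N_i + (f_i - w_i(x_j))/kT
        log_num = log_total
        log_den = logsumexp(
            (f / kt)[:, None] + log_bias + np.log(n_samples)[:, None], axis=0
        )
        log_p = np.where(occupied, log_num - log_den, -np.inf)
        f_new = -kt * logsumexp(log_bias + log_p[None, :], axis=1)
        f_new -= f_new[0]  # gauge: first window pinned at zero
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        raise WhamError(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(last offset change {delta:.3g} kJ/mol)"
        )

    with np.errstate(divide="ignore"):
        pmf = np.where(occupied, -kt * log_p, np.nan)
    pmf -= np.nanmin(pmf)
    return PMFProfile(
        grid=centers,
        free_energy=pmf,
        counts=total_counts.astype(int),
        temperature=windows[0].temperature,
    )


def pmf_delta_g(
    profile: PMFProfile,
    bound_region: tuple[float, float],
    plateau_region: tuple[float, float],
) -> float:
    """Binding free energy from a PMF, in kJ/mol.

    Delta G = min(PMF over the bound region) - mean(PMF over the plateau
    region); negative when the bound well lies below the dissociated
    plateau.
    """
    out = []
    for name, (lo, hi) in (("bound", bound_region), ("plateau", plateau_region)):
        if hi < lo:
            raise ValueError(f"{name} region reversed: ({lo}, {hi})")
        if hi < profile.grid[0] or lo > profile.grid[-1]:
            raise ValueError(f"{name} region lies outside the PMF grid")
        mask = (profile.grid >= lo) & (profile.grid <= hi) & profile.occupied
        if not np.any(mask):
            raise ValueError(f"{name} region contains no occupied bins")
        out.append(profile.free_energy[mask])
    bound_fe, plateau_fe = out
    return float(np.min(bound_fe) - np.mean(plateau_fe))
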