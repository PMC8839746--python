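"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its arguments (seed included): two
calls with identical arguments produce identical output. Per-generator random
streams are derived from (seed, generator name), so adding a generator
never perturbs another's output.

What the generators emulate, and the defaults they emulate it with:

* :func:`gen_reference_descriptors` — a known-drug reference set for
  calibrating the Gaussian drug-likeness indexes. Default moments are
  oral-drug-like: MW 350 +/- 100 Da, logP 2.5 +/- 1.5, 2 +/- 1.5
  donors, 5 +/- 2.5 acceptors, 5 +/- 3 rotatable bonds, PSA 80 +/- 30
  A^2.
* :func:`gen_screening_library` — a diversity library whose descriptors
  mix a druglike and a non-druglike component, with consensus docking
  scores driven by a latent per-compound affinity so the four scoring
  functions correlate configurably.
* :func:`gen_umbrella_windows` — exact draws from the biased Boltzmann
  density of a known 1-D potential (inverse-CDF on a fine grid), the
  statistically exact stand-in for umbrella-sampling output.
* :func:`gen_spr_curves` — Langmuir dose-response data with
  multiplicative Gaussian noise on an eight-point two-fold dilution
  series.
* :func:`gen_toy_structure` — tiny standard-conforming PDB fixtures with
  exactly specified coordinates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .md_analysis import KB_KJ_MOL_K, UmbrellaWindow
from .spr_fit import langmuir_response

__all__ = [
    "rng_for",
    "DEFAULT_REFERENCE_MOMENTS",
    "gen_reference_descriptors",
    "gen_screening_library",
    "gen_umbrella_windows",
    "gen_spr_curves",
    "gen_toy_structure",
    "ToyAtom",
]

#: Default known-drug descriptor moments (mean, sigma) per descriptor.
DEFAULT_REFERENCE_MOMENTS: dict[str, tuple[float, float]] = {
    "mw": (350.0, 100.0),
    "logp": (2.5, 1.5),
    "hd": (2.0, 1.5),
    "ha": (5.0, 2.5),
    "rb": (5.0, 3.0),
    "psa": (80.0, 30.0),
}


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible stream for one generator call."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def gen_reference_descriptors(
    n: int,
    seed: int,
    moments: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Known-drug-like reference table of six Gaussian descriptor columns."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    moments = moments or DEFAULT_REFERENCE_MOMENTS
    rng = rng_for(seed, "reference_descriptors")
    data = {"compound_id": [f"ref-{i:05d}" for i in range(n)]}
    for d, (mu, sigma) in moments.items():
        if not sigma > 0:
            raise ValueError(f"sigma for {d!r} must be positive")
        data[d] = rng.normal(mu, sigma, size=n)
    frame = pd.DataFrame(data)
    # counts and PSA cannot be negative; clip instead of resampling so the
    # draw count stays independent of the parameters
    for d in ("hd", "ha", "rb", "psa"):
        frame[d] = frame[d].clip(lower=0.0)
    frame["mw"] = frame["mw"].clip(lower=50.0)
    return frame


def gen_screening_library(
    n: int,
    seed: int,
    druglike_fraction: float = 0.5,
    score_correlation: float = 0.7,
    stage2_noise: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Screening library: descriptors plus two-stage consensus scores.

    Descriptors come from a two-component mixture (druglike component at
    the reference moments; a wider, shifted non-druglike component). A
    latent standard-normal "affinity" per compound drives all five
    scores through a linear-Gaussian model with correlation
    ``score_correlation`` between any two scoring functions; stage-2
    scores are the stage-1 scores plus independent Gaussian perturbation
    of spread ``stage2_noise`` (re-docking at higher search effort).
    Returns ``descriptors``, ``stage1``, ``stage2`` and ``truth`` (the
    latent affinities) tables.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= score_correlation <= 1:
        raise ValueError(f"score_correlation outside [0, 1]: {score_correlation}")
    rng = rng_for(seed, "screening_library")
    ids = [f"cmpd-{i:06d}" for i in range(n)]

    druglike = rng.random(n) < druglike_fraction
    desc = {"compound_id": ids}
    shift = {"mw": 150.0, "logp": 2.0, "hd": 2.0, "ha": 3.0, "rb": 4.0, "psa": 50.0}
    for d, (mu, sigma) in DEFAULT_REFERENCE_MOMENTS.items():
        base = rng.normal(mu, sigma, size=n)
        off = rng.normal(mu + shift[d], 2.0 * sigma, size=n)
        desc[d] = np.where(druglike, base, off)
    descriptors = pd.DataFrame(desc)
    for d in ("hd", "ha", "rb", "psa"):
        descriptors[d] = descriptors[d].clip(lower=0.0)
    descriptors["mw"] = descriptors["mw"].clip(lower=50.0)

    # latent affinity -> correlated scores: score_f = mu_f + sd_f * z_f,
    # z_f = sqrt(rho)*latent + sqrt(1-rho)*eps_f gives corr(z_f, z_g) = rho
    latent = rng.standard_normal(n)
    score_params = {  # rough scale of each scoring function
        "gs": (72.0, 8.0),
        "cs": (27.0, 4.0),
        "chemplp": (75.0, 10.0),
        "asp": (30.0, 5.0),
        "hb": (1.0, 0.8),
    }
    rho = score_correlation
    stage1 = {"compound_id": ids, "stage": 1}
    stage2 = {"compound_id": ids, "stage": 2}
    for f, (mu, sd) in score_params.items():
        z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        s1 = mu + sd * z
        stage1[f] = s1
        stage2[f] = s1 + rng.normal(0.0, stage2_noise, size=n)
    truth = pd.DataFrame({"compound_id": ids, "latent_affinity": latent})
    return {
        "descriptors": descriptors,
        "stage1": pd.DataFrame(stage1),
        "stage2": pd.DataFrame(stage2),
        "truth": truth,
    }


def gen_umbrella_windows(
    potential: Callable[[np.ndarray], np.ndarray],
    centers: Sequence[float],
    spring_constant: float,
    temperature: float,
    n_samples: int,
    seed: int,
    sample_range: tuple[float, float] | None = None,
    grid_points: int = 2**14,
) -> list[UmbrellaWindow]:
    """Exact biased-Boltzmann samples for each umbrella window.

    For window centre x0 the samples follow the density proportional to
    exp(-[U(x) + k (x - x0)^2 / 2] / kT), drawn by inverse-CDF on a
    ``grid_points`` grid with linear interpolation — exact up to grid
    resolution, with no equilibration or autocorrelation concerns.
    """
    if spring_constant < 0:
        raise ValueError("spring constant must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    centers = list(centers)
    if not centers:
        raise ValueError("need at least one window centre")
    kt = KB_KJ_MOL_K * temperature
    if sample_range is None:
        # cover all windows out to ~6 thermal widths of the stiffest bias,
        # or a generous fixed margin for weak/zero bias
        margin = 6.0 * np.sqrt(kt / spring_constant) if spring_constant > 0 else 1.0
        sample_range = (min(centers) - margin, max(centers) + margin)
    lo, hi = sample_range
    if not hi > lo:
        raise ValueError(f"empty sampling range: {sample_range}")
    grid = np.linspace(lo, hi, grid_points)
    u = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("potential is non-finite on the sampling range")

    rng = rng_for(seed, "umbrella_windows")
    windows = []
    for x0 in centers:
        energy = u + 0.5 * spring_constant * (grid - x0) ** 2
        log_w = -(energy - energy.min()) / kt
        weights = np.exp(log_w)
        total = np.trapezoid(weights, grid)
        if not total > 0:
            raise ValueError(f"biased density is non-integrable for centre {x0}")
        cdf = np.concatenate(
            ([0.0], np.cumsum(0.5 * (weights[1:] + weights[:-1]) * np.diff(grid)))
        )
        cdf /= cdf[-1]
        # strip flat stretches so interpolation stays well defined
        keep = np.concatenate(([True], np.diff(cdf) > 0))
        samples = np.interp(rng.random(n_samples), cdf[keep], grid[keep])
        windows.append(
            UmbrellaWindow(
                bias_center=float(x0),
                spring_constant=float(spring_constant),
                temperature=float(temperature),
                samples=samples,
            )
        )
    return windows


def gen_spr_curves(
    kd: float,
    rmax: float,
    seed: int,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.01,
    n_curves: int = 1,
    compound_id: str = "synthetic",
) -> list["BindingCurve"]:
    """Langmuir curves with multiplicative Gaussian noise.

    Default concentration series is the eight-point two-fold dilution
    from 6.25 to 500 uM used for fragment titrations. ``noise_sd`` is
    the relative (multiplicative) noise level.
    """
    from .spr_fit import BindingCurve

    if concentrations is None:
        # eight points spanning 6.25-500 uM: two-fold steps capped at 500
        concentrations = [6.25e-6 * 2**i for i in range(7)] + [500e-6]
    conc = np.asarray(sorted(concentrations), dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng_for(seed, "spr_curves")
    ideal = langmuir_response(conc, kd, rmax)
    curves = []
    for i in range(n_curves):
        noise = rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else 0.0
        responses = ideal * (1.0 + noise)
        curves.append(
            BindingCurve(
                concentrations=conc,
                responses=responses,
                compound_id=f"{compound_id}-{i}" if n_curves > 1 else compound_id,
            )
        )
    return curves


@dataclass(frozen=True)
class ToyAtom:
    """One atom of a synthetic PDB fixture."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    x: float
    y: float
    z: float
    element: str = ""
    het: bool = False


def gen_toy_structure(atoms: Sequence[ToyAtom], path: str | Path) -> Path:
    """Write a synthetic, standard-conforming PDB file from an atom layout.

    Coordinates are written at PDB precision (3 decimals); parsing the
    file back returns them exactly. Duplicate (chain, residue number,
    atom name) identifiers are rejected.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("layout has no atoms")
    seen = set()
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.atom_name)
        if key in seen:
            raise ValueError(f"duplicate atom identifier: {key}")
        seen.add(key)
    lines = []
    for serial, a in enumerate(atoms, start=1):
        record = "HETATM" if a.het else "ATOM  "
        element = (a.element or a.atom_name[0]).rjust(2)
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
        lines.append(
            f"{record}{serial:5d} {name:4.4s}{a.residue_name:>4.3s} "
            f"{a.chain_id:1.1s}{a.residue_number:4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:2.2s}"
        )
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
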