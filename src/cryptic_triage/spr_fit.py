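"""Steady-state SPR affinity analysis with the 1:1 binding model.

Equilibrium responses R(c) of an analyte titrated over an immobilized
protein follow the Langmuir isotherm

    R(c) = R_max * c / (K_D + c)

when binding is specific and 1:1. :func:`fit_kd` estimates (K_D, R_max)
by nonlinear least squares on the dose-response table (inputs are
assumed already solvent-corrected and reference-subtracted, as the
instrument software does). :func:`saturation_check` flags curves the
concentration series failed to saturate — a hallmark of very weak or
nonspecific binders — and :func:`stoichiometric_rmax` gives the
theoretical response ceiling from the immobilization level and the
analyte/ligand mass ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingCurve",
    "FitResult",
    "langmuir_response",
    "fit_kd",
    "saturation_check",
    "stoichiometric_rmax",
]


@dataclass(frozen=True)
class BindingCurve:
    """Paired analyte concentrations (M) and equilibrium responses (RU)."""

    concentrations: np.ndarray
    responses: np.ndarray
    compound_id: str = ""
    immobilized_ru: float | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if conc.size < 4:
            raise ValueError(f"need >= 4 concentration points, got {conc.size}")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(conc).size != conc.size:
            raise ValueError("duplicate concentrations in curve")
        if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(resp))):
            raise ValueError("non-finite values in binding curve")


@dataclass(frozen=True)
class FitResult:
    kd: float
    rmax: float
    rss: float
    saturating: bool
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def langmuir_response(
    c: float | np.ndarray, kd: float, rmax: float
) -> float | np.ndarray:
    """1:1 equilibrium response R = rmax * c / (kd + c)."""
    if not kd > 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if not rmax > 0:
        raise ValueError(f"rmax must be positive, got {rmax}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = rmax * c / (kd + c)
    return float(out) if out.ndim == 0 else out


def fit_kd(
    curve: BindingCurve,
    saturation_kd_factor: float = 2.0,
    saturation_response_fraction: float = 0.5,
) -> FitResult:
    """Least-squares (K_D, R_max) estimate from one dose-response curve.

    Initialization is deterministic: R_max starts at 1.1x the largest
    observed response and K_D at the concentration whose response is
    nearest half of that, which behaves well for both saturating and
    weak binders. Both parameters are constrained positive via fitting
    in log space.
    """
    conc = curve.concentrations
    resp = curve.responses
    if np.all(resp == 0):
        raise ValueError("responses are all zero; nothing to fit")
    if resp.mean() < 0:
        raise ValueError("mean response is negative; curve looks like buffer noise")

    rmax0 = 1.1 * float(resp.max())
    if rmax0 <= 0:
        raise ValueError("maximum response is non-positive")
    kd0 = float(conc[np.argmin(np.abs(resp - 0.5 * rmax0))])

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, rmax = np.exp(theta)
        return rmax * conc / (kd + conc) - resp

    sol = least_squares(
        residuals,
        x0=np.log([kd0, rmax0]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    kd, rmax = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))
    result = FitResult(
        kd=float(kd),
        rmax=float(rmax),
        rss=rss,
        saturating=False,
        converged=bool(sol.success),
    )
    if not sol.success:
        raise RuntimeError(f"fit did not converge: {sol.message}")
    return saturation_check(
        curve,
        result,
        kd_factor=saturation_kd_factor,
        response_fraction=saturation_response_fraction,
    )


def saturation_check(
    curve: BindingCurve,
    fit: FitResult,
    kd_factor: float = 2.0,
    response_fraction: float = 0.5,
) -> FitResult:
    """Apply the non-saturation rule and attach diagnostics.

    A curve is flagged non-saturating when the fitted K_D exceeds
    ``kd_factor`` times the largest tested concentration (boundary
    included) OR the largest observed response is below
    ``response_fraction`` of the fitted R_max. Non-saturating behaviour
    indicates a very weak interaction or nonspecific binding at the high
    concentrations weak binders require.
    """
    c_max = float(curve.concentrations.max())
    r_max_obs = float(curve.responses.max())
    kd_ratio = fit.kd / c_max
    response_ratio = r_max_obs / fit.rmax
    non_saturating = (kd_ratio >= kd_factor) or (response_ratio < response_fraction)
    diagnostics = {
        "kd_over_cmax": kd_ratio,
        "max_response_over_rmax": response_ratio,
        "kd_factor": kd_factor,
        "response_fraction": response_fraction,
    }
    return FitResult(
        kd=fit.kd,
        rmax=fit.rmax,
        rss=fit.rss,
        saturating=not non_saturating,
        converged=fit.converged,
        diagnostics=diagnostics,
    )


def stoichiometric_rmax(
    immobilized: float,
    analyte_mw: float,
    ligand_mw: float,
    stoichiometry: float = 1.0,
) -> float:
    """Theoretical R_max = immobilized RU x (analyte MW / ligand MW) x n.

    ``ligand`` here is SPR parlance for the immobilized binding partner.
    """
    for name, v in (
        ("immobilized", immobilized),
        ("analyte_mw", analyte_mw),
        ("ligand_mw", ligand_mw),
        ("stoichiometry", stoichiometry),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return immobilized * (analyte_mw / ligand_mw) * stoichiometry
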