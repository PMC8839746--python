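"""Known Drug Index (KDI) drug-likeness scoring and filtering.

Six physicochemical descriptors — molecular weight (MW, Da), logP,
hydrogen-bond donor count (HD), hydrogen-bond acceptor count (HA),
rotatable-bond count (RB) and polar surface area (PSA, A^2) — are each
mapped through a unit-amplitude Gaussian centred on the corresponding
distribution of drugs in clinical use:

    I_d = exp(-(x_d - mu_d)^2 / (2 sigma_d^2))          in (0, 1]

The additive index KDI_2a is the sum of the six (theoretical maximum 6),
and the multiplicative index KDI_2b their product (theoretical maximum
1). A compound library is triaged by keeping compounds whose indexes
reach configurable thresholds; the published screening campaign used
5.66 for KDI_2a and 0.70 for KDI_2b.

Gaussian parameters are calibrated from a user-supplied reference table
of known drugs via sample moments (mean and n-1 standard deviation per
descriptor), which for Gaussian data coincide with a least-squares
histogram fit while requiring no binning choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DESCRIPTORS",
    "DescriptorRecord",
    "GaussianIndexParams",
    "KDIResult",
    "KDI2A_THRESHOLD",
    "KDI2B_THRESHOLD",
    "fit_index_params",
    "descriptor_index",
    "kdi_scores",
    "score_table",
    "kdi_filter",
]

DESCRIPTORS = ("mw", "logp", "hd", "ha", "rb", "psa")

#: Published screening thresholds for the additive and multiplicative index.
KDI2A_THRESHOLD = 5.66
KDI2B_THRESHOLD = 0.70

FilterMode = Literal["both", "either", "2a-only", "2b-only"]
_MODES = ("both", "either", "2a-only", "2b-only")


@dataclass(frozen=True)
class DescriptorRecord:
    compound_id: str
    mw: float
    logp: float
    hd: float
    ha: float
    rb: float
    psa: float

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"{self.compound_id}: mw must be positive")
        for name in ("hd", "ha", "rb", "psa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.compound_id}: {name} must be >= 0")


@dataclass(frozen=True)
class GaussianIndexParams:
    """Per-descriptor Gaussian centre and spread."""

    mean: Mapping[str, float]
    sigma: Mapping[str, float]

    def __post_init__(self) -> None:
        for d in DESCRIPTORS:
            if d not in self.mean or d not in self.sigma:
                raise ValueError(f"missing parameters for descriptor {d!r}")
            if not self.sigma[d] > 0:
                raise ValueError(f"sigma for {d!r} must be positive")

    def to_dict(self) -> dict:
        return {d: {"mean": self.mean[d], "sigma": self.sigma[d]} for d in DESCRIPTORS}

    @classmethod
    def from_dict(cls, payload: Mapping[str, Mapping[str, float]]) -> "GaussianIndexParams":
        return cls(
            mean={d: float(payload[d]["mean"]) for d in DESCRIPTORS},
            sigma={d: float(payload[d]["sigma"]) for d in DESCRIPTORS},
        )


@dataclass(frozen=True)
class KDIResult:
    compound_id: str
    indexes: Mapping[str, float]
    kdi2a: float
    kdi2b: float


def _as_frame(records: Iterable[DescriptorRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in ("compound_id", *DESCRIPTORS) if c not in records.columns]
        if missing:
            raise ValueError(f"descriptor table missing columns: {missing}")
        return records
    rows = [
        {"compound_id": r.compound_id, **{d: getattr(r, d) for d in DESCRIPTORS}}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["compound_id", *DESCRIPTORS])


def fit_index_params(
    reference: Iterable[DescriptorRecord] | pd.DataFrame,
) -> GaussianIndexParams:
    """Calibrate Gaussian index parameters from a known-drug reference set.

    Requires at least three records and non-degenerate spread in every
    descriptor.
    """
    frame = _as_frame(reference)
    if len(frame) < 3:
        raise ValueError(f"need >= 3 reference records, got {len(frame)}")
    mean: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for d in DESCRIPTORS:
        col = frame[d].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"non-finite values in descriptor {d!r}")
        s = float(np.std(col, ddof=1))
        if s == 0.0:
            raise ValueError(f"descriptor {d!r} has zero variance in the reference set")
        mean[d] = float(np.mean(col))
        sigma[d] = s
    return GaussianIndexParams(mean=mean, sigma=sigma)


def descriptor_index(x: float, mu: float, sigma: float) -> float:
    """Unit-amplitude Gaussian index of one descriptor value."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    z = (x - mu) / sigma
    return math.exp(-0.5 * z * z)


def kdi_scores(record: DescriptorRecord, params: GaussianIndexParams) -> KDIResult:
    """Both Known Drug Indexes for one compound."""
    indexes = {
        d: descriptor_index(getattr(record, d), params.mean[d], params.sigma[d])
        for d in DESCRIPTORS
    }
    kdi2a = sum(indexes.values())
    kdi2b = math.prod(indexes.values())
    return KDIResult(record.compound_id, indexes, kdi2a, kdi2b)


def score_table(table: pd.DataFrame, params: GaussianIndexParams) -> pd.DataFrame:
    """Vectorized KDI scoring of a descriptor table.

    Returns the input columns plus one ``i_<descriptor>`` column per
    index and ``kdi2a`` / ``kdi2b`` totals, preserving row order.
    """
    frame = _as_frame(table).copy()
    index_cols = []
    for d in DESCRIPTORS:
        z = (frame[d].to_numpy(dtype=float) - params.mean[d]) / params.sigma[d]
        frame[f"i_{d}"] = np.exp(-0.5 * z * z)
        index_cols.append(f"i_{d}")
    frame["kdi2a"] = frame[index_cols].sum(axis=1)
    frame["kdi2b"] = frame[index_cols].prod(axis=1)
    return frame


def kdi_filter(
    table: pd.DataFrame,
    params: GaussianIndexParams,
    threshold_2a: float = KDI2A_THRESHOLD,
    threshold_2b: float = KDI2B_THRESHOLD,
    mode: FilterMode = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a descriptor table on the two Known Drug Indexes.

    A compound is retained when its score(s) are >= the threshold(s)
    under the chosen combination mode (``both`` = logical AND, the
    default; ``either`` = OR; or a single-index mode). Returns
    ``(retained, report)`` where the report scores every input compound
    and carries a boolean ``retained`` flag; input order is preserved in
    both.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    if not 0 <= threshold_2a <= 6:
        raise ValueError(f"threshold_2a outside [0, 6]: {threshold_2a}")
    if not 0 <= threshold_2b <= 1:
        raise ValueError(f"threshold_2b outside [0, 1]: {threshold_2b}")
    report = score_table(table, params)
    pass_2a = report["kdi2a"] >= threshold_2a
    pass_2b = report["kdi2b"] >= threshold_2b
    if mode == "both":
        keep = pass_2a & pass_2b
    elif mode == "either":
        keep = pass_2a | pass_2b
    elif mode == "2a-only":
        keep = pass_2a
    else:
        keep = pass_2b
    report = report.copy()
    report["retained"] = keep
    retained = table.loc[keep.to_numpy()].copy()
    return retained, report
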