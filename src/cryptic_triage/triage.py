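"""Two-stage consensus docking-score triage cascade.

A docked library carries, per compound and per stage, the four scoring
functions of the consensus protocol — GoldScore (GS), ChemScore (CS),
piecewise-linear potential (ChemPLP) and the Astex statistical potential
(ASP) — plus the hydrogen-bond component (HB) used as a floor criterion.
A compound survives a stage iff every score is at or above that stage's
minimum; any single low score eliminates it. Stage 2 re-scores only
stage-1 survivors at higher search effort, with stricter minima.

Scores are inputs produced by the docking engine; this module owns only
the elimination logic and its bookkeeping (per-compound elimination
reasons, survivor lists, counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SCORE_COLUMNS",
    "StageMinima",
    "CascadeConfig",
    "TriageReport",
    "apply_stage_filter",
    "run_cascade",
    "alert_filter",
]

SCORE_COLUMNS = ("gs", "cs", "chemplp", "asp", "hb")


@dataclass(frozen=True)
class StageMinima:
    """Per-scoring-function floor values for one cascade stage."""

    gs: float
    cs: float
    chemplp: float
    asp: float
    hb: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in SCORE_COLUMNS}


#: Published stage minima: stage 1 eliminates CS < 25, GS < 70,
#: ChemPLP < 70, ASP < 27, HB < 0.2; stage 2 eliminates CS < 30,
#: GS < 75, ChemPLP < 80, ASP < 33, HB < 1.0.
STAGE1_DEFAULT = StageMinima(gs=70.0, cs=25.0, chemplp=70.0, asp=27.0, hb=0.2)
STAGE2_DEFAULT = StageMinima(gs=75.0, cs=30.0, chemplp=80.0, asp=33.0, hb=1.0)


@dataclass(frozen=True)
class CascadeConfig:
    stage1: StageMinima = STAGE1_DEFAULT
    stage2: StageMinima = STAGE2_DEFAULT

    def __post_init__(self) -> None:
        self.check_monotone()

    def check_monotone(self) -> list[str]:
        """Names of scores whose stage-2 minimum is below stage 1 (warn-worthy)."""
        weak = [
            c
            for c in SCORE_COLUMNS
            if getattr(self.stage2, c) < getattr(self.stage1, c)
        ]
        if weak:
            import warnings

            warnings.warn(
                f"stage-2 minima below stage-1 for: {', '.join(weak)}",
                UserWarning,
                stacklevel=2,
            )
        return weak

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CascadeConfig":
        return cls(
            stage1=StageMinima(**payload["stage1"]),
            stage2=StageMinima(**payload["stage2"]),
        )


@dataclass
class TriageReport:
    """Counts, survivor id lists and elimination reasons for a cascade run."""

    input_count: int
    stage1_survivors: list[str]
    stage2_survivors: list[str]
    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def stage1_count(self) -> int:
        return len(self.stage1_survivors)

    @property
    def stage2_count(self) -> int:
        return len(self.stage2_survivors)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "stage1": {"count": self.stage1_count, "survivors": self.stage1_survivors},
                "stage2": {"count": self.stage2_count, "survivors": self.stage2_survivors},
                "reasons": self.reasons,
            },
            **kwargs,
        )


def _validate_scores(records: pd.DataFrame) -> None:
    missing = [c for c in ("compound_id", *SCORE_COLUMNS) if c not in records.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    score_block = records[list(SCORE_COLUMNS)]
    if score_block.isna().any().any():
        bad = records.loc[score_block.isna().any(axis=1), "compound_id"].tolist()
        raise ValueError(f"missing scores for compounds: {bad[:5]}")
    import numpy as np

    if not np.isfinite(score_block.to_numpy(dtype=float)).all():
        raise ValueError("non-finite docking scores in table")


def apply_stage_filter(
    records: pd.DataFrame, minima: StageMinima
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One elimination pass over a score table.

    Returns ``(survivors, reasons)``: the order-preserved sub-table of
    compounds whose five scores all satisfy ``score >= minimum``
    (boundary values survive — the published filter eliminates strictly
    below-threshold scores), and, for each eliminated compound, the full
    list of scores that fell short.
    """
    _validate_scores(records)
    fails = {
        c: records[c].to_numpy(dtype=float) < getattr(minima, c) for c in SCORE_COLUMNS
    }
    any_fail = pd.DataFrame(fails).any(axis=1).to_numpy()
    reasons: dict[str, list[str]] = {}
    for i, eliminated in enumerate(any_fail):
        if eliminated:
            cid = str(records.iloc[i]["compound_id"])
            reasons[cid] = [c for c in SCORE_COLUMNS if fails[c][i]]
    survivors = records.loc[~any_fail].copy()
    return survivors, reasons


def run_cascade(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame,
    config: CascadeConfig | None = None,
) -> TriageReport:
    """Run the full two-stage cascade.

    ``stage2`` must contain only stage-1 survivors (the second docking
    pass is run on survivors alone); an unexpected id is an error, a
    survivor missing from stage 2 simply drops out.
    """
    config = config or CascadeConfig()
    s1_survivors, s1_reasons = apply_stage_filter(stage1, config.stage1)
    s1_ids = s1_survivors["compound_id"].astype(str).tolist()
    _validate_scores(stage2)
    stray = set(stage2["compound_id"].astype(str)) - set(s1_ids)
    if stray:
        raise ValueError(
            f"stage-2 table contains ids that did not survive stage 1: {sorted(stray)[:5]}"
        )
    s2_survivors, s2_reasons = apply_stage_filter(stage2, config.stage2)
    s2_ids = s2_survivors["compound_id"].astype(str).tolist()
    reasons = {cid: [f"stage1:{c}" for c in crit] for cid, crit in s1_reasons.items()}
    for cid, crit in s2_reasons.items():
        reasons.setdefault(cid, []).extend(f"stage2:{c}" for c in crit)
    return TriageReport(
        input_count=len(stage1),
        stage1_survivors=s1_ids,
        stage2_survivors=s2_ids,
        reasons=reasons,
    )


def alert_filter(
    compounds: pd.DataFrame,
    patterns: Sequence[str] = (),
    smiles_column: str = "smiles",
) -> pd.DataFrame:
    """Flag compounds matching structural-alert SMARTS patterns.

    ``compounds`` needs ``compound_id`` and a structure-string column
    (SMILES). Returns one row per compound with the list of matched
    pattern strings; an empty pattern list (the default — the published
    alert list is not distributed) flags nothing. Substructure matching
    is delegated to RDKit.
    """
    from rdkit import Chem

    if smiles_column not in compounds.columns:
        raise ValueError(f"no {smiles_column!r} column in compound table")
    compiled = []
    for p in patterns:
        q = Chem.MolFromSmarts(p)
        if q is None:
            raise ValueError(f"invalid SMARTS pattern: {p!r}")
        compiled.append((p, q))
    rows = []
    for _, rec in compounds.iterrows():
        mol = Chem.MolFromSmiles(str(rec[smiles_column]))
        if mol is None:
            raise ValueError(
                f"unparseable structure for {rec['compound_id']}: {rec[smiles_column]!r}"
            )
        hits = [p for p, q in compiled if mol.HasSubstructMatch(q)]
        rows.append(
            {"compound_id": rec["compound_id"], "alerts": hits, "flagged": bool(hits)}
        )
    return pd.DataFrame(rows, columns=["compound_id", "alerts", "flagged"])
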