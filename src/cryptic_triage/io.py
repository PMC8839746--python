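"""CSV/JSON/YAML readers and writers for the pipeline's table formats.

Formats:

* descriptor tables: ``compound_id,mw,logp,hd,ha,rb,psa``
* docking score tables: ``compound_id,stage,gs,cs,chemplp,asp,hb``
* Gaussian index parameter files: YAML/JSON mapping descriptor ->
  {mean, sigma}
* umbrella window manifests: ``window_id,bias_center,spring_constant,
  temperature,path`` with one single-column ``xi`` CSV per window
* SPR curve tables: ``compound_id,concentration_m,response_ru``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .kdi import DESCRIPTORS, GaussianIndexParams
from .md_analysis import PMFProfile, UmbrellaWindow
from .spr_fit import BindingCurve
from .triage import SCORE_COLUMNS

__all__ = [
    "read_descriptor_table",
    "read_score_table",
    "read_index_params",
    "write_index_params",
    "read_window_manifest",
    "write_windows",
    "write_pmf_profile",
    "read_pmf_profile",
    "read_binding_curves",
]


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("compound_id", *DESCRIPTORS) if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: descriptor table missing columns {missing}")
    return frame


def read_score_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("compound_id", *SCORE_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: score table missing columns {missing}")
    return frame


def read_index_params(path: str | Path) -> GaussianIndexParams:
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    return GaussianIndexParams.from_dict(payload)


def write_index_params(params: GaussianIndexParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


def read_window_manifest(path: str | Path) -> list[UmbrellaWindow]:
    path = Path(path)
    manifest = pd.read_csv(path)
    required = ["bias_center", "spring_constant", "temperature", "path"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ValueError(f"{path}: window manifest missing columns {missing}")
    windows = []
    for _, row in manifest.iterrows():
        sample_path = Path(row["path"])
        if not sample_path.is_absolute():
            sample_path = path.parent / sample_path
        samples = pd.read_csv(sample_path)["xi"].to_numpy(dtype=float)
        windows.append(
            UmbrellaWindow(
                bias_center=float(row["bias_center"]),
                spring_constant=float(row["spring_constant"]),
                temperature=float(row["temperature"]),
                samples=samples,
            )
        )
    return windows


def write_windows(
    windows: Sequence[UmbrellaWindow], directory: str | Path
) -> Path:
    """Write per-window sample CSVs plus the manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        name = f"window_{i:03d}.csv"
        pd.DataFrame({"xi": w.samples}).to_csv(directory / name, index=False)
        rows.append(
            {
                "window_id": i,
                "bias_center": w.bias_center,
                "spring_constant": w.spring_constant,
                "temperature": w.temperature,
                "path": name,
            }
        )
    manifest = directory / "windows.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_pmf_profile(profile: PMFProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "xi": profile.grid,
            "free_energy_kj_mol": profile.free_energy,
            "count": profile.counts,
        }
    ).to_csv(path, index=False)


def read_pmf_profile(path: str | Path, temperature: float = 298.0) -> PMFProfile:
    frame = pd.read_csv(path)
    return PMFProfile(
        grid=frame["xi"].to_numpy(dtype=float),
        free_energy=frame["free_energy_kj_mol"].to_numpy(dtype=float),
        counts=frame["count"].to_numpy(dtype=int),
        temperature=temperature,
    )


def read_binding_curves(path: str | Path) -> list[BindingCurve]:
    frame = pd.read_csv(path)
    required = ["compound_id", "concentration_m", "response_ru"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: SPR table missing columns {missing}")
    curves = []
    for cid, group in frame.groupby("compound_id", sort=False):
        curves.append(
            BindingCurve(
                concentrations=group["concentration_m"].to_numpy(dtype=float),
                responses=group["response_ru"].to_numpy(dtype=float),
                compound_id=str(cid),
            )
        )
    return curves
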