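"""End-to-end orchestration: descriptors -> KDI filter -> docking cascade.

One configured run executes the stages in order, materializes every
stage's output before the next begins (so any stage can be re-run or
audited in isolation — the cascade discards the vast majority of its
input), and writes a manifest with per-stage counts and a config hash
for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ctio
from .kdi import KDI2A_THRESHOLD, KDI2B_THRESHOLD, fit_index_params, kdi_filter
from .triage import CascadeConfig, run_cascade

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("cryptic_triage.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    library_csv: str
    stage1_csv: str
    stage2_csv: str
    output_dir: str
    reference_csv: str | None = None
    params_file: str | None = None
    threshold_2a: float = KDI2A_THRESHOLD
    threshold_2b: float = KDI2B_THRESHOLD
    kdi_mode: str = "both"
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_csv is None and self.params_file is None:
            raise ValueError("config needs either reference_csv or params_file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cascade = payload.pop("cascade", None)
        if cascade is not None:
            payload["cascade"] = CascadeConfig.from_dict(cascade)
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "library_csv": self.library_csv,
            "stage1_csv": self.stage1_csv,
            "stage2_csv": self.stage2_csv,
            "output_dir": self.output_dir,
            "reference_csv": self.reference_csv,
            "params_file": self.params_file,
            "threshold_2a": self.threshold_2a,
            "threshold_2b": self.threshold_2b,
            "kdi_mode": self.kdi_mode,
            "cascade": {
                "stage1": self.cascade.stage1.as_dict(),
                "stage2": self.cascade.stage2.as_dict(),
            },
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    counts: dict[str, int]
    outputs: dict[str, str]
    warnings: list[str] = field(default_factory=list)
    elapsed_s: float = 0.0

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "counts": self.counts,
                "outputs": self.outputs,
                "warnings": self.warnings,
                "elapsed_s": self.elapsed_s,
            },
            **kwargs,
        )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute KDI filter -> stage-1 filter -> stage-2 filter -> report."""
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    warnings_seen: list[str] = []

    stage = "kdi"
    try:
        library = ctio.read_descriptor_table(config.library_csv)
        if config.params_file is not None:
            params = ctio.read_index_params(config.params_file)
        else:
            params = fit_index_params(ctio.read_descriptor_table(config.reference_csv))
        retained, report = kdi_filter(
            library,
            params,
            threshold_2a=config.threshold_2a,
            threshold_2b=config.threshold_2b,
            mode=config.kdi_mode,
        )
        ctio.write_index_params(params, out / "kdi_params.yaml")
        report.to_csv(out / "kdi_report.csv", index=False)
        retained.to_csv(out / "kdi_retained.csv", index=False)
        log.info("stage=kdi in=%d out=%d", len(library), len(retained))

        stage = "cascade"
        kept_ids = set(retained["compound_id"].astype(str))
        stage1 = ctio.read_score_table(config.stage1_csv)
        stage1 = stage1[stage1["compound_id"].astype(str).isin(kept_ids)]
        stage2 = ctio.read_score_table(config.stage2_csv)
        # the stage-2 docking pass is run only on stage-1 survivors;
        # pre-restricting here mirrors that
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            from .triage import apply_stage_filter

            s1_survivors, _ = apply_stage_filter(stage1, config.cascade.stage1)
            s1_ids = set(s1_survivors["compound_id"].astype(str))
            stage2 = stage2[stage2["compound_id"].astype(str).isin(s1_ids)]
            triage_report = run_cascade(stage1, stage2, config.cascade)
        warnings_seen.extend(str(w.message) for w in caught)

        stage1.to_csv(out / "cascade_stage1_input.csv", index=False)
        s1_survivors.to_csv(out / "cascade_stage1_survivors.csv", index=False)
        survivors2 = stage2[
            stage2["compound_id"].astype(str).isin(set(triage_report.stage2_survivors))
        ]
        survivors2.to_csv(out / "cascade_stage2_survivors.csv", index=False)
        (out / "triage_report.json").write_text(triage_report.to_json(indent=2))
        log.info(
            "stage=cascade in=%d s1=%d s2=%d",
            len(stage1),
            triage_report.stage1_count,
            triage_report.stage2_count,
        )
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if failed_marker.exists():
        failed_marker.unlink()
    counts = {
        "library": len(library),
        "kdi_retained": len(retained),
        "stage1_survivors": triage_report.stage1_count,
        "stage2_survivors": triage_report.stage2_count,
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        counts=counts,
        outputs={
            "kdi_report": str(out / "kdi_report.csv"),
            "kdi_retained": str(out / "kdi_retained.csv"),
            "stage1_survivors": str(out / "cascade_stage1_survivors.csv"),
            "stage2_survivors": str(out / "cascade_stage2_survivors.csv"),
            "triage_report": str(out / "triage_report.json"),
        },
        warnings=warnings_seen,
        elapsed_s=time.monotonic() - t0,
    )
    (out / "manifest.json").write_text(manifest.to_json(indent=2))
    return manifest
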