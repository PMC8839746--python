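"""Consensus docking-score cascade: elimination logic and bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from cryptic_triage import synth
from cryptic_triage.triage import (
    SCORE_COLUMNS,
    STAGE1_DEFAULT,
    STAGE2_DEFAULT,
    CascadeConfig,
    StageMinima,
    alert_filter,
    apply_stage_filter,
    run_cascade,
)


def _row(cid="x", stage=1, gs=80.0, cs=30.0, chemplp=85.0, asp=35.0, hb=1.5):
    return {"compound_id": cid, "stage": stage, "gs": gs, "cs": cs,
            "chemplp": chemplp, "asp": asp, "hb": hb}


class TestApplyStageFilter:
    def test_published_fragment_scores_survive_both_stages(self):
        # the original fragment's consensus scores with an HB fixture of 1.0
        scores = _row("fragment-1", gs=75.5, cs=30.7, chemplp=84.9, asp=34.2, hb=1.0)
        table = pd.DataFrame([scores])
        for minima in (STAGE1_DEFAULT, STAGE2_DEFAULT):
            survivors, reasons = apply_stage_filter(table, minima)
            assert list(survivors["compound_id"]) == ["fragment-1"]
            assert reasons == {}

    def test_single_low_score_eliminates(self):
        table = pd.DataFrame([_row("weak", cs=24.9, gs=99, chemplp=99, asp=99, hb=9)])
        survivors, reasons = apply_stage_filter(table, STAGE1_DEFAULT)
        assert len(survivors) == 0
        assert reasons == {"weak": ["cs"]}

    def test_boundary_scores_survive(self):
        table = pd.DataFrame(
            [_row("edge", gs=70.0, cs=25.0, chemplp=70.0, asp=27.0, hb=0.2)]
        )
        survivors, _ = apply_stage_filter(table, STAGE1_DEFAULT)
        assert len(survivors) == 1

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["compound_id", "stage", *SCORE_COLUMNS])
        survivors, reasons = apply_stage_filter(empty, STAGE1_DEFAULT)
        assert len(survivors) == 0 and reasons == {}

    def test_missing_score_column(self):
        with pytest.raises(ValueError, match="missing columns"):
            apply_stage_filter(pd.DataFrame({"compound_id": ["a"]}), STAGE1_DEFAULT)

    def test_non_finite_score(self):
        row = _row("nan-hb")
        row["hb"] = np.nan
        with pytest.raises(ValueError, match="missing scores"):
            apply_stage_filter(pd.DataFrame([row]), STAGE1_DEFAULT)

    def test_matches_brute_force_oracle(self):
        tables = synth.gen_screening_library(1000, seed=17)
        stage1 = tables["stage1"]
        survivors, reasons = apply_stage_filter(stage1, STAGE1_DEFAULT)
        expected_ids, expected_reasons = [], {}
        for _, row in stage1.iterrows():
            failed = [
                c for c in SCORE_COLUMNS if row[c] < getattr(STAGE1_DEFAULT, c)
            ]
            if failed:
                expected_reasons[str(row["compound_id"])] = failed
            else:
                expected_ids.append(row["compound_id"])
        assert list(survivors["compound_id"]) == expected_ids
        assert reasons == expected_reasons

    def test_reasons_partition(self):
        tables = synth.gen_screening_library(500, seed=23)
        stage1 = tables["stage1"]
        survivors, reasons = apply_stage_filter(stage1, STAGE1_DEFAULT)
        eliminated = set(stage1["compound_id"].astype(str)) - set(
            survivors["compound_id"].astype(str)
        )
        assert set(reasons) == eliminated
        by_id = stage1.set_index("compound_id")
        for cid, failed in reasons.items():
            assert failed
            for c in failed:
                assert by_id.loc[cid, c] < getattr(STAGE1_DEFAULT, c)

    def test_monotone_in_each_minimum(self):
        stage1 = synth.gen_screening_library(800, seed=31)["stage1"]
        base = STAGE1_DEFAULT.as_dict()
        for c in SCORE_COLUMNS:
            counts = []
            for bump in (-5.0, 0.0, 5.0):
                minima = StageMinima(**{**base, c: base[c] + bump})
                counts.append(len(apply_stage_filter(stage1, minima)[0]))
            assert counts == sorted(counts, reverse=True)

    def test_idempotent(self):
        stage1 = synth.gen_screening_library(500, seed=37)["stage1"]
        once, _ = apply_stage_filter(stage1, STAGE1_DEFAULT)
        twice, _ = apply_stage_filter(once, STAGE1_DEFAULT)
        pd.testing.assert_frame_equal(once, twice)


class TestRunCascade:
    def test_identical_tables_reduce_to_stage2_minima(self):
        tables = synth.gen_screening_library(500, seed=41)
        stage1 = tables["stage1"]
        s1_survivors, _ = apply_stage_filter(stage1, STAGE1_DEFAULT)
        stage2 = s1_survivors.copy()
        report = run_cascade(stage1, stage2, CascadeConfig())
        direct, _ = apply_stage_filter(stage2, STAGE2_DEFAULT)
        assert report.stage2_survivors == list(direct["compound_id"].astype(str))

    def test_equal_minima_idempotence(self):
        tables = synth.gen_screening_library(300, seed=43)
        stage1 = tables["stage1"]
        config = CascadeConfig(stage1=STAGE1_DEFAULT, stage2=STAGE1_DEFAULT)
        s1, _ = apply_stage_filter(stage1, STAGE1_DEFAULT)
        report = run_cascade(stage1, s1.copy(), config)
        assert report.stage1_survivors == report.stage2_survivors

    def test_survivor_counts_shrink(self):
        tables = synth.gen_screening_library(1000, seed=47)
        stage1 = tables["stage1"]
        s1, _ = apply_stage_filter(stage1, STAGE1_DEFAULT)
        stage2 = tables["stage2"][
            tables["stage2"]["compound_id"].isin(s1["compound_id"])
        ]
        report = run_cascade(stage1, stage2, CascadeConfig())
        assert report.stage2_count <= report.stage1_count <= report.input_count

    def test_stray_stage2_id_rejected(self):
        tables = synth.gen_screening_library(100, seed=53)
        stage1 = tables["stage1"]
        stage2 = tables["stage2"]  # unrestricted: almost surely contains non-survivors
        s1, _ = apply_stage_filter(stage1, STAGE1_DEFAULT)
        assert len(s1) < len(stage1)  # sanity: some were eliminated
        with pytest.raises(ValueError, match="did not survive stage 1"):
            run_cascade(stage1, stage2, CascadeConfig())

    def test_weak_stage2_minima_warn(self):
        with pytest.warns(UserWarning, match="stage-2 minima below stage-1"):
            CascadeConfig(stage1=STAGE2_DEFAULT, stage2=STAGE1_DEFAULT)


class TestAlertFilter:
    TOY = pd.DataFrame(
        {
            "compound_id": ["benzene", "nitrobenzene", "ethanol", "aniline", "toluene"],
            "smiles": ["c1ccccc1", "c1ccccc1[N+](=O)[O-]", "CCO", "Nc1ccccc1", "Cc1ccccc1"],
        }
    )

    def test_empty_pattern_list_flags_nothing(self):
        flags = alert_filter(self.TOY, patterns=())
        assert not flags["flagged"].any()

    def test_nitro_pattern_flags_exactly_one(self):
        nitro = "[N+](=O)[O-]"
        flags = alert_filter(self.TOY, patterns=[nitro])
        flagged = flags.loc[flags["flagged"], "compound_id"].tolist()
        assert flagged == ["nitrobenzene"]
        assert flags.loc[flags["compound_id"] == "nitrobenzene", "alerts"].iloc[0] == [nitro]

    def test_invalid_pattern(self):
        with pytest.raises(ValueError, match="invalid SMARTS"):
            alert_filter(self.TOY, patterns=["this-is-not-smarts"])

    def test_unparseable_structure(self):
        bad = pd.DataFrame({"compound_id": ["junk"], "smiles": ["not_a_smiles(("]})
        with pytest.raises(ValueError, match="unparseable"):
            alert_filter(bad, patterns=["[N+](=O)[O-]"])
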