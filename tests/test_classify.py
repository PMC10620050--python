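"""Sensitivity classification rules, arm/isoform switching, family ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from tdmdscan.classify import (
    DeStore,
    SensitivityCall,
    apply_exclusions,
    classify_tissue,
    detect_arm_switch,
    detect_isoform_switch,
    mark_marginal,
    merge_calls,
    rank_families,
    rescue_broad,
    union_sensitive_sets,
)

from conftest import make_hairpin, make_mature


def de_frame(tissue, rows):
    """rows: species_id -> (log2fc, se, padj)."""
    return pd.DataFrame(
        {
            "species_id": list(rows),
            "tissue": tissue,
            "baseMean": 500.0,
            "log2fc": [v[0] for v in rows.values()],
            "se": [v[1] for v in rows.values()],
            "p": 0.5,
            "padj": [v[2] for v in rows.values()],
        }
    )


def simple_store(tissue="liver", rows=None, expressed=None, cognates=None):
    rows = rows or {}
    de = {tissue: de_frame(tissue, rows)}
    expressed = {tissue: expressed if expressed is not None else set(rows)}
    return DeStore(de, expressed, cognates or {})


class TestClassifyTissue:
    def test_clear_guide_beats_passenger(self):
        store = simple_store(
            rows={"g": (1.0, 0.2, 0.01), "p": (0.0, 0.2, 1.0)},
            cognates={"g": ("p",), "p": ("g",)},
        )
        calls = {c.species_id: c for c in classify_tissue(store, "liver")}
        assert calls["g"].label == "sensitive"
        assert calls["g"].reason == "bbum+passenger_test"
        assert calls["g"].passenger_p < 0.001

    def test_matched_strands_become_secondary_pair(self):
        store = simple_store(
            rows={"g": (0.5, 0.3, 0.01), "p": (0.45, 0.3, 1.0)},
            cognates={"g": ("p",), "p": ("g",)},
        )
        calls = {c.species_id: c for c in classify_tissue(store, "liver")}
        assert calls["g"].label == "secondary"
        assert calls["p"].label == "secondary"

    def test_undetected_passenger_is_sensitive(self):
        store = simple_store(
            rows={"g": (1.0, 0.2, 0.01)},
            expressed={"g"},
            cognates={"g": ("p",)},
        )
        calls = {c.species_id: c for c in classify_tissue(store, "liver")}
        assert calls["g"].label == "sensitive"
        assert calls["g"].reason == "passenger_undetected"

    def test_label_partition_single_label_per_pair(self):
        store = simple_store(
            rows={"g": (1.5, 0.2, 0.001), "p": (0.1, 0.2, 0.3), "x": (0.4, 0.3, 0.02), "y": (0.38, 0.3, 0.9)},
            cognates={"g": ("p",), "p": ("g",), "x": ("y",), "y": ("x",)},
        )
        calls = classify_tissue(store, "liver")
        keys = [(c.species_id, c.tissue) for c in calls]
        assert len(keys) == len(set(keys))
        labels = {c.species_id: c.label for c in calls}
        assert labels["x"] == labels["y"] == "secondary"


class TestRescueBroad:
    def _multi_store(self, lfc_by_tissue, cog_lfc=0.0, n_tissues=12):
        tissues = [f"t{i}" for i in range(n_tissues)]
        de, expressed = {}, {}
        for t, lfc in zip(tissues, lfc_by_tissue):
            de[t] = de_frame(t, {"g": (lfc, 0.3, 0.5), "p": (cog_lfc, 0.3, 1.0)})
            expressed[t] = {"g", "p"}
        return DeStore(de, expressed, {"g": ("p",), "p": ("g",)})

    def test_uniform_increase_rescued(self):
        store = self._multi_store([0.3] * 12)
        rescued = rescue_broad(store, [])
        assert {c.species_id for c in rescued} == {"g"}
        assert all(c.reason == "broad_rescue" for c in rescued)

    def test_ten_of_twelve_not_rescued(self):
        store = self._multi_store([0.3] * 10 + [-0.1, -0.1])
        assert rescue_broad(store, []) == []

    def test_low_median_not_rescued(self):
        store = self._multi_store([0.1] * 12)
        assert rescue_broad(store, []) == []

    def test_already_sensitive_not_duplicated(self):
        store = self._multi_store([0.3] * 12)
        prior = [SensitivityCall("g", "t0", "sensitive", "bbum+passenger_test")]
        assert rescue_broad(store, prior) == []

    def test_scaled_quota_option_evaluates_sparse_species(self):
        store = self._multi_store([0.3] * 6)  # detected in 6 of the 12-tissue design
        assert rescue_broad(store, []) == []  # absolute quota unreachable
        rescued = rescue_broad(store, [], scale_quota=True)
        assert {c.species_id for c in rescued} == {"g"}


class TestMarkMarginal:
    def _store_two_tissues(self):
        de = {
            "forebrain": de_frame("forebrain", {"g": (1.2, 0.2, 0.01), "p": (0.0, 0.2, 1.0)}),
            "lung": de_frame("lung", {"g": (0.9, 0.2, 0.2), "p": (0.0, 0.2, 1.0)}),
        }
        expressed = {t: {"g", "p"} for t in de}
        return DeStore(de, expressed, {"g": ("p",), "p": ("g",)})

    def test_sensitive_elsewhere_plus_passenger_test(self):
        store = self._store_two_tissues()
        calls = [SensitivityCall("g", "forebrain", "sensitive", "bbum+passenger_test")]
        marg = mark_marginal(store, calls)
        assert [(c.species_id, c.tissue, c.label) for c in marg] == [("g", "lung", "marginal")]

    def test_sensitive_nowhere_stays_uncalled(self):
        store = self._store_two_tissues()
        assert mark_marginal(store, []) == []

    def test_reference_list_counts_as_context(self):
        store = self._store_two_tissues()
        marg = mark_marginal(store, [], reference_sensitive={"g"})
        assert {(c.species_id, c.tissue) for c in marg} == {("g", "forebrain"), ("g", "lung")}


class TestExclusions:
    def test_all_scope_removes_every_sensitive_call(self):
        calls = [
            SensitivityCall("m", "liver", "sensitive", "bbum+passenger_test"),
            SensitivityCall("m", "lung", "sensitive", "broad_rescue"),
        ]
        out, audit = apply_exclusions(calls, [("m", "ALL")])
        assert all(c.label == "not_called" and c.reason == "excluded_manual" for c in out)
        assert len(audit) == 2

    def test_empty_list_is_identity(self):
        calls = [SensitivityCall("m", "liver", "sensitive", "bbum+passenger_test")]
        out, audit = apply_exclusions(calls, [])
        assert out == calls and audit == []

    def test_unknown_species_warns_noop(self):
        calls = [SensitivityCall("m", "liver", "marginal", "cross_context_marginal")]
        with pytest.warns(UserWarning, match="unknown"):
            out, audit = apply_exclusions(calls, [("zzz", "ALL")])
        assert out == calls and audit == []


def cpm_frame(rows):
    """rows: species -> (het_cpm, het_se, ko_cpm, ko_se)."""
    return pd.DataFrame(
        {
            ("het", "cpm"): {k: v[0] for k, v in rows.items()},
            ("het", "se"): {k: v[1] for k, v in rows.items()},
            ("ko", "cpm"): {k: v[2] for k, v in rows.items()},
            ("ko", "se"): {k: v[3] for k, v in rows.items()},
        }
    )


class TestArmSwitch:
    def _species(self):
        hp = make_hairpin("hpS")
        m5 = make_mature(hp, "m-5p", arm="5p", offset=4)
        m3 = make_mature(hp, "m-3p", arm="3p", offset=60, role="passenger")
        return [m5, m3], {"m-5p": ("m-3p",), "m-3p": ("m-5p",)}

    def test_dominance_flip_emits_event(self):
        species, cog = self._species()
        cpm = {"brain": cpm_frame({"m-3p": (100, 10, 600, 30), "m-5p": (300, 20, 300, 20)})}
        events = detect_arm_switch(cpm, {"m-3p"}, species, cog)
        assert len(events) == 1
        e = events[0]
        assert (e.dominant_het, e.dominant_ko) == ("5p", "3p")
        assert e.ratio_het.ratio == pytest.approx(3.0)

    def test_stable_dominance_no_event(self):
        species, cog = self._species()
        cpm = {"brain": cpm_frame({"m-3p": (100, 10, 200, 20), "m-5p": (300, 20, 300, 20)})}
        assert detect_arm_switch(cpm, {"m-3p"}, species, cog) == []

    def test_tie_is_flagged_not_event(self):
        species, cog = self._species()
        cpm = {"brain": cpm_frame({"m-3p": (300, 10, 600, 20), "m-5p": (300, 20, 300, 20)})}
        with pytest.warns(UserWarning, match="tie"):
            assert detect_arm_switch(cpm, {"m-3p"}, species, cog) == []


class TestIsoformSwitch:
    def test_plus1_exceeding_annotated_strands_in_ko(self):
        cpm = {
            "lung": cpm_frame(
                {
                    "m-3p": (200, 10, 200, 10),
                    "m-3p.iso+1": (100, 10, 500, 20),
                    "m-5p": (300, 20, 300, 20),
                }
            )
        }
        events = detect_isoform_switch(cpm, "m-3p", cognate_id="m-5p")
        assert len(events) == 1
        assert events[0].nonannotated_exceeds_guides
        assert (events[0].dominant_het, events[0].dominant_ko) == (0, 1)

    def test_proportional_scaling_no_event(self):
        cpm = {
            "lung": cpm_frame(
                {"m-3p": (200, 10, 400, 10), "m-3p.iso+1": (100, 10, 200, 10), "m-5p": (600, 10, 600, 10)}
            )
        }
        assert detect_isoform_switch(cpm, "m-3p", cognate_id="m-5p") == []


class TestRankFamilies:
    def _species(self):
        hp1, hp2 = make_hairpin("hp1"), make_hairpin("hp2", start=99000)
        a = make_mature(hp1, "a-5p", family="famA")
        a3 = make_mature(hp1, "a-3p", arm="3p", offset=60, role="passenger", family="famA*")
        b = make_mature(hp2, "b-5p", family="famB")
        return [a, a3, b]

    def test_pool_share_percentage(self):
        cpm = cpm_frame({"a-5p": (1000, 10, 9000, 10), "a-3p": (50, 5, 50, 5), "b-5p": (100, 5, 100, 5)})
        calls = [SensitivityCall("a-5p", "liver", "sensitive", "bbum+passenger_test")]
        df = rank_families(cpm, calls, self._species(), "liver")
        assert df.loc[0, "family_id"] == "famA"
        assert df.loc[0, "delta_cpm"] == pytest.approx(8000)
        assert df.loc[0, "pool_share_pct"] == pytest.approx(0.8)

    def test_absolute_change_outranks_fold_change(self):
        cpm = cpm_frame(
            {"a-5p": (5000, 10, 10000, 10), "a-3p": (50, 5, 50, 5), "b-5p": (100, 5, 600, 5)}
        )
        calls = [
            SensitivityCall("a-5p", "liver", "sensitive", "bbum+passenger_test"),
            SensitivityCall("b-5p", "liver", "sensitive", "bbum+passenger_test"),
        ]
        df = rank_families(cpm, calls, self._species(), "liver")
        # famA gained 5000 CPM (2x), famB gained 500 CPM (6x): famA ranks first
        assert list(df["family_id"]) == ["famA", "famB"]


def test_union_of_embryo_and_reference_sets():
    embryo = {f"mir-{i}" for i in range(51)}
    reference = {f"mir-{i}" for i in range(29, 58)}
    assert len(embryo & reference) == 22
    assert len(union_sensitive_sets(embryo, reference)) == 58


def test_merge_calls_precedence_and_uniqueness():
    a = SensitivityCall("m", "liver", "secondary", "none")
    b = SensitivityCall("m", "liver", "sensitive", "broad_rescue")
    merged = merge_calls([a], [b])
    assert len(merged) == 1 and merged[0].label == "sensitive"
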