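import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qcfmri.review import (CANONICAL_KEYS, ChecklistRule, MISSING, QCLabel,
                           ReviewDictionary, apply_checklist, categorize,
                           collect_review_dict, default_checklists,
                           format_qc_label, parse_qc_label)


def make_dict(subject_id="sub-01", **overrides):
    base = {
        "censor fraction": 0.05,
        "average censored motion": 0.05,
        "max censored displacement": 1.0,
        "global correlation (GCOR)": 0.08,
        "TSNR average": 220.0,
        "final DF fraction": 0.9,
        "flip guess": "NO_FLIP",
        "fraction TRs censored": 0.05,
        "num regs of interest": 2,
        "final voxel resolution": "3.000x3.000x3.000",
        "num TRs per run": "150",
        "AFNI version": "0.1.0",
    }
    base.update(overrides)
    return ReviewDictionary(subject_id=subject_id, values=base)


class TestDefaultChecklists:
    def test_rest_has_six_exclusion_rules(self):
        rules = default_checklists("rest")
        assert len(rules["exclusion"]) == 6

    def test_task_has_seven_exclusion_rules(self):
        rules = default_checklists("task")
        assert len(rules["exclusion"]) == 7
        extra = rules["exclusion"][-1]
        assert extra.key == "fraction TRs censored"
        assert extra.comparator == "GE" and extra.threshold == 0.2

    def test_warning_list_contains_tsnr_lt_150(self):
        rules = default_checklists("rest")["warning"]
        tsnr = [r for r in rules if r.key == "TSNR average"]
        assert len(tsnr) == 1
        assert tsnr[0].comparator == "LT" and tsnr[0].threshold == 150

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            default_checklists("nonsense")


class TestApplyChecklist:
    def test_censor_fraction_flagged_at_rest_threshold(self):
        d = make_dict(**{"censor fraction": 0.25})
        rules = default_checklists("rest")["exclusion"]
        result = apply_checklist([d], rules)
        reasons = result.flagged.loc["sub-01", "reasons"]
        assert "'censor fraction' GE 0.2" in reasons

    def test_identical_subjects_no_vary_flag(self):
        dicts = [make_dict(f"sub-{i}") for i in range(4)]
        rules = default_checklists("rest")["consistency"]
        result = apply_checklist(dicts, rules)
        assert result.vary_keys == []
        assert len(result.flagged) == 0

    def test_vary_flag_on_version_difference(self):
        dicts = [make_dict("sub-01"),
                 make_dict("sub-02", **{"AFNI version": "0.2.0"})]
        rules = default_checklists("rest")["consistency"]
        result = apply_checklist(dicts, rules)
        assert "AFNI version" in result.vary_keys

    def test_crafted_dicts_match_bruteforce(self):
        """Six dicts, each straddling one rest exclusion rule: the
        flagged set equals a literal re-evaluation of every rule."""
        rules = default_checklists("rest")["exclusion"]
        dicts = [
            make_dict("sub-df", **{"final DF fraction": 0.55}),
            make_dict("sub-cf", **{"censor fraction": 0.31}),
            make_dict("sub-mot", **{"average censored motion": 0.2}),
            make_dict("sub-disp", **{"max censored displacement": 9.5}),
            make_dict("sub-gcor", **{"global correlation (GCOR)": 0.47}),
            make_dict("sub-flip", **{"flip guess": "DO_FLIP"}),
            make_dict("sub-ok"),
        ]
        result = apply_checklist(dicts, rules)
        got = {(f.subject_id, f.rule.key) for f in result.flags}

        ops = {"GE": lambda v, t: v >= t, "LE": lambda v, t: v <= t,
               "GT": lambda v, t: v > t, "LT": lambda v, t: v < t,
               "EQ": lambda v, t: v == t}
        expected = set()
        for d in dicts:
            for r in rules:
                if ops[r.comparator](d.get(r.key), r.threshold):
                    expected.add((d.subject_id, r.key))
        assert got == expected
        assert ("sub-ok", "censor fraction") not in got
        assert len({s for s, _ in got}) == 6

    def test_missing_key_flagged_as_missing(self):
        d = make_dict()
        d.values.pop("TSNR average")
        rules = default_checklists("rest")["warning"]
        result = apply_checklist([d], rules)
        assert any(f.missing for f in result.flags)

    def test_idempotent_and_order_independent(self):
        dicts = [make_dict("a", **{"censor fraction": 0.3}),
                 make_dict("b"), make_dict("c", **{"TSNR average": 100.0})]
        rules = default_checklists("rest")["warning"]
        r1 = apply_checklist(dicts, rules)
        r2 = apply_checklist(list(reversed(dicts)), rules)
        key = lambda f: (f.subject_id, f.rule.key)
        assert sorted(map(key, r1.flags)) == sorted(map(key, r2.flags))


NUMERIC_NESTED = [
    ("final DF fraction", "LE", 0.6, 0.7),
    ("censor fraction", "GE", 0.2, 0.15),
    ("average censored motion", "GE", 0.15, 0.1),
    ("max censored displacement", "GE", 8, 6),
    ("global correlation (GCOR)", "GE", 0.20, 0.15),
]


class TestNestedThresholds:
    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5),
           st.floats(0, 20), st.floats(0, 400))
    def test_excluded_implies_at_least_uncertain(self, fracs, disp, tsnr):
        """Any subject tripping a numeric exclusion rule also trips the
        matching (laxer) warning rule, so the warning checklist can
        never categorize an excluded subject as a clean include."""
        d = make_dict(**{
            "final DF fraction": fracs[0],
            "censor fraction": fracs[1],
            "average censored motion": fracs[2],
            "global correlation (GCOR)": fracs[3],
            "max censored displacement": disp,
            "TSNR average": tsnr})
        excl = [ChecklistRule(k, c, te, "exclusion")
                for k, c, te, _ in NUMERIC_NESTED]
        warn = [ChecklistRule(k, c, tw, "warning")
                for k, c, _, tw in NUMERIC_NESTED]
        excl_flags = apply_checklist([d], excl).flags
        warn_flags = apply_checklist([d], warn).flags
        excl_keys = {f.rule.key for f in excl_flags}
        warn_keys = {f.rule.key for f in warn_flags}
        assert excl_keys <= warn_keys


class TestCollect:
    def test_all_keys_present_and_missing_semantics(self):
        d = collect_review_dict("sub-01")
        assert set(d.values) == set(CANONICAL_KEYS)
        # nothing supplied: everything explicitly missing
        assert all(d.is_missing(k) for k in CANONICAL_KEYS)

    def test_rest_mode_stim_fraction_missing_not_zero(self):
        d = collect_review_dict("sub-01", gcor=0.1, stim_censor=None)
        assert d.get("fraction TRs censored") == MISSING
        assert d.get("global correlation (GCOR)") == 0.1


class TestCategorize:
    def test_high_gcor_excluded(self):
        d = make_dict(**{"global correlation (GCOR)": 0.47})
        rules = default_checklists("rest")
        flags = apply_checklist([d], rules["exclusion"]).flags
        ev = categorize("sub-01", flags)
        assert ev.category == "exclude"
        assert any("GCOR" in t for t in ev.triggers)

    def test_warning_only_subject_uncertain(self):
        d = make_dict(**{"TSNR average": 120.0})
        rules = default_checklists("rest")
        flags = apply_checklist([d], rules["exclusion"]).flags + \
            apply_checklist([d], rules["warning"]).flags
        ev = categorize("sub-01", flags)
        assert ev.category == "uncertain"

    def test_manual_label_overrides_clean_quant(self):
        """A rater's qualitative exclusion stands even when every
        quantitative field is clean."""
        d = make_dict()
        rules = default_checklists("rest")
        flags = apply_checklist([d], rules["exclusion"]).flags + \
            apply_checklist([d], rules["warning"]).flags
        label = parse_qc_label("APQUAL.vstat.artifact")
        ev = categorize("sub-01", flags, [(label, "exclusion")])
        assert ev.category == "exclude"
        assert "APQUAL.vstat.artifact" in ev.triggers

    def test_clean_subject_included(self):
        d = make_dict()
        rules = default_checklists("rest")
        flags = apply_checklist([d], rules["exclusion"]).flags + \
            apply_checklist([d], rules["warning"]).flags
        assert categorize("sub-01", flags).category == "include"


class TestQCLabels:
    @pytest.mark.parametrize("text", [
        "APQUANT.excl('flip guess')",
        "APQUAL.regr.TSNR_final-artifact",
        "GUI.instacorr(odd patterns)",
        "STIM.isi",
    ])
    def test_round_trip(self, text):
        assert format_qc_label(parse_qc_label(text)) == text

    def test_parse_fields(self):
        lab = parse_qc_label("APQUAL.regr.TSNR_final-artifact")
        assert lab.stage == "APQUAL"
        assert lab.type == "regr"
        assert lab.subtype == "TSNR_final-artifact"

    def test_bad_stage_rejected(self):
        with pytest.raises(ValueError, match="BOGUS"):
            parse_qc_label("BOGUS.x")

    def test_malformed_rejected_with_position(self):
        with pytest.raises(ValueError, match="position"):
            parse_qc_label("APQUANT")
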