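"""Rule-set engine and cohort classification behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petresponse.classify import classify_cohort, category_counts, select_target
from petresponse.criteria import (
    CRITERIA,
    EORTC,
    MPERCIST,
    PERCIST10,
    classify_eortc,
    classify_percist_family,
    dichotomize,
    percent_change,
)
from petresponse.types import Category, Dichotomy


class TestPercentChange:
    @pytest.mark.parametrize("base,follow,expected",
                             [(5.0, 7.0, 40.0), (5.0, 5.0, 0.0), (4.0, 2.0, -50.0)])
    def test_arithmetic(self, base, follow, expected):
        assert percent_change(base, follow) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestPercistRules:
    def test_large_increase_with_absolute_floor_is_pmd(self):
        assert classify_percist_family(PERCIST10, 5.0, 7.0) is Category.PMD

    def test_percentage_increase_without_absolute_floor_stays_smd(self):
        # +35 % but only +0.7 SUL: the conjunctive rule withholds progression
        assert classify_percist_family(PERCIST10, 2.0, 2.7) is Category.SMD

    def test_large_decrease_is_pmr(self):
        assert classify_percist_family(PERCIST10, 5.0, 3.0) is Category.PMR

    def test_new_lesion_overrides_response(self):
        assert classify_percist_family(PERCIST10, 5.0, 3.0, new_lesion=True) \
            is Category.PMD

    def test_size_progression_alone_is_pmd(self):
        assert classify_percist_family(
            MPERCIST, 5.0, 5.1, target_size_change_pct=35.0
        ) is Category.PMD

    def test_pmr_absolute_floor_only_for_sul_metric(self):
        # -40 % but only -0.4 units: PMR under mPERCIST, SMD under PERCIST 1.0
        assert classify_percist_family(PERCIST10, 1.0, 0.6) is Category.SMD
        assert classify_percist_family(MPERCIST, 1.0, 0.6) is Category.PMR

    def test_cmr_requires_resolution_and_liver_background(self):
        kwargs = dict(background_level=1.8, followup_lesion_values=[1.5])
        assert classify_percist_family(PERCIST10, 5.0, 1.5, all_resolved=True,
                                       **kwargs) is Category.CMR
        # uptake below liver but lesion not judged resolved -> PMR, not CMR
        assert classify_percist_family(PERCIST10, 5.0, 1.5, all_resolved=False,
                                       **kwargs) is Category.PMR

    def test_eortc_spec_rejected(self):
        with pytest.raises(ValueError):
            classify_percist_family(EORTC, 5.0, 5.0)


class TestEortcRules:
    def test_boundaries_inclusive_at_25(self):
        assert classify_eortc(6.0, 7.5) is Category.PMD    # exactly +25 %
        assert classify_eortc(6.0, 4.5) is Category.PMR    # exactly -25 %
        assert classify_eortc(6.0, 7.49) is Category.SMD

    def test_diameter_rule_strictly_greater_than_20(self):
        assert classify_eortc(6.0, 6.6, longest_diameter_change_pct=30.0) \
            is Category.PMD
        assert classify_eortc(6.0, 6.6, longest_diameter_change_pct=20.0) \
            is Category.SMD

    def test_new_lesion_is_pmd(self):
        assert classify_eortc(6.0, 3.0, new_lesion=True) is Category.PMD


class TestDichotomy:
    @pytest.mark.parametrize("category,expected", [
        (Category.PMD, Dichotomy.PD), (Category.CMR, Dichotomy.DC),
        (Category.PMR, Dichotomy.DC), (Category.SMD, Dichotomy.DC),
    ])
    def test_pmd_maps_to_pd_all_else_dc(self, category, expected):
        assert dichotomize(category) is expected


ORDER = {Category.PMR: 0, Category.SMD: 1, Category.PMD: 2}


@given(
    base=st.floats(min_value=1.0, max_value=20.0),
    follow=st.floats(min_value=0.01, max_value=40.0),
    bump=st.floats(min_value=0.01, max_value=10.0),
    name=st.sampled_from(sorted(CRITERIA)),
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_increasing_followup_never_moves_toward_response(base, follow, bump, name):
    """With everything else fixed, more follow-up uptake is never 'better'."""
    spec = CRITERIA[name]
    lo = classify_percist_family(spec, base, follow) if name != "eortc" \
        else classify_eortc(base, follow)
    hi = classify_percist_family(spec, base, follow + bump) if name != "eortc" \
        else classify_eortc(base, follow + bump)
    assert ORDER[hi] >= ORDER[lo]


def _lesions(rows):
    defaults = dict(mtv_cm3=1.0, tlg=1.0, longest_diameter_mm=10.0,
                    is_new=False, resolved=False, suvmean=1.0)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestTargetSelection:
    def setup_method(self):
        self.base = _lesions([
            {"lesion_id": "A", "compartment": "lung", "suvmax": 8.0,
             "suvpeak": 8.0, "sulpeak": 8.0},
            {"lesion_id": "B", "compartment": "bone", "suvmax": 5.0,
             "suvpeak": 5.0, "sulpeak": 5.0},
        ])
        self.follow = _lesions([
            {"lesion_id": "A", "compartment": "lung", "suvmax": 4.0,
             "suvpeak": 4.0, "sulpeak": 4.0},
            {"lesion_id": "B", "compartment": "bone", "suvmax": 6.0,
             "suvpeak": 6.0, "sulpeak": 6.0},
        ])

    def test_percist_hottest_compares_each_scans_hottest(self):
        target = select_target(self.base, self.follow, "sulpeak", "hottest",
                               "percist10")
        assert (target.baseline_value, target.followup_value) == (8.0, 6.0)
        assert percent_change(*[target.baseline_value, target.followup_value]) \
            == pytest.approx(-25.0)

    def test_eortc_hottest_tracks_baseline_hottest_lesion(self):
        target = select_target(self.base, self.follow, "suvmax", "hottest", "eortc")
        assert (target.baseline_value, target.followup_value) == (8.0, 4.0)
        assert target.followup_ids == ("A",)

    def test_all_mode_sums_per_compartment_index_lesions(self):
        target = select_target(self.base, self.follow, "suvmax", "all", "percist10")
        assert (target.baseline_value, target.followup_value) == (13.0, 10.0)

    def test_single_lesion_conventions_agree(self):
        base = self.base.iloc[:1]
        follow = self.follow.iloc[:1]
        values = {
            (mode, crit): select_target(base, follow, "suvmax", mode, crit)
            for mode in ("hottest", "all") for crit in ("percist10", "eortc")
        }
        assert len({(t.baseline_value, t.followup_value)
                    for t in values.values()}) == 1

    def test_tie_breaks_by_mtv_then_id(self):
        base = _lesions([
            {"lesion_id": "B", "compartment": "lung", "suvmax": 8.0,
             "suvpeak": 8.0, "sulpeak": 8.0, "mtv_cm3": 9.0},
            {"lesion_id": "A", "compartment": "bone", "suvmax": 8.0,
             "suvpeak": 8.0, "sulpeak": 8.0, "mtv_cm3": 1.0},
        ])
        target = select_target(base, base, "suvmax", "hottest", "eortc")
        assert target.baseline_ids == ("B",)


class TestCohortClassification:
    def test_truth_recovery_on_zero_noise_cohort(self, zero_noise_cohort):
        lesions, patients, liver = zero_noise_cohort
        results = classify_cohort(lesions, liver)
        expected = {"complete": "CMR", "responder": "PMR",
                    "stable": "SMD", "progressor": "PMD"}
        truth = patients.set_index("patient_id")["truth_class"].map(expected)
        for (_, _), group in results.groupby(["criteria", "selection"]):
            got = group.set_index("patient_id")["category"]
            assert (got == truth.loc[got.index]).all()

    def test_all_progressor_cohort_has_no_disease_control(self):
        from conftest import zero_noise_config
        from petresponse.simulate import generate_lesion_table_cohort
        config = zero_noise_config(
            n_patients=20, fraction_complete=0.0, fraction_responder=0.0,
            fraction_stable=0.0, fraction_progressor=1.0, seed=3,
        )
        lesions, _, liver = generate_lesion_table_cohort(config)
        results = classify_cohort(lesions, liver)
        classified = results[results["status"] == "ok"]
        assert (classified["dichotomy"] == "PD").all()

    def test_non_comparable_excluded_from_percist_but_in_eortc(self):
        from conftest import zero_noise_config
        from petresponse.simulate import generate_lesion_table_cohort
        config = zero_noise_config(n_patients=10, p_liver_drift_patient=1.0, seed=9)
        lesions, _, liver = generate_lesion_table_cohort(config)
        counts = category_counts(classify_cohort(lesions, liver))
        assert counts["percist10/hottest"]["n_classified"] == 0
        assert counts["percist10/hottest"]["not_comparable"] == 10
        assert counts["eortc/hottest"]["n_classified"] == 10

    def test_duplicate_rows_rejected(self, zero_noise_cohort):
        lesions, _, liver = zero_noise_cohort
        dup = pd.concat([lesions, lesions.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            classify_cohort(dup, liver)
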