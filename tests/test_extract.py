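"""Rule-based age extraction: arithmetic, golden tweets, rule ordering."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tweetage.extract import (
    AGE_MAX,
    AGE_MIN,
    ExtractionRule,
    TimePeriod,
    apply_rule,
    extract_age,
    load_rules,
    period_to_years,
    validate_rule_order,
)

from conftest import GOLDEN_EXTRACTIONS, NEAR_MISS_PREDICTIONS


class TestPeriodToYears:
    @pytest.mark.parametrize(
        "magnitude,unit,expected",
        [
            (3, "weeks", 1),   # sub-year offsets round up
            (0, "months", 0),
            (13, "months", 2),
            (52, "weeks", 1),
            (53, "weeks", 2),
            (365, "days", 1),
            (366, "days", 2),
            (7, "years", 7),
        ],
    )
    def test_examples(self, magnitude, unit, expected):
        assert period_to_years(TimePeriod(magnitude, unit)) == expected

    def test_matches_ceil_division_oracle(self):
        divisors = {"years": 1, "months": 12, "weeks": 52, "days": 365}
        for unit, d in divisors.items():
            for magnitude in range(0, 1001):
                expected = math.ceil(magnitude / d)
                assert period_to_years(TimePeriod(magnitude, unit)) == expected

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            TimePeriod(-1, "years")


def _rule(arithmetic, expr=r"(?P<n>\d+)(?:\D+(?P<k>\d+))?(?:\s*(?P<unit>\w+))?",
          **kw):
    return ExtractionRule("test", 1, expr, arithmetic, **kw)


class TestApplyRule:
    def test_minus_period_years(self):
        rule = _rule("minus_period")
        assert apply_rule(rule, {"n": "21", "k": "2", "unit": "years"}) == 19

    def test_plus_period(self):
        rule = _rule("plus_period")
        assert apply_rule(rule, {"n": "19", "k": "20", "unit": "yrs"}) == 39

    def test_repeat_count(self):
        rule = _rule("plus_repeats_minus_one")
        assert apply_rule(rule, {"n": "21", "k": "3"}) == 23

    def test_max_of_two(self):
        rule = ExtractionRule("t", 1, r"(?P<n>\d+) (?P<n2>\d+)", "max_of_two")
        assert apply_rule(rule, {"n": "28", "n2": "35"}) == 35

    def test_missing_unit_defaults_to_years(self):
        rule = _rule("minus_period")
        assert apply_rule(rule, {"n": "30", "k": "4", "unit": None}) == 26

    def test_rule_arity_validated_at_construction(self):
        with pytest.raises(ValueError):
            ExtractionRule("bad", 1, r"(?P<n>\d+)", "max_of_two")
        with pytest.raises(ValueError):
            ExtractionRule("bad", 1, r"(?P<n>\d+)", "minus_period")
        with pytest.raises(ValueError):
            ExtractionRule("bad", 1, r"(?P<n>\d+)", "frobnicate")


class TestExtractAge:
    @pytest.mark.parametrize("text,expected", GOLDEN_EXTRACTIONS)
    def test_golden_worked_examples(self, text, expected, rules):
        pred = extract_age(text, rules)
        assert pred is not None and pred.age == expected

    @pytest.mark.parametrize("text,expected", NEAR_MISS_PREDICTIONS)
    def test_documented_near_miss_outputs(self, text, expected, rules):
        # possessive "my Nth" / bare "turning N" without a present-tense
        # marker read as the next birthday: predicted age is N - 1
        pred = extract_age(text, rules)
        assert pred is not None and pred.age == expected

    def test_no_digits_gives_no_age(self, rules):
        assert extract_age("no digits at all", rules) is None

    def test_fallback_takes_first_two_digit_group(self, rules):
        pred = extract_age("random words 47 and then 21", rules)
        assert pred is not None and pred.age == 47 and pred.rule_id == "fallback"

    def test_fallback_ignores_longer_digit_groups(self, rules):
        pred = extract_age("code 2104 then plain 33", rules)
        assert pred is not None and pred.age == 33

    def test_out_of_range_arithmetic_yields_no_age(self, rules):
        # "turning 10 in 5 years" computes 5: out of range, not clamped
        assert extract_age("turning 10 in 5 years, weird", rules) is None

    def test_determinism(self, rules):
        text = GOLDEN_EXTRACTIONS[0][0]
        assert extract_age(text, rules) == extract_age(text, rules)

    def test_span_is_within_normalized_text(self, rules):
        from tweetage.textprep import preprocess_for_extraction

        for text, _ in GOLDEN_EXTRACTIONS:
            pred = extract_age(text, rules)
            n = len(preprocess_for_extraction(text).normalized)
            assert 0 <= pred.matched_span[0] < pred.matched_span[1] <= n

    def test_age_always_in_range(self, rules):
        preds = [extract_age(t, rules) for t, _ in GOLDEN_EXTRACTIONS]
        assert all(AGE_MIN <= p.age <= AGE_MAX for p in preds)


@settings(derandomize=True, max_examples=100)
@given(n=st.integers(13, 99), k1=st.integers(1, 200), dk=st.integers(0, 200),
       unit=st.sampled_from(["years", "months", "weeks", "days"]))
def test_future_offset_monotonicity(n, k1, dk, unit):
    # for fixed N, a larger future offset never increases the extracted age
    rule = ExtractionRule(
        "probe", 1, r"turning (?P<n>\d+) in (?P<k>\d+) (?P<unit>\w+)", "minus_period"
    )
    a1 = apply_rule(rule, {"n": str(n), "k": str(k1), "unit": unit})
    a2 = apply_rule(rule, {"n": str(n), "k": str(k1 + dk), "unit": unit})
    assert a2 <= a1


class TestRuleTable:
    def test_loads_with_unique_sorted_order(self, rules):
        orders = [r.order_index for r in rules]
        assert orders == sorted(orders) and len(set(orders)) == len(orders)

    def test_order_probes(self, rules):
        # the repeated-birthday rule must fire before the bare turned-N rule
        probes = [
            ("I've turned 21 three times now.", "turned_times"),
            ("Recently turned 47.", "turned_bare"),
            ("Two more years until my 21st birthday!", "until_my_nth"),
            ("excited for my 18th", "my_nth"),
            ("It's my 18th birthday!", "its_my_nth"),
        ]
        assert validate_rule_order(rules, probes) == []

    def test_order_violation_reported(self, rules):
        report = validate_rule_order(rules, [("Recently turned 47.", "turned_times")])
        assert len(report) == 1
        assert report[0].expected_rule_id == "turned_times"
        assert report[0].actual_rule_id == "turned_bare"

    def test_empty_probe_list_rejected(self, rules):
        with pytest.raises(ValueError):
            validate_rule_order(rules, [])

    def test_repeat_rule_precedes_bare_turned(self, rules):
        pred = extract_age("I've turned 21 three times now.", rules)
        assert pred.age == 23 and pred.rule_id == "turned_times"

    def test_duplicate_order_index_rejected(self, tmp_path):
        bad = tmp_path / "rules.tsv"
        bad.write_text(
            "10\ta\tdirect\tnone\t(?P<n>\\d\\d)\n10\tb\tdirect\tnone\t(?P<n>\\d\\d)x\n"
        )
        with pytest.raises(ValueError):
            load_rules(bad)
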