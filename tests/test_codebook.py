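"""Data model: item encoding, report validation, eligibility, transactions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from surveyrules import (
    Codebook,
    CodebookError,
    ItemParseError,
    Question,
    SurveyReport,
    ValidationError,
    build_transactions,
    decode_item,
    eligibility_filter,
    encode_item,
)


class TestItemEncoding:
    @pytest.mark.parametrize(
        "question,answer,expected",
        [(153, 4, "153-4"), (2, 0, "2-0"), (37, 2, "37-2"), (41, 7, "41-7")],
    )
    def test_encode(self, small_codebook, question, answer, expected):
        assert encode_item(question, answer, small_codebook) == expected

    @pytest.mark.parametrize("code,expected", [("41-7", (41, 7)), ("2-0", (2, 0)), ("153-4", (153, 4))])
    def test_decode(self, code, expected):
        assert decode_item(code) == expected

    @pytest.mark.parametrize("bad", ["x41", "41", "41-", "41-77", "41-x", "-4", "a-4"])
    def test_decode_rejects_malformed(self, bad):
        with pytest.raises(ItemParseError):
            decode_item(bad)

    def test_encode_rejects_unknown_question(self, small_codebook):
        with pytest.raises(CodebookError):
            encode_item(999, 1, small_codebook)

    def test_encode_rejects_out_of_range_answer(self, small_codebook):
        with pytest.raises(ValidationError):
            encode_item(37, 0, small_codebook)  # base-1 question
        with pytest.raises(ValidationError):
            encode_item(37, 6, small_codebook)

    def test_round_trip_over_whole_codebook(self, small_codebook):
        for question in small_codebook:
            for answer in question.valid_indices:
                item = encode_item(question.number, answer, small_codebook)
                assert decode_item(item) == (question.number, answer)

    @given(
        number=st.integers(min_value=1, max_value=10_000),
        base=st.sampled_from([0, 1]),
        k=st.integers(min_value=1, max_value=9),
        data=st.data(),
    )
    def test_round_trip_property(self, number, base, k, data):
        if base + k - 1 > 9:
            k = 9 - base + 1
        codebook = Codebook(
            [Question(number=number, text="q", answer_labels=tuple("x" * k), answer_index_base=base)]
        )
        answer = data.draw(st.integers(min_value=base, max_value=base + k - 1))
        assert decode_item(encode_item(number, answer, codebook)) == (number, answer)


class TestQuestionInvariants:
    def test_ten_answer_choices_rejected(self):
        # the single-trailing-digit encoding requires k < 10
        with pytest.raises(ValidationError):
            Question(number=37, text="q", answer_labels=tuple(str(i) for i in range(10)))

    def test_base1_nine_choices_allowed(self):
        # indices 1..9 are still single digits
        q = Question(number=1, text="q", answer_labels=tuple("x" * 9), answer_index_base=1)
        assert q.valid_indices == range(1, 10)

    def test_possible_item_count_is_sum_of_arities(self, small_codebook):
        assert small_codebook.n_possible_items() == 3 + 5 + 5 + 7 + 5

    def test_duplicate_question_numbers_rejected(self):
        q = Question(number=5, text="q", answer_labels=("a", "b"))
        with pytest.raises(ValidationError):
            Codebook([q, q])


def _report(pid, answers, **flags):
    return SurveyReport(participant_id=pid, answers=answers, **flags)


class TestEligibilityFilter:
    def test_reproduces_cohort_screen(self, small_codebook):
        """366 recruits minus 37 outside-US minus 7 non-binary leaves 322."""
        answers = {2: 1, 37: 3, 38: 3, 41: 4, 153: 2}
        reports = (
            [_report(f"ok{i}", answers) for i in range(322)]
            + [_report(f"out{i}", answers, outside_us=True) for i in range(37)]
            + [_report(f"nb{i}", answers, nonbinary_gender=True) for i in range(7)]
        )
        retained, log = eligibility_filter(reports, small_codebook)
        assert len(retained) == 322
        assert log.counts == {"outside_us": 37, "nonbinary_gender": 7, "missingness": 0}
        assert log.n_input == log.n_retained + log.n_excluded

    def test_empty_input(self, small_codebook):
        retained, log = eligibility_filter([], small_codebook)
        assert retained == [] and log.n_input == 0 and log.n_excluded == 0

    def test_missingness_rule(self, small_codebook):
        # 5-question codebook: 3 missing of 5 = 60% > 50% threshold
        full = {2: 0, 37: 1, 38: 1, 41: 1, 153: 1}
        sparse = {2: 0, 37: 1}
        reports = [_report(f"r{i}", full) for i in range(9)] + [_report("sparse", sparse)]
        retained, log = eligibility_filter(reports, small_codebook, max_missing_fraction=0.5)
        assert len(retained) == 9
        assert log.counts["missingness"] == 1

    def test_flag_precedence_counts_each_report_once(self, small_codebook):
        both = _report("both", {}, outside_us=True, nonbinary_gender=True)
        _, log = eligibility_filter([both], small_codebook, max_missing_fraction=1.0)
        assert log.counts == {"outside_us": 1, "nonbinary_gender": 0, "missingness": 0}

    def test_idempotent(self, small_codebook):
        answers = {2: 1, 37: 3, 38: 3, 41: 4}
        reports = [_report("a", answers), _report("b", {}, outside_us=True), _report("c", {2: 0})]
        retained, _ = eligibility_filter(reports, small_codebook, max_missing_fraction=0.6)
        again, log = eligibility_filter(retained, small_codebook, max_missing_fraction=0.6)
        assert again == retained and log.n_excluded == 0


class TestBuildTransactions:
    def test_sample_basket(self, small_codebook):
        report = _report("p1", {2: 0, 37: 2, 41: 4})
        (t,) = build_transactions([report], small_codebook)
        assert t.items == frozenset({"2-0", "37-2", "41-4"})

    def test_no_answers_yields_empty_transaction(self, small_codebook):
        (t,) = build_transactions([_report("p1", {})], small_codebook)
        assert len(t) == 0

    def test_one_transaction_per_report_with_scope(self, small_codebook):
        answers = {2: 0, 37: 2, 41: 4, 153: 5}
        reports = [_report(f"p{i}", answers) for i in range(3)]
        tx = build_transactions(reports, small_codebook, include_questions={37, 41, 153})
        assert len(tx) == 3
        assert all(len(t) == 3 for t in tx)

    def test_group_item_dropped_by_default(self, small_codebook):
        report = _report("p1", {2: 0, 37: 2})
        (t,) = build_transactions([report], small_codebook, group_question=2)
        assert t.items == frozenset({"37-2"})
        (t2,) = build_transactions(
            [report], small_codebook, group_question=2, include_group_item=True
        )
        assert t2.items == frozenset({"2-0", "37-2"})

    def test_item_count_bounded_by_scope(self, small_codebook):
        reports = [_report("p", {2: 1, 37: 1, 38: 2, 41: 3, 153: 4})]
        for t in build_transactions(reports, small_codebook):
            assert len(t) <= len(small_codebook)
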