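"""Naive Bayes ranking, completeness assessment, selection, engagement metrics."""
from __future__ import annotations

import math
from collections import Counter
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from forumvigil import followup as fu
from forumvigil import synthetic as syn
from forumvigil.ingest import Post

T0 = datetime(2020, 1, 1, tzinfo=timezone.utc)


class TestNaiveBayes:
    def test_hand_computed_posterior_on_two_documents(self):
        # vocab {rash,bad,garden,nice}, V+OOV=5; per-class denom = 2 + 5 = 7
        # "rash": P(AE) = (2/7)/(2/7 + 1/7) = 2/3
        model = fu.train_nb([("rash bad", 1), ("garden nice", 0)])
        assert model.predict_proba("rash") == pytest.approx(2 / 3, abs=1e-12)
        assert model.predict_proba("rash garden") == pytest.approx(0.5, abs=1e-12)

    def test_empty_document_returns_class_prior(self):
        model = fu.train_nb([("a b", 1), ("a b", 1), ("c d", 0)])
        assert model.predict_proba("") == pytest.approx(2 / 3, abs=1e-12)

    def test_identical_texts_in_balanced_classes_score_half(self):
        model = fu.train_nb([("same words here", 1), ("same words here", 0)])
        assert model.predict_proba("same words") == pytest.approx(0.5, abs=1e-12)

    def test_disjoint_vocabularies_separate_heldout(self):
        train = syn.generate_labeled_posts(
            100, 100, seed=1, pos_vocab=["alpha", "beta", "gamma"],
            neg_vocab=["delta", "epsilon", "zeta"], pos_rate=1.0, neg_rate=1.0)
        test = syn.generate_labeled_posts(
            50, 50, seed=2, pos_vocab=["alpha", "beta", "gamma"],
            neg_vocab=["delta", "epsilon", "zeta"], pos_rate=1.0, neg_rate=1.0)
        model = fu.train_nb(train)
        for lp in test:
            p = model.predict_proba(lp.text)
            assert (p > 0.99) if lp.label == 1 else (p < 0.01)

    def test_scores_are_probabilities(self):
        model = fu.train_nb(syn.generate_labeled_posts(50, 50, seed=3))
        for text in ("rash nausea", "garden coffee", "zzz unseen token"):
            p = model.predict_proba(text)
            assert 0.0 < p < 1.0
            lj = model.log_joint(text)
            total = math.exp(lj[0]) + math.exp(lj[1])
            assert math.exp(lj[1]) / total == pytest.approx(p)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fu.train_nb([("a", 1), ("b", 1)])


class TestRanking:
    def _posts(self):
        return [
            Post(forum="f", post_id=f"p{i}", thread_id="t", author_id=f"a{i}",
                 timestamp=T0 + timedelta(days=30 * i - 60), text=text)
            for i, text in enumerate(
                ["rash nausea fracture", "garden coffee", "rash coffee", "headache dizzy"])
        ]

    def test_date_floor_filters(self):
        model = fu.train_nb(syn.generate_labeled_posts(100, 100, seed=0))
        ranked = fu.rank_by_ae_probability(model, self._posts(), T0)
        assert all(r.post.timestamp >= T0 for r in ranked)
        assert len(ranked) == 2  # p2, p3 only
        far_future = T0 + timedelta(days=10_000)
        assert fu.rank_by_ae_probability(model, self._posts(), far_future) == []

    def test_floor_at_minimum_includes_all_and_order_matches_brute_force(self):
        model = fu.train_nb(syn.generate_labeled_posts(100, 100, seed=0))
        posts = self._posts()
        floor = min(p.timestamp for p in posts)
        ranked = fu.rank_by_ae_probability(model, posts, floor)
        assert len(ranked) == len(posts)
        oracle = sorted(
            [(model.predict_proba(p.text), p.post_id) for p in posts],
            key=lambda t: (-t[0], t[1]))
        assert [r.post.post_id for r in ranked] == [pid for _, pid in oracle]


REQS = {"fracture": ["diagnosis_confirmation", "time_to_onset", "duration",
                     "risk_factors", "history_of_similar_events",
                     "concomitant_medication", "relevant_medical_history"]}


class TestCompleteness:
    def test_nothing_missing_means_no_followup(self):
        out = fu.assess_completeness("fracture", REQS["fracture"], REQS)
        assert out.complete and out.missing == () and out.questions == ()

    def test_nothing_provided_asks_all_seven(self):
        out = fu.assess_completeness("fracture", [], REQS)
        assert len(out.missing) == 7 and len(out.questions) == 7
        assert len(out.question_texts) == 7

    def test_set_difference_matches_elementwise_oracle(self):
        provided = ["duration", "risk_factors"]
        out = fu.assess_completeness("fracture", provided, REQS)
        oracle = {e for e in REQS["fracture"] if e not in provided}
        assert set(out.missing) == oracle

    def test_short_list_padded_to_four_with_generics_first(self):
        provided = [e for e in REQS["fracture"] if e != "time_to_onset"]
        out = fu.assess_completeness("fracture", provided, REQS)
        assert out.missing == ("time_to_onset",)
        assert len(out.questions) == 4
        assert out.questions[0] == "time_to_onset"
        assert set(out.questions[1:3]) == {"outcome", "action_taken"}

    def test_question_count_never_exceeds_eleven(self):
        reqs = {"x": list(fu.ELEMENTS)}
        out = fu.assess_completeness("x", [], reqs)
        assert fu.MIN_QUESTIONS <= len(out.questions) <= fu.MAX_QUESTIONS

    def test_unknown_ae_class_rejected(self):
        with pytest.raises(KeyError):
            fu.assess_completeness("unknown", [], REQS)


def make_case(i, author=None, similarity="fall", serious=True, missing=("outcome",)):
    return fu.FollowUpCase(
        post_id=f"p{i:03d}", author_id=author or f"a{i:03d}", drug="denosumab",
        serious=serious, similarity_class=similarity,
        missing_elements=list(missing),
        questions=["diagnosis_confirmation", "time_to_onset", "outcome", "action_taken"],
    )


class TestSelection:
    def test_similarity_class_capped_at_two(self):
        cases = [make_case(i, similarity="same") for i in range(3)]
        with pytest.warns(UserWarning):
            sel = fu.select_candidates(cases, fu.SelectionConfig(pool_size=30, seed=0))
        assert len(sel.pool) == 2

    def test_one_case_per_author(self):
        cases = [make_case(0, author="a"), make_case(1, author="a", similarity="other")]
        with pytest.warns(UserWarning):
            sel = fu.select_candidates(cases, fu.SelectionConfig(seed=0))
        assert len(sel.pool) == 1

    def test_non_serious_and_complete_cases_excluded(self):
        cases = [make_case(0, serious=False), make_case(1, missing=()), make_case(2)]
        with pytest.warns(UserWarning, match="widening"):
            sel = fu.select_candidates(cases, fu.SelectionConfig(seed=0))
        assert [c.post_id for c in sel.pool] == ["p002"] and sel.widened
        assert all(c.serious and c.missing_elements for c in sel.pool)

    def test_matches_brute_force_filter_then_sample(self):
        rng = np.random.default_rng(77)
        classes = ["fall", "rash", "fatigue", "gi", "cardiac", "other"]
        cases = [
            make_case(i, author=f"a{int(rng.integers(40)):03d}",
                      similarity=classes[int(rng.integers(len(classes)))],
                      serious=bool(rng.random() < 0.8),
                      missing=("outcome",) if rng.random() < 0.9 else ())
            for i in range(120)
        ]
        config = fu.SelectionConfig(pool_size=30, batch_size=15,
                                    max_per_similarity_class=2, max_per_author=1, seed=5)
        with pytest.warns(UserWarning):  # 6 classes x 2 caps the pool at 12
            sel = fu.select_candidates(cases, config)
        # independent re-implementation of the documented algorithm
        eligible = [c for c in cases if c.serious and c.missing_elements]
        order = np.random.default_rng(5).permutation(len(eligible))
        oracle, pc, pa = [], Counter(), Counter()
        for idx in order:
            c = eligible[int(idx)]
            if len(oracle) >= 30 or pc[c.similarity_class] >= 2 or pa[c.author_id] >= 1:
                continue
            oracle.append(c.post_id)
            pc[c.similarity_class] += 1
            pa[c.author_id] += 1
        assert [c.post_id for c in sel.pool] == oracle
        # caps hold on the output itself
        assert max(Counter(c.similarity_class for c in sel.pool).values()) <= 2
        assert max(Counter(c.author_id for c in sel.pool).values()) <= 1
        assert all(len(b) <= 15 for b in sel.batches)


class TestCaseValidation:
    def test_timeline_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            fu.FollowUpCase(post_id="p", author_id="a", drug="d",
                            contacted_at=T0 + timedelta(days=2), consented_at=T0)

    def test_question_count_bounds_enforced_when_sent(self):
        with pytest.raises(ValueError, match="questions sent"):
            fu.FollowUpCase(post_id="p", author_id="a", drug="d",
                            questions=["outcome"], contacted_at=T0,
                            consented_at=T0, questions_sent_at=T0)

    def test_answers_must_be_subset_of_questions(self):
        with pytest.raises(ValueError, match="unasked"):
            fu.FollowUpCase(post_id="p", author_id="a", drug="d",
                            questions=["outcome"], answers={"dose": True})


class TestEngagement:
    def test_printed_rates(self):
        cases = []
        for i in range(39):
            c = make_case(i)
            c.contacted_at = T0
            if i < 8:
                c.consented_at = T0 + timedelta(days=1)
                c.questions_sent_at = T0 + timedelta(days=1, hours=2)
            if i < 6:
                c.received_at = T0 + timedelta(days=2)
                c.answers = {q: True for q in c.questions}
            cases.append(c)
        m = fu.engagement_metrics(cases)
        assert (m.n_sent, m.n_consented, m.n_received) == (39, 8, 6)
        assert m.consent_rate == 21.0      # 8/39
        assert m.receipt_rate == 75.0      # 6/8
        assert m.question_completeness == 100.0
        assert m.n_sent >= m.n_consented >= m.n_received

    def test_median_midpoint_and_ranges(self):
        days = [0.0, 1.0, 2.0, 27.0]
        summary = fu._day_summary(days)
        assert summary == {"median": 1.5, "min": 0.0, "max": 27.0}
        assert fu._day_summary([0.5])["median"] == 0.5

    def test_received_without_questions_rejected(self):
        c = make_case(0)
        c.contacted_at, c.received_at = T0, T0 + timedelta(days=1)
        with pytest.raises(ValueError, match="questions never sent"):
            fu.engagement_metrics([c])

    def test_metrics_invariant_to_case_order_and_match_configured_rates(self):
        pool = [make_case(i) for i in range(1000)]
        cases = fu.run_followup_campaign(
            pool, start_date=T0, consent_p=0.205, receipt_p=0.75, seed=11,
            batch_size=1000, target_received=None)
        m1 = fu.engagement_metrics(cases)
        m2 = fu.engagement_metrics(list(reversed(cases)))
        assert m1 == m2
        # configured probabilities recovered within 3 binomial SE
        se_consent = math.sqrt(0.205 * 0.795 / 1000)
        assert abs(m1.n_consented / m1.n_sent - 0.205) < 3 * se_consent
        se_receipt = math.sqrt(0.75 * 0.25 / m1.n_consented)
        assert abs(m1.n_received / m1.n_consented - 0.75) < 3 * se_receipt
        # timelines are valid and turnaround summaries ordered
        assert m1.days_from_questions["median"] <= m1.days_from_contact["median"]

    def test_campaign_replaces_declines_until_target(self):
        pool = [make_case(i) for i in range(200)]
        cases = fu.run_followup_campaign(pool, start_date=T0, consent_p=0.5,
                                         receipt_p=1.0, seed=3, batch_size=15,
                                         target_received=15)
        received = [c for c in cases if c.received_at is not None]
        assert len(received) >= 15
        assert len(cases) > 15  # replacements were drawn from the remainder

    def test_agreement_report(self):
        a = [make_case(i, missing=("outcome", "dose")) for i in range(4)]
        b = [make_case(i, missing=("outcome",)) for i in range(4)]
        rep = fu.agreement_report(a, b)
        assert rep["outcome"] == 100.0 and rep["dose"] == 0.0
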