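"""Author dossiers, complexity scoring, ranking, and insight coverage."""
from __future__ import annotations

import random
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from forumvigil import linking as lk
from forumvigil.ingest import CleanPost
from forumvigil.terminology import MatchedEvent

T0 = datetime(2015, 1, 1, tzinfo=timezone.utc)


def clean_post(pid, author, days=0, text="an update", thread="t1", drugs=("denosumab",)):
    return CleanPost(forum="f", post_id=pid, thread_id=thread, author_id=author,
                     timestamp=T0 + timedelta(days=days), text=text,
                     masked_text=text, drug_mentions=frozenset(drugs))


class TestBuildDossiers:
    def test_partition_three_authors_five_posts(self):
        posts = [clean_post("p1", "a"), clean_post("p2", "b"), clean_post("p3", "a"),
                 clean_post("p4", "c"), clean_post("p5", "b")]
        dossiers = lk.build_dossiers(posts)
        assert len(dossiers) == 3
        assert sum(len(d.posts) for d in dossiers) == 5

    def test_single_post_author_is_legal(self):
        [d] = lk.build_dossiers([clean_post("p1", "solo")])
        assert len(d.posts) == 1

    def test_within_dossier_order_time_then_id(self):
        posts = [clean_post("p2", "a", days=3), clean_post("p3", "a", days=1),
                 clean_post("p1", "a", days=1)]
        [d] = lk.build_dossiers(posts)
        assert [p.post_id for p in d.posts] == ["p1", "p3", "p2"]

    def test_missing_author_listed_in_error(self):
        bad = clean_post("p9", "a").model_copy(update={"author_id": ""})
        with pytest.raises(lk.ValidationError, match="p9"):
            lk.build_dossiers([bad])

    def test_corpus_sizes_match_groupby_oracle(self, pipeline):
        dossiers = lk.build_dossiers(pipeline.posts)
        oracle: dict[str, int] = {}
        for p in pipeline.posts:
            oracle[p.author_id] = oracle.get(p.author_id, 0) + 1
        assert {d.author_id: len(d.posts) for d in dossiers} == oracle


class TestComplexityScore:
    def test_default_registry_has_28_unit_weight_indicators(self):
        reg = lk.default_registry()
        assert len(reg) == lk.DEFAULT_REGISTRY_SIZE == 28
        assert all(ind.weight == 1.0 for ind in reg)
        assert len({ind.name for ind in reg}) == 28

    def test_empty_text_scores_only_structural_indicators(self):
        posts = [clean_post(f"p{i}", "a", days=i, text="", thread=f"t{i}")
                 for i in range(12)]
        [d] = lk.build_dossiers(posts)
        score, vec = lk.complexity_score(d)
        by_name = dict(zip([i.name for i in lk.default_registry()], vec))
        assert by_name["posts_ge_10"] == 1.0
        assert by_name["threads_ge_3"] == 1.0
        assert by_name["drug_mention"] == 1.0
        # every lexicon/text indicator is off
        assert score == 3.0

    def test_all_indicators_fire_gives_28(self, terminology):
        text = (
            "I was diagnosed 3 years ago and my condition got worse, severe pain. "
            "I also take vitamin supplements and tried yoga. My lab results and "
            "blood test came back at 9.1 mg/dl. I used to take alendronate but "
            "switched to denosumab 60 mg dose, together with calcium. "
            "Days after the injection a reaction started because of the drug; "
            "I was prescribed cream to manage it and it resolved, but came back "
            "when I restarted. Not sure why? My doctor and my husband agree. "
            "It happened 2 weeks after the appointment."
        )
        posts = [clean_post(f"p{i:02d}", "a", days=10 * i, text=text, thread=f"t{i}")
                 for i in range(10)]
        [d] = lk.build_dossiers(posts, events=[
            MatchedEvent(f"p0{j}", f"PT000{j}", "x", 0, 1) for j in range(1, 6)
        ])
        score, vec = lk.complexity_score(d)
        missing = [ind.name for ind, v in zip(lk.default_registry(), vec) if v == 0.0]
        assert missing == [] and score == 28.0

    def test_invariant_to_post_order_permutation(self, pipeline):
        dossiers = lk.build_dossiers(pipeline.posts)
        d = max(dossiers, key=lambda d: len(d.posts))
        s1, v1 = lk.complexity_score(d)
        shuffled = list(d.posts)
        random.Random(3).shuffle(shuffled)
        [d2] = lk.build_dossiers(shuffled)
        s2, v2 = lk.complexity_score(d2)
        assert s1 == s2 and np.array_equal(v1, v2)

    def test_monotone_when_appending_posts(self, pipeline):
        dossiers = [d for d in lk.build_dossiers(pipeline.posts) if len(d.posts) >= 6]
        rng = random.Random(9)
        for d in rng.sample(dossiers, min(10, len(dossiers))):
            prev = -1.0
            for k in range(1, len(d.posts) + 1):
                prefix = lk.AuthorDossier(d.author_id, d.posts[:k], set(d.pt_codes))
                score, _ = lk.complexity_score(prefix)
                assert score >= prev
                prev = score

    def test_registry_size_mismatch_rejected(self):
        [d] = lk.build_dossiers([clean_post("p1", "a")])
        with pytest.raises(lk.ValidationError, match="27"):
            lk.complexity_score(d, lk.default_registry()[:27], expected_size=28)


class TestRankDossiers:
    def _scored(self, scores):
        dossiers = []
        for i, s in enumerate(scores):
            [d] = lk.build_dossiers([clean_post(f"p{i}", f"a{i}", days=i)])
            d.complexity = float(s)
            d.indicator_vector = np.zeros(28)
            dossiers.append(d)
        return dossiers

    def test_matches_brute_force_sort(self):
        rng = random.Random(5)
        scores = [rng.randint(0, 20) for _ in range(30)]
        dossiers = self._scored(scores)
        top = lk.rank_dossiers(dossiers, 10)
        oracle = sorted(dossiers, key=lambda d: (-d.complexity, d.first_post_at,
                                                 d.author_id))[:10]
        assert [d.author_id for d in top] == [d.author_id for d in oracle]

    def test_k_equals_n_returns_all_sorted(self):
        dossiers = self._scored([3, 1, 2])
        top = lk.rank_dossiers(dossiers, 3)
        assert [d.complexity for d in top] == [3.0, 2.0, 1.0]

    def test_tie_broken_by_earlier_first_post(self):
        a = lk.build_dossiers([clean_post("p1", "late", days=5)])[0]
        b = lk.build_dossiers([clean_post("p2", "early", days=1)])[0]
        for d in (a, b):
            d.complexity, d.indicator_vector = 7.0, np.zeros(28)
        assert [d.author_id for d in lk.rank_dossiers([a, b], 2)] == ["early", "late"]

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            lk.rank_dossiers(self._scored([1]), 2)


class TestPostsPerAuthor:
    def test_mean_presentation_truncates(self):
        # 16 authors, 1,672 posts in total, sizes spanning 11..534
        sizes = [534, 11] + [80] * 13 + [87]
        assert sum(sizes) == 1672 and len(sizes) == 16
        dossiers = []
        pid = 0
        for i, size in enumerate(sizes):
            posts = [clean_post(f"q{pid + j}", f"a{i}", days=j) for j in range(size)]
            pid += size
            dossiers.extend(lk.build_dossiers(posts))
        stats = lk.posts_per_author(dossiers)
        assert stats["n_posts"] == 1672 and stats["n_authors"] == 16
        assert stats["mean"] == pytest.approx(104.5)
        assert stats["mean_presented"] == 104
        assert stats["min"] == 11 and stats["max"] == 534


class TestInsightCoverage:
    def _ann(self, gid, n_true=7, ae=None, subs=()):
        fields = {c: i < n_true for i, c in enumerate(lk.INSIGHT_CATEGORIES)}
        if ae is not None:
            fields["ae_mention"] = ae
        if subs:
            fields["ae_mention"] = True
        fields.update({s: s in subs for s in lk.AE_SUBELEMENTS})
        return lk.InsightAnnotation(group_id=gid, **fields)

    def test_twelve_of_sixteen_is_75_percent(self):
        anns = [self._ann(f"g{i}", 7) for i in range(12)]
        anns += [self._ann(f"g{i}", 5, ae=True) for i in range(12, 16)]
        report = lk.insight_coverage(anns)
        assert report.n_all_seven == 12 and report.pct_all_seven == 75.0

    def test_all_false_annotations_give_zeros(self):
        anns = [lk.InsightAnnotation(group_id=f"g{i}") for i in range(4)]
        report = lk.insight_coverage(anns)
        assert all(v == 0 for v in report.category_counts.values())
        assert report.pct_all_seven == 0.0

    def test_counts_equal_column_sums_oracle(self, pipeline, matched_events):
        dossiers = lk.build_dossiers(pipeline.posts, matched_events)
        anns = [lk.auto_annotate(d) for d in dossiers[:60]]
        report = lk.insight_coverage(anns)
        matrix = np.array([[getattr(a, c) for c in lk.INSIGHT_CATEGORIES] for a in anns])
        assert list(report.category_counts.values()) == list(matrix.sum(axis=0))
        assert report.n_all_seven <= min(report.category_counts.values())

    def test_subelement_without_ae_mention_rejected(self):
        with pytest.raises(ValueError, match="time_to_onset"):
            lk.InsightAnnotation(group_id="g", time_to_onset=True)

    def test_single_post_all_seven_counted_separately(self):
        groups = [self._ann("g0", 7)]
        singles = [self._ann("s0", 7), self._ann("s1", 3)]
        report = lk.insight_coverage(groups, singles)
        assert report.n_single_posts == 2 and report.n_single_posts_all_seven == 1

    def test_csv_roundtrip(self, tmp_path):
        anns = [self._ann("g0", 7, subs=("outcome", "dose")), self._ann("g1", 2, ae=False)]
        path = tmp_path / "ann.csv"
        lk.write_annotations_csv(anns, path)
        assert lk.read_annotations_csv(path) == anns
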