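"""Ranking, precision–recall, tolerance sweep, and the nearness matrix."""

import numpy as np
import pytest

from nearsets import (
    CloudSpec,
    PerceptualObject,
    epsilon_sweep,
    gen_cloud,
    nearness_matrix,
    precision_recall,
    rank_database,
)
from nearsets.retrieval import (
    RetrievalReport,
    average_precision,
    pair_measure,
    report_from_matrix,
)

from oracles import disjoint_copy


def cloud_db(seeds, labels, n=12):
    """A tiny database of 1-feature object sets from seeded clouds."""
    db, cats = {}, {}
    for (name, seed), cat in zip(seeds.items(), labels):
        db[name] = gen_cloud(CloudSpec(n=n, l=1, k=1, std=0.03, seed=seed))
        cats[name] = cat
    return db, cats


def report_with(ranked_relevance, query_cat="a"):
    """Build a report with prescribed relevant/irrelevant ranking."""
    ranked = [(f"im{i}", 1.0 - 0.01 * i) for i in range(len(ranked_relevance))]
    cats = {
        f"im{i}": (query_cat if rel else "other")
        for i, rel in enumerate(ranked_relevance)
    }
    return RetrievalReport(
        query_id="q",
        epsilon=0.1,
        measure="tnm",
        ranked=ranked,
        categories=cats,
        query_category=query_cat,
    )


class TestRankDatabase:
    def test_identical_copy_ranks_first_with_measure_one(self):
        query = gen_cloud(CloudSpec(n=10, l=1, k=1, std=0.05, seed=1))
        db = {
            "twin": disjoint_copy(query),
            "far": [
                PerceptualObject(id=f"f{i}", set_label="far", description=(0.95,))
                for i in range(10)
            ],
        }
        report = rank_database(query, db, 0.05)
        assert report.ranked[0][0] == "twin"
        assert report.ranked[0][1] == pytest.approx(1.0)

    def test_tied_entries_ordered_by_image_id(self):
        query = [PerceptualObject(id="q0", set_label="q", description=(0.1,))]
        same = [PerceptualObject(id="d0", set_label="d", description=(0.9,))]
        db = {"b": list(same), "a": list(same), "c": list(same)}
        report = rank_database(query, db, 0.05)
        values = [v for _, v in report.ranked]
        assert len(set(values)) == 1
        assert [i for i, _ in report.ranked] == ["a", "b", "c"]

    def test_ranking_agrees_with_externally_sorted_pair_measures(self):
        db, cats = cloud_db(
            {"a1": 1, "a2": 2, "b1": 11, "b2": 12, "c1": 21, "c2": 22},
            ["a", "a", "b", "b", "c", "c"],
        )
        query = gen_cloud(CloudSpec(n=12, l=1, k=1, std=0.03, seed=1))
        report = rank_database(query, db, 0.1)
        external = sorted(
            ((im, pair_measure(query, objs, 0.1)) for im, objs in db.items()),
            key=lambda kv: (-kv[1], kv[0]),
        )
        assert [i for i, _ in report.ranked] == [i for i, _ in external]
        for (_, va), (_, vb) in zip(report.ranked, external):
            assert va == pytest.approx(vb)

    def test_empty_database_rejected(self):
        query = [PerceptualObject(id="q", set_label="q", description=(0.5,))]
        with pytest.raises(ValueError, match="empty"):
            rank_database(query, {}, 0.1)

    def test_retrieved_before_miss_counts_leading_same_category(self):
        db, cats = cloud_db(
            {"a1": 1, "a2": 2, "b1": 31, "b2": 32},
            ["a", "a", "b", "b"],
        )
        query = gen_cloud(CloudSpec(n=12, l=1, k=1, std=0.03, seed=1))
        report = rank_database(
            query, db, 0.1, labels=cats, query_id="q", query_category="a"
        )
        rel = report.relevance()
        expected = int(np.argmin(rel)) if not rel.all() else len(rel)
        assert report.retrieved_before_miss == expected


class TestPrecisionRecall:
    def test_perfect_ranking_has_unit_precision_through_all_relevant(self):
        report = report_with([True, True, True, False, False])
        p, r = precision_recall(report)
        assert p[:3] == pytest.approx([1.0, 1.0, 1.0])
        assert r[-1] == 1.0
        assert (np.diff(r) >= 0).all()

    def test_alternating_ranking_closed_form(self):
        report = report_with([True, False, True, False])
        p, _ = precision_recall(report)
        assert p == pytest.approx([1.0, 0.5, 2 / 3, 0.5])

    def test_random_ranking_matches_cumulative_count(self):
        rng = np.random.default_rng(17)
        rel = list(rng.uniform(size=20) < 0.4)
        if not any(rel):
            rel[0] = True
        report = report_with(rel)
        p, r = precision_recall(report)
        hits = np.cumsum(rel)
        assert p == pytest.approx(hits / np.arange(1, 21))
        assert r == pytest.approx(hits / hits[-1])

    def test_query_category_absent_is_degenerate(self):
        report = report_with([False, False])
        with pytest.raises(ValueError, match="absent"):
            precision_recall(report)

    def test_average_precision_of_perfect_ranking_is_one(self):
        report = report_with([True, True, False, False])
        assert average_precision(report) == 1.0


class TestNearnessMatrix:
    def test_six_image_matrix_matches_pairwise_recomputation(self):
        db, _ = cloud_db(
            {"a1": 1, "a2": 2, "b1": 11, "b2": 12, "c1": 21, "c2": 22},
            ["a", "a", "b", "b", "c", "c"],
        )
        mat = nearness_matrix(db, 0.1)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)
        ids = mat.ids
        for i in range(6):
            for j in range(i + 1, 6):
                v = pair_measure(db[ids[i]], db[ids[j]], 0.1)
                assert mat.values[i, j] == pytest.approx(v)

    def test_two_identical_images_have_unit_off_diagonal(self):
        base = gen_cloud(CloudSpec(n=10, l=1, k=1, std=0.05, seed=3))
        db = {"u": base, "v": disjoint_copy(base)}
        mat = nearness_matrix(db, 0.05)
        assert mat.values[0, 1] == pytest.approx(1.0)

    def test_png_rendering_round_trip(self, tmp_path):
        db, _ = cloud_db({"a1": 1, "b1": 31}, ["a", "b"])
        mat = nearness_matrix(db, 0.1)
        out = tmp_path / "matrix.png"
        mat.to_png(out, scale=2)
        from PIL import Image

        arr = np.asarray(Image.open(out))
        assert arr.shape == (4, 4)
        assert arr.max() == 255  # the unit diagonal renders white


class TestEpsilonSweep:
    def test_single_category_database_rejected(self):
        db, cats = cloud_db({"a1": 1, "a2": 2}, ["a", "a"])
        with pytest.raises(ValueError, match="two categories"):
            epsilon_sweep(db, cats, [0.1])

    def test_empty_grid_rejected(self):
        db, cats = cloud_db({"a1": 1, "b1": 31}, ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            epsilon_sweep(db, cats, [])

    def test_tiny_epsilon_is_the_degenerate_regime(self):
        # clouds far apart: at eps too small to relate anything across
        # images every measure is 0 and counts collapse
        db, cats = cloud_db({"a1": 1, "a2": 2, "b1": 31, "b2": 32}, ["a", "a", "b", "b"])
        result = epsilon_sweep(db, cats, [1e-6, 0.2])
        degenerate = result.entries[0]
        off_diag = degenerate.matrix.values[~np.eye(4, dtype=bool)]
        assert (off_diag == 0).all()

    def test_sweep_summary_matches_recomputation_from_stored_matrices(self):
        db, cats = cloud_db(
            {"a1": 1, "a2": 2, "b1": 11, "b2": 12, "c1": 21, "c2": 22},
            ["a", "a", "b", "b", "c", "c"],
        )
        result = epsilon_sweep(db, cats, [0.05, 0.2], precision_floor=0.9)
        for entry in result.entries:
            counts = {}
            for image_id in entry.matrix.ids:
                report = report_from_matrix(entry.matrix, image_id, cats)
                below = report.precision_at_k < 0.9
                counts[image_id] = (
                    int(np.argmax(below)) if below.any() else len(report.ranked)
                )
            assert counts == entry.counts
            assert entry.mean_count == pytest.approx(np.mean(list(counts.values())))
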