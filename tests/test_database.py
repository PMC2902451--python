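import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnagauss import (
    DescriptorDatabase,
    GaussDescriptor,
    build_database,
    compare,
    descriptor_distance,
    read_descriptors_tsv,
    roc_curve,
    scan,
    significance,
    update_database,
    write_descriptors_tsv,
)
from rnagauss.database import BackgroundDistribution
from rnagauss.synthetic import helix, perturbed_copy, random_walk, write_fixture_pdb


def desc(eid, vec):
    v = np.zeros(30)
    v[: len(vec)] = vec
    return GaussDescriptor(eid, v)


@pytest.fixture
def fixture_files(tmp_path):
    """Five valid synthetic chains plus one too-short chain on disk."""
    paths = {}
    curves = {
        "helix": helix(20, entry_id="HLX_A"),
        "walk1": random_walk(20, seed=1, entry_id="WLK1_A"),
        "walk2": random_walk(20, seed=2, entry_id="WLK2_A"),
        "walk3": random_walk(24, seed=3, entry_id="WLK3_A"),
        "walk4": random_walk(16, seed=4, entry_id="WLK4_A"),
    }
    for name, curve in curves.items():
        paths[name] = write_fixture_pdb(curve, tmp_path / f"{name}.pdb")
    from rnagauss.synthetic import planar_zigzag

    paths["short"] = write_fixture_pdb(planar_zigzag(7), tmp_path / "short.pdb")
    return paths


class TestDistance:
    def test_identity(self):
        d = desc("a", [1.0, 2.0])
        assert descriptor_distance(d, d) == 0.0

    def test_single_axis(self):
        assert descriptor_distance(desc("a", [10.0]), desc("b", [7.0])) == 3.0

    def test_version_mismatch_rejected(self):
        a = desc("a", [1.0])
        b = GaussDescriptor("b", np.zeros(30), version="other-enumeration")
        with pytest.raises(ValueError):
            descriptor_distance(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (desc(k, rng.normal(size=30)) for k in "abc")
        dab = descriptor_distance(a, b)
        assert dab >= 0.0
        assert dab == descriptor_distance(b, a)
        assert descriptor_distance(a, c) <= dab + descriptor_distance(b, c) + 1e-12


class TestSignificance:
    def make_db(self, sample):
        return DescriptorDatabase(
            entries={"x": desc("x", [0.0])},
            background=BackgroundDistribution(sample=sample),
        )

    def test_zero_distance_with_positive_background(self):
        assert significance(0.0, self.make_db([1.0, 2.0, 3.0])) == 1.0

    def test_above_maximum(self):
        assert significance(4.0, self.make_db([1.0, 2.0, 3.0])) == 0.0

    def test_strict_inequality_at_tie(self):
        # "larger than" is strict: a background value equal to D does not count
        assert significance(2.0, self.make_db([1.0, 2.0, 3.0, 4.0])) == 0.5

    def test_monotone_non_increasing(self):
        db = self.make_db(np.random.default_rng(0).uniform(0, 5, 200))
        grid = np.linspace(-1, 6, 100)
        values = [significance(d, db) for d in grid]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_background_rejected(self):
        db = DescriptorDatabase(entries={"x": desc("x", [0.0])})
        with pytest.raises(ValueError):
            significance(1.0, db)

    def test_histogram_fallback_approximates_sample(self):
        sample = np.random.default_rng(1).uniform(0, 10, 5000)
        exact = BackgroundDistribution(sample=sample)
        edges = np.linspace(0, 10, 10_001)
        counts, _ = np.histogram(sample, bins=edges)
        binned = BackgroundDistribution(bin_edges=edges, counts=counts)
        for d in (0.5, 3.3, 9.9):
            assert binned.survival(d) == pytest.approx(exact.survival(d), abs=1e-2)


class TestBuildUpdate:
    def test_build_counts_entries_and_background(self, fixture_files):
        db = build_database([fixture_files[k] for k in ("helix", "walk1", "walk2")])
        assert len(db) == 3
        assert db.background.size == 3  # C(3,2)

    def test_short_chain_skipped_and_logged(self, fixture_files, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="rnagauss.database"):
            db = build_database(
                [fixture_files["helix"], fixture_files["walk1"], fixture_files["short"]]
            )
        assert len(db) == 2
        assert any("short" in p for p, _ in db.skipped)
        assert "short" in caplog.text

    def test_rebuild_is_deterministic(self, fixture_files):
        paths = [fixture_files[k] for k in ("helix", "walk1", "walk2")]
        a = build_database(paths)
        b = build_database(paths)
        assert np.array_equal(a.background.sample, b.background.sample)
        for eid in a.entries:
            assert np.array_equal(a.entries[eid].vector, b.entries[eid].vector)

    def test_no_valid_chains_rejected(self, fixture_files):
        with pytest.raises(ValueError):
            build_database([fixture_files["short"]])

    def test_update_idempotent_for_existing_id(self, fixture_files):
        paths = [fixture_files[k] for k in ("helix", "walk1", "walk2")]
        db = build_database(paths)
        updated = update_database(db, [fixture_files["helix"]])
        assert set(updated.entries) == set(db.entries)
        assert updated.background.size == db.background.size

    def test_update_equals_full_rebuild(self, fixture_files):
        """update(build(A), B) and build(A u B) agree entry-wise and give
        the same background distance multiset."""
        a_paths = [fixture_files[k] for k in ("helix", "walk1", "walk2")]
        b_paths = [fixture_files[k] for k in ("walk3", "walk4")]
        incremental = update_database(build_database(a_paths), b_paths)
        full = build_database(a_paths + b_paths)
        assert set(incremental.entries) == set(full.entries)
        assert np.allclose(
            np.sort(incremental.background.sample),
            np.sort(full.background.sample),
        )

    def test_update_with_short_chain_leaves_db_unchanged(self, fixture_files):
        db = build_database([fixture_files["helix"], fixture_files["walk1"]])
        updated = update_database(db, [fixture_files["short"]])
        assert set(updated.entries) == set(db.entries)
        assert any("short" in p for p, _ in updated.skipped)

    def test_update_version_guard(self, fixture_files):
        db = build_database([fixture_files["helix"], fixture_files["walk1"]])
        db.version = "other-enumeration"
        with pytest.raises(ValueError):
            update_database(db, [fixture_files["walk2"]])


class TestScan:
    def make_db(self, n=15, seed=0):
        rng = np.random.default_rng(seed)
        entries = {}
        for i in range(n):
            entries[f"E{i:02d}"] = desc(f"E{i:02d}", rng.uniform(0, 0.1, size=5))
        sample = [
            descriptor_distance(a, b)
            for i, a in enumerate(entries.values())
            for b in list(entries.values())[i + 1:]
        ]
        return DescriptorDatabase(
            entries=entries, background=BackgroundDistribution(sample=sample)
        )

    def test_query_equal_to_entry_is_first_hit(self):
        db = self.make_db()
        query = db.entries["E07"]
        hits = scan(query, db)
        assert hits[0].entry_id == "E07"
        assert hits[0].distance == 0.0
        assert hits[0].significance == 1.0

    def test_cutoff_below_minimum_gives_empty_list(self):
        db = self.make_db()
        query = desc("far", [100.0])
        assert scan(query, db, cutoff=1.0) == []

    def test_defaults_cap_at_ten(self):
        # 15 entries all within the default cutoff 0.5 -> exactly 10 hits
        db = self.make_db()
        hits = scan(db.entries["E00"], db)
        assert len(hits) == 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 1.0))
    def test_matches_naive_filter_and_sort(self, seed, cutoff):
        """Scan output equals filtering every entry by the cutoff, sorting
        by (distance, id) and truncating."""
        db = self.make_db(n=12, seed=seed)
        query = desc("q", np.random.default_rng(seed + 1).uniform(0, 0.1, size=5))
        hits = scan(query, db, cutoff=cutoff, top_n=5)
        naive = sorted(
            (descriptor_distance(query, d), eid)
            for eid, d in db.entries.items()
            if descriptor_distance(query, d) <= cutoff
        )[:5]
        assert [(h.distance, h.entry_id) for h in hits] == naive
        assert all(
            hits[i].distance <= hits[i + 1].distance for i in range(len(hits) - 1)
        )

    def test_tie_break_lexicographic(self):
        entries = {k: desc(k, [1.0]) for k in ("B", "A", "C")}
        db = DescriptorDatabase(
            entries=entries, background=BackgroundDistribution(sample=[0.0, 0.0, 0.0])
        )
        hits = scan(desc("q", [1.0]), db, cutoff=0.5, top_n=3)
        assert [h.entry_id for h in hits] == ["A", "B", "C"]

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            scan(desc("q", [0.0]), DescriptorDatabase())


class TestCompare:
    def test_with_and_without_background(self):
        a, b = desc("a", [0.0]), desc("b", [2.0])
        bare = compare(a, b)
        assert bare.distance == 2.0 and bare.significance is None
        db = DescriptorDatabase(
            entries={"a": a},
            background=BackgroundDistribution(sample=[1.0, 3.0, 5.0, 7.0]),
        )
        with_bg = compare(a, b, db)
        assert with_bg.significance == 0.75
        assert with_bg.background_size == 4


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, fixture_files):
        db = build_database([fixture_files[k] for k in ("helix", "walk1", "walk2")])
        path = tmp_path / "db.json"
        db.save(path)
        loaded = DescriptorDatabase.load(path)
        assert set(loaded.entries) == set(db.entries)
        for eid in db.entries:
            assert np.array_equal(loaded.entries[eid].vector, db.entries[eid].vector)
        assert np.array_equal(loaded.background.sample, db.background.sample)
        assert loaded.version == db.version

    def test_load_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text(json.dumps({"hello": 1}))
        with pytest.raises(ValueError):
            DescriptorDatabase.load(path)

    def test_tsv_roundtrip(self, tmp_path, fixture_files):
        db = build_database([fixture_files["helix"], fixture_files["walk1"]])
        path = write_descriptors_tsv(db, tmp_path / "d.tsv")
        back = read_descriptors_tsv(path)
        assert set(back.entries) == set(db.entries)
        for eid in db.entries:
            assert np.array_equal(back.entries[eid].vector, db.entries[eid].vector)


class TestRoc:
    def pairwise(self, vectors):
        v = np.asarray(vectors, dtype=float)
        diff = v[:, None, :] - v[None, :, :]
        return np.linalg.norm(diff, axis=2)

    def test_perfect_separation_gives_auc_one(self):
        rng = np.random.default_rng(0)
        cluster_a = rng.normal(0, 0.01, size=(5, 3))
        cluster_b = rng.normal(10, 0.01, size=(5, 3))
        d = self.pairwise(np.vstack([cluster_a, cluster_b]))
        roc = roc_curve(d, [0] * 5 + [1] * 5)
        assert roc.auc == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(42)
        d = self.pairwise(rng.normal(size=(25, 4)))
        labels = rng.permutation([0] * 13 + [1] * 12)
        roc = roc_curve(d, labels)
        assert 0.35 < roc.auc < 0.65

    def test_hand_enumerated_toy_auc(self):
        """6 items, 2 clusters: within-pair distances {1..5,7}, between
        {6,8..15}; 53 of the 54 (within, between) orderings are correct,
        so AUC = 53/54 by the rank (Mann-Whitney) identity."""
        within = [1, 2, 3, 4, 5, 7]
        between = [6, 8, 9, 10, 11, 12, 13, 14, 15]
        d = np.zeros((6, 6))
        pairs_within = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        pairs_between = [(i, j) for i in range(3) for j in range(3, 6)]
        for (i, j), v in zip(pairs_within, within):
            d[i, j] = d[j, i] = v
        for (i, j), v in zip(pairs_between, between):
            d[i, j] = d[j, i] = v
        roc = roc_curve(d, [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(53 / 54)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        d = self.pairwise(rng.normal(size=(12, 5)))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        roc = roc_curve(d, labels)
        iu, ju = np.triu_indices(12, k=1)
        same = (labels[iu] == labels[ju]).astype(int)
        ref = roc_auc_score(same, -d[iu, ju])
        assert roc.auc == pytest.approx(ref, abs=1e-12)

    def test_single_cluster_rejected(self):
        d = self.pairwise(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            roc_curve(d, [0, 0, 0, 0])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        d = self.pairwise(rng.normal(size=(10, 3)))
        roc = roc_curve(d, [0] * 5 + [1] * 5)
        assert roc.sensitivity[0] == 0.0 and roc.one_minus_specificity[0] == 0.0
        assert roc.sensitivity[-1] == 1.0 and roc.one_minus_specificity[-1] == 1.0
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.one_minus_specificity) >= 0)
        assert 0.0 <= roc.auc <= 1.0
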