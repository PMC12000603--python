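"""Task builders and episode sampling: partition arithmetic, determinism,
cluster bookkeeping, and support/query contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnproto import synthetic, tasks
from rxnproto.data import split_dataset
from rxnproto.features import fingerprints as fp


class TestRandomTasks:
    def test_partition_sizes(self, medium_encoded):
        ds, _, X = medium_encoded
        out = tasks.random_tasks(ds, 5, seed=1, features=X)
        assert len(out) == 5
        sizes = [len(t) for t in out]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(ds)

    def test_union_is_dataset(self, medium_encoded):
        ds, _, X = medium_encoded
        out = tasks.random_tasks(ds, 4, seed=2, features=X)
        ids = [rid for t in out for rid in t.record_ids]
        assert sorted(ids) == sorted(ds.record_ids)
        assert len(set(ids)) == len(ids)

    def test_deterministic(self, medium_encoded):
        ds, _, X = medium_encoded
        a = tasks.random_tasks(ds, 5, seed=9)
        b = tasks.random_tasks(ds, 5, seed=9)
        assert [t.record_ids for t in a] == [t.record_ids for t in b]

    def test_too_many_tasks_raises(self, tiny_dataset):
        with pytest.raises(ValueError):
            tasks.random_tasks(tiny_dataset, 50, seed=0)


class TestClustering:
    @pytest.fixture(scope="class")
    def two_pool_clusters(self):
        """Two well-separated component pools; k=2 must recover them."""
        ds, truth = synthetic.generate(synthetic.GeneratorConfig(
            n_records=240, n_clusters=2, seed=5))
        scaler = fp.fit_condition_scaler(ds)
        X = fp.encode_dataset(ds, scaler)
        model = tasks.fit_clusters(ds, X, k=2, seed=5)
        return ds, truth, model

    def test_two_separated_pools_recovered(self, two_pool_clusters):
        from sklearn.metrics import adjusted_rand_score
        ds, truth, model = two_pool_clusters
        found = model.clusters_of(ds)
        assert adjusted_rand_score(truth["cluster"].to_numpy(), found) == 1.0

    def test_every_record_assigned(self, two_pool_clusters):
        ds, _, model = two_pool_clusters
        clusters = model.clusters_of(ds)
        assert set(np.unique(clusters)) <= set(range(model.k))
        assert len(clusters) == len(ds)

    def test_k_one_degenerate(self, tiny_dataset, tiny_encoded):
        model = tasks.fit_clusters(tiny_dataset, tiny_encoded, k=1, seed=0)
        assert set(model.assignment.values()) == {0}

    def test_cluster_tasks_partition(self, two_pool_clusters):
        ds, _, model = two_pool_clusters
        train, test, _ = split_dataset(ds, (160, 60, 20), seed=1)
        t_train, t_test = tasks.cluster_tasks(model, train, test)
        # conservation: each side's tasks partition that side's records
        got = sorted(r for t in t_train for r in t.record_ids)
        assert got == sorted(train.record_ids)
        got = sorted(r for t in t_test for r in t.record_ids)
        assert got == sorted(test.record_ids)
        # matched pairs share cluster ids
        train_cl = {t.cluster_id for t in t_train}
        test_cl = {t.cluster_id for t in t_test}
        assert test_cl <= train_cl

    def test_loco_folds(self, two_pool_clusters):
        ds, _, model = two_pool_clusters
        folds = tasks.loco_folds(model, ds)
        assert len(folds) == model.k
        held = [fold_test.record_ids for _, fold_test in folds]
        # held-out tasks are pairwise disjoint and each fold conserves records
        assert not set(held[0]) & set(held[1])
        for train_tasks, fold_test in folds:
            ids = sorted(r for t in train_tasks for r in t.record_ids)
            assert sorted(ids + list(fold_test.record_ids)) == sorted(ds.record_ids)


class TestEpisodes:
    @pytest.fixture(scope="class")
    def task(self, medium_encoded):
        ds, _, X = medium_encoded
        return tasks.random_tasks(ds, 2, seed=0, features=X)[0]

    def test_sizes_and_disjoint(self, task):
        ep = tasks.sample_episode(task, 16, 128, seed=3)
        assert len(ep.support_idx) == 16 and len(ep.query_idx) == 128
        assert not set(ep.support_idx) & set(ep.query_idx)

    def test_support_has_both_classes(self, task):
        for seed in range(10):
            ep = tasks.sample_episode(task, 16, 64, seed=seed)
            assert len(np.unique(task.labels[ep.support_idx])) == 2

    def test_ten_seeds_give_distinct_splits(self, task):
        splits = {tuple(tasks.sample_episode(task, 16, 128, seed=s).support_idx)
                  for s in range(10)}
        assert len(splits) == 10

    def test_oversized_episode_raises(self, task):
        with pytest.raises(ValueError):
            tasks.sample_episode(task, len(task), 10, seed=0)

    def test_single_class_task_raises_by_name(self, medium_encoded):
        ds, _, X = medium_encoded
        idx = np.flatnonzero(ds.labels == 1)[:20]
        t = tasks.Task("mono", [ds.records[i].record_id for i in idx],
                       np.ones(20, dtype=int), "random")
        with pytest.raises(ValueError, match="mono"):
            tasks.sample_episode(t, 4, 4, seed=0)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_disjointness_for_every_seed(self, task, seed):
        ep = tasks.sample_episode(task, 32, 64, seed=seed)
        assert not set(ep.support_idx) & set(ep.query_idx)

    def test_manifest_round_trip(self, task, tmp_path):
        ep = tasks.sample_episode(task, 8, 16, seed=1)
        path = tmp_path / "episodes.json"
        tasks.save_manifest(path, [ep], {task.task_id: task})
        import json
        payload = json.loads(path.read_text())
        assert payload[0]["support"] == [task.record_ids[i]
                                         for i in ep.support_idx]
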