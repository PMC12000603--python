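"""Meta-learning task construction and episode sampling.

Tasks are labelled subsets of a reaction dataset.  Three builders are
provided: random partition of a split into equal-size tasks; cluster-based
tasks from a UMAP (10 dims) + k-means model fitted on the full dataset's
fingerprint encoding; and leave-one-cluster-out folds.  Episodes are
disjoint support/query samples drawn from one task.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .data import ReactionDataset

logger = logging.getLogger(__name__)


@dataclass
class Task:
    """A labelled subset of one split, identified by record ids."""

    task_id: str
    record_ids: list[str]
    labels: np.ndarray
    origin: str                      # "random" | "cluster:<c>" | "loco-fold:<c>"
    features: np.ndarray | None = None   # optional (n, 1544) encoding
    records: list | None = None          # optional ReactionRecord list

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.record_ids) == 0:
            raise ValueError(f"task {self.task_id} is empty")
        if len(self.labels) != len(self.record_ids):
            raise ValueError(f"task {self.task_id}: labels misaligned")

    def __len__(self) -> int:
        return len(self.record_ids)

    @property
    def cluster_id(self) -> int | None:
        for prefix in ("cluster:", "loco-fold:"):
            if self.origin.startswith(prefix):
                return int(self.origin[len(prefix):])
        return None


@dataclass
class Episode:
    """Disjoint support/query index sets into a task."""

    support_idx: np.ndarray
    query_idx: np.ndarray
    task_id: str

    def __post_init__(self):
        s, q = set(self.support_idx.tolist()), set(self.query_idx.tolist())
        if s & q:
            raise ValueError("support and query overlap")
        if not s or not q:
            raise ValueError("support and query must be nonempty")

    def manifest(self, task: Task) -> dict:
        return {
            "task_id": self.task_id,
            "support": [task.record_ids[i] for i in self.support_idx],
            "query": [task.record_ids[i] for i in self.query_idx],
        }


def _make_task(dataset: ReactionDataset, idx: np.ndarray, task_id: str,
               origin: str, features: np.ndarray | None) -> Task:
    idx = np.asarray(idx, dtype=np.intp)
    return Task(
        task_id=task_id,
        record_ids=[dataset.records[i].record_id for i in idx],
        labels=dataset.labels[idx],
        origin=origin,
        features=None if features is None else features[idx],
        records=[dataset.records[i] for i in idx],
    )


def random_tasks(dataset: ReactionDataset, n_tasks: int, seed: int,
                 features: np.ndarray | None = None) -> list[Task]:
    """Randomly partition a labelled split into `n_tasks` near-equal tasks."""
    if n_tasks > len(dataset):
        raise ValueError(f"cannot make {n_tasks} tasks from {len(dataset)} records")
    if dataset.labels is None:
        raise ValueError("dataset must be labelled before task construction")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    chunks = np.array_split(perm, n_tasks)
    return [_make_task(dataset, np.sort(chunk), f"random-{t}", "random", features)
            for t, chunk in enumerate(chunks)]


@dataclass
class ClusterModel:
    """Fitted UMAP reducer + k-means centroids + per-record assignment."""

    reducer: object
    kmeans: object
    assignment: dict[str, int]       # record_id -> cluster in 0..k-1
    k: int

    def clusters_of(self, dataset: ReactionDataset) -> np.ndarray:
        return np.array([self.assignment[r.record_id] for r in dataset.records])


def fit_clusters(dataset: ReactionDataset, X: np.ndarray, k: int = 10,
                 reduced_dim: int = 10, seed: int = 0,
                 n_neighbors: int = 15, min_dist: float = 0.1) -> ClusterModel:
    """UMAP to `reduced_dim` dimensions, then k-means into `k` clusters.

    Fitted on the full dataset's fingerprint encoding (transductive by
    design: train and test rows are clustered together, labels unseen).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    import umap
    from sklearn.cluster import KMeans

    if k == 1:
        assignment = {r.record_id: 0 for r in dataset.records}
        return ClusterModel(None, None, assignment, 1)

    reducer = umap.UMAP(n_components=reduced_dim, n_neighbors=n_neighbors,
                        min_dist=min_dist, metric="euclidean",
                        random_state=seed)
    Z = reducer.fit_transform(X)
    for attempt in range(5):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=seed + attempt)
        labels = km.fit_predict(Z)
        if len(np.unique(labels)) == k:
            break
        logger.warning("k-means produced an empty cluster; re-running "
                       "(attempt %d)", attempt + 1)
    assignment = {r.record_id: int(c) for r, c in zip(dataset.records, labels)}
    return ClusterModel(reducer, km, assignment, k)


def cluster_tasks(model: ClusterModel, train: ReactionDataset,
                  test: ReactionDataset,
                  train_features: np.ndarray | None = None,
                  test_features: np.ndarray | None = None
                  ) -> tuple[list[Task], list[Task]]:
    """One train task and one test task per cluster.

    Clusters with no members on one side are dropped from that side with a
    log message; matched pairs share the cluster id in their origin tag.
    """
    out_train, out_test = [], []
    for side, ds, feats, out in (("train", train, train_features, out_train),
                                 ("test", test, test_features, out_test)):
        clusters = model.clusters_of(ds)
        for c in range(model.k):
            idx = np.flatnonzero(clusters == c)
            if idx.size == 0:
                logger.info("cluster %d has no %s records; dropped", c, side)
                continue
            out.append(_make_task(ds, idx, f"{side}-C{c}", f"cluster:{c}", feats))
    return out_train, out_test


def loco_folds(model: ClusterModel, dataset: ReactionDataset,
               features: np.ndarray | None = None
               ) -> list[tuple[list[Task], Task]]:
    """Leave-one-cluster-out folds: each cluster is the held-out test task
    exactly once; the remaining clusters form the training tasks."""
    if model.k < 2:
        raise ValueError("leave-one-cluster-out needs k >= 2")
    clusters = model.clusters_of(dataset)
    per_cluster = {c: np.flatnonzero(clusters == c) for c in range(model.k)}
    folds = []
    for held in range(model.k):
        if per_cluster[held].size == 0:
            logger.info("cluster %d empty; fold skipped", held)
            continue
        test_task = _make_task(dataset, per_cluster[held], f"loco-test-C{held}",
                               f"loco-fold:{held}", features)
        train_tasks = [
            _make_task(dataset, per_cluster[c], f"loco-train-C{c}",
                       f"loco-fold:{c}", features)
            for c in range(model.k) if c != held and per_cluster[c].size > 0
        ]
        folds.append((train_tasks, test_task))
    return folds


def sample_episode(task: Task, n_support: int, n_query: int, seed: int,
                   require_both_classes: bool = True,
                   max_retries: int = 50) -> Episode:
    """Sample a disjoint support/query split of a task without replacement.

    When `require_both_classes` the support must contain at least one
    example of each class; sampling is stratified, so the requirement fails
    only if the task itself is single-class.
    """
    n = len(task)
    if n_support + n_query > n:
        raise ValueError(
            f"task {task.task_id}: requested {n_support}+{n_query} > {n}")
    rng = np.random.default_rng(seed)
    classes = np.unique(task.labels)
    if require_both_classes and len(classes) < 2:
        raise ValueError(
            f"task {task.task_id} is single-class; cannot satisfy "
            "require_both_classes")
    for _ in range(max_retries):
        if require_both_classes and n_support >= 2:
            support = _stratified_sample(task.labels, n_support, rng)
        else:
            support = rng.choice(n, size=n_support, replace=False)
        rest = np.setdiff1d(np.arange(n), support)
        query = rng.choice(rest, size=n_query, replace=False)
        if not require_both_classes or len(np.unique(task.labels[support])) == 2:
            return Episode(np.sort(support), np.sort(query), task.task_id)
    raise ValueError(f"task {task.task_id}: could not sample a support set "
                     f"with both classes in {max_retries} tries")


def _stratified_sample(labels: np.ndarray, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Class-proportional sample with at least one per present class."""
    out = []
    classes = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in classes])
    quota = np.maximum(1, np.round(n * counts / counts.sum()).astype(int))
    quota = np.minimum(quota, counts)
    while quota.sum() > n:
        quota[np.argmax(quota)] -= 1
    while quota.sum() < n:
        room = counts - quota
        quota[np.argmax(room)] += 1
    for c, q in zip(classes, quota):
        pool = np.flatnonzero(labels == c)
        out.append(rng.choice(pool, size=q, replace=False))
    return np.concatenate(out)


def save_manifest(path, episodes: list[Episode], tasks: dict[str, Task]) -> None:
    """Serialize episodes as record-id lists so runs replay bit-exactly."""
    payload = [ep.manifest(tasks[ep.task_id]) for ep in episodes]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
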