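"""Single-task baselines: random forest, SVM, gradient boosting, and a GNN
classifier, each trained from scratch on whatever support set the protocol
supplies (no meta-learned state is reused).

All baselines expose ``predict_proba``-style positive-class scores and are
evaluated on the same episode manifests as the meta-learner so that every
method sees byte-identical query sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalReport, auprc, auroc
from .nn.autograd import Tensor, logsumexp
from .nn.layers import MLP, Adam
from .protonet import _support_sample, feasible_sizes
from .tasks import Task, sample_episode

logger = logging.getLogger(__name__)


@dataclass
class BaselineSpec:
    kind: str                                  # random_forest | gnn | svm | gradient_boosting
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("random_forest", "gnn", "svm", "gradient_boosting"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")


class _SklearnBaseline:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y, records=None):
        self.est.fit(X, y)
        return self

    def scores(self, X, records=None) -> np.ndarray:
        proba = self.est.predict_proba(X)
        pos = list(self.est.classes_).index(1)
        return proba[:, pos]


class GNNBaseline:
    """Graph encoder + 2-layer classification head, cross-entropy training.

    Consumes raw reaction records end-to-end through the MPNN featurizer.
    """

    def __init__(self, featurizer, scaler, seed: int, epochs: int = 60,
                 lr: float = 1e-3, head_dims: tuple[int, ...] = (1544, 128, 2)):
        self.featurizer = featurizer
        self.scaler = scaler
        self.epochs = epochs
        rng = np.random.default_rng(seed)
        self.head = MLP(list(head_dims), rng)
        self.rng = rng
        self.lr = lr

    def _logits(self, records) -> Tensor:
        X = self.featurizer.encode_records(records, self.scaler)
        return self.head(X)

    def fit(self, X, y, records=None):
        if records is None:
            raise ValueError("GNN baseline needs raw records")
        y = np.asarray(y)
        onehot = np.zeros((len(y), 2))
        onehot[np.arange(len(y)), y] = 1.0
        params = self.head.parameters() + self.featurizer.encoder.parameters()
        opt = Adam(params, lr=self.lr)
        for _ in range(self.epochs):
            logits = self._logits(records)
            log_p = logits - logsumexp(logits, axis=1, keepdims=True)
            loss = -(log_p * Tensor(onehot)).sum() * (1.0 / len(y))
            opt.zero_grad()
            loss.backward()
            opt.step()
        return self

    def scores(self, X, records=None) -> np.ndarray:
        logits = self._logits(records).data
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return (p / p.sum(axis=1, keepdims=True))[:, 1]


def fit_baseline(spec: BaselineSpec, X: np.ndarray | None, y: np.ndarray,
                 records=None, featurizer=None, scaler=None):
    """Build and fit a baseline model on a (support) training set."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set; resample the support")
    if spec.kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        hp = dict(n_estimators=500, class_weight="balanced",
                  random_state=spec.seed, n_jobs=1)
        hp.update(spec.hyperparameters)
        model = _SklearnBaseline(RandomForestClassifier(**hp))
    elif spec.kind == "svm":
        from sklearn.svm import SVC
        hp = dict(kernel="rbf", probability=True, random_state=spec.seed)
        hp.update(spec.hyperparameters)
        model = _SklearnBaseline(SVC(**hp))
    elif spec.kind == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingClassifier
        hp = dict(n_estimators=200, max_depth=3, random_state=spec.seed)
        hp.update(spec.hyperparameters)
        model = _SklearnBaseline(GradientBoostingClassifier(**hp))
    else:  # gnn
        hp = dict(spec.hyperparameters)
        model = GNNBaseline(featurizer, scaler, seed=spec.seed, **hp)
    return model.fit(X, y, records=records)


def evaluate_baseline(spec: BaselineSpec, test_tasks: list[Task],
                      protocol: str, support_size: int | str = 16,
                      n_repeats: int = 10, seed: int = 0,
                      query_size: int = 128,
                      train_support_task: Task | None = None,
                      train_tasks: list[Task] | None = None,
                      featurizer=None, scaler=None,
                      threshold: float = 80.0) -> EvalReport:
    """Evaluate a single-task baseline under the same protocols and report
    schema as the meta-learner (pooled per-repeat AUPRC/AUROC)."""
    if protocol not in ("episodic", "full_train_support", "cluster_support"):
        raise ValueError(f"unknown protocol {protocol!r}")
    by_cluster = {}
    if protocol == "cluster_support":
        if not train_tasks:
            raise ValueError("cluster_support needs the cluster train tasks")
        by_cluster = {t.cluster_id: t for t in train_tasks
                      if t.cluster_id is not None}
    if protocol == "episodic":
        usable = []
        for t in test_tasks:
            if len(np.unique(t.labels)) == 2:
                usable.append(t)
            else:
                logger.warning("task %s is single-class; dropped from "
                               "episodic evaluation", t.task_id)
        if not usable:
            raise ValueError("no test task has both classes")
        test_tasks = usable

    rng = np.random.default_rng(seed)
    report = EvalReport(method=spec.kind, protocol=protocol,
                        support_size=support_size, threshold=threshold)

    full_model = None
    if protocol == "full_train_support":
        if train_support_task is None:
            raise ValueError("full_train_support needs the training split")
        full_model = fit_baseline(
            spec, train_support_task.features, train_support_task.labels,
            records=train_support_task.records, featurizer=featurizer,
            scaler=scaler)

    for _ in range(n_repeats):
        labels, scores, manifest = [], [], []
        for task in test_tasks:
            if protocol == "episodic":
                s, q = feasible_sizes(len(task), int(support_size), query_size)
                ep = sample_episode(task, s, q, seed=int(rng.integers(2 ** 31)))
                model = fit_baseline(
                    spec,
                    None if task.features is None else task.features[ep.support_idx],
                    task.labels[ep.support_idx],
                    records=None if task.records is None
                    else [task.records[i] for i in ep.support_idx],
                    featurizer=featurizer, scaler=scaler)
                q_idx = ep.query_idx
                manifest.append(ep.manifest(task))
            elif protocol == "full_train_support":
                model = full_model
                nq = min(query_size, len(task))
                q_idx = np.sort(rng.choice(len(task), size=nq, replace=False))
                manifest.append({"task_id": task.task_id,
                                 "query": [task.record_ids[i] for i in q_idx]})
            else:
                c = task.cluster_id
                if c not in by_cluster:
                    raise ValueError(f"no training task for cluster {c}")
                src = by_cluster[c]
                if support_size == "full":
                    s_idx = np.arange(len(src))
                else:
                    s_idx = _support_sample(src, int(support_size), rng)
                model = fit_baseline(
                    spec,
                    None if src.features is None else src.features[s_idx],
                    src.labels[s_idx],
                    records=None if src.records is None
                    else [src.records[i] for i in s_idx],
                    featurizer=featurizer, scaler=scaler)
                nq = min(query_size, len(task))
                q_idx = np.sort(rng.choice(len(task), size=nq, replace=False))
                manifest.append({"task_id": task.task_id,
                                 "support_source": src.task_id,
                                 "query": [task.record_ids[i] for i in q_idx]})
            Xq = None if task.features is None else task.features[q_idx]
            rq = None if task.records is None else [task.records[i] for i in q_idx]
            scores.append(model.scores(Xq, records=rq))
            labels.append(task.labels[q_idx])
        y = np.concatenate(labels)
        p = np.concatenate(scores)
        report.auprc_runs.append(auprc(y, p))
        report.auroc_runs.append(auroc(y, p))
        report.manifests.append(manifest)
    return report
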