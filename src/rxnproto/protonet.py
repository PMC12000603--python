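"""Prototypical-network meta-learner for few-shot reaction classification.

An embedding network maps each 1544-dimensional reaction vector into a
metric space.  Within an episode, each class's prototype is the arithmetic
mean of its support-set embeddings; a query is classified by a softmax over
negative (squared) Euclidean distances to the prototypes.  The network is
meta-trained by minimizing the query-set negative log-likelihood over
batches of training tasks, and meta-tested under three support protocols:

``episodic``
    support and query are disjoint random splits of the test task itself;
``full_train_support``
    the entire training split serves as the support set (test records are
    never part of it);
``cluster_support``
    the support is drawn from the *training-side* task of the same
    UMAP/k-means cluster as the test task, so no labels from the test task
    are needed at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalReport, auprc, auroc
from .nn.autograd import Tensor, concat, logsumexp
from .nn.layers import MLP, Adam
from .tasks import Episode, Task, sample_episode

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- prototypes
@dataclass
class PrototypeSet:
    """Per-class mean embeddings; `classes` aligns with rows of `vectors`."""

    classes: np.ndarray
    vectors: np.ndarray

    def __post_init__(self):
        if len(self.classes) != self.vectors.shape[0]:
            raise ValueError("one prototype per class required")


def compute_prototypes(support_embeddings) -> PrototypeSet:
    """Class-mean prototypes from (embedding, label) pairs."""
    pairs = list(support_embeddings)
    if not pairs:
        raise ValueError("empty support set")
    vecs = np.asarray([np.asarray(v, dtype=float) for v, _ in pairs])
    labels = np.asarray([y for _, y in pairs])
    classes = np.unique(labels)
    protos = np.stack([vecs[labels == c].mean(axis=0) for c in classes])
    return PrototypeSet(classes, protos)


def classify_query(query_embedding, prototypes: PrototypeSet,
                   distance: str = "squared_euclidean") -> np.ndarray:
    """Class probabilities: softmax over negative distances to prototypes.

    Returns probabilities aligned with ``prototypes.classes``.
    """
    q = np.asarray(query_embedding, dtype=float)
    if q.shape[-1] != prototypes.vectors.shape[-1]:
        raise ValueError("embedding dimension mismatch")
    d = ((prototypes.vectors - q) ** 2).sum(axis=-1)
    if distance == "euclidean":
        d = np.sqrt(d)
    elif distance != "squared_euclidean":
        raise ValueError(f"unknown distance {distance!r}")
    logits = -d
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


# ------------------------------------------------------------ configuration
@dataclass
class TrainConfig:
    """Episodic training settings (defaults follow the study protocol:
    batches of 5 tasks, 512/64 train support/query, 64/128 validation)."""

    tasks_per_batch: int = 5
    train_support: int = 512
    train_query: int = 64
    valid_support: int = 64
    valid_query: int = 128
    lr: float = 1e-3
    max_episodes: int = 2000
    check_every: int = 50
    patience: int = 10
    embedding_dims: tuple[int, ...] = (1544, 512, 256)
    dropout: float = 0.1
    distance: str = "squared_euclidean"
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if min(self.train_support, self.train_query,
               self.valid_support, self.valid_query) < 1:
            raise ValueError("episode sizes must be positive")


def feasible_sizes(n_task: int, support: int, query: int) -> tuple[int, int]:
    """Shrink (support, query) to fit a small task, keeping the same ratio."""
    if n_task >= support + query:
        return support, query
    ratio = support / (support + query)
    s = max(2, int(np.floor(n_task * ratio)))
    q = max(1, n_task - s)
    s = n_task - q
    return s, q


# ------------------------------------------------------------------- model
class ProtoNet:
    """Embedding network + prototype classification.

    ``mode="fingerprint"`` embeds precomputed composite vectors through a
    feed-forward encoder; ``mode="graph"`` embeds raw records through the
    MPNN graph featurizer followed by the same feed-forward head.
    """

    def __init__(self, config: TrainConfig, mode: str = "fingerprint",
                 graph_featurizer=None, condition_scaler=None):
        self.config = config
        self.mode = mode
        rng = np.random.default_rng(config.seed)
        self.encoder = MLP(list(config.embedding_dims), rng,
                           dropout=config.dropout)
        self.graph_featurizer = graph_featurizer
        self.condition_scaler = condition_scaler
        if mode == "graph" and (graph_featurizer is None or condition_scaler is None):
            raise ValueError("graph mode needs a featurizer and scaler")

    # -- embedding -------------------------------------------------------
    def parameters(self):
        params = self.encoder.parameters()
        if self.mode == "graph":
            params = params + self.graph_featurizer.encoder.parameters()
        return params

    def _input_tensor(self, task: Task, idx: np.ndarray) -> Tensor:
        if self.mode == "fingerprint":
            if task.features is None:
                raise ValueError(f"task {task.task_id} carries no features")
            return Tensor(task.features[idx])
        records = [task.records[i] for i in idx]
        return self.graph_featurizer.encode_records(records, self.condition_scaler)

    def embed(self, task: Task, idx: np.ndarray, training: bool = False,
              rng: np.random.Generator | None = None) -> Tensor:
        self.encoder.train(training)
        try:
            return self.encoder(self._input_tensor(task, idx), rng)
        finally:
            self.encoder.train(False)

    def embed_array(self, task: Task, idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            idx = np.arange(len(task))
        return self.embed(task, np.asarray(idx, dtype=np.intp)).data

    # -- episodic loss ---------------------------------------------------
    def _logits(self, support_emb: Tensor, support_y: np.ndarray,
                query_emb: Tensor) -> tuple[Tensor, np.ndarray]:
        classes = np.unique(support_y)
        protos = concat(
            [support_emb.gather_rows(np.flatnonzero(support_y == c))
             .mean(axis=0, keepdims=True) for c in classes], axis=0)
        nq, k = query_emb.shape[0], protos.shape[0]
        d = query_emb.shape[1]
        diff = query_emb.reshape(nq, 1, d) - protos.reshape(1, k, d)
        dist = (diff ** 2.0).sum(axis=2)
        if self.config.distance == "euclidean":
            dist = dist.sqrt()
        return -dist, classes

    def episode_loss(self, task: Task, episode: Episode,
                     training: bool = True,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Mean query negative log-likelihood for one episode."""
        support_y = task.labels[episode.support_idx]
        query_y = task.labels[episode.query_idx]
        if len(np.unique(support_y)) < 2:
            raise ValueError("episode support is single-class")
        s_emb = self.embed(task, episode.support_idx, training, rng)
        q_emb = self.embed(task, episode.query_idx, training, rng)
        logits, classes = self._logits(s_emb, support_y, q_emb)
        log_p = logits - logsumexp(logits, axis=1, keepdims=True)
        onehot = np.zeros((len(query_y), len(classes)))
        onehot[np.arange(len(query_y)), np.searchsorted(classes, query_y)] = 1.0
        return -(log_p * Tensor(onehot)).sum() * (1.0 / len(query_y))

    def predict_scores(self, support_emb: np.ndarray, support_y: np.ndarray,
                       query_emb: np.ndarray) -> np.ndarray:
        """P(high-selectivity class) for each query row (no gradients)."""
        protos = compute_prototypes(zip(support_emb, support_y))
        scores = np.array([
            classify_query(q, protos, self.config.distance)
            for q in query_emb])
        if 1 in protos.classes:
            return scores[:, list(protos.classes).index(1)]
        return np.zeros(len(query_emb))   # positive class absent from support

    def state_dict(self):
        state = self.encoder.state_dict()
        if self.mode == "graph":
            state = state + self.graph_featurizer.encoder.state_dict()
        return state

    def load_state_dict(self, state):
        n = len(self.encoder.state_dict())
        self.encoder.load_state_dict(state[:n])
        if self.mode == "graph":
            self.graph_featurizer.encoder.load_state_dict(state[n:])


# -------------------------------------------------------------- checkpoints
def save_checkpoint(model: ProtoNet, path) -> None:
    """Single-file archive: weights + config + format version tag."""
    import dataclasses
    import json

    meta = {"version": "rxnproto-ckpt-1", "mode": model.mode,
            "config": dataclasses.asdict(model.config)}
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_dict())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path, graph_featurizer=None, condition_scaler=None) -> ProtoNet:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        n = sum(1 for k in archive.files if k.startswith("param_"))
        state = [archive[f"param_{i}"] for i in range(n)]
    cfg_d = meta["config"]
    cfg_d["embedding_dims"] = tuple(cfg_d["embedding_dims"])
    config = TrainConfig(**cfg_d)
    model = ProtoNet(config, mode=meta["mode"],
                     graph_featurizer=graph_featurizer,
                     condition_scaler=condition_scaler)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------- training
def meta_train(model: ProtoNet, train_tasks: list[Task],
               valid_tasks: list[Task], config: TrainConfig | None = None
               ) -> dict:
    """Episodic meta-training with validation-based early stopping.

    Each step samples one (support, query) episode from each task in a
    batch of ``tasks_per_batch`` tasks and minimizes the mean query NLL.
    Returns a log dict; the model keeps the best-validation weights.
    """
    config = config or model.config
    if len(train_tasks) < 1:
        raise ValueError("no training tasks")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    best_metric, best_state, bad_checks = -np.inf, None, 0
    log = {"loss": [], "valid_auprc": [], "episodes_run": 0}

    for step in range(config.max_episodes):
        batch_ids = rng.choice(len(train_tasks),
                               size=min(config.tasks_per_batch, len(train_tasks)),
                               replace=False)
        losses = []
        for t in batch_ids:
            task = train_tasks[t]
            s, q = feasible_sizes(len(task), config.train_support,
                                  config.train_query)
            ep = sample_episode(task, s, q, seed=int(rng.integers(2 ** 31)))
            losses.append(model.episode_loss(task, ep, training=True, rng=rng))
        loss = concat([l.reshape(1) for l in losses], axis=0).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        log["loss"].append(float(loss.data))
        log["episodes_run"] = step + 1

        if (step + 1) % config.check_every == 0 and valid_tasks:
            metric = _validate(model, valid_tasks, config, rng)
            log["valid_auprc"].append(metric)
            if metric > best_metric:
                best_metric, best_state, bad_checks = metric, model.state_dict(), 0
            else:
                bad_checks += 1
                if bad_checks >= config.patience:
                    logger.info("early stop at episode %d (best AUPRC %.4f)",
                                step + 1, best_metric)
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    log["best_valid_auprc"] = best_metric if np.isfinite(best_metric) else None
    return log


def _validate(model: ProtoNet, valid_tasks: list[Task], config: TrainConfig,
              rng: np.random.Generator) -> float:
    labels, scores = [], []
    for task in valid_tasks:
        s, q = feasible_sizes(len(task), config.valid_support, config.valid_query)
        try:
            ep = sample_episode(task, s, q, seed=int(rng.integers(2 ** 31)))
        except ValueError:
            continue
        s_emb = model.embed_array(task, ep.support_idx)
        q_emb = model.embed_array(task, ep.query_idx)
        scores.append(model.predict_scores(s_emb, task.labels[ep.support_idx], q_emb))
        labels.append(task.labels[ep.query_idx])
    if not labels:
        raise ValueError("no valid episodes constructible for validation")
    return auprc(np.concatenate(labels), np.concatenate(scores))


# ----------------------------------------------------------------- testing
def meta_test(model: ProtoNet, test_tasks: list[Task], protocol: str,
              support_size: int | str = 16, n_repeats: int = 10,
              seed: int = 0, query_size: int = 128,
              train_support_task: Task | None = None,
              train_tasks: list[Task] | None = None,
              threshold: float = 80.0) -> EvalReport:
    """Evaluate under one of the three support protocols.

    Per repeat, query predictions are pooled over all test tasks before
    computing AUPRC/AUROC; mean and standard error are taken over repeats.
    For ``full_train_support`` and ``cluster_support`` the support never
    contains test-task records.
    """
    if protocol not in ("episodic", "full_train_support", "cluster_support"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if protocol == "full_train_support" and train_support_task is None:
        raise ValueError("full_train_support needs the training split as a task")
    by_cluster: dict[int, Task] = {}
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
    report = EvalReport(method=f"protonet-{model.mode}", protocol=protocol,
                        support_size=support_size, threshold=threshold)

    full_train_emb = None
    if protocol == "full_train_support":
        full_train_emb = model.embed_array(train_support_task)

    for _ in range(n_repeats):
        labels, scores, manifest = [], [], []
        for task in test_tasks:
            if protocol == "episodic":
                s, q = feasible_sizes(len(task), int(support_size), query_size)
                ep = sample_episode(task, s, q, seed=int(rng.integers(2 ** 31)))
                s_emb = model.embed_array(task, ep.support_idx)
                s_y = task.labels[ep.support_idx]
                q_idx = ep.query_idx
                manifest.append(ep.manifest(task))
            else:
                if protocol == "full_train_support":
                    src, s_emb_all = train_support_task, full_train_emb
                else:
                    c = task.cluster_id
                    if c not in by_cluster:
                        raise ValueError(
                            f"no training task for cluster {c} "
                            f"(test task {task.task_id})")
                    src, s_emb_all = by_cluster[c], None
                if support_size == "full":
                    s_idx = np.arange(len(src))
                else:
                    s_idx = _support_sample(src, int(support_size), rng)
                s_emb = (s_emb_all[s_idx] if s_emb_all is not None
                         else model.embed_array(src, s_idx))
                s_y = src.labels[s_idx]
                nq = min(query_size, len(task))
                q_idx = np.sort(rng.choice(len(task), size=nq, replace=False))
                manifest.append({
                    "task_id": task.task_id,
                    "support_source": src.task_id,
                    "support": [src.record_ids[i] for i in s_idx],
                    "query": [task.record_ids[i] for i in q_idx],
                })
            q_emb = model.embed_array(task, q_idx)
            scores.append(model.predict_scores(s_emb, s_y, q_emb))
            labels.append(task.labels[q_idx])
        y = np.concatenate(labels)
        p = np.concatenate(scores)
        report.auprc_runs.append(auprc(y, p))
        report.auroc_runs.append(auroc(y, p))
        report.manifests.append(manifest)
    return report


def _support_sample(task: Task, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified support sample containing both classes when possible."""
    from .tasks import _stratified_sample
    n = min(n, len(task))
    if len(np.unique(task.labels)) < 2 or n < 2:
        return np.sort(rng.choice(len(task), size=n, replace=False))
    return np.sort(_stratified_sample(task.labels, n, rng))
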