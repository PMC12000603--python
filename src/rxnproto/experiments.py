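"""Experiment orchestration: build a dataset (synthetic or from CSV),
construct tasks, meta-train, and evaluate a grid of methods, protocols and
support sizes from one config, with a replayable manifest.

Also hosts the desk-scale benchmark routines used to validate the workflow
end-to-end on synthetic data: the method-comparison grid, the
label-shuffled null control, and latent-cluster recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .baselines import BaselineSpec, evaluate_baseline
from .data import ReactionDataset, binarize_labels, read_dataset, split_dataset
from .evaluation import EvalReport, reports_to_frame
from .features import fingerprints as fp
from .features import graphs as gr
from .protonet import ProtoNet, TrainConfig, meta_test, meta_train
from .synthetic import GeneratorConfig, generate, make_fixture
from .tasks import Task, cluster_tasks, fit_clusters, random_tasks

logger = logging.getLogger(__name__)

BASELINE_KINDS = ("random_forest", "gnn", "svm", "gradient_boosting")


@dataclass
class ExperimentConfig:
    """One experiment grid over a single dataset."""

    generator: GeneratorConfig | None = None
    dataset_path: str | None = None
    threshold: float = 80.0
    representation: str = "fingerprint"          # fingerprint | graph
    task_scheme: str = "random"                  # random | cluster
    methods: tuple[str, ...] = ("protonet", "random_forest", "gnn")
    protocols: tuple[str, ...] = ("episodic",)
    support_sizes: tuple = (16, 32, 64)
    n_repeats: int = 10
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_train_tasks: int = 5
    n_test_tasks: int = 2
    n_valid_tasks: int = 1
    k_clusters: int = 10
    train: TrainConfig | None = None
    gnn_epochs: int = 40
    gnn_node_dim: int = 32
    output_dir: str | None = None

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if (self.generator is None) == (self.dataset_path is None):
            raise ValueError("give exactly one of generator / dataset_path")
        for m in self.methods:
            if m != "protonet" and m not in BASELINE_KINDS:
                raise ValueError(f"unknown method {m!r}")


@dataclass
class ExperimentContext:
    """Prepared data shared by every method in a grid."""

    train: ReactionDataset
    test: ReactionDataset
    valid: ReactionDataset
    scaler: fp.ConditionScaler
    X_train: np.ndarray
    X_test: np.ndarray
    X_valid: np.ndarray
    train_tasks: list[Task]
    test_tasks: list[Task]
    valid_tasks: list[Task]
    full_train_task: Task
    cluster_train_tasks: list[Task] | None = None


def prepare(config: ExperimentConfig) -> ExperimentContext:
    """Load/generate, binarize, split, encode and build tasks."""
    if config.generator is not None:
        dataset, _ = generate(config.generator)
    else:
        dataset = read_dataset(config.dataset_path)
    dataset = binarize_labels(dataset, config.threshold)

    fracs = config.split_fractions
    n = len(dataset)
    sizes = (int(n * fracs[0]), int(n * fracs[1]),
             n - int(n * fracs[0]) - int(n * fracs[1]))
    train, test, valid = split_dataset(dataset, sizes, seed=config.seed)

    scaler = fp.fit_condition_scaler(train)
    X_train = fp.encode_dataset(train, scaler)
    X_test = fp.encode_dataset(test, scaler)
    X_valid = fp.encode_dataset(valid, scaler)

    valid_tasks = random_tasks(valid, config.n_valid_tasks, seed=config.seed + 1,
                               features=X_valid)
    cluster_train = None
    if config.task_scheme == "random":
        train_tasks = random_tasks(train, config.n_train_tasks,
                                   seed=config.seed + 2, features=X_train)
        test_tasks = random_tasks(test, config.n_test_tasks,
                                  seed=config.seed + 3, features=X_test)
    elif config.task_scheme == "cluster":
        # cluster the full dataset's fingerprint encoding (transductive)
        X_all = np.concatenate([X_train, X_test], axis=0)
        union = ReactionDataset(list(train.records) + list(test.records),
                                np.concatenate([train.labels, test.labels]))
        model = fit_clusters(union, X_all, k=config.k_clusters,
                             seed=config.seed)
        cluster_train, test_tasks = cluster_tasks(
            model, train, test, train_features=X_train, test_features=X_test)
        # meta-training tasks stay random; clusters shape meta-test support
        train_tasks = random_tasks(train, config.n_train_tasks,
                                   seed=config.seed + 2, features=X_train)
    else:
        raise ValueError(f"unknown task scheme {config.task_scheme!r}")

    full_train_task = Task("D-train", train.record_ids, train.labels,
                           "random", features=X_train,
                           records=list(train.records))
    return ExperimentContext(train, test, valid, scaler, X_train, X_test,
                             X_valid, train_tasks, test_tasks, valid_tasks,
                             full_train_task, cluster_train)


def _graph_featurizer(config: ExperimentConfig, seed: int) -> gr.GraphFeaturizer:
    params = gr.GraphEncoderParams(node_dim=config.gnn_node_dim)
    enc = gr.GraphEncoder(params, np.random.default_rng(seed))
    return gr.GraphFeaturizer(enc)


def run_experiment(config: ExperimentConfig
                   ) -> tuple["pandas.DataFrame", dict]:  # noqa: F821
    """Run the full grid; returns (result table, replay manifest)."""
    ctx = prepare(config)
    train_cfg = config.train or TrainConfig(seed=config.seed)

    reports: list[EvalReport] = []
    manifest: dict = {"config": _config_dict(config), "reports": []}

    protonet_model = None
    if "protonet" in config.methods:
        if config.representation == "graph":
            feat = _graph_featurizer(
                dataclasses.replace(config, gnn_node_dim=64), train_cfg.seed)
            protonet_model = ProtoNet(train_cfg, mode="graph",
                                      graph_featurizer=feat,
                                      condition_scaler=ctx.scaler)
        else:
            protonet_model = ProtoNet(train_cfg)
        log = meta_train(protonet_model, ctx.train_tasks, ctx.valid_tasks,
                         train_cfg)
        manifest["meta_train_log"] = {
            "episodes_run": log["episodes_run"],
            "best_valid_auprc": log["best_valid_auprc"],
        }

    for protocol in config.protocols:
        sizes = (["full"] if protocol == "full_train_support"
                 else list(config.support_sizes))
        if protocol == "cluster_support" and ctx.cluster_train_tasks is None:
            raise ValueError("cluster_support requires task_scheme='cluster'")
        for size in sizes:
            for method in config.methods:
                logger.info("evaluating %s / %s / support=%s",
                            method, protocol, size)
                if method == "protonet":
                    rep = meta_test(
                        protonet_model, ctx.test_tasks, protocol,
                        support_size=size, n_repeats=config.n_repeats,
                        seed=config.seed + 10,
                        train_support_task=ctx.full_train_task,
                        train_tasks=ctx.cluster_train_tasks,
                        threshold=config.threshold)
                else:
                    feat = scaler = None
                    if method == "gnn":
                        feat = _graph_featurizer(config, config.seed + 20)
                        scaler = ctx.scaler
                    spec = BaselineSpec(
                        method, seed=config.seed + 30,
                        hyperparameters=({"epochs": config.gnn_epochs}
                                         if method == "gnn" else {}))
                    rep = evaluate_baseline(
                        spec, ctx.test_tasks, protocol, support_size=size,
                        n_repeats=config.n_repeats, seed=config.seed + 10,
                        train_support_task=ctx.full_train_task,
                        train_tasks=ctx.cluster_train_tasks,
                        featurizer=feat, scaler=scaler,
                        threshold=config.threshold)
                reports.append(rep)
                manifest["reports"].append(
                    {"summary": rep.summary(), "manifests": rep.manifests})

    table = reports_to_frame(reports)
    if config.output_dir:
        out = pathlib.Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return table, manifest


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("train") is not None:
        d["train"] = dataclasses.asdict(config.train)
    return d


def run_loco_experiment(config: ExperimentConfig
                        ) -> tuple["pandas.DataFrame", dict]:  # noqa: F821
    """Leave-one-cluster-out grid: each cluster is held out as the test
    task once; a fresh meta-model is trained on the remaining clusters and
    evaluated episodically, next to baselines trained on the full
    training-side data of that fold.
    """
    from .tasks import loco_folds

    if config.generator is not None:
        dataset, _ = generate(config.generator)
    else:
        dataset = read_dataset(config.dataset_path)
    dataset = binarize_labels(dataset, config.threshold)
    n_valid = max(1, int(len(dataset) * config.split_fractions[2]))
    body, valid, _ = split_dataset(
        dataset, (len(dataset) - n_valid, n_valid, 0), seed=config.seed)
    scaler = fp.fit_condition_scaler(body)
    X = fp.encode_dataset(body, scaler)
    X_valid = fp.encode_dataset(valid, scaler)
    valid_tasks = random_tasks(valid, config.n_valid_tasks,
                               seed=config.seed + 1, features=X_valid)
    model = fit_clusters(body, X, k=config.k_clusters, seed=config.seed)
    folds = loco_folds(model, body, features=X)
    train_cfg = config.train or TrainConfig(seed=config.seed)

    reports: list[EvalReport] = []
    manifest: dict = {"config": _config_dict(config), "folds": []}
    for train_tasks, test_task in folds:
        fold_id = test_task.origin
        logger.info("LOCO fold %s (%d train tasks, %d held out)",
                    fold_id, len(train_tasks), len(test_task))
        fold_rows = {"fold": fold_id, "reports": []}
        full_task = Task(f"{fold_id}-train",
                         [r for t in train_tasks for r in t.record_ids],
                         np.concatenate([t.labels for t in train_tasks]),
                         "random",
                         features=np.concatenate([t.features for t in train_tasks]),
                         records=[r for t in train_tasks for r in t.records])
        if "protonet" in config.methods:
            net = ProtoNet(train_cfg)
            meta_train(net, train_tasks, valid_tasks, train_cfg)
            for size in config.support_sizes:
                rep = meta_test(net, [test_task], "episodic",
                                support_size=size,
                                n_repeats=config.n_repeats,
                                seed=config.seed + 10,
                                threshold=config.threshold)
                rep.method = f"protonet-{size}"
                reports.append(rep)
                fold_rows["reports"].append(rep.summary() | {"fold": fold_id})
        for method in config.methods:
            if method == "protonet":
                continue
            feat = scl = None
            if method == "gnn":
                feat = _graph_featurizer(config, config.seed + 20)
                scl = scaler
            spec = BaselineSpec(method, seed=config.seed + 30,
                                hyperparameters=({"epochs": config.gnn_epochs}
                                                 if method == "gnn" else {}))
            rep = evaluate_baseline(spec, [test_task], "full_train_support",
                                    support_size="full",
                                    n_repeats=config.n_repeats,
                                    seed=config.seed + 10,
                                    train_support_task=full_task,
                                    featurizer=feat, scaler=scl,
                                    threshold=config.threshold)
            rep.method = f"{method}-full"
            reports.append(rep)
            fold_rows["reports"].append(rep.summary() | {"fold": fold_id})
        manifest["folds"].append(fold_rows)

    import pandas as pd
    table = pd.DataFrame([row for fold in manifest["folds"]
                          for row in fold["reports"]])
    if config.output_dir:
        out = pathlib.Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "loco_results.csv", index=False)
        with open(out / "loco_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return table, manifest


# ----------------------------------------------------- desk-scale benchmarks
def run_comparison_benchmark(seed: int, n_records: int = 2000,
                             n_clusters: int = 5, n_repeats: int = 10,
                             max_episodes: int = 400) -> dict:
    """Method-comparison grid on synthetic clustered data.

    Part 1 (random tasks, episodic supports 16/32/64): the meta-trained
    prototypical network against RF and GNN trained from scratch on the
    same supports.  Part 2 (cluster tasks): cluster-matched support vs a
    same-size support drawn from the whole training split, at size 16.
    Returns a nested dict of mean AUPRC (and stderr) per method/size.
    """
    gen = GeneratorConfig(n_records=n_records, n_clusters=n_clusters,
                          seed=seed)
    train_cfg = TrainConfig(max_episodes=max_episodes, check_every=25,
                            patience=6, seed=seed)
    cfg = ExperimentConfig(
        generator=gen, seed=seed, train=train_cfg,
        methods=("protonet", "random_forest", "gnn"),
        protocols=("episodic",), support_sizes=(16, 32, 64),
        n_repeats=n_repeats)
    table, _ = run_experiment(cfg)

    out: dict = {"episodic": {}}
    for _, row in table.iterrows():
        out["episodic"].setdefault(row["method"], {})[int(row["support_size"])] = {
            "auprc": row["auprc_mean"], "stderr": row["auprc_stderr"],
            "auroc": row["auroc_mean"]}

    # part 2: support-source effect on byte-identical cluster test tasks —
    # support from the matched train-side task (no test labels needed) vs
    # the test task's own random support split vs 16 drawn from all of
    # D_train
    ctx = prepare(dataclasses.replace(cfg, task_scheme="cluster",
                                      k_clusters=n_clusters))
    model = ProtoNet(train_cfg)
    meta_train(model, ctx.train_tasks, ctx.valid_tasks, train_cfg)
    rep_cluster = meta_test(model, ctx.test_tasks, "cluster_support",
                            support_size=16, n_repeats=n_repeats,
                            seed=seed + 10,
                            train_tasks=ctx.cluster_train_tasks)
    rep_episodic = meta_test(model, ctx.test_tasks, "episodic",
                             support_size=16, n_repeats=n_repeats,
                             seed=seed + 10)
    rep_train = meta_test(model, ctx.test_tasks, "full_train_support",
                          support_size=16, n_repeats=n_repeats,
                          seed=seed + 10,
                          train_support_task=ctx.full_train_task)
    out["cluster_support_16"] = rep_cluster.summary()["auprc_mean"]
    out["episodic_cluster_tasks_16"] = rep_episodic.summary()["auprc_mean"]
    out["train_support_16"] = rep_train.summary()["auprc_mean"]
    return out


def run_null_control(seed: int, n_repeats: int = 10,
                     support_size: int = 32, n_records: int = 2000,
                     n_clusters: int = 5) -> dict:
    """Label-shuffled control: no method should beat positive prevalence.

    The study dataset (2000 records, 5 latent clusters) is generated and
    its (label, %ee) pairs are randomly permuted across records, severing
    the feature-label link while preserving the class marginal.  Returns
    per-method mean AUPRC, stderr, and the test-split prevalence.
    """
    import dataclasses as _dc

    dataset, _ = generate(GeneratorConfig(n_records=n_records,
                                          n_clusters=n_clusters, seed=seed))
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(len(dataset))
    records = [_dc.replace(r, ee=dataset.records[j].ee)
               for r, j in zip(dataset.records, perm)]
    dataset = ReactionDataset(records, dataset.labels[perm])
    train, test, valid = split_dataset(
        dataset, (int(0.7 * len(dataset)), int(0.2 * len(dataset)),
                  len(dataset) - int(0.7 * len(dataset)) - int(0.2 * len(dataset))),
        seed=seed)
    scaler = fp.fit_condition_scaler(train)
    Xtr, Xte, Xva = (fp.encode_dataset(d, scaler) for d in (train, test, valid))
    train_tasks = random_tasks(train, 5, seed=seed + 2, features=Xtr)
    test_tasks = random_tasks(test, 2, seed=seed + 3, features=Xte)
    valid_tasks = random_tasks(valid, 1, seed=seed + 1, features=Xva)

    train_cfg = TrainConfig(max_episodes=150, check_every=25, patience=4,
                            seed=seed)
    model = ProtoNet(train_cfg)
    meta_train(model, train_tasks, valid_tasks, train_cfg)

    out = {"prevalence": float(test.labels.mean()), "n": n_records,
           "methods": {}}
    rep = meta_test(model, test_tasks, "episodic", support_size=support_size,
                    n_repeats=n_repeats, seed=seed + 10)
    out["methods"]["protonet"] = {
        "auprc": rep.summary()["auprc_mean"],
        "stderr": rep.summary()["auprc_stderr"]}
    feat = gr.GraphFeaturizer(gr.GraphEncoder(
        gr.GraphEncoderParams(node_dim=32), np.random.default_rng(seed + 20)))
    for kind in ("random_forest", "gnn"):
        spec = BaselineSpec(kind, seed=seed + 30,
                            hyperparameters={"epochs": 40} if kind == "gnn" else {})
        rep = evaluate_baseline(spec, test_tasks, "episodic",
                                support_size=support_size,
                                n_repeats=n_repeats, seed=seed + 10,
                                featurizer=feat, scaler=scaler)
        out["methods"][kind] = {"auprc": rep.summary()["auprc_mean"],
                                "stderr": rep.summary()["auprc_stderr"]}
    return out


def run_cluster_recovery(seed: int) -> dict:
    """Adjusted Rand index between UMAP/k-means clusters and the synthetic
    generator's latent clusters on the separable fixture."""
    from sklearn.metrics import adjusted_rand_score

    dataset, truth = make_fixture("separable", seed=seed)
    scaler = fp.fit_condition_scaler(dataset)
    X = fp.encode_dataset(dataset, scaler)
    model = fit_clusters(dataset, X, k=4, seed=seed)
    found = model.clusters_of(dataset)
    ari = adjusted_rand_score(truth["cluster"].to_numpy(), found)
    return {"ari": float(ari), "k": 4, "n": len(dataset)}
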