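"""Synthetic asymmetric-hydrogenation datasets with controlled structure.

The generator emulates the statistical shape of literature-mined AHO data:
three metals with highly imbalanced frequencies (Rh-heavy, Co rare), a
~65/35 class split at the 80 %ee threshold, and latent clusters that tie
reaction components and conditions to selectivity.  Component pools are
short curated lists of real, parseable SMILES (simple olefins,
phosphine-type ligands, common solvents), partitioned across clusters so
cluster structure is visible in fingerprint space.  The generator validates
statistics, not chemistry: no mechanistic structure-selectivity claim is
made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METALS, ReactionDataset, ReactionRecord

# ----------------------------------------------------------- component pools
OLEFINS = [
    "C=C", "C=CC", "C=C(C)C", "CC=CC", "C=Cc1ccccc1", "CC(=Cc1ccccc1)C",
    "C=CC(=O)O", "CC(=C)C(=O)OC", "C=CC(=O)OCC", "CC(=CC(=O)O)C",
    "C=C(c1ccccc1)C(=O)O", "CC(=O)NC(=C)C(=O)O",
    "CC(=O)NC(=Cc1ccccc1)C(=O)O", "C=C(C)c1ccccc1", "C=CCO", "CC=CCO",
    "C=CCN", "C=Cc1ccc(C)cc1", "C=Cc1ccc(OC)cc1", "CC(=CC(=O)OC)C",
    "C=C(C)C(=O)O", "C/C=C/c1ccccc1", "C=CC#N", "C=CC(=O)N",
]
LIGANDS = [
    "CP(C)C", "CCP(CC)CC", "CCCP(CCC)CCC", "CC(C)P(C(C)C)C(C)C",
    "c1ccc(P(c2ccccc2)c3ccccc3)cc1", "CP(c1ccccc1)c1ccccc1",
    "CCP(c1ccccc1)c1ccccc1", "COP(OC)OC", "CCOP(OCC)OCC",
    "CC(C)OP(OC(C)C)OC(C)C",
    "Cc1ccc(P(c2ccc(C)cc2)c2ccc(C)cc2)cc1",
    "COc1ccc(P(c2ccc(OC)cc2)c2ccc(OC)cc2)cc1",
    "C1CCC(P(C2CCCCC2)C2CCCCC2)CC1", "CC(C)(C)P(C(C)(C)C)C(C)(C)C",
    "c1ccc(P(CCP(c2ccccc2)c2ccccc2)c2ccccc2)cc1",
    "CC1CCCC(C)P1C", "CN(C)P(N(C)C)N(C)C", "CCN(CC)P(N(CC)CC)N(CC)CC",
    "c1ccc(P(C2CCCCC2)C2CCCCC2)cc1",
    "COc1ccccc1P(c1ccccc1OC)c1ccccc1OC",
    "CC(C)c1ccc(P(c2ccc(C(C)C)cc2)c2ccc(C(C)C)cc2)cc1",
    "Fc1ccc(P(c2ccc(F)cc2)c2ccc(F)cc2)cc1",
    "Clc1ccc(P(c2ccc(Cl)cc2)c2ccc(Cl)cc2)cc1",
    "CC(C)P(c1ccccc1)C(C)C",
]
SOLVENTS = [
    "CO", "CCO", "CC(C)O", "C1CCOC1", "ClCCl", "C(Cl)(Cl)Cl", "c1ccccc1",
    "Cc1ccccc1", "CC#N", "CC(=O)OCC", "COC(C)(C)C", "CCCCCC", "CCOCC",
    "CC(C)=O", "OCC(F)(F)F", "CCCCO",
]

#: pools for the held-out-chemistry fixture — disjoint from the lists above
HELDOUT_OLEFINS = [
    "C=Cc1ccc(F)cc1", "CC(=C(C)C)c1ccccc1", "C=C(CC)C(=O)OC",
    "C/C=C/C(=O)O", "C=Cc1cccnc1", "CC(=C)CC(=O)O",
]
HELDOUT_LIGANDS = [
    "CCCCP(CCCC)CCCC", "CC(C)CP(CC(C)C)CC(C)C",
    "c1ccc(P(c2ccccc2)c2ccccn2)cc1",
    "Brc1ccc(P(c2ccc(Br)cc2)c2ccc(Br)cc2)cc1",
    "CCC(C)P(C(C)CC)C(C)CC", "COCCP(CCOC)CCOC",
]
HELDOUT_SOLVENTS = ["ClCCCl", "Cc1ccc(C)cc1", "CCCCOCCCC"]

#: metal frequencies matching the Ir/Rh/Co composition of literature AHO data
DEFAULT_METAL_FREQS = (0.42, 0.535, 0.045)


def _partition(pool: list[str], k: int) -> list[list[str]]:
    out = [pool[c::k] for c in range(k)]
    if any(len(p) == 0 for p in out):
        raise ValueError(f"not enough pool entries for {k} clusters")
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_records: int = 2000
    n_clusters: int = 5
    olefin_pools: list[list[str]] | None = None
    ligand_pools: list[list[str]] | None = None
    solvent_pools: list[list[str]] | None = None
    metal_freqs: tuple[float, float, float] = DEFAULT_METAL_FREQS
    target_positive_fraction: float = 0.65
    label_temperature: float = 0.6       # softness of the label model; 0 = noiseless
    cluster_effect_scale: float = 2.0
    olefin_effect_scale: float = 1.0
    condition_effect_scale: float = 0.4
    cluster_effects: list[float] | None = None   # explicit per-cluster logits
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_positive_fraction < 1.0:
            raise ValueError("target positive fraction must be in (0, 1)")
        if abs(sum(self.metal_freqs) - 1.0) > 1e-9:
            raise ValueError("metal frequencies must sum to 1")
        k = self.n_clusters
        if self.olefin_pools is None:
            self.olefin_pools = _partition(OLEFINS, k)
        if self.ligand_pools is None:
            self.ligand_pools = _partition(LIGANDS, k)
        if self.solvent_pools is None:
            self.solvent_pools = _partition(SOLVENTS, k)
        for pools in (self.olefin_pools, self.ligand_pools, self.solvent_pools):
            if len(pools) != k or any(len(p) == 0 for p in pools):
                raise ValueError("need one nonempty pool per cluster")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: GeneratorConfig) -> tuple[ReactionDataset, pd.DataFrame]:
    """Draw a dataset and its ground-truth table.

    The ground truth records each reaction's latent cluster, its noiseless
    label probability, the realized label, and %ee drawn so that
    binarization at 80 recovers the label exactly.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_clusters

    # latent per-cluster structure
    clusters = rng.integers(0, k, size=config.n_records)
    cl_effect = (np.asarray(config.cluster_effects, dtype=float)
                 if config.cluster_effects is not None
                 else rng.normal(0.0, config.cluster_effect_scale, size=k))
    if len(cl_effect) != k:
        raise ValueError("cluster_effects length must equal n_clusters")
    olefin_eff = [rng.normal(0.0, config.olefin_effect_scale,
                             size=len(config.olefin_pools[c])) for c in range(k)]
    p_mean = rng.uniform(3.0, 80.0, size=k)        # bar
    t_mean = rng.uniform(15.0, 80.0, size=k)       # deg C
    sc_mean = rng.uniform(1.5, 3.5, size=k)        # log10 S/C
    additive_p = rng.uniform(0.1, 0.5, size=k)

    o_idx = np.array([rng.integers(len(config.olefin_pools[c])) for c in clusters])
    l_idx = np.array([rng.integers(len(config.ligand_pools[c])) for c in clusters])
    s_idx = np.array([rng.integers(len(config.solvent_pools[c])) for c in clusters])
    metal = rng.choice(len(METALS), size=config.n_records, p=config.metal_freqs)
    additive = rng.random(config.n_records) < additive_p[clusters]
    zp = rng.normal(0.0, 1.0, size=config.n_records)
    zt = rng.normal(0.0, 1.0, size=config.n_records)
    zs = rng.normal(0.0, 1.0, size=config.n_records)
    pressure = np.maximum(1.0, p_mean[clusters] * (1 + 0.12 * zp))
    temperature = t_mean[clusters] + 5.0 * zt
    sc_ratio = 10.0 ** (sc_mean[clusters] + 0.3 * zs)

    logit = (cl_effect[clusters]
             + np.array([olefin_eff[c][o] for c, o in zip(clusters, o_idx)])
             + config.condition_effect_scale * (0.8 * zp - 0.5 * zt + 0.6 * zs))

    temp = max(config.label_temperature, 1e-6)
    if config.calibrate:
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _sigmoid((logit + mid) / temp).mean() < config.target_positive_fraction:
                lo = mid
            else:
                hi = mid
        b0 = 0.5 * (lo + hi)
        achieved = _sigmoid((logit + b0) / temp).mean()
        if abs(achieved - config.target_positive_fraction) > 0.1:
            raise ValueError(
                f"label model cannot reach positive fraction "
                f"{config.target_positive_fraction} (best {achieved:.3f})")
    else:
        b0 = 0.0
    p_label = _sigmoid((logit + b0) / temp)
    y = (rng.random(config.n_records) < p_label).astype(np.int64)

    # %ee consistent with the label: >80 for class 1, <80 for class 0
    ee = np.where(
        y == 1,
        80.0 + 20.0 * rng.beta(2.0, 1.5, size=config.n_records),
        80.0 * rng.beta(8.0, 2.5, size=config.n_records))
    ee = np.clip(ee, 0.5, 99.9)
    ee = np.where(y == 1, np.clip(ee, 80.1, None), np.clip(ee, None, 79.9))
    ee = np.round(ee, 1)

    records = []
    for i in range(config.n_records):
        c = clusters[i]
        records.append(ReactionRecord(
            record_id=f"R{i:05d}",
            olefin=config.olefin_pools[c][o_idx[i]],
            ligand=config.ligand_pools[c][l_idx[i]],
            solvent=config.solvent_pools[c][s_idx[i]],
            metal=METALS[metal[i]],
            additive_present=bool(additive[i]),
            pressure=round(float(pressure[i]), 2),
            temperature=round(float(temperature[i]), 1),
            sc_ratio=round(float(sc_ratio[i]), 1),
            ee=float(ee[i]),
        ))
    dataset = ReactionDataset(records, labels=y)
    truth = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "cluster": clusters,
        "p_label": p_label,
        "label": y,
        "ee_percent": ee,
    })
    return dataset, truth


def make_fixture(name: str, seed: int = 0) -> tuple[ReactionDataset, pd.DataFrame]:
    """Small named datasets used throughout the test suite.

    ``tiny``
        30 records, 2 clusters, both classes present.
    ``separable``
        600 records, 4 clusters with labels perfectly aligned to clusters
        (alternating high/low clusters, near-noiseless label model).
    ``shuffled-null``
        the separable dataset with (label, %ee) pairs randomly permuted,
        destroying any feature-label relationship.
    ``heldout-chemistry``
        generated from component pools disjoint from every other fixture's
        pools, emulating an out-of-sample test set.
    """
    if name == "tiny":
        return generate(GeneratorConfig(n_records=30, n_clusters=2, seed=seed))
    if name == "separable":
        return generate(GeneratorConfig(
            n_records=600, n_clusters=4,
            cluster_effects=[4.0, -4.0, 4.0, -4.0],
            olefin_effect_scale=0.0, condition_effect_scale=0.0,
            label_temperature=0.05, calibrate=False, seed=seed))
    if name == "shuffled-null":
        dataset, truth = make_fixture("separable", seed=seed)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(len(dataset))
        from dataclasses import replace
        records = [replace(r, ee=dataset.records[j].ee)
                   for r, j in zip(dataset.records, perm)]
        labels = dataset.labels[perm]
        truth = truth.assign(label=labels,
                             ee_percent=[r.ee for r in records])
        return ReactionDataset(records, labels), truth
    if name == "heldout-chemistry":
        k = 3
        return generate(GeneratorConfig(
            n_records=300, n_clusters=k,
            olefin_pools=_partition(HELDOUT_OLEFINS, k),
            ligand_pools=_partition(HELDOUT_LIGANDS, k),
            solvent_pools=_partition(HELDOUT_SOLVENTS, k),
            seed=seed))
    raise ValueError(f"unknown fixture {name!r}")
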