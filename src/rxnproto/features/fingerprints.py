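"""Composite fingerprint representation of a reaction.

Each reaction becomes a fixed 1544-dimensional vector: three 512-bit
radius-2 Morgan fingerprints (olefin, ligand, solvent), a 3-wide metal
one-hot (Ir, Rh, Co), a 2-wide additive one-hot (absent, present) and three
standardized condition scalars (pressure, temperature, log10 S/C ratio):
512*3 + 3 + 2 + 3 = 1544.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from ..data import METALS, ReactionDataset, ReactionRecord, RecordError

logger = logging.getLogger(__name__)

FP_BITS = 512
FP_RADIUS = 2

#: slot layout of the composite vector (half-open index ranges)
SLOT_MAP = {
    "olefin_fp": (0, 512),
    "ligand_fp": (512, 1024),
    "solvent_fp": (1024, 1536),
    "metal_onehot": (1536, 1539),
    "additive_onehot": (1539, 1541),
    "conditions": (1541, 1544),
}
VECTOR_DIM = 1544

_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(n_bits: int, radius: int):
    key = (n_bits, radius)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)
    return _GENERATORS[key]


def morgan_fingerprint(smiles: str, n_bits: int = FP_BITS,
                       radius: int = FP_RADIUS) -> np.ndarray:
    """Binary circular (Morgan) fingerprint of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RecordError(f"unparseable SMILES {smiles!r}")
    fp = _generator(n_bits, radius).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


@dataclass
class ConditionScaler:
    """Affine standardization of (pressure, temperature, log10 S/C) fitted
    on training data only."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, record: ReactionRecord) -> np.ndarray:
        raw = np.array([record.pressure, record.temperature,
                        np.log10(record.sc_ratio)])
        return (raw - self.center) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.center

    def to_json(self) -> str:
        return json.dumps({"center": self.center.tolist(),
                           "scale": self.scale.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "ConditionScaler":
        d = json.loads(s)
        return cls(np.array(d["center"]), np.array(d["scale"]))


def fit_condition_scaler(train: ReactionDataset) -> ConditionScaler:
    """Fit per-feature mean/std on the training split.

    The S/C ratio is log10-transformed first because catalyst loading spans
    orders of magnitude.  Zero-variance features get scale 1 with a warning.
    """
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    raw = np.array([[r.pressure, r.temperature, np.log10(r.sc_ratio)]
                    for r in train.records])
    center = raw.mean(axis=0)
    scale = raw.std(axis=0)
    zero = scale == 0.0
    if zero.any():
        logger.warning("zero-variance condition feature(s) %s; scale set to 1",
                       np.flatnonzero(zero).tolist())
        scale[zero] = 1.0
    return ConditionScaler(center, scale)


def metal_onehot(metal: str) -> np.ndarray:
    if metal not in METALS:
        raise RecordError(f"unknown metal category {metal!r}")
    v = np.zeros(len(METALS))
    v[METALS.index(metal)] = 1.0
    return v


def additive_onehot(present: bool) -> np.ndarray:
    # slot 0 = absent, slot 1 = present
    return np.array([0.0, 1.0]) if present else np.array([1.0, 0.0])


def encode_tail(record: ReactionRecord, scaler: ConditionScaler) -> np.ndarray:
    """The 8 trailing slots shared by the fingerprint and graph composites."""
    return np.concatenate([
        metal_onehot(record.metal),
        additive_onehot(record.additive_present),
        scaler.transform(record),
    ])


def encode_reaction(record: ReactionRecord, scaler: ConditionScaler) -> np.ndarray:
    """Encode one reaction into the 1544-dim composite vector."""
    vec = np.concatenate([
        morgan_fingerprint(record.olefin),
        morgan_fingerprint(record.ligand),
        morgan_fingerprint(record.solvent),
        encode_tail(record, scaler),
    ])
    assert vec.shape == (VECTOR_DIM,)
    return vec


def encode_dataset(dataset: ReactionDataset, scaler: ConditionScaler) -> np.ndarray:
    """Design matrix of shape (n_records, 1544); rows follow dataset order.

    Fingerprints for repeated molecules are computed once and reused.
    """
    cache: dict[str, np.ndarray] = {}

    def fp(smiles: str) -> np.ndarray:
        if smiles not in cache:
            cache[smiles] = morgan_fingerprint(smiles)
        return cache[smiles]

    rows = np.empty((len(dataset), VECTOR_DIM))
    for i, r in enumerate(dataset.records):
        rows[i] = np.concatenate([fp(r.olefin), fp(r.ligand), fp(r.solvent),
                                  encode_tail(r, scaler)])
    return rows


def save_design_matrix(path, X: np.ndarray, labels: np.ndarray | None = None) -> None:
    """Cache an encoded design matrix (+labels) with the slot map alongside."""
    import pathlib
    path = pathlib.Path(path)
    if labels is None:
        np.savez_compressed(path, X=X)
    else:
        np.savez_compressed(path, X=X, labels=labels)
    path.with_suffix(".slots.json").write_text(json.dumps(SLOT_MAP))
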