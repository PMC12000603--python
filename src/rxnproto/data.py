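"""Reaction records, datasets, CSV I/O, label binarization and splitting.

A record describes one transition-metal-catalyzed asymmetric hydrogenation
of an olefin: the olefin/ligand/solvent structures (SMILES), the metal
(Ir, Rh or Co), whether an additive was present, the reaction conditions
(H2 pressure in bar, temperature in deg C, substrate-to-catalyst ratio) and
the measured enantiomeric excess in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

METALS = ("Ir", "Rh", "Co")

#: canonical CSV column order
CSV_COLUMNS = [
    "record_id", "olefin_smiles", "ligand_smiles", "solvent_smiles", "metal",
    "additive_present", "pressure_bar", "temperature_c", "sc_ratio",
    "ee_percent", "label",
]

DEFAULT_SCHEMA = {c: c for c in CSV_COLUMNS}


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class RecordError(ValueError):
    """A row violates record invariants (bad SMILES, metal, range)."""


@dataclass(frozen=True)
class ReactionRecord:
    record_id: str
    olefin: str
    ligand: str
    solvent: str
    metal: str
    additive_present: bool
    pressure: float      # bar
    temperature: float   # deg C
    sc_ratio: float      # substrate / catalyst, dimensionless
    ee: float            # % enantiomeric excess in [0, 100]

    def validate(self) -> None:
        for role, smi in (("olefin", self.olefin), ("ligand", self.ligand),
                          ("solvent", self.solvent)):
            if Chem.MolFromSmiles(smi) is None:
                raise RecordError(
                    f"record {self.record_id!r}: unparseable {role} SMILES {smi!r}")
        if self.metal not in METALS:
            raise RecordError(
                f"record {self.record_id!r}: metal {self.metal!r} not in {METALS}")
        if not np.isnan(self.sc_ratio) and self.sc_ratio <= 0:
            raise RecordError(f"record {self.record_id!r}: sc_ratio must be > 0")
        if not np.isnan(self.ee) and not (0.0 <= self.ee <= 100.0):
            raise RecordError(f"record {self.record_id!r}: ee outside [0, 100]")


@dataclass
class ReactionDataset:
    """An ordered collection of reaction records with optional binary labels
    (1 = highly enantioselective)."""

    records: list[ReactionRecord]
    labels: np.ndarray | None = None

    def __post_init__(self):
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise RecordError("record_ids are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.records):
                raise RecordError("labels do not align with records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def subset(self, indices) -> "ReactionDataset":
        indices = np.asarray(indices, dtype=np.intp)
        return ReactionDataset(
            [self.records[i] for i in indices],
            None if self.labels is None else self.labels[indices],
        )

    def by_ids(self, ids) -> "ReactionDataset":
        pos = {rid: i for i, rid in enumerate(self.record_ids)}
        return self.subset([pos[r] for r in ids])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            rows.append({
                "record_id": r.record_id,
                "olefin_smiles": r.olefin,
                "ligand_smiles": r.ligand,
                "solvent_smiles": r.solvent,
                "metal": r.metal,
                "additive_present": r.additive_present,
                "pressure_bar": r.pressure,
                "temperature_c": r.temperature,
                "sc_ratio": r.sc_ratio,
                "ee_percent": r.ee,
                "label": None if self.labels is None else int(self.labels[i]),
            })
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        if self.labels is None:
            df = df.drop(columns=["label"])
        return df


def read_dataset(path, schema: dict[str, str] | None = None,
                 on_bad_row: str = "raise") -> ReactionDataset:
    """Read a reaction table from CSV.

    Parameters
    ----------
    path
        CSV file (UTF-8, comma separated, header row required).
    schema
        Mapping from canonical column names to the file's column names, so
        external files with different headers can be adapted without code
        changes.  Defaults to the canonical names.
    on_bad_row
        ``"raise"`` fails on the first invalid row; ``"skip"`` drops invalid
        rows with a logged warning.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, encoding="utf-8")
    required = [c for c in CSV_COLUMNS if c != "label"]
    for canonical in required:
        if schema[canonical] not in df.columns:
            raise SchemaError(f"missing column {schema[canonical]!r} "
                              f"(mapped from {canonical!r})")
    records: list[ReactionRecord] = []
    keep: list[int] = []
    for i, row in df.iterrows():
        rec = ReactionRecord(
            record_id=str(row[schema["record_id"]]),
            olefin=str(row[schema["olefin_smiles"]]),
            ligand=str(row[schema["ligand_smiles"]]),
            solvent=str(row[schema["solvent_smiles"]]),
            metal=str(row[schema["metal"]]),
            additive_present=bool(row[schema["additive_present"]]),
            pressure=float(row[schema["pressure_bar"]]),
            temperature=float(row[schema["temperature_c"]]),
            sc_ratio=float(row[schema["sc_ratio"]]),
            ee=float(row[schema["ee_percent"]]),
        )
        try:
            rec.validate()
        except RecordError:
            if on_bad_row == "skip":
                logger.warning("skipping invalid row %s", rec.record_id)
                continue
            raise
        records.append(rec)
        keep.append(i)
    labels = None
    label_col = schema.get("label", "label")
    if label_col in df.columns:
        labels = df.loc[keep, label_col].to_numpy(dtype=np.int64)
    return ReactionDataset(records, labels)


def write_dataset(dataset: ReactionDataset, path) -> None:
    """Write the canonical CSV (full float precision preserved)."""
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")


def binarize_labels(dataset: ReactionDataset, threshold: float = 80.0) -> ReactionDataset:
    """Label each reaction 1 iff %ee is strictly greater than `threshold`.

    A reaction exactly at the threshold is assigned the low-selectivity
    class (label 0): "high" is the strict inequality ee > threshold.
    """
    ee = np.array([r.ee for r in dataset.records])
    bad = np.flatnonzero(np.isnan(ee))
    if bad.size:
        raise RecordError(
            f"missing ee for records: {[dataset.records[i].record_id for i in bad]}")
    labels = (ee > threshold).astype(np.int64)
    return ReactionDataset(list(dataset.records), labels)


def split_dataset(dataset: ReactionDataset, sizes: tuple[int, int, int],
                  seed: int) -> tuple[ReactionDataset, ReactionDataset, ReactionDataset]:
    """Random disjoint train/test/validation split of the requested sizes."""
    n_train, n_test, n_valid = sizes
    total = n_train + n_test + n_valid
    if total > len(dataset):
        raise ValueError(
            f"requested {total} records but dataset has {len(dataset)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    train = dataset.subset(np.sort(perm[:n_train]))
    test = dataset.subset(np.sort(perm[n_train:n_train + n_test]))
    valid = dataset.subset(np.sort(perm[n_train + n_test:total]))
    return train, test, valid


def impute_conditions(dataset: ReactionDataset,
                      medians: dict[str, float] | None = None
                      ) -> tuple[ReactionDataset, dict[str, float]]:
    """Fill missing pressure/temperature/sc_ratio with (training) medians.

    Returns the imputed dataset and the medians used, so the same statistics
    fitted on a training split can be applied to other splits.
    """
    fields_ = ("pressure", "temperature", "sc_ratio")
    if medians is None:
        medians = {}
        for f in fields_:
            vals = np.array([getattr(r, f) for r in dataset.records])
            medians[f] = float(np.nanmedian(vals))
    out = []
    n_imputed = 0
    for r in dataset.records:
        updates = {f: medians[f] for f in fields_ if np.isnan(getattr(r, f))}
        if updates:
            n_imputed += 1
            r = replace(r, **updates)
        out.append(r)
    if n_imputed:
        logger.info("imputed conditions for %d records with medians %s",
                    n_imputed, medians)
    return ReactionDataset(out, dataset.labels), medians
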