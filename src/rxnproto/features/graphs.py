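"""Learned graph representation of a reaction.

Each component molecule (olefin, ligand, solvent) is parsed into a graph
with atom and bond features and passed through a message-passing neural
network: an edge network computes per-bond message transforms, a GRU
updates 64-dimensional node states over three message-passing steps, and a
set2set readout (3 processing steps) pools the nodes.  Set2set natively
emits 2 x 64 = 128 dimensions; a learned linear projection maps it to the
512-dimensional component embedding.  The three component embeddings are
concatenated with the same 8 trailing slots as the fingerprint composite,
giving a 1544-dimensional learned reaction vector.

For speed, batches of molecules are encoded in one pass: message passing
runs on the disjoint union of the graphs, and set2set attention is
computed on a padded node tensor with masked softmax, so the number of
array operations is independent of batch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from ..data import ReactionDataset, ReactionRecord, RecordError
from ..nn.autograd import Tensor, concat, index_add
from ..nn.layers import MLP, GRUCell, Linear, LSTMCell, Module
from .fingerprints import ConditionScaler, encode_tail

ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Si")
N_ATOM_FEATURES = len(ELEMENTS) + 1 + 6 + 1 + 1 + 5   # element, degree, charge, arom, H count
N_BOND_FEATURES = 4 + 1 + 1                            # order one-hot, ring, conjugation

_MASK_NEG = -1e9   # additive mask value for padded set2set attention slots


@dataclass
class MolGraph:
    """Molecular graph: per-atom features and undirected bonds stored once.

    ``edge_src``/``edge_dst`` list each bond in both directions so message
    passing traverses it both ways; ``bond_features`` aligns with them.
    """

    atom_features: np.ndarray   # (n_atoms, N_ATOM_FEATURES)
    edge_src: np.ndarray        # (2 * n_bonds,)
    edge_dst: np.ndarray        # (2 * n_bonds,)
    bond_features: np.ndarray   # (2 * n_bonds, N_BOND_FEATURES)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edge_src.shape[0] // 2


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(N_ATOM_FEATURES)
    sym = atom.GetSymbol()
    v[ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)] = 1.0
    off = len(ELEMENTS) + 1
    v[off + min(atom.GetDegree(), 5)] = 1.0
    off += 6
    v[off] = atom.GetFormalCharge()
    v[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    off += 2
    v[off + min(atom.GetTotalNumHs(), 4)] = 1.0
    return v


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(N_BOND_FEATURES)
    order = {Chem.BondType.SINGLE: 0, Chem.BondType.DOUBLE: 1,
             Chem.BondType.TRIPLE: 2, Chem.BondType.AROMATIC: 3}
    v[order.get(bond.GetBondType(), 0)] = 1.0
    v[4] = 1.0 if bond.IsInRing() else 0.0
    v[5] = 1.0 if bond.GetIsConjugated() else 0.0
    return v


def mol_to_graph(smiles: str) -> MolGraph:
    """Parse a SMILES into a heavy-atom molecular graph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RecordError(f"unparseable SMILES {smiles!r}")
    atoms = np.array([_atom_features(a) for a in mol.GetAtoms()])
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        src += [i, j]
        dst += [j, i]
        feats += [f, f]
    return MolGraph(
        atom_features=atoms,
        edge_src=np.array(src, dtype=np.intp),
        edge_dst=np.array(dst, dtype=np.intp),
        bond_features=np.array(feats).reshape(len(src), N_BOND_FEATURES),
    )


@dataclass
class GraphEncoderParams:
    """Hyperparameters of the graph encoder."""

    message_passing_steps: int = 3
    node_dim: int = 64
    set2set_steps: int = 3
    output_dim: int = 512
    edge_hidden_dim: int = 64

    def __post_init__(self):
        if min(self.node_dim, self.output_dim, self.edge_hidden_dim) <= 0:
            raise ValueError("widths must be positive")
        if min(self.message_passing_steps, self.set2set_steps) < 1:
            raise ValueError("steps must be >= 1")


class GraphEncoder(Module):
    """MPNN (edge network + GRU) with set2set readout and output projection.

    One shared encoder is applied to olefin, ligand and solvent graphs.
    """

    def __init__(self, params: GraphEncoderParams, rng: np.random.Generator):
        d = params.node_dim
        self.params_cfg = params
        self.atom_proj = Linear(N_ATOM_FEATURES, d, rng)
        self.edge_net = MLP([N_BOND_FEATURES, params.edge_hidden_dim, d * d], rng)
        self.gru = GRUCell(d, d, rng)
        self.s2s_lstm = LSTMCell(2 * d, d, rng)
        self.out_proj = Linear(2 * d, params.output_dim, rng)
        self.last_step_count = 0

    def forward_batch(self, graphs: list[MolGraph]) -> Tensor:
        """Embed a batch of molecules: output (n_graphs, output_dim)."""
        d = self.params_cfg.node_dim
        n_graphs = len(graphs)
        sizes = [g.n_atoms for g in graphs]
        offsets = np.cumsum([0] + sizes)
        n_total = offsets[-1]
        X = np.concatenate([g.atom_features for g in graphs], axis=0)
        src = np.concatenate([g.edge_src + off for g, off in zip(graphs, offsets)])
        dst = np.concatenate([g.edge_dst + off for g, off in zip(graphs, offsets)])
        bonds = np.concatenate([g.bond_features for g in graphs], axis=0)

        # message passing on the disjoint union
        h = self.atom_proj(Tensor(X)).relu()
        has_edges = src.size > 0
        if has_edges:
            # bond feature vectors repeat heavily; run the edge network on
            # the unique rows and gather per edge
            uniq, inv = np.unique(bonds, axis=0, return_inverse=True)
            edge_mat = (self.edge_net(Tensor(uniq)).gather_rows(inv)
                        .reshape(-1, d, d))
        self.last_step_count = 0
        for _ in range(self.params_cfg.message_passing_steps):
            if has_edges:
                src_h = h.gather_rows(src).reshape(-1, d, 1)
                msgs = (edge_mat @ src_h).reshape(-1, d)
                agg = index_add(n_total, dst, msgs)
            else:
                agg = Tensor(np.zeros((n_total, d)))
            h = self.gru(agg, h)
            self.last_step_count += 1

        # padded node tensor for batched set2set attention
        max_n = max(sizes)
        pos = np.concatenate([off + np.arange(s) for off, s in
                              zip(np.arange(n_graphs) * max_n, sizes)])
        padded = index_add(n_graphs * max_n, pos, h).reshape(n_graphs, max_n, d)
        mask = np.full((n_graphs, max_n), _MASK_NEG)
        for g, s in enumerate(sizes):
            mask[g, :s] = 0.0
        mask_t = Tensor(mask)

        q_star = Tensor(np.zeros((n_graphs, 2 * d)))
        hq = Tensor(np.zeros((n_graphs, d)))
        cq = Tensor(np.zeros((n_graphs, d)))
        for _ in range(self.params_cfg.set2set_steps):
            hq, cq = self.s2s_lstm(q_star, hq, cq)
            energy = (padded * hq.reshape(n_graphs, 1, d)).sum(axis=2) + mask_t
            shift = Tensor(energy.data.max(axis=1, keepdims=True))
            w = (energy - shift).exp()
            attn = w * (w.sum(axis=1, keepdims=True) ** -1.0)
            readout = (padded * attn.reshape(n_graphs, max_n, 1)).sum(axis=1)
            q_star = concat([hq, readout], axis=1)
        return self.out_proj(q_star)

    def __call__(self, graph: MolGraph) -> Tensor:
        return self.forward_batch([graph])


def mpnn_encode(graph: MolGraph, encoder: GraphEncoder) -> np.ndarray:
    """Embed a single molecular graph (no gradient tracking)."""
    return encoder(graph).data.reshape(-1)


class GraphFeaturizer:
    """Caches parsed graphs; embeds each unique molecule once per pass."""

    def __init__(self, encoder: GraphEncoder):
        self.encoder = encoder
        self._graphs: dict[str, MolGraph] = {}

    def graph(self, smiles: str) -> MolGraph:
        if smiles not in self._graphs:
            self._graphs[smiles] = mol_to_graph(smiles)
        return self._graphs[smiles]

    def encode_records(self, records: list[ReactionRecord],
                       scaler: ConditionScaler) -> Tensor:
        """(n, 1544) learned composite; each unique molecule embedded once."""
        unique: dict[str, int] = {}
        for r in records:
            for smi in (r.olefin, r.ligand, r.solvent):
                if smi not in unique:
                    unique[smi] = len(unique)
        emb = self.encoder.forward_batch(
            [self.graph(s) for s in unique])              # (G, 512)
        o_idx = np.array([unique[r.olefin] for r in records])
        l_idx = np.array([unique[r.ligand] for r in records])
        s_idx = np.array([unique[r.solvent] for r in records])
        tails = np.stack([encode_tail(r, scaler) for r in records])
        return concat([emb.gather_rows(o_idx), emb.gather_rows(l_idx),
                       emb.gather_rows(s_idx), Tensor(tails)], axis=1)


def encode_reaction_graph(record: ReactionRecord, encoder: GraphEncoder,
                          scaler: ConditionScaler) -> np.ndarray:
    """Encode one reaction into the 1544-dim learned composite vector."""
    feat = GraphFeaturizer(encoder)
    return feat.encode_records([record], scaler).data.reshape(-1)


def encode_dataset_graph(dataset: ReactionDataset, encoder: GraphEncoder,
                         scaler: ConditionScaler) -> np.ndarray:
    feat = GraphFeaturizer(encoder)
    return feat.encode_records(list(dataset.records), scaler).data
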