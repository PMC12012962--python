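"""SMILES -> molecular graph featurization for the convolutional regressor.

Atoms are nodes carrying a fixed-width feature vector; bonds are untyped
edges (aromaticity lives on atoms).  Hydrogens are implicit — they appear in
the attached-H block, not as nodes — so the graph has exactly the molecule's
heavy atoms.  The node feature vector concatenates, in fixed order:

==========================  =====  ==========================================
block                       width  encoding
==========================  =====  ==========================================
atom symbol                 13     one-hot over C,N,O,S,F,Cl,Br,I,P,B,Si,Se
                                   plus an "other" bucket
degree                      7      one-hot 0-6, saturating at 6
implicit valence            7      one-hot 0-6, saturating
formal charge               1      signed integer scalar
radical electrons           1      scalar
hybridization               6      one-hot s, sp, sp2, sp3, sp3d, sp3d2
aromaticity                 1      flag
attached hydrogens          5      one-hot 0-4 (total H), saturating
chirality                   3      one-hot R, S, unspecified
==========================  =====  ==========================================

Total width d = 44.  The :class:`FeatureSpec` used at training time is
serialized with the model so prediction always featurizes identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from rdkit import Chem

from .records import mol_from_smiles

ATOM_ALPHABET = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se")
HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
MAX_DEGREE = 6
MAX_VALENCE = 6
MAX_NUM_H = 4


@dataclass(frozen=True)
class FeatureSpec:
    """Featurization contract; frozen into trained model files."""

    atom_alphabet: tuple[str, ...] = ATOM_ALPHABET
    max_degree: int = MAX_DEGREE
    max_valence: int = MAX_VALENCE
    max_num_h: int = MAX_NUM_H
    version: str = "1"

    @property
    def width(self) -> int:
        return (
            len(self.atom_alphabet) + 1  # symbol + other
            + self.max_degree + 1
            + self.max_valence + 1
            + 1  # formal charge
            + 1  # radical electrons
            + len(HYBRIDIZATIONS)
            + 1  # aromatic
            + self.max_num_h + 1
            + 3  # chirality R/S/unspecified
        )

    def to_dict(self) -> dict:
        return {
            "atom_alphabet": list(self.atom_alphabet),
            "max_degree": self.max_degree,
            "max_valence": self.max_valence,
            "max_num_h": self.max_num_h,
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(
            atom_alphabet=tuple(d["atom_alphabet"]),
            max_degree=int(d["max_degree"]),
            max_valence=int(d["max_valence"]),
            max_num_h=int(d["max_num_h"]),
            version=str(d.get("version", "1")),
        )


@dataclass
class MolGraph:
    """One molecule as node features + symmetric neighbor lists."""

    node_features: np.ndarray  # (n_atoms, d) float32
    neighbors: list[list[int]]
    parent_id: str = ""
    label: float | None = None

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)


def _one_hot(value: int, size: int, saturate: bool = True) -> np.ndarray:
    v = np.zeros(size, dtype=np.float32)
    idx = min(value, size - 1) if saturate else value
    if 0 <= idx < size:
        v[idx] = 1.0
    return v


def _atom_features(atom: Chem.Atom, spec: FeatureSpec) -> np.ndarray:
    alphabet = spec.atom_alphabet
    sym = atom.GetSymbol()
    sym_idx = alphabet.index(sym) if sym in alphabet else len(alphabet)
    sym_oh = np.zeros(len(alphabet) + 1, dtype=np.float32)
    sym_oh[sym_idx] = 1.0

    hyb = np.zeros(len(HYBRIDIZATIONS), dtype=np.float32)
    if atom.GetHybridization() in HYBRIDIZATIONS:
        hyb[HYBRIDIZATIONS.index(atom.GetHybridization())] = 1.0

    tag = atom.GetChiralTag()
    chirality = np.zeros(3, dtype=np.float32)
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
        chirality[0] = 1.0
    elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
        chirality[1] = 1.0
    else:
        chirality[2] = 1.0

    return np.concatenate(
        [
            sym_oh,
            _one_hot(atom.GetDegree(), spec.max_degree + 1),
            _one_hot(atom.GetImplicitValence(), spec.max_valence + 1),
            np.array([atom.GetFormalCharge()], dtype=np.float32),
            np.array([atom.GetNumRadicalElectrons()], dtype=np.float32),
            hyb,
            np.array([1.0 if atom.GetIsAromatic() else 0.0], dtype=np.float32),
            _one_hot(atom.GetTotalNumHs(), spec.max_num_h + 1),
            chirality,
        ]
    )


def featurize(
    smiles: str,
    spec: FeatureSpec | None = None,
    parent_id: str = "",
    label: float | None = None,
) -> MolGraph:
    """Convert a SMILES string into a :class:`MolGraph`.

    Raises :class:`~solugraph.records.StructureError` on invalid input.
    Atoms outside the alphabet land in the "other" bucket; degree, valence
    and H counts saturate at the last one-hot bucket.
    """
    spec = spec or FeatureSpec()
    mol = mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError(f"molecule with no heavy atoms: {smiles!r}")
    feats = np.stack([_atom_features(a, spec) for a in mol.GetAtoms()])
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        neighbors[i].append(j)
        neighbors[j].append(i)
    for nb in neighbors:  # sorted lists make batching round-trips exact
        nb.sort()
    return MolGraph(feats.astype(np.float32), neighbors, parent_id=parent_id, label=label)


@dataclass
class GraphBatch:
    """Several MolGraphs packed into one node matrix for vectorized compute.

    ``adjacency`` is the (N, N) block-diagonal CSR adjacency (no self loops),
    used for neighbor-sum aggregation.  ``pool_index`` is an (N, K) integer
    matrix whose row i lists node i itself followed by its neighbors, padded
    with i — gathering node states through it and taking a row-max implements
    the self-plus-neighbors max pool.
    """

    node_features: np.ndarray  # (N, d)
    graph_index: np.ndarray  # (N,) graph membership of each node
    adjacency: sp.csr_matrix
    pool_index: np.ndarray  # (N, K)
    n_graphs: int
    sizes: np.ndarray  # (n_graphs,)
    labels: np.ndarray | None = None
    parent_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def pool_scatter(self) -> sp.csr_matrix:
        """(N, N*K) matrix scattering per-candidate values back to nodes."""
        cached = self.__dict__.get("_pool_scatter")
        if cached is None:
            n, k = self.pool_index.shape
            cached = sp.csr_matrix(
                (
                    np.ones(n * k, dtype=np.float32),
                    (self.pool_index.ravel(), np.arange(n * k)),
                ),
                shape=(n, n * k),
            )
            self.__dict__["_pool_scatter"] = cached
        return cached

    @property
    def segment(self) -> sp.csr_matrix:
        """(n_graphs, N) matrix summing node states per graph (sum readout)."""
        cached = self.__dict__.get("_segment")
        if cached is None:
            n = self.n_nodes
            cached = sp.csr_matrix(
                (np.ones(n, dtype=np.float32), (self.graph_index, np.arange(n))),
                shape=(self.n_graphs, n),
            )
            self.__dict__["_segment"] = cached
        return cached


def _graph_arrays(g: MolGraph) -> tuple[np.ndarray, np.ndarray]:
    """Cached (edges, local pool matrix) for one graph; used by batching."""
    cached = g.__dict__.get("_arrays")
    if cached is not None:
        return cached
    rows, cols = [], []
    for i, nbrs in enumerate(g.neighbors):
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs)
    edges = np.array([rows, cols], dtype=np.int64).reshape(2, -1)
    max_deg = max((len(nb) for nb in g.neighbors), default=0)
    pool = np.empty((g.n_atoms, max_deg + 1), dtype=np.int64)
    for i, nbrs in enumerate(g.neighbors):
        pool[i, 0] = i
        pool[i, 1 : 1 + len(nbrs)] = nbrs
        pool[i, 1 + len(nbrs) :] = i
    g.__dict__["_arrays"] = (edges, pool)
    return edges, pool


def batch_graphs(graphs: Sequence[MolGraph]) -> GraphBatch:
    """Pack a list of MolGraphs into one :class:`GraphBatch`."""
    if not graphs:
        raise ValueError("cannot batch zero graphs")
    d = graphs[0].node_features.shape[1]
    for g in graphs:
        if g.node_features.shape[1] != d:
            raise ValueError("mixed feature dimensions in batch")
    sizes = np.array([g.n_atoms for g in graphs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])

    X = np.concatenate([g.node_features for g in graphs]).astype(np.float32)
    graph_index = np.repeat(np.arange(len(graphs)), sizes)

    arrays = [_graph_arrays(g) for g in graphs]
    edge_list = [edges + off for (edges, _), off in zip(arrays, offsets)]
    edges = np.concatenate(edge_list, axis=1)
    adjacency = sp.csr_matrix(
        (np.ones(edges.shape[1], dtype=np.float32), (edges[0], edges[1])),
        shape=(total, total),
    )

    width = max(p.shape[1] for _, p in arrays)
    pool_blocks = []
    for (_, p), off in zip(arrays, offsets):
        block = p + off
        if block.shape[1] < width:
            pad = np.repeat(block[:, :1], width - block.shape[1], axis=1)
            block = np.concatenate([block, pad], axis=1)
        pool_blocks.append(block)
    pool = np.concatenate(pool_blocks, axis=0)

    labels = None
    if all(g.label is not None for g in graphs):
        labels = np.array([g.label for g in graphs], dtype=np.float64)
    return GraphBatch(
        node_features=X,
        graph_index=graph_index,
        adjacency=adjacency,
        pool_index=pool,
        n_graphs=len(graphs),
        sizes=sizes,
        labels=labels,
        parent_ids=[g.parent_id for g in graphs],
    )


def unbatch_graphs(batch: GraphBatch) -> list[MolGraph]:
    """Invert :func:`batch_graphs` exactly."""
    offsets = np.concatenate([[0], np.cumsum(batch.sizes)])
    coo = batch.adjacency.tocoo()
    out = []
    for gi in range(batch.n_graphs):
        lo, hi = int(offsets[gi]), int(offsets[gi + 1])
        feats = batch.node_features[lo:hi].copy()
        neighbors: list[list[int]] = [[] for _ in range(hi - lo)]
        mask = (coo.row >= lo) & (coo.row < hi)
        for r, c in zip(coo.row[mask], coo.col[mask]):
            neighbors[int(r) - lo].append(int(c) - lo)
        label = float(batch.labels[gi]) if batch.labels is not None else None
        pid = batch.parent_ids[gi] if batch.parent_ids else ""
        out.append(MolGraph(feats, neighbors, parent_id=pid, label=label))
    return out
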