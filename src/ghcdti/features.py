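"""Initial 128-dimensional node features for the four node types.

Drugs: MACCS fingerprints of their SMILES, reduced by PCA.
Proteins: amino-acid composition (20) + dipeptide frequencies (400), PCA.
Diseases / side effects: network embeddings from biased second-order random
walks over the union association network, factorized via shifted-PPMI SVD
(the classic matrix-factorization form of skip-gram with negative sampling).

All builders return exactly ``dim``-wide (default 128) finite matrices,
zero-padded when fewer informative components exist, and are deterministic
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hetgraph import NODE_TYPES, RELATIONS, HeteroGraph

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NONSTANDARD = set("BJOUXZ")

FEATURE_DIM = 128


@dataclass
class FeatureTable:
    """Per node type, an (n_type, dim) real matrix plus a provenance tag."""

    tables: dict[str, np.ndarray]
    provenance: dict[str, str]

    def validate(self, g: HeteroGraph | None = None, dim: int = FEATURE_DIM) -> "FeatureTable":
        for t, X in self.tables.items():
            if not np.isfinite(X).all():
                raise ValueError(f"feature table for '{t}' has non-finite entries")
            if X.shape[1] != dim:
                raise ValueError(f"feature table for '{t}' is {X.shape[1]}-wide, expected {dim}")
            if g is not None and X.shape[0] != g.node_counts[t]:
                raise ValueError(f"feature table for '{t}' has {X.shape[0]} rows, "
                                 f"expected {g.node_counts[t]}")
        return self

    def __getitem__(self, node_type: str) -> np.ndarray:
        return self.tables[node_type]


# -- PCA -----------------------------------------------------------------------

def pca_reduce(X: np.ndarray, k: int) -> np.ndarray:
    """Column-centered projection onto the top-k right singular vectors.

    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive.  If fewer than ``k``
    informative components exist the result is zero-padded to width ``k``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite entries")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # drop numerically-null components
    tol = max(Xc.shape) * np.finfo(np.float64).eps * (s[0] if s.size else 0.0)
    r = int((s > tol).sum())
    r = min(r, k)
    V = Vt[:r]
    # deterministic sign: largest-|loading| positive
    for i in range(r):
        j = np.argmax(np.abs(V[i]))
        if V[i, j] < 0:
            V[i] = -V[i]
    proj = Xc @ V.T
    if r < k:
        proj = np.hstack([proj, np.zeros((X.shape[0], k - r))])
    return proj


# -- drugs ---------------------------------------------------------------------

def maccs_fingerprints(smiles: list[str]) -> np.ndarray:
    """167-bit MACCS keys for a list of SMILES strings."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.*")
    bad = [i for i, s in enumerate(smiles) if Chem.MolFromSmiles(s) is None]
    if bad:
        raise ValueError(f"unparseable SMILES at indices {bad}")
    fps = []
    for s in smiles:
        fp = MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(s))
        fps.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0"))
    return np.asarray(fps, dtype=np.float64)


def drug_features(smiles: list[str], dim: int = FEATURE_DIM, seed: int = 0) -> np.ndarray:
    """MACCS fingerprints reduced by PCA to ``dim`` (zero-padded as needed)."""
    if not smiles:
        raise ValueError("empty SMILES list")
    fps = maccs_fingerprints(smiles)
    return pca_reduce(fps, dim)


# -- proteins ------------------------------------------------------------------

def sequence_descriptors(seq: str) -> np.ndarray:
    """20 composition fractions + 400 dipeptide frequencies (each block sums to 1)."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    dropped = sorted(set(seq) - set(AMINO_ACIDS))
    if dropped:
        extra = set(dropped) - _NONSTANDARD
        if extra:
            raise ValueError(f"unknown residue letters {sorted(extra)}")
        warnings.warn(f"dropping non-standard residues {dropped}", stacklevel=2)
        seq = "".join(a for a in seq if a in _AA_INDEX)
    if len(seq) < 2:
        raise ValueError("sequence too short after filtering (need >= 2 residues)")
    comp = np.zeros(20)
    for a in seq:
        comp[_AA_INDEX[a]] += 1
    comp /= comp.sum()
    dipep = np.zeros((20, 20))
    for a, b in zip(seq[:-1], seq[1:]):
        dipep[_AA_INDEX[a], _AA_INDEX[b]] += 1
    dipep /= dipep.sum()
    return np.concatenate([comp, dipep.ravel()])


def protein_features(seqs: list[str], dim: int = FEATURE_DIM, seed: int = 0) -> np.ndarray:
    """AAC + dipeptide descriptors reduced by PCA to ``dim``."""
    if not seqs:
        raise ValueError("empty sequence list")
    raw = np.asarray([sequence_descriptors(s) for s in seqs])
    return pca_reduce(raw, dim)


# -- network embeddings (disease / side-effect nodes) --------------------------

def union_association_graph(g: HeteroGraph) -> tuple[sp.csr_matrix, dict[str, np.ndarray]]:
    """Union of all typed edges as one undirected graph over all nodes.

    Returns the CSR adjacency and, per node type, the global index range of
    that type's nodes.
    """
    offsets, start = {}, 0
    for t in NODE_TYPES:
        n = g.node_counts[t]
        offsets[t] = np.arange(start, start + n)
        start += n
    N = start
    rows, cols = [], []
    for rel, (src, dst) in RELATIONS.items():
        A = g.adj[rel]
        if src == dst:  # strip self-loops for the walk graph
            A = A.copy()
            np.fill_diagonal(A, 0)
        r, c = np.nonzero(A)
        rows.extend(offsets[src][r]); cols.extend(offsets[dst][c])
        rows.extend(offsets[dst][c]); cols.extend(offsets[src][r])
    data = np.ones(len(rows))
    A = sp.csr_matrix((data, (rows, cols)), shape=(N, N))
    A.data[:] = 1.0
    return A, offsets


def biased_walks(A: sp.csr_matrix, n_walks: int, walk_length: int,
                 p: float, q: float, rng: np.random.Generator) -> list[np.ndarray]:
    """node2vec-style biased second-order random walks on an unweighted graph.

    Transition weights from walk step (prev -> cur -> next): 1/p back to
    ``prev``, 1 to common neighbors of prev and cur, 1/q otherwise.
    """
    indptr, indices = A.indptr, A.indices
    nbr_sets = [set(indices[indptr[i]:indptr[i + 1]]) for i in range(A.shape[0])]
    walks = []
    nodes = np.arange(A.shape[0])
    for _ in range(n_walks):
        for start in rng.permutation(nodes):
            nbrs = indices[indptr[start]:indptr[start + 1]]
            if len(nbrs) == 0:
                continue
            walk = [start, rng.choice(nbrs)]
            while len(walk) < walk_length:
                prev, cur = walk[-2], walk[-1]
                nbrs = indices[indptr[cur]:indptr[cur + 1]]
                if len(nbrs) == 0:
                    break
                w = np.where(nbrs == prev, 1.0 / p,
                             np.where([n in nbr_sets[prev] for n in nbrs], 1.0, 1.0 / q))
                w = w / w.sum()
                walk.append(rng.choice(nbrs, p=w))
            walks.append(np.asarray(walk, dtype=np.int64))
    return walks


def _ppmi_embed(walks: list[np.ndarray], n_nodes: int, dim: int, window: int,
                rng: np.random.Generator, negative: float = 1.0) -> np.ndarray:
    """Skip-gram-style embeddings via truncated SVD of the shifted PPMI matrix."""
    rows, cols = [], []
    for walk in walks:
        L = len(walk)
        for i in range(L):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    rows.append(walk[i]); cols.append(walk[j])
    if not rows:
        return np.zeros((n_nodes, dim))
    C = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes))
    C = np.asarray(C.todense())
    total = C.sum()
    wr = C.sum(axis=1, keepdims=True)
    wc = C.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(C * total / (wr * wc)) - np.log(negative)
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    k = min(dim, n_nodes - 1)
    if k < 1:
        return np.zeros((n_nodes, dim))
    U, s, _ = spla.svds(sp.csr_matrix(ppmi), k=k,
                        v0=rng.standard_normal(n_nodes))
    order = np.argsort(s)[::-1]
    emb = U[:, order] * np.sqrt(s[order])[None, :]
    # deterministic sign convention per component
    for i in range(emb.shape[1]):
        j = np.argmax(np.abs(emb[:, i]))
        if emb[j, i] < 0:
            emb[:, i] = -emb[:, i]
    if emb.shape[1] < dim:
        emb = np.hstack([emb, np.zeros((n_nodes, dim - emb.shape[1]))])
    return emb


def network_embeddings(g: HeteroGraph, types: tuple[str, ...] = ("disease", "side_effect"),
                       dim: int = FEATURE_DIM, p: float = 1.0, q: float = 1.0,
                       n_walks: int = 10, walk_length: int = 80, window: int = 5,
                       seed: int = 0) -> dict[str, np.ndarray]:
    """Biased-random-walk co-occurrence embeddings for the requested node types."""
    A, offsets = union_association_graph(g)
    if A.nnz == 0:
        raise ValueError("association network is empty")
    rng = np.random.default_rng(seed)
    walks = biased_walks(A, n_walks=n_walks, walk_length=walk_length, p=p, q=q, rng=rng)
    emb = _ppmi_embed(walks, A.shape[0], dim, window, rng)
    out = {}
    degs = np.asarray(A.sum(axis=1)).ravel()
    for t in types:
        E = emb[offsets[t]].copy()
        isolated = np.flatnonzero(degs[offsets[t]] == 0)
        if isolated.size:
            warnings.warn(f"{isolated.size} isolated '{t}' nodes get noise embeddings",
                          stacklevel=2)
            E[isolated] = 0.01 * rng.standard_normal((isolated.size, dim))
        out[t] = E
    return out


# -- assembly ------------------------------------------------------------------

def build_feature_table(g: HeteroGraph, smiles: list[str] | None = None,
                        seqs: list[str] | None = None, dim: int = FEATURE_DIM,
                        seed: int = 0, **walk_params) -> FeatureTable:
    """Construct the full FeatureTable from chemistry, sequences and walks."""
    tables, prov = {}, {}
    if smiles is not None:
        tables["drug"] = drug_features(smiles, dim=dim, seed=seed)
        prov["drug"] = "fingerprint_pca"
    if seqs is not None:
        tables["protein"] = protein_features(seqs, dim=dim, seed=seed)
        prov["protein"] = "sequence_pca"
    net = network_embeddings(g, dim=dim, seed=seed, **walk_params)
    for t, E in net.items():
        tables[t] = E
        prov[t] = "network_embedding"
    return FeatureTable(tables=tables, provenance=prov).validate(g, dim=dim)
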