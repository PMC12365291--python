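"""Heterogeneous biomedical network data model and DTINet-dialect I/O.

The network has four node types (drug, protein, disease, side_effect) and the
binary relations between them (drug–drug interaction, drug–protein
interaction, drug–disease and drug–side-effect association, protein–protein
interaction, protein–disease association), plus real-valued drug–drug and
protein–protein similarity matrices.  Files are whitespace-delimited dense
matrices, one row per line, matching the public DTINet release.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

NODE_TYPES = ("drug", "protein", "disease", "side_effect")

#: relation key -> (source type, destination type)
RELATIONS: dict[str, tuple[str, str]] = {
    "drug_drug": ("drug", "drug"),
    "drug_protein": ("drug", "protein"),
    "drug_disease": ("drug", "disease"),
    "drug_se": ("drug", "side_effect"),
    "protein_protein": ("protein", "protein"),
    "protein_disease": ("protein", "disease"),
}

#: default DTINet file names for each relation / similarity / name list
DEFAULT_MANIFEST = {
    "drug_drug": "mat_drug_drug.txt",
    "drug_protein": "mat_drug_protein.txt",
    "drug_disease": "mat_drug_disease.txt",
    "drug_se": "mat_drug_se.txt",
    "protein_protein": "mat_protein_protein.txt",
    "protein_disease": "mat_protein_disease.txt",
    "sim_drug": "Similarity_Matrix_Drugs.txt",
    "sim_protein": "Similarity_Matrix_Proteins.txt",
    "names_drug": "drug.txt",
    "names_protein": "protein.txt",
    "names_disease": "disease.txt",
    "names_side_effect": "se.txt",
}


class GraphValidationError(ValueError):
    pass


class GraphLoadError(IOError):
    pass


@dataclass
class HeteroGraph:
    """Typed node counts, binary typed adjacency and similarity matrices."""

    node_counts: dict[str, int]
    adj: dict[str, np.ndarray]
    sim: dict[str, np.ndarray] = field(default_factory=dict)
    names: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> "HeteroGraph":
        for rel, (src, dst) in RELATIONS.items():
            if rel not in self.adj:
                raise GraphValidationError(f"missing adjacency for relation '{rel}'")
            A = self.adj[rel]
            expect = (self.node_counts[src], self.node_counts[dst])
            if A.shape != expect:
                raise GraphValidationError(
                    f"relation '{rel}' has shape {A.shape}, expected {expect}")
            if not np.isin(A, (0, 1)).all():
                raise GraphValidationError(f"relation '{rel}' has non-binary entries")
            if src == dst and not np.array_equal(A, A.T):
                raise GraphValidationError(f"within-type relation '{rel}' is not symmetric")
        for t, S in self.sim.items():
            n = self.node_counts[t]
            if S.shape != (n, n):
                raise GraphValidationError(f"similarity for '{t}' has shape {S.shape}")
            if not np.allclose(S, S.T):
                raise GraphValidationError(f"similarity for '{t}' is not symmetric")
            if not np.allclose(np.diag(S), 1.0):
                raise GraphValidationError(f"similarity for '{t}' diagonal is not 1")
        for t, lst in self.names.items():
            if len(lst) != self.node_counts[t]:
                raise GraphValidationError(
                    f"name list for '{t}' has {len(lst)} entries, "
                    f"expected {self.node_counts[t]}")
        return self

    def relation(self, src: str, dst: str) -> np.ndarray:
        """Adjacency block from ``src`` type to ``dst`` type (transposing if needed)."""
        for rel, (a, b) in RELATIONS.items():
            if (a, b) == (src, dst):
                return self.adj[rel]
            if (a, b) == (dst, src):
                return self.adj[rel].T
        raise KeyError(f"no relation between '{src}' and '{dst}'")

    def incident_relations(self, node_type: str) -> list[tuple[str, str]]:
        """Ordered (relation_key, neighbor_type) pairs incident to ``node_type``."""
        out = []
        for rel, (src, dst) in RELATIONS.items():
            if src == node_type:
                out.append((rel, dst))
            elif dst == node_type:
                out.append((rel, src))
        return out

    # -- persistence ----------------------------------------------------------
    def save(self, path: str) -> None:
        """Write a self-describing .npz archive of the validated graph."""
        payload: dict[str, np.ndarray] = {}
        for rel, A in self.adj.items():
            payload[f"adj/{rel}"] = A
        for t, S in self.sim.items():
            payload[f"sim/{t}"] = S
        meta = {
            "node_counts": self.node_counts,
            "names": self.names,
        }
        payload["meta"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str) -> "HeteroGraph":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode("utf-8"))
            adj = {k.split("/", 1)[1]: z[k] for k in z.files if k.startswith("adj/")}
            sim = {k.split("/", 1)[1]: z[k] for k in z.files if k.startswith("sim/")}
        return cls(node_counts={k: int(v) for k, v in meta["node_counts"].items()},
                   adj=adj, sim=sim,
                   names={k: list(v) for k, v in meta["names"].items()}).validate()


@dataclass(frozen=True)
class MetaPath:
    """A typed node sequence whose composed adjacency defines a same-type graph."""

    types: tuple[str, ...]
    label: str

    def __post_init__(self):
        if len(self.types) < 2:
            raise ValueError("meta-path needs at least two node types")


#: default meta-paths used by the deep-view encoder (drug side mirrors protein)
DEFAULT_METAPATHS = {
    "protein": [
        MetaPath(("protein", "protein"), "P-P"),
        MetaPath(("protein", "drug", "protein"), "P-D-P"),
        MetaPath(("protein", "drug", "drug", "protein"), "P-D-D-P"),
    ],
    "drug": [
        MetaPath(("drug", "drug"), "D-D"),
        MetaPath(("drug", "protein", "drug"), "D-P-D"),
        MetaPath(("drug", "protein", "protein", "drug"), "D-P-P-D"),
    ],
}


# -- core matrix operations ----------------------------------------------------

def add_self_loops(A: np.ndarray) -> np.ndarray:
    """A + I implemented as elementwise max(A, I) so the result stays binary."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"add_self_loops needs a square matrix, got {A.shape}")
    out = A.copy()
    np.fill_diagonal(out, np.maximum(np.diag(out), 1))
    return out


def sym_normalize(A_tilde: np.ndarray, d_row: np.ndarray | None = None,
                  d_col: np.ndarray | None = None) -> np.ndarray:
    """Symmetric degree normalization D_row^{-1/2} A D_col^{-1/2}.

    Degrees default to the row/column sums of ``A_tilde``; zero degrees on
    rectangular cross-type blocks get +1 smoothing so isolated nodes stay
    well-defined, while an explicit zero degree raises.
    """
    A_tilde = np.asarray(A_tilde, dtype=np.float64)
    if d_row is None:
        d_row = A_tilde.sum(axis=1)
        d_row = np.where(d_row == 0, 1.0, d_row)
    else:
        d_row = np.asarray(d_row, dtype=np.float64)
        if (d_row <= 0).any():
            idx = int(np.flatnonzero(d_row <= 0)[0])
            raise ValueError(f"non-positive row degree at node {idx}")
    if d_col is None:
        d_col = A_tilde.sum(axis=0)
        d_col = np.where(d_col == 0, 1.0, d_col)
    else:
        d_col = np.asarray(d_col, dtype=np.float64)
        if (d_col <= 0).any():
            idx = int(np.flatnonzero(d_col <= 0)[0])
            raise ValueError(f"non-positive column degree at node {idx}")
    return A_tilde / np.sqrt(d_row)[:, None] / np.sqrt(d_col)[None, :]


def metapath_adjacency(g: HeteroGraph, path: MetaPath,
                       binarize: bool = True) -> np.ndarray:
    """Composed adjacency of a same-endpoint meta-path, with self-loops.

    The per-step adjacencies are chain-multiplied; the product is binarized by
    default (counts preserved with ``binarize=False`` for sensitivity checks)
    and self-loops are added.  A length-2 within-type path returns that
    relation's adjacency itself (with self-loops).
    """
    t = path.types
    if t[0] != t[-1]:
        raise ValueError(f"meta-path {path.label} must start and end on the same type")
    M = g.relation(t[0], t[1]).astype(np.float64)
    for a, b in zip(t[1:-1], t[2:]):
        M = M @ g.relation(a, b).astype(np.float64)
    if binarize:
        M = (M > 0).astype(np.float64)
    return add_self_loops(M) if binarize else _weighted_self_loops(M)


def _weighted_self_loops(M: np.ndarray) -> np.ndarray:
    out = M.copy()
    np.fill_diagonal(out, np.maximum(np.diag(out), 1.0))
    return out


def metapath_count_matrix(g: HeteroGraph, path: MetaPath) -> np.ndarray:
    """Raw path-count matrix (no binarization, no self-loops)."""
    t = path.types
    M = g.relation(t[0], t[1]).astype(np.float64)
    for a, b in zip(t[1:-1], t[2:]):
        M = M @ g.relation(a, b).astype(np.float64)
    return M


# -- DTINet directory I/O ------------------------------------------------------

def _read_matrix(path: str) -> np.ndarray:
    try:
        return np.loadtxt(path, dtype=np.float64, ndmin=2)
    except OSError as e:
        raise GraphLoadError(f"cannot read matrix file {path}: {e}") from e


def _read_names(path: str) -> list[str] | None:
    if not os.path.exists(path):
        return None
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def threshold_similarity(S: np.ndarray, threshold: float) -> np.ndarray:
    """Zero entries below ``threshold``; keep the unit diagonal."""
    out = np.where(S >= threshold, S, 0.0)
    np.fill_diagonal(out, 1.0)
    return out


def load_dtinet_dir(path: str, threshold: float = 0.5,
                    manifest: dict[str, str] | None = None) -> HeteroGraph:
    """Load a DTINet-style directory into a validated :class:`HeteroGraph`.

    Similarity entries below ``threshold`` are zeroed (diagonal kept at 1) and
    self-loops are added to every within-type adjacency.
    """
    files = dict(DEFAULT_MANIFEST)
    if manifest:
        files.update(manifest)
    mpath = os.path.join(path, "manifest.json")
    if os.path.exists(mpath):
        with open(mpath, encoding="utf-8") as fh:
            files.update(json.load(fh))

    adj: dict[str, np.ndarray] = {}
    for rel in RELATIONS:
        fp = os.path.join(path, files[rel])
        if not os.path.exists(fp):
            raise GraphLoadError(f"missing file for relation '{rel}': {files[rel]}")
        A = _read_matrix(fp)
        if not np.isin(A, (0, 1)).all():
            raise GraphValidationError(
                f"adjacency file for '{rel}' contains non-{{0,1}} entries")
        adj[rel] = A.astype(np.int8).astype(np.float64)

    node_counts = {
        "drug": adj["drug_protein"].shape[0],
        "protein": adj["drug_protein"].shape[1],
        "disease": adj["drug_disease"].shape[1],
        "side_effect": adj["drug_se"].shape[1],
    }

    # self-loops on within-type interaction networks
    for rel in ("drug_drug", "protein_protein"):
        adj[rel] = add_self_loops(adj[rel])

    sim: dict[str, np.ndarray] = {}
    for t, key in (("drug", "sim_drug"), ("protein", "sim_protein")):
        fp = os.path.join(path, files[key])
        if os.path.exists(fp):
            sim[t] = threshold_similarity(_read_matrix(fp), threshold)

    names: dict[str, list[str]] = {}
    for t in NODE_TYPES:
        lst = _read_names(os.path.join(path, files[f"names_{t}"]))
        names[t] = lst if lst is not None else [f"{t}_{i}" for i in range(node_counts[t])]

    return HeteroGraph(node_counts=node_counts, adj=adj, sim=sim, names=names).validate()


def save_dtinet_dir(g: HeteroGraph, path: str) -> None:
    """Write a graph back out in the DTINet dense-matrix dialect."""
    os.makedirs(path, exist_ok=True)
    for rel in RELATIONS:
        np.savetxt(os.path.join(path, DEFAULT_MANIFEST[rel]),
                   g.adj[rel], fmt="%d")
    for t, key in (("drug", "sim_drug"), ("protein", "sim_protein")):
        if t in g.sim:
            np.savetxt(os.path.join(path, DEFAULT_MANIFEST[key]),
                       g.sim[t], fmt="%.10g")
    for t in NODE_TYPES:
        with open(os.path.join(path, DEFAULT_MANIFEST[f"names_{t}"]),
                  "w", encoding="utf-8") as fh:
            fh.write("\n".join(g.names.get(t, [])) + "\n")
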