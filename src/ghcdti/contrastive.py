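"""Multi-level cross-view contrastive alignment.

Positive pairs come from a composite multi-order path similarity: per
meta-path, the row-normalized path-count matrix; summed over paths and
augmented with the identity so every node is its own positive.  Rows with
more than K positive candidates keep only the K most similar (Top-10 for
drugs, Top-5 for proteins by default); rows below the threshold keep all.

The deep-view and neighborhood-view embeddings are aligned per layer with a
bidirectional temperature-scaled InfoNCE objective; all non-positive columns
of the full node set act as implicit negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .hetgraph import HeteroGraph, MetaPath, metapath_count_matrix


@dataclass
class ContrastConfig:
    tau: float = 0.5
    k_drug: int = 10
    k_protein: int = 5
    contrast_types: tuple[str, ...] = ("drug", "protein")
    proj_dim: int = 512
    paths: dict = field(default_factory=lambda: {
        "drug": [MetaPath(("drug", "drug"), "D-D"),
                 MetaPath(("drug", "protein", "drug"), "D-P-D")],
        "protein": [MetaPath(("protein", "protein"), "P-P"),
                    MetaPath(("protein", "drug", "protein"), "P-D-P")],
    })

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.k_drug < 1 or self.k_protein < 1:
            raise ValueError("Top-K thresholds must be >= 1")

    def k_for(self, node_type: str) -> int:
        return {"drug": self.k_drug, "protein": self.k_protein}[node_type]


def composite_similarity(g: HeteroGraph, node_type: str,
                         paths: list[MetaPath]) -> np.ndarray:
    """Sum of row-normalized meta-path count matrices plus the identity."""
    if not paths:
        raise ValueError("no meta-paths supplied")
    n = g.node_counts[node_type]
    S = np.zeros((n, n))
    for p in paths:
        if p.types[0] != node_type or p.types[-1] != node_type:
            raise ValueError(f"meta-path {p.label} does not start/end on '{node_type}'")
        C = metapath_count_matrix(g, p)
        rows = C.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Cn = np.where(rows > 0, C / rows, 0.0)
        S += Cn
    return S + np.eye(n)


def build_pos_dict(S: np.ndarray, K: int) -> np.ndarray:
    """Binary positive-pair indicator from a composite similarity matrix.

    Per row: off-diagonal entries with S > 0 are candidates; if more than K
    exist, keep the K largest (ties broken toward the lower index); otherwise
    keep all.  The diagonal is always positive.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    S = np.asarray(S)
    n = S.shape[0]
    P = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        row = S[i].copy()
        row[i] = 0.0
        cand = np.flatnonzero(row > 0)
        if cand.size > K:
            # stable sort on (-similarity, index): ties go to the lower index
            order = np.lexsort((cand, -row[cand]))
            cand = cand[order[:K]]
        P[i, cand] = 1
        P[i, i] = 1
    return P


def build_pos_dicts(g: HeteroGraph, cfg: ContrastConfig) -> dict[str, np.ndarray]:
    return {t: build_pos_dict(composite_similarity(g, t, cfg.paths[t]), cfg.k_for(t))
            for t in cfg.contrast_types}


def pos_dict_to_coo(P: np.ndarray) -> list[tuple[int, int]]:
    """Serialize a positive-pair indicator as a sparse coordinate list."""
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(P))]


def pos_dict_from_coo(coords: list[tuple[int, int]], n: int) -> np.ndarray:
    P = np.zeros((n, n), dtype=np.int8)
    for i, j in coords:
        P[i, j] = 1
    return P


def cross_view_similarity(Z_dv: Tensor | np.ndarray, Z_nv: Tensor | np.ndarray,
                          tau: float) -> Tensor:
    """Temperature-scaled cosine similarity S_ij between DV row i and NV row j."""
    Z_dv, Z_nv = ad.as_tensor(Z_dv), ad.as_tensor(Z_nv)
    for name, Z in (("DV", Z_dv), ("NV", Z_nv)):
        norms = np.linalg.norm(Z.data, axis=1)
        if (norms == 0).any():
            idx = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"zero-norm {name} embedding at node {idx}")
    dn = _row_normalize(Z_dv)
    nn = _row_normalize(Z_nv)
    return (dn @ nn.T) * (1.0 / tau)


def _row_normalize(Z: Tensor) -> Tensor:
    sq = ad.square(Z).sum(axis=1, keepdims=True)
    return Z / ad.sqrt(sq)


def directional_loss(S: Tensor | np.ndarray, P: np.ndarray) -> Tensor:
    """InfoNCE for one direction.

    L = -(1/n) sum_k [ log sum_l exp(S_kl) P_kl - log sum_l exp(S_kl) ],
    computed with masked log-sum-exp for numerical stability.
    """
    S = ad.as_tensor(S)
    P = np.asarray(P)
    if S.shape != P.shape:
        raise ValueError(f"shape mismatch: S {S.shape} vs P {P.shape}")
    if not (P.sum(axis=1) >= 1).all():
        k = int(np.flatnonzero(P.sum(axis=1) == 0)[0])
        raise ValueError(f"row {k} of the positive indicator has no positives")
    pos = ad.logsumexp(S, axis=1, mask=P > 0)
    alln = ad.logsumexp(S, axis=1)
    return -(pos - alln).mean()


def multilevel_loss(nv: dict[int, dict[str, Tensor]], dv: dict[int, dict[str, Tensor]],
                    pos: dict[str, np.ndarray], cfg: ContrastConfig,
                    heads: dict | None = None) -> Tensor:
    """Bidirectional InfoNCE summed over layers and contrasted node types.

    L = sum_h 1/2 [ L^{(h),DV->NV} + L^{(h),NV->DV} ]; the reverse direction
    uses the transposed similarity.  ``heads`` optionally holds the per-view
    projection heads (see :func:`init_projection_heads`).
    """
    if set(nv.keys()) != set(dv.keys()):
        raise ValueError(f"layer mismatch: NV {sorted(nv)} vs DV {sorted(dv)}")
    total = None
    for h in sorted(nv):
        for t in cfg.contrast_types:
            z_nv, z_dv = nv[h][t], dv[h][t]
            if heads is not None:
                z_nv = apply_head(z_nv, heads["nv"])
                z_dv = apply_head(z_dv, heads["dv"])
            S = cross_view_similarity(z_dv, z_nv, cfg.tau)
            P = pos[t]
            term = (directional_loss(S, P) + directional_loss(S.T, P.T)) * 0.5
            total = term if total is None else total + term
    return total


def init_projection_heads(rng: np.random.Generator, d_in: int, proj_dim: int) -> dict:
    """One-hidden-layer projection per view (shared across layers and types)."""
    def head(name):
        return {
            "W1": ad.glorot(rng, (d_in, proj_dim), name=f"{name}.W1"),
            "b1": ad.zeros((proj_dim,), name=f"{name}.b1"),
            "W2": ad.glorot(rng, (proj_dim, proj_dim), name=f"{name}.W2"),
            "b2": ad.zeros((proj_dim,), name=f"{name}.b2"),
            "slope": Tensor(np.array(0.25), requires_grad=True, name=f"{name}.slope"),
        }
    return {"nv": head("proj_nv"), "dv": head("proj_dv")}


def apply_head(Z: Tensor, head: dict) -> Tensor:
    hidden = ad.prelu(Z @ head["W1"] + head["b1"], head["slope"])
    return hidden @ head["W2"] + head["b2"]
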