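"""Neighborhood-view encoder.

Per edge type, a heterogeneous graph convolution aggregates normalized
neighbor features through a relation-specific linear map; each relational
aggregate is fused with the (projected) base features of the target type by
elementwise multiplication ("Multiple" fusion) and the fused views are
mean-pooled.  Two such layers are stacked so every node sees its two-hop
neighborhood.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from ._autodiff import Tensor
from .hetgraph import NODE_TYPES, HeteroGraph, sym_normalize


def normalized_blocks(g: HeteroGraph) -> dict[tuple[str, str], sp.csr_matrix]:
    """Symmetrically normalized adjacency block for every (type, relation) pair.

    Keys are (node_type, relation_key); the block maps neighbor-type rows to
    node_type rows, i.e. has shape (n_type, n_neighbor).  Blocks with no edges
    are omitted.
    """
    blocks: dict[tuple[str, str], sp.csr_matrix] = {}
    for v in NODE_TYPES:
        for rel, u in g.incident_relations(v):
            A = g.relation(v, u).astype(np.float64)
            if A.sum() == 0:
                continue
            N = sym_normalize(A)
            blocks[(v, rel)] = sp.csr_matrix(N) if (N != 0).mean() < 0.05 else N
    return blocks


def init_nv_params(rng: np.random.Generator, g: HeteroGraph, d_in: int, d_out: int,
                   n_layers: int = 2, dropout: float = 0.5) -> dict:
    """Trainable bundle: per layer, per type a self projection W_self and a
    relation-specific W per incident relation, plus a PReLU slope per type."""
    layers = []
    for layer in range(n_layers):
        din = d_in if layer == 0 else d_out
        lp: dict = {"W_self": {}, "W_rel": {}, "slope": {}}
        for v in NODE_TYPES:
            lp["W_self"][v] = ad.glorot(rng, (din, d_out), name=f"nv{layer}.{v}.self")
            lp["slope"][v] = Tensor(np.array(0.25), requires_grad=True,
                                    name=f"nv{layer}.{v}.slope")
            for rel, u in g.incident_relations(v):
                lp["W_rel"][(v, rel)] = ad.glorot(rng, (din, d_out),
                                                  name=f"nv{layer}.{v}.{rel}")
        layers.append(lp)
    return {"layers": layers, "dropout": dropout}


def hgcn_aggregate(blocks: dict, H_all: dict[str, Tensor], layer_params: dict,
                   g: HeteroGraph, v: str) -> dict[str, Tensor]:
    """Per-relation aggregates N_{v,u} = norm(A_{v,u}) H_u W_{v,u} for type v."""
    out = {}
    for rel, u in g.incident_relations(v):
        if (v, rel) not in blocks:
            continue
        key = (v, rel)
        if key not in layer_params["W_rel"]:
            raise KeyError(f"missing weight for relation {key}")
        out[rel] = ad.spmm(blocks[key], H_all[u] @ layer_params["W_rel"][key])
    return out


def hgcn_combine(aggregates: dict[str, Tensor], H_v: Tensor) -> Tensor:
    """Plain combination 1/(|N(v)|+1) (sum_u N_{v,u} + H_v) over neighbor TYPES."""
    total = H_v
    for N in aggregates.values():
        total = total + N
    return total * (1.0 / (len(aggregates) + 1))


def multiple_fuse(relational: Tensor | np.ndarray, base: Tensor | np.ndarray):
    """Element-wise multiplicative ("Multiple") modality fusion."""
    r_shape = relational.shape if hasattr(relational, "shape") else np.shape(relational)
    b_shape = base.shape if hasattr(base, "shape") else np.shape(base)
    if tuple(r_shape) != tuple(b_shape):
        raise ValueError(f"shape mismatch in Multiple fusion: {r_shape} vs {b_shape}")
    if isinstance(relational, Tensor) or isinstance(base, Tensor):
        return ad.as_tensor(relational) * ad.as_tensor(base)
    return np.asarray(relational) * np.asarray(base)


def nv_forward(g: HeteroGraph, features: dict[str, Tensor | np.ndarray], params: dict,
               blocks: dict | None = None,
               rng: np.random.Generator | None = None) -> dict[int, dict[str, Tensor]]:
    """Two stacked neighborhood-view layers for all four node types.

    Per layer and node type: project the base features, aggregate each
    incident relation, fuse every relational aggregate (and the self path)
    with the projected base via elementwise product, mean-pool, then PReLU.
    ``rng`` enables feature-level dropout (training mode); None is eval mode.

    Returns ``{layer_index: {node_type: Tensor}}`` with layers numbered 1..H.
    """
    if blocks is None:
        blocks = normalized_blocks(g)
    H_all: dict[str, Tensor] = {t: ad.as_tensor(features[t]) for t in NODE_TYPES}
    out: dict[int, dict[str, Tensor]] = {}
    rate = params.get("dropout", 0.0)
    for li, lp in enumerate(params["layers"]):
        H_in = {t: ad.dropout(H_all[t], rate, rng) for t in NODE_TYPES}
        H_next: dict[str, Tensor] = {}
        for v in NODE_TYPES:
            base_proj = H_in[v] @ lp["W_self"][v]
            fused = [multiple_fuse(base_proj, base_proj)]
            aggs = hgcn_aggregate(blocks, H_in, lp, g, v)
            for rel in aggs:
                fused.append(multiple_fuse(aggs[rel], base_proj))
            pooled = fused[0]
            for f in fused[1:]:
                pooled = pooled + f
            pooled = pooled * (1.0 / len(fused))
            H_next[v] = ad.prelu(pooled, lp["slope"][v])
            if not np.isfinite(H_next[v].data).all():
                raise FloatingPointError(
                    f"non-finite NV activation at layer {li + 1}, type '{v}'")
        out[li + 1] = H_next
        H_all = H_next
    return out
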