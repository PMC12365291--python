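"""Full model assembly: both encoders, contrastive alignment, decoder.

A :class:`GHCDTIModel` owns the parameter bundle, the precomputed constant
operators (normalized adjacency blocks, meta-path operators, positive-pair
indicators) and the joint loss.  Forward passes are pure functions of the
parameters; dropout is driven by an explicit RNG so evaluation is
deterministic.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import RunConfig
from .contrastive import (ContrastConfig, build_pos_dicts,
                          init_projection_heads, multilevel_loss)
from .decoder import (DEFAULT_RECON_RELATIONS, LossWeights, fuse_views,
                      init_distmult_params, predict_dti, reconstruction_loss,
                      total_loss)
from .dv_encoder import (GWTConfig, dv_forward, init_attention_params,
                         init_dv_params, metapath_operator, semantic_attention)
from .hetgraph import DEFAULT_METAPATHS, NODE_TYPES, HeteroGraph
from .nv_encoder import init_nv_params, normalized_blocks, nv_forward


def _flatten(obj, out: list[Tensor]) -> None:
    if isinstance(obj, Tensor):
        if obj.requires_grad:
            out.append(obj)
    elif isinstance(obj, dict):
        for v in obj.values():
            _flatten(v, out)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _flatten(v, out)


def init_gcn_params(rng: np.random.Generator, d_in: int, d_out: int,
                    types=("drug", "protein"), n_layers: int = 2) -> dict:
    """Plain one-hop graph convolution per meta-path view (GWT-ablated deep view)."""
    layers = []
    for layer in range(n_layers):
        din = d_in if layer == 0 else d_out
        lp = {}
        for t in types:
            lp[t] = {
                "gcn": {p.label: {
                    "W": ad.glorot(rng, (din, d_out), name=f"gcn{layer}.{t}.{p.label}.W"),
                    "b": ad.zeros((d_out,), name=f"gcn{layer}.{t}.{p.label}.b"),
                    "slope": Tensor(np.array(0.25), requires_grad=True,
                                    name=f"gcn{layer}.{t}.{p.label}.slope"),
                } for p in DEFAULT_METAPATHS[t]},
                "att": init_attention_params(rng, d_out, name=f"gcn{layer}.{t}.att"),
            }
        layers.append(lp)
    return {"layers": layers, "types": types}


def gcn_forward(g: HeteroGraph, features, params: dict, operators,
                att_dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> dict[int, dict[str, Tensor]]:
    types = params["types"]
    H = {t: ad.as_tensor(features[t]) for t in types}
    out: dict[int, dict[str, Tensor]] = {}
    for li, lp in enumerate(params["layers"]):
        H_next = {}
        for t in types:
            views = []
            for label, G_op in operators[t].items():
                pr = lp[t]["gcn"][label]
                views.append(ad.prelu(ad.spmm(G_op, H[t] @ pr["W"]) + pr["b"],
                                      pr["slope"]))
            _, fused = semantic_attention(views, lp[t]["att"], rng=rng,
                                          dropout_rate=att_dropout)
            H_next[t] = fused
        out[li + 1] = H_next
        H = H_next
    return out


class GHCDTIModel:
    """Joint dual-view encoder + DistMult decoder over one heterogeneous graph."""

    def __init__(self, g: HeteroGraph, features: dict[str, np.ndarray],
                 config: RunConfig, seed: int = 0):
        self.g = g
        self.config = config
        self.features = {t: np.asarray(features[t], dtype=np.float64)
                         for t in NODE_TYPES}
        if config.standardize_features:
            # elementwise fusion multiplies variances, so inputs must arrive
            # at unit scale or activations collapse geometrically per layer
            for t, X in self.features.items():
                Xc = X - X.mean(axis=0, keepdims=True)
                rms = np.sqrt((Xc ** 2).mean())
                self.features[t] = Xc / max(rms, 1e-12)
        rng = np.random.default_rng(seed)
        d_in = self.features["drug"].shape[1]
        dim = config.dim

        self.blocks = normalized_blocks(g)
        self.operators = {
            t: {p.label: metapath_operator(g, p) for p in DEFAULT_METAPATHS[t]}
            for t in ("drug", "protein")
        }
        self.ccfg = ContrastConfig(tau=config.tau, k_drug=config.k_drug,
                                   k_protein=config.k_protein,
                                   proj_dim=config.proj_dim)
        self.pos = build_pos_dicts(g, self.ccfg) if config.use_contrast else None

        self.nv_params = init_nv_params(rng, g, d_in, dim,
                                        n_layers=config.hgcn_layers,
                                        dropout=config.feat_dropout)
        if config.use_gwt:
            gcfg = GWTConfig(J=config.J, M=config.M, d_out=dim)
            self.dv_params = init_dv_params(rng, d_in, gcfg,
                                            n_layers=config.gwt_layers,
                                            att_dropout=config.att_dropout)
        else:
            self.dv_params = init_gcn_params(rng, d_in, dim,
                                             n_layers=config.gwt_layers)
        self.heads = (init_projection_heads(rng, dim, config.proj_dim)
                      if config.use_contrast else None)
        self.theta = init_distmult_params(rng, dim, DEFAULT_RECON_RELATIONS)
        self.weights = LossWeights(lam_contrast=config.lam_contrast if config.use_contrast else 0.0,
                                   lam_l2=config.lam_l2)

    # -- parameters -----------------------------------------------------------
    def trainables(self) -> list[Tensor]:
        out: list[Tensor] = []
        _flatten(self.nv_params, out)
        _flatten(self.dv_params, out)
        if self.heads is not None:
            _flatten(self.heads, out)
        _flatten(self.theta, out)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name or f"param_{i}": p.data.copy()
                for i, p in enumerate(self.trainables())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.trainables()):
            key = p.name or f"param_{i}"
            p.data = state[key].copy()

    # -- forward / loss -------------------------------------------------------
    def forward(self, rng: np.random.Generator | None = None):
        nv = nv_forward(self.g, self.features, self.nv_params,
                        blocks=self.blocks, rng=rng)
        if self.config.use_gwt:
            dv = dv_forward(self.g, self.features, self.dv_params,
                            operators=self.operators, rng=rng)
        else:
            dv = gcn_forward(self.g, self.features, self.dv_params,
                             self.operators, att_dropout=self.config.att_dropout,
                             rng=rng)
        phi = fuse_views(nv, dv)
        return nv, dv, phi

    def loss(self, mask: dict[str, np.ndarray] | None = None,
             rng: np.random.Generator | None = None) -> tuple[Tensor, dict]:
        nv, dv, phi = self.forward(rng=rng)
        L_re = reconstruction_loss(self.g, phi, self.theta,
                                   mask=mask,
                                   on_sigmoid=self.config.recon_on_sigmoid)
        L_cl = None
        if self.config.use_contrast:
            common = sorted(set(nv) & set(dv))
            nv_c = {h: nv[h] for h in common}
            dv_c = {h: dv[h] for h in common}
            L_cl = multilevel_loss(nv_c, dv_c, self.pos, self.ccfg, heads=self.heads)
        L = total_loss(L_re, L_cl, self.trainables(), self.weights)
        parts = {"L_re": float(L_re.data),
                 "L_cl": float(L_cl.data) if L_cl is not None else 0.0,
                 "L_total": float(L.data)}
        return L, parts

    # -- prediction -----------------------------------------------------------
    def predict_matrix(self) -> np.ndarray:
        """Drug x protein interaction probability matrix (eval mode)."""
        _, _, phi = self.forward(rng=None)
        return predict_dti(phi, self.theta)
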