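"""Deep-view encoder: multi-scale graph-wavelet transform per meta-path,
fused across meta-path views by semantic attention.

The "wavelet" here is the dyadic-scale propagation/difference construction:
node signals are propagated 1, 2 and 4 hops through the normalized meta-path
operator; absolute differences between adjacent scales (first order) and
between successive propagations of the concatenated multi-scale signal
(second order) expose band-pass structure — stable topological backbone in
the low frequencies, localized variation in the high frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from ._autodiff import Tensor
from .hetgraph import DEFAULT_METAPATHS, HeteroGraph, metapath_adjacency, sym_normalize


@dataclass(frozen=True)
class GWTConfig:
    """Dyadic scales s_j = 2^{j-1}, j = 1..J, plus M extra propagation steps
    of the concatenated signal for the second-order differences."""

    J: int = 3
    M: int = 3
    d_out: int = 2048

    def __post_init__(self):
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.M < 2:
            # two second-order differences (the default, M=3) need M >= 3;
            # at least one needs M >= 2
            raise ValueError("M >= 2 required for second-order differences")

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(2 ** (j - 1) for j in range(1, self.J + 1))

    @property
    def n_second_order(self) -> int:
        return self.M - 1

    def concat_width(self, d_in: int) -> int:
        # X^{(s_J)} + (J-1) first-order blocks + (M-1) second-order blocks of U
        return d_in * (1 + (self.J - 1) + (self.M - 1) * self.J)


def metapath_operator(g: HeteroGraph, path):
    """Symmetrically normalized meta-path adjacency (with self-loops).

    Returned sparse below ~5% density, dense otherwise (BLAS wins there)."""
    A = sym_normalize(metapath_adjacency(g, path))
    if (A != 0).mean() < 0.05:
        return sp.csr_matrix(A)
    return A


def propagate(G_op, X: Tensor | np.ndarray, t: int) -> Tensor:
    """Apply the propagation operator ``t`` times; t = 0 returns X unchanged."""
    if t < 0:
        raise ValueError("t must be >= 0")
    out = ad.as_tensor(X)
    if G_op.shape[1] != out.shape[0]:
        raise ValueError(f"operator {G_op.shape} incompatible with X {out.shape}")
    for _ in range(t):
        out = ad.spmm(G_op, out)
    return out


def multiscale_stack(G_op, X: Tensor | np.ndarray, cfg: GWTConfig):
    """Per-scale features X^{(s_1)}, ..., X^{(s_J)} and their concatenation U.

    Propagation is incremental: each scale continues from the previous one
    rather than restarting from X.
    """
    X = ad.as_tensor(X)
    scale_feats = []
    cur, steps_done = X, 0
    for s in cfg.scales:
        cur = propagate(G_op, cur, s - steps_done)
        steps_done = s
        scale_feats.append(cur)
    U = ad.concat(scale_feats, axis=1)
    return scale_feats, U


def wavelet_differences(scale_feats: list[Tensor], U: Tensor, G_op, cfg: GWTConfig):
    """First-order (adjacent-scale) and second-order (propagated-U) absolute
    differences, each concatenated along the feature axis."""
    f1_blocks = [ad.absolute(scale_feats[i] - scale_feats[i + 1])
                 for i in range(len(scale_feats) - 1)]
    U_steps = [U]
    for _ in range(cfg.M):
        U_steps.append(ad.spmm(G_op, U_steps[-1]))
    f2_blocks = [ad.absolute(U_steps[i] - U_steps[i + 1]) for i in range(1, cfg.M)]
    F1 = ad.concat(f1_blocks, axis=1) if f1_blocks else None
    F2 = ad.concat(f2_blocks, axis=1) if f2_blocks else None
    return F1, F2


def init_gwt_params(rng: np.random.Generator, d_in: int, cfg: GWTConfig,
                    name: str = "gwt") -> dict:
    width = cfg.concat_width(d_in)
    return {
        "W": ad.glorot(rng, (width, cfg.d_out), name=f"{name}.W"),
        "b": ad.zeros((cfg.d_out,), name=f"{name}.b"),
        "slope": Tensor(np.array(0.25), requires_grad=True, name=f"{name}.slope"),
    }


def gwt_forward(G_op, X: Tensor | np.ndarray, cfg: GWTConfig, params: dict) -> Tensor:
    """Z = PReLU(concat(X^{(s_J)}, F1, F2) W + b)."""
    X = ad.as_tensor(X)
    scale_feats, U = multiscale_stack(G_op, X, cfg)
    F1, F2 = wavelet_differences(scale_feats, U, G_op, cfg)
    blocks = [scale_feats[-1]]
    if F1 is not None:
        blocks.append(F1)
    if F2 is not None:
        blocks.append(F2)
    Z_in = ad.concat(blocks, axis=1)
    expect = cfg.concat_width(X.shape[1])
    if Z_in.shape[1] != expect or params["W"].shape[0] != expect:
        raise ValueError(f"concat width {Z_in.shape[1]} / W rows "
                         f"{params['W'].shape[0]}; expected {expect}")
    return ad.prelu(Z_in @ params["W"] + params["b"], params["slope"])


def init_attention_params(rng: np.random.Generator, d: int, d_att: int | None = None,
                          name: str = "att") -> dict:
    d_att = d_att or d
    return {
        "W": ad.glorot(rng, (d, d_att), name=f"{name}.W"),
        "b": ad.zeros((d_att,), name=f"{name}.b"),
        "a": ad.glorot(rng, (d_att, 1), name=f"{name}.a"),
    }


def semantic_attention(Z_views: list[Tensor | np.ndarray], params: dict,
                       rng: np.random.Generator | None = None,
                       dropout_rate: float = 0.0,
                       fusion: str = "weighted_sum"):
    """Softmax-weighted fusion of per-view embeddings with a shared attention
    vector: score_i = a^T mean_n tanh(W z + b), alpha = softmax(scores).

    Returns (alpha as a numpy array, fused Tensor).  ``rng`` enables
    attention-level dropout on the raw view scores (training mode).
    ``fusion="product"`` multiplies the alpha-scaled views elementwise
    instead of summing them (an alternative fusion variant; the weighted
    sum is the operative default).
    """
    if fusion not in ("weighted_sum", "product"):
        raise ValueError(f"unknown fusion mode '{fusion}'")
    if not Z_views:
        raise ValueError("empty view list")
    Z_views = [ad.as_tensor(Z) for Z in Z_views]
    scores = []
    for Z in Z_views:
        proj = ad.tanh(Z @ params["W"] + params["b"])
        scores.append(proj.mean(axis=0, keepdims=True) @ params["a"])  # (1,1)
    stacked = ad.concat(scores, axis=0)  # (P,1)
    stacked = ad.dropout(stacked, dropout_rate, rng)
    lse = ad.logsumexp(stacked, axis=0)  # (1,)
    fused = None
    alphas = []
    for i, Z in enumerate(Z_views):
        s_i = _row(stacked, i)
        a_t = ad.exp(s_i - lse)  # (1,1)
        alphas.append(a_t)
        term = a_t * Z
        if fused is None:
            fused = term
        elif fusion == "weighted_sum":
            fused = fused + term
        else:
            fused = fused * term
    alpha = np.array([float(a.data.ravel()[0]) for a in alphas])
    return alpha, fused


def _row(x: Tensor, i: int) -> Tensor:
    """Differentiable single-row slice of a 2-D tensor."""
    out = Tensor(x.data[i:i + 1], _parents=(x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[i:i + 1] = g
        x._accumulate(full)

    out._backward = bwd
    return out


def init_dv_params(rng: np.random.Generator, d_in: int, cfg: GWTConfig,
                   n_layers: int = 2, types: tuple[str, ...] = ("drug", "protein"),
                   att_dropout: float = 0.2) -> dict:
    """Per layer and node type: one GWT projection per meta-path view plus
    semantic-attention parameters."""
    layers = []
    for layer in range(n_layers):
        din = d_in if layer == 0 else cfg.d_out
        lp: dict = {}
        for t in types:
            paths = DEFAULT_METAPATHS[t]
            lp[t] = {
                "gwt": {p.label: init_gwt_params(rng, din, cfg,
                                                 name=f"dv{layer}.{t}.{p.label}")
                        for p in paths},
                "att": init_attention_params(rng, cfg.d_out,
                                             name=f"dv{layer}.{t}.att"),
            }
        layers.append(lp)
    return {"layers": layers, "cfg": cfg, "types": types, "att_dropout": att_dropout}


def dv_forward(g: HeteroGraph, features: dict[str, Tensor | np.ndarray], params: dict,
               operators: dict[str, dict[str, sp.csr_matrix]] | None = None,
               rng: np.random.Generator | None = None) -> dict[int, dict[str, Tensor]]:
    """Stacked deep-view layers for drug and protein nodes.

    ``operators`` maps node type -> {meta-path label: normalized operator};
    built from the graph when omitted.  Returns {layer: {type: Tensor}}.
    """
    cfg: GWTConfig = params["cfg"]
    types = params["types"]
    if operators is None:
        operators = {t: {p.label: metapath_operator(g, p) for p in DEFAULT_METAPATHS[t]}
                     for t in types}
    H = {t: ad.as_tensor(features[t]) for t in types}
    out: dict[int, dict[str, Tensor]] = {}
    for li, lp in enumerate(params["layers"]):
        H_next = {}
        for t in types:
            views, labels = [], []
            for label, G_op in operators[t].items():
                if label not in lp[t]["gwt"]:
                    raise KeyError(f"missing GWT params for meta-path '{label}'")
                views.append(gwt_forward(G_op, H[t], cfg, lp[t]["gwt"][label]))
                labels.append(label)
            _, fused = semantic_attention(views, lp[t]["att"], rng=rng,
                                          dropout_rate=params.get("att_dropout", 0.0))
            H_next[t] = fused
            if not np.isfinite(fused.data).all():
                raise FloatingPointError(
                    f"non-finite DV activation at layer {li + 1}, type '{t}'")
        out[li + 1] = H_next
        H = H_next
    return out
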