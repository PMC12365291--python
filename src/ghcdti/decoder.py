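"""View fusion, DistMult multi-relation reconstruction and the joint loss.

Final embeddings: drugs and proteins are the elementwise sum of the
top-layer neighborhood-view and deep-view embeddings; diseases and side
effects (which have no deep view) use the neighborhood view alone.  Every
reconstructed relation r gets a learnable diagonal bilinear form
Phi_src diag(theta_r) Phi_dst^T, trained with squared-error reconstruction
against the observed 0/1 matrices (held-out drug-protein pairs masked out),
plus the weighted contrastive term and a mean-square L2 penalty:

    L = L_re + lambda1 * L_cl + lambda2 * L_L2
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .hetgraph import RELATIONS, HeteroGraph

#: relations reconstructed by default (similarity relations excluded)
DEFAULT_RECON_RELATIONS = tuple(RELATIONS)


@dataclass
class LossWeights:
    lam_contrast: float = 0.5
    lam_l2: float = 20000.0

    def __post_init__(self):
        if self.lam_contrast < 0 or self.lam_l2 < 0:
            raise ValueError("loss weights must be non-negative")


def init_distmult_params(rng: np.random.Generator, d: int,
                         relations=DEFAULT_RECON_RELATIONS,
                         scale: float | None = None) -> dict[str, Tensor]:
    # keep initial bilinear scores O(1): |score| ~ d * E|phi|^2 * scale
    if scale is None:
        scale = 1.0 / d
    return {r: Tensor(rng.uniform(-scale, scale, size=d), requires_grad=True,
                      name=f"theta.{r}") for r in relations}


def fuse_views(nv: dict[int, dict[str, Tensor]],
               dv: dict[int, dict[str, Tensor]]) -> dict[str, Tensor]:
    """Per-type final embedding: NV + DV top layer (NV alone where no DV)."""
    top = max(nv)
    out: dict[str, Tensor] = {}
    for t, z in nv[top].items():
        if t in dv[max(dv)]:
            zd = dv[max(dv)][t]
            if z.shape != zd.shape:
                raise ValueError(f"width mismatch fusing '{t}': {z.shape} vs {zd.shape}")
            out[t] = z + zd
        else:
            out[t] = z
    return out


def distmult_reconstruct(phi_src: Tensor | np.ndarray, theta: Tensor | np.ndarray,
                         phi_dst: Tensor | np.ndarray,
                         sigmoid: bool = False) -> Tensor:
    """Bilinear scores Phi_src diag(theta) Phi_dst^T (optionally squashed)."""
    phi_src, phi_dst = ad.as_tensor(phi_src), ad.as_tensor(phi_dst)
    theta = ad.as_tensor(theta)
    if phi_src.shape[1] != theta.data.size or phi_dst.shape[1] != theta.data.size:
        raise ValueError(
            f"width mismatch: src {phi_src.shape[1]}, dst {phi_dst.shape[1]}, "
            f"theta {theta.data.size}")
    scores = (phi_src * theta) @ phi_dst.T
    return ad.sigmoid(scores) if sigmoid else scores


def reconstruction_loss(g: HeteroGraph, phi: dict[str, Tensor],
                        params: dict[str, Tensor],
                        relations=DEFAULT_RECON_RELATIONS,
                        mask: dict[str, np.ndarray] | None = None,
                        on_sigmoid: bool = True) -> Tensor:
    """Sum over relations of the squared Frobenius reconstruction error.

    ``mask`` maps relation -> binary matrix; entries with mask 0 (held-out
    pairs) are excluded from the residual.  With ``on_sigmoid`` the 0/1
    targets are compared against sigmoid scores (same scale); otherwise
    against the raw bilinear form.
    """
    total = None
    for rel in relations:
        if rel not in params:
            raise KeyError(f"no DistMult parameters for relation '{rel}'")
        src, dst = RELATIONS[rel]
        G = g.adj[rel]
        G_re = distmult_reconstruct(phi[src], params[rel], phi[dst], sigmoid=on_sigmoid)
        resid = G_re - Tensor(G)
        if mask is not None and rel in mask:
            resid = resid * Tensor(mask[rel].astype(np.float64))
        term = ad.square(resid).sum()
        total = term if total is None else total + term
    return total


def l2_penalty(trainables: list[Tensor]) -> Tensor:
    """Mean of squared entries over all trainable tensors."""
    total, count = None, 0
    for p in trainables:
        term = ad.square(p).sum()
        total = term if total is None else total + term
        count += p.data.size
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / count)


def total_loss(L_re: Tensor, L_cl: Tensor | None, trainables: list[Tensor],
               w: LossWeights) -> Tensor:
    """L = L_re + lambda1 * L_cl + lambda2 * L_L2."""
    for name, term in (("reconstruction", L_re), ("contrastive", L_cl)):
        if term is not None and not np.isfinite(term.data).all():
            raise FloatingPointError(f"non-finite {name} loss term")
    out = L_re
    if L_cl is not None and w.lam_contrast > 0:
        out = out + L_cl * w.lam_contrast
    if w.lam_l2 > 0:
        out = out + l2_penalty(trainables) * w.lam_l2
    return out


def predict_dti(phi: dict[str, Tensor | np.ndarray],
                params: dict[str, Tensor | np.ndarray]) -> np.ndarray:
    """Predicted interaction probability matrix sigmoid(Phi_d theta Phi_p^T)."""
    pd = phi["drug"].data if isinstance(phi["drug"], Tensor) else np.asarray(phi["drug"])
    pp = phi["protein"].data if isinstance(phi["protein"], Tensor) else np.asarray(phi["protein"])
    th = params["drug_protein"]
    th = th.data if isinstance(th, Tensor) else np.asarray(th)
    raw = (pd * th) @ pp.T
    return 1.0 / (1.0 + np.exp(-raw))
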