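"""Synthetic heterogeneous networks with planted low-rank drug-protein
structure.

The generator emulates the statistical shape of the real biomedical network:
a sparse drug-protein interaction matrix driven by latent factors, denser
association relations, similarity matrices correlated with the same factors,
and node features that are noisy projections of the factors.  Because the
drug-protein matrix is (noisy) low-rank by construction, a model that learns
the latent structure must separate held-out positives from negatives, which
makes end-to-end learnability testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_DIM, FeatureTable
from .hetgraph import HeteroGraph, add_self_loops


@dataclass
class SyntheticSpec:
    n_drug: int = 300
    n_protein: int = 400
    n_disease: int = 60
    n_se: int = 60
    latent_rank: int = 8
    densities: dict = field(default_factory=lambda: {
        "drug_protein": 0.02,
        "drug_drug": 0.05,
        "protein_protein": 0.05,
        "drug_disease": 0.05,
        "drug_se": 0.05,
        "protein_disease": 0.05,
    })
    noise_flip_prob: float = 0.01
    feature_noise: float = 0.1
    feature_dim: int = FEATURE_DIM
    seed: int = 0

    def __post_init__(self):
        if self.latent_rank > min(self.n_drug, self.n_protein):
            raise ValueError("latent rank exceeds min(n_drug, n_protein)")
        if min(self.n_drug, self.n_protein, self.n_disease, self.n_se) < 2:
            raise ValueError("all node counts must be >= 2")
        for rel, rho in self.densities.items():
            if not 0 < rho < 1:
                raise ValueError(f"density for '{rel}' must lie in (0,1)")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_bias(logits: np.ndarray, target: float) -> float:
    """Bisection for b such that mean(sigmoid(logits + b)) == target."""
    lo, hi = -40.0, 40.0
    f = lambda b: _sigmoid(logits + b).mean() - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"cannot calibrate density {target}; achievable range "
                         f"[{_sigmoid(logits + lo).mean():.3g}, "
                         f"{_sigmoid(logits + hi).mean():.3g}]")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _unit_rows(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    return F / np.where(norms == 0, 1.0, norms)


def _factor_bernoulli(F1: np.ndarray, F2: np.ndarray, density: float,
                      rng: np.random.Generator, scale: float = 4.0) -> np.ndarray:
    """Bernoulli adjacency with success probability sigmoid(a cos(F1_i, F2_j) + b),
    a and b calibrated to hit the target density.

    Rows are normalized before the product so edge probabilities depend only
    on factor *alignment*: raw-norm factors would otherwise give high-norm
    nodes elevated probability against every partner, and that popularity
    margin alone (degree, feature norm) would predict held-out edges without
    any pair-level learning."""
    M = _unit_rows(F1) @ _unit_rows(F2).T
    a = scale / max(M.std(), 1e-12)
    logits = a * M
    b = _calibrate_bias(logits, density)
    return (rng.random(M.shape) < _sigmoid(logits + b)).astype(np.float64)


def _cosine(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    C = (F / norms) @ (F / norms).T
    return C


def _factor_similarity(F: np.ndarray, noise: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Cosine-of-factors similarity in [0,1] with symmetric noise, unit diagonal."""
    S = np.clip(_cosine(F), 0.0, 1.0)
    N = rng.normal(scale=noise, size=S.shape)
    S = np.clip(S + (N + N.T) / 2, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def _pad_features(F: np.ndarray, dim: int, noise: float,
                  rng: np.random.Generator) -> np.ndarray:
    n, r = F.shape
    X = np.zeros((n, dim))
    X[:, :min(r, dim)] = F[:, :min(r, dim)]
    return X + rng.normal(scale=noise, size=X.shape)


def generate(spec: SyntheticSpec) -> tuple[HeteroGraph, FeatureTable, dict[str, np.ndarray]]:
    """Draw a planted-factor heterogeneous network.

    Returns the graph, a matched feature table (provenance "synthetic") and
    the ground-truth latent factors per node type.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.latent_rank
    factors = {
        "drug": rng.standard_normal((spec.n_drug, r)),
        "protein": rng.standard_normal((spec.n_protein, r)),
        "disease": rng.standard_normal((spec.n_disease, r)),
        "side_effect": rng.standard_normal((spec.n_se, r)),
    }

    dti = _factor_bernoulli(factors["drug"], factors["protein"],
                            spec.densities["drug_protein"], rng)
    if spec.noise_flip_prob > 0:
        # density-preserving label noise: flip a fraction of the edges off and
        # an equal number of non-edges on (independent per-entry flips would
        # swamp a sparse relation with false positives and shift its density)
        ones = np.flatnonzero(dti.ravel() == 1)
        zeros = np.flatnonzero(dti.ravel() == 0)
        n_flip = int(round(spec.noise_flip_prob * ones.size))
        off = rng.choice(ones, size=n_flip, replace=False)
        on = rng.choice(zeros, size=n_flip, replace=False)
        flat = dti.ravel()
        flat[off] = 0.0
        flat[on] = 1.0
        dti = flat.reshape(dti.shape)

    def within(F, density):
        A = _factor_bernoulli(F, F, density, rng)
        A = np.maximum(A, A.T)  # symmetrize
        return add_self_loops(A)

    def aux_bipartite(n_left, n_right, density):
        # associations to auxiliary node types come from their own random
        # factors, independent of the planted drug-protein structure, so side
        # information alone cannot reveal the interaction matrix
        L = rng.standard_normal((n_left, r))
        R = rng.standard_normal((n_right, r))
        return _factor_bernoulli(L, R, density, rng)

    adj = {
        "drug_protein": dti,
        "drug_drug": within(factors["drug"], spec.densities["drug_drug"]),
        "protein_protein": within(factors["protein"], spec.densities["protein_protein"]),
        "drug_disease": aux_bipartite(spec.n_drug, spec.n_disease,
                                      spec.densities["drug_disease"]),
        "drug_se": aux_bipartite(spec.n_drug, spec.n_se,
                                 spec.densities["drug_se"]),
        "protein_disease": aux_bipartite(spec.n_protein, spec.n_disease,
                                         spec.densities["protein_disease"]),
    }
    sim = {
        "drug": _factor_similarity(factors["drug"], 0.05, rng),
        "protein": _factor_similarity(factors["protein"], 0.05, rng),
    }
    counts = {"drug": spec.n_drug, "protein": spec.n_protein,
              "disease": spec.n_disease, "side_effect": spec.n_se}
    names = {t: [f"{t}_{i}" for i in range(n)] for t, n in counts.items()}
    g = HeteroGraph(node_counts=counts, adj=adj, sim=sim, names=names).validate()

    tables = {t: _pad_features(F, spec.feature_dim, spec.feature_noise, rng)
              for t, F in factors.items()}
    ft = FeatureTable(tables=tables,
                      provenance={t: "synthetic" for t in tables}).validate(g, spec.feature_dim)
    return g, ft, factors


# -- hand-written tiny fixture -------------------------------------------------

def tiny_fixture() -> tuple[HeteroGraph, FeatureTable]:
    """4-drug / 5-protein / 3-disease / 3-side-effect hand-written graph.

    The same values are stored as a text fixture directory in the test suite;
    this function is the in-code source of truth.
    """
    adj = {
        "drug_protein": np.array([
            [1, 1, 0, 0, 0],
            [0, 1, 1, 0, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0]], dtype=np.float64),
        "drug_drug": np.array([
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1]], dtype=np.float64),
        "protein_protein": np.array([
            [1, 1, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 0, 0, 1]], dtype=np.float64),
        "drug_disease": np.array([
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [1, 0, 0]], dtype=np.float64),
        "drug_se": np.array([
            [0, 1, 0],
            [1, 0, 0],
            [0, 0, 0],
            [0, 0, 1]], dtype=np.float64),
        "protein_disease": np.array([
            [1, 0, 0],
            [0, 0, 1],
            [0, 1, 0],
            [0, 0, 0],
            [1, 1, 0]], dtype=np.float64),
    }
    sim_drug = np.eye(4)
    sim_drug[0, 1] = sim_drug[1, 0] = 0.8
    sim_drug[1, 3] = sim_drug[3, 1] = 0.6
    sim_protein = np.eye(5)
    sim_protein[0, 1] = sim_protein[1, 0] = 0.9
    sim_protein[2, 3] = sim_protein[3, 2] = 0.7
    counts = {"drug": 4, "protein": 5, "disease": 3, "side_effect": 3}
    names = {t: [f"{t}_{i}" for i in range(n)] for t, n in counts.items()}
    g = HeteroGraph(node_counts=counts, adj=adj,
                    sim={"drug": sim_drug, "protein": sim_protein},
                    names=names).validate()
    rng = np.random.default_rng(1234)
    tables = {t: rng.standard_normal((n, FEATURE_DIM)) for t, n in counts.items()}
    ft = FeatureTable(tables=tables, provenance={t: "synthetic" for t in tables})
    return g, ft.validate(g)
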