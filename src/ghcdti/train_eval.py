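"""Training loop, cross-validation splits, negative sampling and metrics.

Standard evaluation is stratified 10-fold cross-validation over the labeled
drug-protein pairs (positives plus 1:10 uniformly sampled negatives); the
training portion is further split 90/10 into train/validation.  Cold-start
modes partition the drugs (or proteins) themselves into folds so no test
entity appears in training in any form — its interaction edges are also
removed from the graph used to build adjacency blocks, meta-path operators
and positive-pair indicators.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._autodiff import Adam
from .config import RunConfig
from .hetgraph import HeteroGraph
from .model import GHCDTIModel


# -- negative sampling ---------------------------------------------------------

def sample_negatives(positives: list[tuple[int, int]], n_drug: int, n_prot: int,
                     ratio: int = 10, sim_drug: np.ndarray | None = None,
                     sim_protein: np.ndarray | None = None,
                     excl_cutoff: float = 0.0, seed: int = 0) -> list[tuple[int, int]]:
    """Uniformly sample ``ratio * len(positives)`` drug-protein non-pairs.

    Pairs whose drug (or protein) has similarity above ``excl_cutoff`` to a
    partner with a known interaction with the same protein (or drug) are
    excluded as likely false negatives; ``excl_cutoff <= 0`` disables the rule.
    Deterministic per seed.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    pos_set = set(positives)
    interacting = np.zeros((n_drug, n_prot), dtype=bool)
    for d, p in positives:
        interacting[d, p] = True

    forbidden = interacting.copy()
    if excl_cutoff > 0:
        if sim_drug is not None:
            # drug d similar to drug d' that interacts with protein p
            close = (sim_drug - np.eye(n_drug)) > excl_cutoff
            forbidden |= close @ interacting
        if sim_protein is not None:
            close = (sim_protein - np.eye(n_prot)) > excl_cutoff
            forbidden |= interacting @ close

    candidates = np.flatnonzero(~forbidden.ravel())
    need = ratio * len(positives)
    if candidates.size < need:
        raise ValueError(f"insufficient negative candidates: need {need}, "
                         f"have {candidates.size}")
    chosen = rng.choice(candidates, size=need, replace=False)
    negs = [(int(i // n_prot), int(i % n_prot)) for i in np.sort(chosen)]
    assert not pos_set.intersection(negs)
    return negs


# -- split plans ---------------------------------------------------------------

@dataclass
class Fold:
    train_pairs: np.ndarray  # (n, 3) columns: drug, protein, label
    valid_pairs: np.ndarray
    test_pairs: np.ndarray


@dataclass
class SplitPlan:
    mode: str
    folds: list[Fold]
    seed: int
    meta: dict = field(default_factory=dict)


def make_split_plan(pairs: np.ndarray, mode: str = "standard", k: int = 10,
                    seed: int = 0, n_drug: int | None = None,
                    n_prot: int | None = None,
                    valid_fraction: float = 0.1) -> SplitPlan | list[SplitPlan]:
    """Build a cross-validation plan over labeled (drug, protein, label) rows.

    ``standard``: stratified k-fold over pairs; per-fold positive counts
    differ by at most one.  ``cold_drug`` / ``cold_target``: partition the
    entities into k folds; every pair touching a test entity goes to test and
    the remaining pairs are split 90/10 into train/validation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pairs = np.asarray(pairs, dtype=np.int64)
    labels = pairs[:, 2]
    if mode == "standard":
        if labels.sum() < k:
            raise ValueError(f"fewer than k={k} positives; use a smaller k")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = []
        for tr, te in skf.split(pairs, labels):
            tr_idx, va_idx = train_test_split(
                tr, test_size=valid_fraction, random_state=seed,
                stratify=labels[tr])
            folds.append(Fold(pairs[tr_idx], pairs[va_idx], pairs[te]))
        return SplitPlan(mode=mode, folds=folds, seed=seed)

    if mode not in ("cold_drug", "cold_target"):
        raise ValueError(f"unknown split mode '{mode}'")
    col = 0 if mode == "cold_drug" else 1
    n_ent = n_drug if mode == "cold_drug" else n_prot
    if n_ent is None:
        n_ent = int(pairs[:, col].max()) + 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_ent)
    ent_folds = np.array_split(perm, k)
    folds = []
    for ent_test in ent_folds:
        test_mask = np.isin(pairs[:, col], ent_test)
        rest = pairs[~test_mask]
        if rest[:, 2].sum() == 0 or pairs[test_mask][:, 2].sum() == 0:
            raise ValueError("a fold has zero positives; use a smaller k")
        tr_idx, va_idx = train_test_split(
            np.arange(len(rest)), test_size=valid_fraction,
            random_state=seed, stratify=rest[:, 2])
        folds.append(Fold(rest[tr_idx], rest[va_idx], pairs[test_mask]))
    return SplitPlan(mode=mode, folds=folds, seed=seed,
                     meta={"entity_column": col})


# -- metrics -------------------------------------------------------------------

def evaluate(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, AUPR).  AUC is the tie-aware concordance probability; AUPR is
    the step-wise (non-interpolated) area under the precision-recall curve."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def bootstrap_ci(scores: np.ndarray, labels: np.ndarray, B: int = 1000,
                 level: float = 0.95, seed: int = 0,
                 max_redraws: int = 1000) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CI for AUC and AUPR over prediction rows.

    Single-class resamples are redrawn (they leave the metrics undefined).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores, labels = np.asarray(scores), np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs, auprs = [], []
    for _ in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        a, p = evaluate(scores[idx], labels[idx])
        aucs.append(a)
        auprs.append(p)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    return {
        "auc": (float(np.percentile(aucs, lo)), float(np.percentile(aucs, hi))),
        "aupr": (float(np.percentile(auprs, lo)), float(np.percentile(auprs, hi))),
    }


# -- training ------------------------------------------------------------------

def _masked_graph(g: HeteroGraph, heldout_pairs: np.ndarray) -> HeteroGraph:
    """Copy of the graph with held-out positive DTI edges removed from the
    structure (they must not leak into adjacency or meta-path operators)."""
    g2 = copy.deepcopy(g)
    A = g2.adj["drug_protein"]
    for d, p, y in heldout_pairs:
        if y == 1:
            A[d, p] = 0
    return g2


def _dti_mask(n_drug: int, n_prot: int, heldout_pairs: np.ndarray) -> np.ndarray:
    """1 = entry participates in the reconstruction loss, 0 = held out."""
    mask = np.ones((n_drug, n_prot))
    for d, p, _ in heldout_pairs:
        mask[d, p] = 0.0
    return mask


@dataclass
class TrainResult:
    model: GHCDTIModel
    history: list[dict]
    best_epoch: int
    val_auc: float
    val_aupr: float


def train(g: HeteroGraph, features: dict[str, np.ndarray], config: RunConfig,
          fold: Fold, seed: int = 0, verbose: bool = False,
          restore_best: bool = True) -> TrainResult:
    """Full-batch joint training of both encoders, the contrastive module and
    the decoder on one fold, with early stopping on validation AUPR.

    ``restore_best=False`` keeps the final-epoch parameters (used for
    degenerate controls whose validation metric is meaningless)."""
    heldout = np.vstack([fold.valid_pairs, fold.test_pairs])
    g_train = _masked_graph(g, heldout)
    n_drug, n_prot = g.node_counts["drug"], g.node_counts["protein"]
    mask = {"drug_protein": _dti_mask(n_drug, n_prot, heldout)}

    model = GHCDTIModel(g_train, features, config, seed=seed)
    opt = Adam(model.trainables(), lr=config.lr)
    drop_rng = np.random.default_rng(seed + 1)

    best = {"metric": -np.inf, "state": model.state_dict(), "epoch": 0,
            "auc": 0.0, "aupr": 0.0}
    stale = 0
    history = []
    vd, vp, vy = fold.valid_pairs[:, 0], fold.valid_pairs[:, 1], fold.valid_pairs[:, 2]
    for epoch in range(1, config.epochs + 1):
        opt.zero_grad()
        rng = drop_rng if (config.feat_dropout > 0 or config.att_dropout > 0) else None
        L, parts = model.loss(mask=mask, rng=rng)
        if not np.isfinite(L.data):
            raise FloatingPointError(f"training diverged at epoch {epoch}; "
                                     f"last finite parts: {history[-1] if history else None}")
        L.backward()
        opt.step()

        rec = {"epoch": epoch, **parts}
        history.append(rec)
        if epoch % config.eval_every == 0:
            Y = model.predict_matrix()
            val_auc, val_aupr = evaluate(Y[vd, vp], vy)
            rec.update(val_auc=val_auc, val_aupr=val_aupr)
            if verbose:
                print(f"epoch {epoch}: L={parts['L_total']:.4f} "
                      f"L_re={parts['L_re']:.4f} L_cl={parts['L_cl']:.4f} "
                      f"val_auc={val_auc:.4f} val_aupr={val_aupr:.4f}")
            if val_aupr > best["metric"]:
                best = {"metric": val_aupr, "state": model.state_dict(),
                        "epoch": epoch, "auc": val_auc, "aupr": val_aupr}
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    if restore_best:
        model.load_state_dict(best["state"])
    return TrainResult(model=model, history=history, best_epoch=best["epoch"],
                       val_auc=best["auc"], val_aupr=best["aupr"])


@dataclass
class EvalReport:
    mode: str
    fold_metrics: list[dict]
    mean_auc: float
    std_auc: float
    mean_aupr: float
    std_aupr: float
    ci: dict
    runtime_s: float
    last_model: "GHCDTIModel | None" = None

    def to_dict(self) -> dict:
        return {"mode": self.mode, "folds": self.fold_metrics,
                "auc": {"mean": self.mean_auc, "std": self.std_auc,
                        "ci95": self.ci.get("auc")},
                "aupr": {"mean": self.mean_aupr, "std": self.std_aupr,
                         "ci95": self.ci.get("aupr")},
                "runtime_s": self.runtime_s}


def run_plan(g: HeteroGraph, features: dict[str, np.ndarray], config: RunConfig,
             plan: SplitPlan, seed: int = 0, bootstrap: int = 0,
             verbose: bool = False) -> EvalReport:
    """Train and evaluate every fold of a split plan."""
    t0 = time.time()
    fold_metrics = []
    all_scores, all_labels = [], []
    for fi, fold in enumerate(plan.folds):
        res = train(g, features, config, fold, seed=seed + fi, verbose=verbose)
        Y = res.model.predict_matrix()
        td, tp, ty = fold.test_pairs[:, 0], fold.test_pairs[:, 1], fold.test_pairs[:, 2]
        auc, aupr = evaluate(Y[td, tp], ty)
        fold_metrics.append({"fold": fi, "auc": auc, "aupr": aupr,
                             "best_epoch": res.best_epoch})
        all_scores.append(Y[td, tp])
        all_labels.append(ty)
    last_model = res.model
    aucs = [m["auc"] for m in fold_metrics]
    auprs = [m["aupr"] for m in fold_metrics]
    ci = {}
    if bootstrap:
        ci = bootstrap_ci(np.concatenate(all_scores), np.concatenate(all_labels),
                          B=bootstrap, seed=seed)
    return EvalReport(mode=plan.mode, fold_metrics=fold_metrics,
                      mean_auc=float(np.mean(aucs)), std_auc=float(np.std(aucs)),
                      mean_aupr=float(np.mean(auprs)), std_aupr=float(np.std(auprs)),
                      ci=ci, runtime_s=time.time() - t0, last_model=last_model)


def labeled_pairs(g: HeteroGraph, config: RunConfig, seed: int = 0) -> np.ndarray:
    """Positives from the DTI matrix plus 1:ratio sampled negatives, as an
    (n, 3) integer array of (drug, protein, label) rows."""
    A = g.adj["drug_protein"]
    pos = [(int(d), int(p)) for d, p in zip(*np.nonzero(A))]
    negs = sample_negatives(pos, g.node_counts["drug"], g.node_counts["protein"],
                            ratio=config.neg_ratio,
                            sim_drug=g.sim.get("drug"),
                            sim_protein=g.sim.get("protein"),
                            excl_cutoff=config.neg_excl_cutoff, seed=seed)
    rows = [(d, p, 1) for d, p in pos] + [(d, p, 0) for d, p in negs]
    return np.asarray(rows, dtype=np.int64)
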