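"""Run configuration with the model's default hyperparameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """All tunable hyperparameters.

    Defaults: up to 5000 epochs with early stopping after 500 stale
    validation rounds, node embedding dimension 2048, learning rate 1e-3,
    dropout 0.5 at the feature level and 0.2 at the attention level,
    temperature 0.5, a 1:10 positive:negative ratio, loss weights
    lambda1 = 0.5 (contrastive) and lambda2 = 20000 (mean-square L2),
    Top-10/Top-5 contrastive positives for drugs/proteins and J = 3 wavelet
    scales.
    """

    epochs: int = 5000
    patience: int = 500
    dim: int = 2048
    lr: float = 0.001
    feat_dropout: float = 0.5
    att_dropout: float = 0.2
    tau: float = 0.5
    neg_ratio: int = 10
    lam_contrast: float = 0.5
    lam_l2: float = 20000.0
    k_drug: int = 10
    k_protein: int = 5
    J: int = 3
    M: int = 3
    proj_dim: int = 512
    feature_dim: int = 128
    hgcn_layers: int = 2
    gwt_layers: int = 2
    use_gwt: bool = True
    use_contrast: bool = True
    recon_on_sigmoid: bool = True
    standardize_features: bool = True
    sim_threshold: float = 0.5
    neg_excl_cutoff: float = 0.8
    cv_folds: int = 10
    n_seeds_cold: int = 3
    eval_every: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"invalid config keys {sorted(unknown)}; "
                             f"valid keys: {sorted(valid)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "RunConfig":
        d = self.to_dict()
        d.update(kw)
        return RunConfig(**d)
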