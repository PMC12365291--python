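# ghcdti

Drug–target interaction (DTI) prediction on heterogeneous biomedical
networks. The package implements a dual-view graph neural model: a
**neighborhood-view encoder** (per-relation heterogeneous graph convolution
with multiplicative "Multiple" fusion and mean pooling, stacked twice) and a
**deep-view encoder** (a dyadic-scale graph-wavelet transform over meta-path
graphs, fused across meta-paths by semantic attention). The two views are
aligned with a multi-level bidirectional InfoNCE objective over
path-derived positive pairs, fused, and decoded with relation-specific
DistMult bilinear forms that jointly reconstruct all network relations:

    L = Σ_r ‖G_r − Φ_src diag(θ_r) Φ_dstᵀ‖²  +  λ₁ L_contrast  +  λ₂ L_L2

It is aimed at computational drug-discovery work: ranking candidate
drug–protein pairs from network context (known interactions, drug–drug and
protein–protein networks, disease and side-effect associations) plus
molecular features (MACCS fingerprints, sequence composition), with
standard, cold-drug and cold-target cross-validation protocols and
bootstrap confidence intervals.

All training runs on plain numpy/scipy (the package carries its own small
reverse-mode autodiff tape); no GPU or deep-learning framework is needed.

## Data

Input directories follow the DTINet dense-matrix dialect
(`mat_drug_protein.txt`, `mat_drug_drug.txt`, …, `Similarity_Matrix_Drugs.txt`,
`drug.txt`, `protein.txt`; file names configurable through a
`manifest.json`). A synthetic generator produces networks with planted
low-rank drug–protein structure in the exact same dialect, so the whole
pipeline runs without any downloads:

```bash
ghcdti simulate --spec spec.yaml --out data/synthetic --seed 7
ghcdti cv       --data data/synthetic --out runs/cv --seed 7
ghcdti coldstart --data data/synthetic --mode cold_drug --n-seeds 3 --out runs/cold
```

## Worked example

```python
from ghcdti.benchmark import benchmark_spec, benchmark_config, run_planted_benchmark

# 300 drugs x 400 proteins, planted rank-8 interactions at 2% density
result = run_planted_benchmark(seed=1)
print(f"held-out AUC  {result['auc']:.3f}")
print(f"held-out AUPR {result['aupr']:.3f}")
```

Output from this exact call:

```
held-out AUC  0.816
held-out AUPR 0.365
```

The model was trained on one stratified fold (90 % train / 10 % validation
inside the training partition) and scored on the 2 654 held-out pairs
(1:10 positive:negative). AUC 0.816 means a random true interaction
outranks a random non-interaction 81.6 % of the time; AUPR 0.365 compares
against a 0.091 positive base rate, so the ranking concentrates true pairs
near the top. The benchmark's planted signal is pure pair-level factor
alignment — node-popularity margins are deliberately removed — and a
control trained identically after shuffling the training labels falls to
chance (AUC ≈ 0.5), which is the package's evidence that the planted
structure, not an artifact, is being learned.

## Layout

| Module | Contents |
| --- | --- |
| `ghcdti.hetgraph` | graph data model, DTINet I/O, normalization, meta-paths |
| `ghcdti.features` | MACCS+PCA, sequence stats+PCA, biased-walk embeddings |
| `ghcdti.nv_encoder` | per-relation heterogeneous convolution, Multiple fusion |
| `ghcdti.dv_encoder` | graph-wavelet transform, semantic attention |
| `ghcdti.contrastive` | pos-pair construction, multi-level InfoNCE |
| `ghcdti.decoder` | view fusion, DistMult reconstruction, joint loss |
| `ghcdti.train_eval` | training loop, CV splits, negative sampling, metrics |
| `ghcdti.synthetic` | planted-factor generator, hand-written tiny fixture |
| `ghcdti.benchmark` | end-to-end recoverability and ablation benchmarks |
| `ghcdti.cli` | `ghcdti` command: simulate / train / cv / coldstart / predict / ablate |

See `docs/methods.md` for the model equations, defaults and their
rationale, the synthetic-data design, and known limitations.
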