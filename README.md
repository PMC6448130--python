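# hopes — high-order path elucidated similarity for multi-omics integration

Cancer cohorts are routinely profiled on several omics layers at once —
gene expression, DNA methylation, miRNA expression — and no single layer
separates all molecular subtypes: each one typically leaves some subgroups
indistinguishable. `hopes` fuses the per-layer patient-similarity networks
into one global similarity matrix and carries it through subtype
discovery (spectral / consensus clustering), clinical evaluation
(log-rank survival tests, χ² association with histology) and
back-projection onto the original features (multi-cluster feature
selection). It is aimed at computational biologists who have 2+
sample-aligned omics matrices and want robust, reproducible molecular
subtypes.

## The model

Each layer *i* yields a KNN-restricted, row-normalised local affinity
*S<sub>i</sub>* (scaled exponential kernel on Euclidean sample distances,
truncated to each sample's K nearest neighbours). The fused similarity
*W* minimises the high-order path energy

```
E(W) = Σᵢ ( ‖W − Sᵢ‖²F  +  α‖W − SᵢW‖²F  +  β Σⱼ ‖W − Sᵢ W Sⱼᵀ‖²F )  +  λ‖W‖²F
```

* **path-0** fits every layer's observed neighbour weights (and anchors
  *W* to zero where a layer records no neighbour relation),
* **path-1** makes *W* stable under one-hop smoothing by each layer,
* **path-2** demands that every retained edge survive two-hop filtration
  through each *pair* of layers — an edge backed by a single layer is
  progressively weakened.

The energy is a strictly convex quadratic, minimised by consensus ADMM
(closed-form path-0 block, prefactorised per-layer path-1 solves, one
pooled conjugate-gradient path-2 block) and verified in the test suite
against an independent dense Kronecker-form solve. The classical
similarity-network-fusion (SNF) iteration is included as a baseline, and
a seeded synthetic multi-omics generator reproduces the benchmark design
in which each layer merges a different cluster pair so that only
integration can recover the full structure.

## Worked example

```python
from hopes import HOPES, SNF
from hopes.evaluation import nmi
from hopes.simulate import default_config, simulate_multiomics

sim = simulate_multiomics(default_config(seed=0))   # 4 x 50 samples, 3 layers
res = HOPES(sim.dataset, alpha=1.0, beta=1.0).fit()
print(res.summary())
subtypes = res.cluster(k=4, seed=0)
print("fused NMI:", round(nmi(subtypes, sim.true_labels), 3))
```

```
Similarity Fusion Results
==========================================================
Method:                   HOPES
No. samples:              200
No. layers:               3
  layer rna:              500 features
  layer methylation:      500 features
  layer mirna:            200 features
Affinity K / mu:          20 / 0.5
alpha / beta:             1 / 1
ridge / rho / tol:        1e-08 / 1 / 1e-06
Iterations used:          73
Converged:                True
Final energy:             23.5506
Final primal/dual res:    2.67e-06 / 8.84e-07
==========================================================
fused NMI: 1.0
```

Each of the three simulated layers merges a different cluster pair, so no
single layer can exceed NMI ≈ 0.86 against the 4-cluster truth (its
spectral clustering typically reaches ≈ 0.80); the fused similarity
recovers the full structure (NMI 1.0). `res.select_features("rna",
k_clusters=4, n_top=15)` then ranks the layer's features by how strongly
they track the fused cluster structure.

The same workflow is scriptable from the shell:

```bash
hopes simulate --out-dir data/ --seed 0
hopes fuse --layer data/rna.tsv --layer data/methylation.tsv \
           --layer data/mirna.tsv --method hopes --out W.tsv
hopes cluster --similarity W.tsv --k 4 --seed 0 --out labels.tsv
hopes evaluate --pred labels.tsv --truth data/truth.tsv --out metrics.json
```

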