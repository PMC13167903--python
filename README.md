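# ithsim

Agent-based simulation and analysis of **intratumor heterogeneity (ITH)**
in BRAF-driven superficially spreading melanoma.

Tumors are rarely genetically uniform: branching clonal evolution produces
subclones that differ in proliferation, survival, immune visibility and
motility, and that diversity shapes prognosis and therapy response.
`ithsim` provides a hallmark-driven lattice model of this process — a
tumor–immune system in which melanocytes carry explicit 50-gene binary
genomes and cytotoxic T lymphocytes (CTLs) prune immunogenic subclones —
together with the metrics needed to quantify the resulting heterogeneity,
morphology and spatial structure, and tools for sampling strategies and
sensitivity analysis. It is aimed at computational oncologists and
mathematical biologists who want a reproducible platform for exploring how
cancer-hallmark interactions shape clonal architecture.

## Model

Each melanocyte has a genome of n = 50 binary genes, seven of which are
melanoma driver genes (BRAF, NRAS, KIT, TERT, CDKN2A, MITF, PTEN; BRAF,
NRAS and KIT are mutually exclusive). Each driver carries hallmark tags,
and the number of mutated drivers per hallmark d_i sets the cell's
per-step action probabilities through decade scaling with driver strength
f:

    p = p0 · 10^(f·d_p)      (proliferation, clipped to 1)
    q = q0 · 10^(−f·d_q)     (apoptosis)
    r = r0 · 10^(f·d_r)      (per-gene mutation probability per division)
    a = a0 · 10^(f·(d_c̃ − d_c))   (antigenicity, a0 ~ U[1,2])

Cells live on a 2D lattice; daughters occupy empty Moore-neighborhood
sites (surface growth), and in the motility extension BRAF-mutant cells
move with probability m0, pushing rows of cells outward when crowded.
An immune stimulatory factor F(h) sums the antigenicity of melanoma cells
within Chebyshev radius 5 of each grid point; CTLs are recruited to the
tumor periphery by a Poisson process with Hill-function rate

    s_T = s0 + f_T · F_b^n_T / (γ_T + F_b^n_T),

where F_b is the total ISF of border tumor cells, and they kill,
proliferate and chemotax in an ISF-dependent manner.

Analysis modules implement:

* **entropy ε** — SVD entropy of the pairwise genome-similarity matrix
  S_ij = 1 − Hamming(g_i, g_j)/n (ε = 0 for a monoclonal tumor, ln b for b
  equal fully dissimilar clones);
* **β** — mean mutation count per cell (tumor mutational burden proxy);
* **clustered FD** — mean box-counting fractal dimension over subclone
  masks (k-means on driver-gene combinations);
* **convexity C = P_H/P** and **border fractal dimension FD_b** of the
  tumor mask;
* **cross-pair correlation function (cPCF)** with exact window edge
  correction (1 under complete spatial randomness);
* four **population sampling strategies** (simple random, CLARANS-stratified,
  time-systematic, space-systematic) with error evaluation against
  full-population metrics;
* **Morris elementary-effects (MOAT) screening** of model parameters.

## Worked example

```python
import dataclasses
import numpy as np
import ithsim
from ithsim import engine, ith, morphology

hp = dataclasses.replace(ithsim.HallmarkParams(), r0=1e-4, f=1.6)
cfg = ithsim.SimulationConfig(hallmarks=hp, c_max=10_000, seed=1)
trace = engine.run(cfg)
snap = trace.final

print(trace.termination, trace.n_steps, snap["type"].value_counts().to_dict())
metrics = ith.population_metrics(snap, rng=np.random.default_rng(0),
                                 grid_size=cfg.grid_size)
mask = morphology.tumor_mask(snap, cfg.grid_size)
rep = morphology.morphology_report(mask)
print({k: round(v, 3) for k, v in metrics.items()},
      round(rep.C, 3), round(rep.FD_b, 3))
```

prints

```
c_max 83 {'MTC': 10031, 'CTL': 30, 'NC': 8}
{'m': 10039.0, 'entropy': 0.151, 'beta': 2.182, 'clustered_fd': 1.822} 0.829 1.037
```

The tumor reached its 10,000-cell stopping size in 83 steps; at this high
mutation rate (r0 = 1e-4) the population carries β ≈ 2.2 mutations per
cell and a nonzero heterogeneity entropy, its driver-defined subclones are
near-space-filling patches (clustered FD ≈ 1.8), and the non-motile tumor
remains compact (C ≈ 0.83) with a smooth border (FD_b ≈ 1.04). Lowering
r0 to 1e-6 collapses ε and β toward the monoclonal anchor while leaving
growth speed essentially unchanged — mutation rate, not driver strength,
controls heterogeneity.

A command-line interface mirrors the library
(`ithsim run|sweep|morris|hotcold|metrics|sample|pcf`); see
`ithsim --help`.

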