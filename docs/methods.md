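# Methods

## Model overview and assumptions

`ithsim` simulates branching clonal evolution of a BRAF-founded melanoma
on a 2D square lattice with two agent types: melanocytes (normal cells,
NCs, and melanoma tumor cells, MTCs) and cytotoxic T lymphocytes (CTLs).
The 2D geometry targets radially growing superficially spreading
melanoma; it deliberately omits vertical invasion, stroma, vasculature and
mechanics. Time steps are abstract: calibration of a step to wall-clock
tumor growth is out of scope, so all stopping conditions are expressed in
steps (`t_max`) or population size (`c_max`).

A simulation starts from 9 unmutated NCs and one MTC carrying only the
BRAF founder mutation, placed contiguously at the grid center with the MTC
on the edge of the NC block (a fully enclosed founder could never divide
under the surface-growth rule). Each step sweeps the melanocytes alive at
the start of the step in a fresh random order (asynchronous update; random
order avoids directional artifacts), then runs the immune round, then
increments the step counter. Per cell the action order is death →
division → motility:

* apoptosis with probability q;
* otherwise a division attempt with probability p: the daughter inherits
  the parent genome after one mutation pass (each wild gene flips with
  probability r; mutated genes never revert; at most one of BRAF/NRAS/KIT
  may ever be mutated, conflicts resolved in fixed index order) and is
  placed on a uniformly chosen empty Moore site — with no empty site the
  division fails (surface growth, which produces the compact radial
  morphology; pushing is reserved for motility);
* a BRAF-mutant cell that neither died nor divided moves with probability
  m0: to a uniform empty Moore site if one exists, otherwise one site in a
  uniform direction, pushing the contiguous run of occupied cells outward
  by one site (aborted at the grid boundary).

All randomness flows through one `numpy` generator per simulation, so a
(config, seed) pair determines the trajectory bitwise, and the immune
round is skipped without consuming random numbers when it cannot act
(zero recruitment, no live CTLs) so immune-free configurations reproduce
runs of the pure growth model exactly.

## Hallmark parameterization

Mutated drivers shift their hallmark's base rate by f decades (see
README for the formulas). Defaults, all configurable in YAML:

| parameter | default | meaning |
|---|---|---|
| p0 | 0.01 | base proliferation probability / step |
| q0 | 0.002 | base apoptosis probability / step |
| r0 | 1e-5 | base per-gene mutation probability / division |
| f | 1.6 | decades shifted per mutated driver |
| a0 | U[1, 2] | base antigenicity, drawn at creation, inherited |
| m0 | 0 | BRAF-mutant motility probability / step |

p0 and q0 describe slowly renewing normal melanocytes; with f = 1.6 the
BRAF founder divides at p ≈ 0.40 per step and a 10,000-cell tumor forms in
roughly 80–120 steps on the default 300×300 grid (600×600 is appropriate
for 50,000 cells). p and r are clipped to 1 after scaling — the decade
form exceeds 1 for f ≳ 1.4 with two drivers — which keeps probabilities
valid and preserves monotonicity in the driver counts.

The driver map ships as `ithsim/data/driver_map.yaml`: BRAF {p, q, c},
NRAS {p}, KIT {p}, TERT {q}, CDKN2A {p}, MITF {q}, PTEN {q, r}, with
BRAF/NRAS/KIT mutually exclusive. These hallmark assignments are editable
conventions of this toolkit grounded in the genes' known roles
(BRAF-MAPK activation drives proliferation, survival and immune evasion;
TERT/MITF support survival; CDKN2A loss releases the cell cycle; PTEN
loss marks advanced, genomically unstable tumors). Removing BRAF's
immune-evasion tag `c` produces the *hot* (immune-infiltrated) tumor
variant used in the immune-contrast experiments; the default map is the
*cold* variant. Passenger mutations carry no hallmark effect by default;
`passenger_antigenicity` optionally adds a small additive antigenicity
increment per passenger mutation (off by default because the underlying
mechanism is not specified by the biology we encode).

## Immune subsystem

The immune stimulatory factor F(h) is the unweighted sum of MTC
antigenicities within Chebyshev radius 5 of h (NCs contribute 0). The
uniform kernel means one isolated cell produces a flat plateau — a CTL
cannot home in on a single source — but across any multi-cell tumor the
field counts sources in range and slopes toward the tumor mass, which is
what chemotaxis requires.

CTL recruitment is Poisson with the Hill rate s_T of the total border-MTC
ISF F_b (border MTC = MTC with a non-MTC Moore neighbor); recruits land
on free sites within Chebyshev distance 2 of a border MTC. Each CTL per
round: dies with constant probability q_i; else kills the
highest-antigenicity adjacent MTC with probability k0·F/(isf_sat + F);
else divides into a CTL-free Moore site with probability
p_i0·F/(isf_sat + F); else moves strictly uphill in F (ties uniform,
holds position on a plateau). The saturating (Michaelis–Menten) forms are
this package's choice for "ISF-dependent" kill and proliferation — they
bound the probabilities and match the Hill-style recruitment. Defaults
(q_i = 0.05, p_i0 = 0.2, k0 = 0.5, s0 = 0.5, f_T = 5, n_T = 2,
γ_T = 3·10⁴ ≈ F_b² of a ~1,000-cell cold tumor border, isf_sat = 10) are
toolkit defaults, not published measurements.

Under these defaults the hot variant experiences strong immunoediting: at
low mutation rate the founder MTC is eliminated outright in roughly 2 of
10 seeds before a fixed early measurement step. The hot/cold experiment
reports CTL density inside the MTC convex hull as NaN for eliminated
tumors, and comparisons exclude those pairs.

## Heterogeneity metrics

The mutation profile matrix M (cells × 50 genes) yields the similarity
matrix S_ij = 1 − Hamming/n; ε is the Shannon entropy of the normalized
singular values of S. Choices: the **natural logarithm** (so b equal,
fully dissimilar clones give ε = ln b — absolute values differ from a
log₁₀ or log₂ dialect by a constant factor); the **full singular
spectrum** (reproduces the ε = 0 monoclonal anchor); singular values
below 1e−12 of the largest are treated as numerical zeros, making the
monoclonal anchor exact. For m > 5,000 cells ε is computed on a 10%
space-systematic sample by default; `entropy_from_profiles` also exploits
duplicate genomes (S = U K Uᵀ shares its nonzero spectrum with
D^½ K D^½ over distinct genomes), which makes the full-population value
exact and cheap whenever the number of distinct genomes is modest.

Box-counting dimension: boxes of dyadic side 2, 4, …, ≤ half the longer
bounding-box side, anchored at the bounding-box origin; FD is the
least-squares slope of log N(ℓ) vs log(1/ℓ). Masks whose bounding box
supplies fewer than two box sizes get dimension 0 (point-like sets). The
clustered FD k-means-clusters cells by driver-gene combination and
averages the per-cluster mask dimensions; k defaults to the number of
combinations carried by ≥1% of cells (capped at 8), so a driver mutant
born a few steps before the snapshot — a handful of scattered cells with
box dimension ~0 — does not masquerade as a subclone and collapse the
mean. Note that a compact monoclonal tumor is a single near-plane-filling
cluster (FD ≈ 1.85 at 10,000 cells), so at desk scale the clustered FD
discriminates regime structure only weakly from above; the high-mutation
regime is asserted against a lower bound, not against the clonal regime.

Morphology: the tumor mask contains MTC sites only. Convexity
C = P_H/P uses the marching-squares (sub-pixel) contour length of the
largest Moore-connected component for P — edge-count perimeters
overestimate smooth boundaries and would bias C downward — and the convex
hull perimeter of occupied site centers for P_H, clipped to C ≤ 1.
Rasterization still inflates P by a few percent, so an ideal disk scores
C ≈ 0.94 rather than 1.0; detached satellites (a motility phenomenon) are
excluded from C/FD_b and reported separately as a satellite count. FD_b
applies box counting to the one-pixel boundary (erosion residue) of the
largest component.

The cross-pair correlation function for annulus (r₁, r₂] is the mean over
reference points of (target count in the annulus) / (λ_target × annulus
area ∩ window), i.e. per-reference exact window-intersection edge
correction and no other correction. Circle–window areas are computed by
Simpson integration of the clipped chord under the angular substitution
x = c_x − r·cosθ (relative error ~1e−4, validated against polygon
clipping), far below the Monte-Carlo noise of the estimator. cPCF = 1
under complete spatial randomness.

## Sampling strategies

All four strategies return exactly round(fraction·m) distinct cells
(default fraction 10%). SRS: uniform without replacement. TS: cells
sorted by birth step, evenly spaced positions from a random fractional
offset. SS: a regular grid of nodes with stride √(1/fraction) lattice
units and random offset; each node takes its nearest cell provided one
lies within one lattice unit (a node on empty space would otherwise snap
to tumor-rim cells and over-represent the boundary), with random top-up
for any shortfall. CC: CLARANS-style randomized k-medoids (k = 8,
numlocal = 2, maxneighbor = 50, chosen for speed at ~25,000 cells) on
(scaled position, driver profile) features, then proportional allocation
within clusters with largest-remainder rounding. Sample-based ε uses the
same estimator as the full population (no finite-sample correction), so
errors measure the sampling design alone; ε error falls back to absolute
error when the true ε is 0.

## Synthetic data

`synthetic.segregated_clones` emulates the end state of a
high-heterogeneity tumor for sampling studies: 8 clones filling compact,
densely packed lattice patches (Eden-like growth) arranged on a ring,
Dirichlet-unbalanced sizes, distinct genomes (BRAF + 2–6 private
passengers) and birth steps independent of clone identity — mirroring how
stochastic death and mutation decouple birth order from genotype in grown
tumors. It reproduces the features the samplers are sensitive to (spatial
segregation, unequal clone sizes, packed tissue) but not others (no
gradual within-clone divergence, no NC/CTL admixture, no density
gradients), so sampling results transfer to real snapshots only insofar
as those features dominate. Reference shapes (disk, Sierpinski carpet,
quadratic Koch island, CSR patterns) have known dimensions/statistics and
serve as oracles for the metric pipelines.

## Experiments

Sweeps derive one seed per (grid point, replicate) from a 64-bit mix of
the base seed, making every run independently reproducible; failures are
recorded per row without aborting the sweep. Desk-scale defaults —
c_max = 10,000 on a 300² grid with 5 replicates per condition, 5,000–6,000
cells for immune experiments — keep a full campaign within minutes on one
CPU while preserving the qualitative regime structure (the full-scale
50,000-cell setting is available through configuration). Morris screening
uses the standard trajectory design (p even levels, Δ = p/(2(p−1)),
default 4 levels) with μ* = mean |elementary effect|, σ = their standard
deviation, and bootstrap confidence intervals over trajectories;
model-based screening evaluates all points with common random numbers so
elementary effects are not swamped by replicate noise. The
clonal/subclonal/fractal mode classifier thresholds (ε < 0.1 clonal;
fractal iff clustered FD ≥ 1.3 and ε ≥ 0.5) are conventions of this
toolkit calibrated on the default sweep, not published cutoffs.

## Known limitations

* 2D only; no stroma, vasculature, mechanics, or therapy.
* One melanocyte action set per step with abstract step duration; no
  calibration to physical time is included.
* Immune parameters and the saturating forms of CTL kill/proliferation
  are plausible defaults, not fitted values; conclusions about immune
  dynamics are qualitative (orderings, contrasts), not quantitative.
* Absolute ε values depend on the log base and sampling convention;
  compare only within one convention.
* Desk-scale clustered FD is compressed near its plane-filling ceiling;
  between-regime differences are smaller than at 50,000-cell scale.
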