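# Methods

## Model

The pipeline scores each protein in an undirected PPI network for
essentiality in four stages.

**1. Weighted PPI matrix.** Expression time series (length M, default 36)
are transformed to magnitude spectra. The transform is the literal sum
`Σ_{y=1..M} x_y exp(−i2πty/M)` for t = 0..N−1: the index starts at 1 and the
exponent base stays M even when N > M, so the extra components repeat the
length-M spectrum periodically. Relative to the conventional 0-based DFT
this multiplies each term by a unit-modulus phase, leaving every magnitude
unchanged; N defaults to M, the canonical choice, which preserves the
Parseval identity Σ|DF(t)|² = M·Σx². Spectral similarity is a Gaussian
interaction-profile kernel with bandwidth α′ divided by the mean squared
spectrum norm (α′ = 1, the usual unit-numerator convention). Topological
similarity TFP is the common-neighbour count plus one over the product of
(degree + 1) terms. Edge weights are β·PA + (1−β) with PA = GK where both
endpoints are expressed, TFP otherwise. Non-adjacent pairs receive TFP·GK
only when both endpoints are expressed *and* share at least one neighbour;
all other non-edges are 0. Computing the product for all O² pairs would make
unrelated isolated pairs maximally similar (TFP = 1) and destroy sparsity,
so support is restricted to the 2-hop neighbourhood; for unexpressed pairs
the GK factor is undefined and the product is taken as 0 rather than
inventing a similarity.

**2. Weighted DDI and heterogeneous PDI matrix.** Domain profiles are the
columns of the binary membership matrix; the same Gaussian kernel (δ′ = 1)
gives a Q×Q similarity matrix with unit diagonal. The heterogeneous matrix
is a single symmetric (O+Q)×(O+Q) block matrix — PP block the weighted PPI
matrix, DD block the weighted DDI matrix — whose PD block averages two
directed propagations: the protein side normalises the PPI-weighted
membership of a protein's neighbourhood by its total PPI weight (defined 0
when that weight is 0), the domain side normalises the DDI-weighted
similarity of a protein's domains by the DDI column sum (always ≥ 1). The
block-matrix reading is what makes domain-to-protein indexing in the
allocation step well-defined.

**3. Initial scores.** Every domain carries one unit of score, allocated
over its member proteins in proportion to the PD-block weights; a domain
whose member weights are all 0 allocates uniformly so that the total mass
stays exactly Q. Subcellular compartments are scored by size relative to
the mean compartment size, and a protein sums its compartments' scores (no
max-normalisation — the score is used as defined, unlike the other two
channels). Triangle support averages (shared-neighbour count + 1) over a
protein's neighbours and is max-normalised; degree-0 proteins score 0.
Orthology counts are max-normalised. The combined feature score uses
weights φ = 0.25, θ = 0.35, τ = 0.45 verbatim even though they sum to 1.05;
`renormalize_features` rescales them to sum 1 if a proper convex combination
is wanted. The initial score mixes the domain-derived and feature scores
with ω = 0.7.

**4. Iterative ranking.** For each ordered pair (i, j) with at least one
common neighbour in the weighted network (nonzero entries; "common
neighbour" is taken in the weighted network because the allocation consumes
its weights), the allocation weight is W(i, k*)·W(k*, j) where k* is the
common neighbour with the maximum weight to j, ties broken by ascending
protein id. Directly adjacent pairs without a common neighbour get 0.
Nonzero rows are rescaled to sum ρ = 0.85 (the damping value is a design
choice in the classic PageRank tradition; it is exposed in the
configuration). The update S ← μ·WAPM·S + (1−μ)·S0 with μ = 0.4 contracts
with factor ≤ μρ = 0.34 in the max norm, so the iteration reaches the
unique solution of (I − μ·WAPM)S = (1−μ)S0 geometrically; it stops when the
squared step norm falls below ε = 1e−6 (a safety valve raises an error
after 10,000 iterations, unreachable under valid configurations since the
config validator enforces μρ < 1). Ranking is descending by score with
ascending-id tie-breaks, so runs are bit-reproducible.

## Parameters

| name | default | meaning |
|---|---|---|
| beta | 0.5 | weight of the similarity term in edge weights |
| phi, theta, tau | 0.25, 0.35, 0.45 | subcellular / triangle / orthology feature weights |
| omega | 0.7 | domain-derived vs. feature score mixing |
| mu | 0.4 | propagation weight of the iterative update |
| rho | 0.85 | row mass of the weight-allocation matrix |
| epsilon | 1e−6 | squared-step stopping tolerance |
| dft_length | M | spectrum length (N ≥ M) |
| alpha_prime, delta_prime | 1 | kernel bandwidth numerators |

## Synthetic data

The generator emulates the six inputs of a yeast essentiality study at desk
scale. Defaults: 300 proteins, 60 domains, 20% planted essentials,
preferential-attachment growth with 3 edges per arriving node (mean degree
≈ 6) in which planted essentials carry 2× attachment mass, expression
series of length 36 (sinusoid, period 12 time points, Gaussian noise σ =
0.25) with phase shared across 50% of edges and 10% of proteins lacking a
profile, Poisson domain annotations (rate 1.5, 2× for essentials, every
domain guaranteed a member), 11 compartments with Bernoulli membership (2×
for essentials), and Poisson orthology counts (mean 2, 2× for essentials).
A repair pass joins stray components so the network is always connected.
All draws come from one seeded generator, so a seed fixes the files
byte-for-byte. The `null_fixture_config` variant sets every enrichment
ratio to 1 and removes co-phasing, giving a label-free control.

What the fixtures do *not* model: false-positive/false-negative interaction
noise, the heavy-tailed degree exponents and clustering of real PPI data,
correlated annotation biases (well-studied proteins have more annotations
of every kind), or realistic domain co-occurrence structure. Passing the
planted-recovery test therefore shows the pipeline integrates multi-channel
signal correctly, not that it attains any particular accuracy on real yeast
data.

## Numerical choices

- Edge weights are computed once per unordered pair and mirrored, so the
  weighted matrices are symmetric to exactly 0.
- Both Gaussian kernels use `scipy.spatial.distance.pdist`; an all-zero
  spectrum set raises a degenerate-input error rather than dividing by 0.
- 0/0 propagation ratios in the PD block are defined as 0 (nothing to
  propagate).
- Top-k% candidate counts use the ceiling convention ceil(f·O).
- ROC-AUC uses the Mann–Whitney tie convention (half credit), via
  scikit-learn; PR area is trapezoidal over the precision–recall points.
- Baselines: DC is the raw degree; BC/CC are networkx defaults (closeness
  normalised within the reachable component); EC is computed on the largest
  connected component and 0 elsewhere; NC sums edge clustering coefficients
  ECC(u,v) = |N(u)∩N(v)| / min(deg u −1, deg v −1), 0 when the denominator
  is 0.

## Problem sizes

The test-suite and the acceptance script run the full pipeline on
300-protein / 60-domain bundles (five seeds, plus five matched null
bundles), which completes in a few seconds; the dense-matrix implementation
is comfortable to a few thousand proteins, matching real yeast PPI networks.

## Known limitations

- All matrices are dense; beyond ~10⁴ proteins a sparse weight-allocation
  construction would be needed.
- The subcellular feature is used unnormalised; with many large
  compartments it can dominate the feature mix (the φ/θ/τ weights are the
  tuning surface).
- Domain–domain similarity derives solely from annotation profiles; no
  structural DDI databases are consulted.
- Competing published predictors beyond the five classical centralities are
  out of scope; external rankings can be compared via ranking files.
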