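# wpdinm

Rank proteins by essentiality from a protein–protein interaction (PPI)
network plus four annotation layers, using a weighted protein–domain
heterogeneous network and a damped PageRank-style iteration.

Essential proteins are those whose deletion is lethal; in yeast they are
enriched among network hubs (the centrality–lethality rule), but topology
alone is a weak predictor because PPI data are noisy and incomplete. This
package fuses five evidence channels — gene-expression dynamics, network
topology, Pfam-style domain annotations, subcellular localisation, and
orthology conservation — into a single ranking. It is aimed at systems
biologists who have a PPI edge list and standard yeast-style annotation
tables (pre-converted to TSV) and want a reproducible essentiality ranking
with built-in evaluation against a gold-standard list.

## The model

Let `OppiM` be the binary O×O adjacency matrix of the PPI network and
`OpdiM` the binary O×Q protein–domain membership matrix.

**Weighted PPI network.** Each expression time series `Gep(p, 1..M)` is
mapped to a magnitude spectrum `DF(p)` with the discrete Fourier transform;
pairs are compared with a Gaussian interaction-profile kernel

    GK(p_i, p_j) = exp(−α_p ‖DF(p_i) − DF(p_j)‖²),
    α_p = α′ / mean_k ‖DF(p_k)‖²,

and with a topology score `TFP(p_i, p_j) = (|Com| + 1) / ((|Np(p_i)| + 1)(|Np(p_j)| + 1))`
built from common neighbours and degrees. Interacting pairs get weight
`β·PA + (1 − β)` with `PA = GK` when both proteins are expressed and `TFP`
otherwise; non-interacting pairs that share a neighbour and are both
expressed get `TFP·GK`.

**Weighted DDI and heterogeneous PDI network.** Domains are compared with
the same kernel applied to the columns of `OpdiM`, giving `WddiM`. A
symmetric (O+Q)×(O+Q) block matrix joins proteins and domains; its
protein–domain block averages a PPI-weighted propagation of membership with
a DDI-weighted propagation.

**Initial scores.** Each domain distributes one unit of score over its
members in proportion to the heterogeneous weights (allocation probability
matrix `APM`; the resulting `PSD` vector conserves total mass Q). Three
feature scores — subcellular localisation `FS_SL`, triangle support
`FS_TRI`, orthology `FS_ORT` — combine as `FS = φ·FS_SL + θ·FS_TRI + τ·FS_ORT`,
and the initial score is `S0 = ω·PSD + (1 − ω)·FS`.

**Iterative ranking.** A directed weight-allocation matrix `WAPM` routes
score between proteins through their strongest shared neighbour, each
nonzero row rescaled to sum ρ. Scores iterate to the fixed point of

    S_{t+1} = μ·WAPM·S_t + (1 − μ)·S0,

which converges geometrically because μρ < 1, and the final scores are
sorted (ties broken by protein id) into the ranking.

Defaults: β=0.5, φ/θ/τ=0.25/0.35/0.45, ω=0.7, μ=0.4, ρ=0.85, ε=1e−6.

## Worked example

Generate a 300-protein synthetic bundle with 20% planted essential proteins
(enriched in degree, domain annotations, compartments and orthologs), then
run the pipeline:

```sh
wpdinm simulate --out fixture --n-proteins 300 --n-domains 60 --seed 1
wpdinm run --ppi fixture/ppi_edges.tsv --domains fixture/protein_domains.tsv \
    --expr fixture/expression.tsv --subcell fixture/subcellular.tsv \
    --ortho fixture/orthology.tsv --essential fixture/essentials.txt \
    --out results
```

which logs

```
INFO wpdinm.pipeline: network: 300 proteins, 894 edges
INFO wpdinm.pipeline: weighted PPI matrix built (270 expressed proteins)
INFO wpdinm.pipeline: heterogeneous PDI matrix: 300 protein + 60 domain nodes
INFO wpdinm.pipeline: converged after 7 iterations (residual^2 = 3.711e-07)
```

and writes `results/ranking.tsv`:

```
rank  protein_id  score           is_essential
1     p0251       0.89458476583   1
2     p0211       0.885506302631  1
3     p0272       0.835854999989  1
```

The top of the ranking is dominated by planted essentials. Because an
essential list was supplied, `results/evaluation.tsv` is also written: all 3
of the top-1% candidates are essential (hit rate 1.00), the top-5% hit rate
is 0.73, and the ROC-AUC against the planted labels is 0.848 — against a
base rate of 0.20. `results/manifest.json` records the resolved
configuration, input digests and iteration count, and is identical across
re-runs of the same inputs.

`wpdinm evaluate` scores an existing ranking file, and `wpdinm compare`
prints the top-k overlap table between two rankings.

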