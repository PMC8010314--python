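"""Seeded generator of complete synthetic input bundles.

Emulates the six inputs of a yeast essentiality study at desk scale: a
degree-skewed PPI network grown by preferential attachment in which a
planted essential subset receives extra attachment mass, domain/compartment/
orthology annotations enriched on the essentials by a configurable ratio,
and periodic expression time series (sinusoid + Gaussian noise) in which a
fraction of interacting pairs share phase and a fraction of proteins lack a
profile altogether.  Everything is drawn from one numpy Generator, so a
given seed yields byte-identical files.

The defaults mirror the scale used throughout the test-suite: 300 proteins,
60 domains, 20% planted essentials, enrichment ratio 2 on every channel,
expression length 36 (the length of the classic yeast cell-cycle compendium)
and 11 compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .datatypes import (
    DomainAnnotation,
    EssentialSet,
    ExpressionTable,
    InputBundle,
    OrthologyScores,
    ProteinNetwork,
    SubcellularAnnotation,
)
from .errors import ConfigError


@dataclass
class FixtureConfig:
    n_proteins: int = 300
    n_domains: int = 60
    essential_fraction: float = 0.2
    #: edges added per arriving node in the preferential-attachment growth
    attachment_edges: int = 3
    #: multiplicative attachment mass for planted essentials (degree signal)
    essential_attachment_ratio: float = 2.0
    expression_length: int = 36
    expression_noise: float = 0.25
    expression_period: float = 12.0
    #: mean domain annotations per non-essential protein
    domain_rate: float = 1.5
    #: essential : non-essential annotation-rate ratio (domains, orthology)
    domain_enrichment: float = 2.0
    n_compartments: int = 11
    compartment_enrichment: float = 2.0
    compartment_rate: float = 0.15
    orthology_mean: float = 2.0
    orthology_enrichment: float = 2.0
    #: fraction of edges whose endpoints share expression phase
    coexpression_edge_fraction: float = 0.5
    missing_expression_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 2 or self.n_domains < 1 or self.n_compartments < 1:
            raise ConfigError("counts must be positive (n_proteins >= 2)")
        if not 0.0 < self.essential_fraction < 1.0:
            raise ConfigError("essential_fraction must be in (0, 1)")
        if not 0.0 <= self.missing_expression_fraction < 1.0:
            raise ConfigError("missing_expression_fraction must be in [0, 1)")
        if not 0.0 <= self.coexpression_edge_fraction <= 1.0:
            raise ConfigError("coexpression_edge_fraction must be in [0, 1]")
        for name in ("essential_attachment_ratio", "domain_enrichment",
                     "compartment_enrichment", "orthology_enrichment"):
            if getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_domains > self.n_proteins * 50:
            raise ConfigError("more domain slots than can plausibly be filled")
        if self.attachment_edges < 1 or self.attachment_edges >= self.n_proteins:
            raise ConfigError("attachment_edges must be in [1, n_proteins)")


def _grow_network(cfg: FixtureConfig, rng: np.random.Generator,
                  essential_mask: np.ndarray) -> np.ndarray:
    """Preferential attachment with boosted mass on planted essentials.

    A final repair pass joins any disconnected components to the largest
    one so the graph is always connected.
    """
    n, m = cfg.n_proteins, cfg.attachment_edges
    adj = np.zeros((n, n), dtype=np.int8)
    core = m + 1
    for i in range(core):
        for j in range(i + 1, core):
            adj[i, j] = adj[j, i] = 1
    boost = np.where(essential_mask, cfg.essential_attachment_ratio, 1.0)
    for v in range(core, n):
        deg = adj[:v, :v].sum(axis=1)
        mass = (deg + 1.0) * boost[:v]
        targets = rng.choice(v, size=min(m, v), replace=False,
                             p=mass / mass.sum())
        for t in targets:
            adj[v, t] = adj[t, v] = 1
    # connectivity repair: attach each stray component to the largest one
    comp = _components(adj)
    labels, sizes = np.unique(comp, return_counts=True)
    if labels.size > 1:
        giant = labels[np.argmax(sizes)]
        anchor = int(np.nonzero(comp == giant)[0][0])
        for lab in labels:
            if lab == giant:
                continue
            v = int(np.nonzero(comp == lab)[0][0])
            adj[v, anchor] = adj[anchor, v] = 1
    return adj


def _components(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    comp = -np.ones(n, dtype=int)
    label = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = label
        while stack:
            v = stack.pop()
            for u in np.nonzero(adj[v])[0]:
                if comp[u] < 0:
                    comp[u] = label
                    stack.append(u)
        label += 1
    return comp


def generate_fixture_bundle(
    cfg: FixtureConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> InputBundle:
    """Generate a full input bundle with planted essentials, deterministically."""
    cfg = cfg or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    ids = [f"p{i + 1:04d}" for i in range(n)]

    n_ess = round(cfg.essential_fraction * n)
    essential_idx = rng.choice(n, size=n_ess, replace=False)
    essential_mask = np.zeros(n, dtype=bool)
    essential_mask[essential_idx] = True

    adj = _grow_network(cfg, rng, essential_mask)
    network = ProteinNetwork(protein_ids=ids, adjacency=adj)

    # expression: sinusoid with protein phase; co-phased endpoints on a
    # fraction of edges; an exact count of proteins lack a profile
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n)
    ii, jj = np.nonzero(np.triu(adj, 1))
    n_edges = ii.size
    n_cophase = round(cfg.coexpression_edge_fraction * n_edges)
    if n_cophase:
        chosen = rng.choice(n_edges, size=n_cophase, replace=False)
        for e in chosen:
            phase[jj[e]] = phase[ii[e]]
    n_missing = round(cfg.missing_expression_fraction * n)
    missing = set(rng.choice(n, size=n_missing, replace=False).tolist())
    t = np.arange(1, cfg.expression_length + 1, dtype=float)
    profiles: dict[str, np.ndarray] = {}
    for i in range(n):
        noise = rng.normal(0.0, cfg.expression_noise, size=cfg.expression_length)
        if i in missing:
            continue  # draw consumed above keeps the stream aligned per protein
        profiles[ids[i]] = (
            1.0 + np.sin(2.0 * np.pi * t / cfg.expression_period + phase[i]) + noise
        )
    expression = ExpressionTable(series_length=cfg.expression_length,
                                 profiles=profiles)

    # domains: Poisson annotation counts, enriched on essentials; every
    # domain slot is guaranteed at least one member
    rate = np.where(essential_mask,
                    cfg.domain_rate * cfg.domain_enrichment, cfg.domain_rate)
    membership = np.zeros((n, cfg.n_domains), dtype=np.int8)
    for i in range(n):
        k = min(int(rng.poisson(rate[i])), cfg.n_domains)
        if k:
            cols = rng.choice(cfg.n_domains, size=k, replace=False)
            membership[i, cols] = 1
    for j in np.nonzero(membership.sum(axis=0) == 0)[0]:
        membership[int(rng.integers(n)), j] = 1
    domain_ids = [f"d{j + 1:04d}" for j in range(cfg.n_domains)]
    domains = DomainAnnotation(domain_ids=domain_ids, matrix=membership)

    # compartments: Bernoulli membership per compartment, enriched
    loc_ids = [f"loc{j + 1:02d}" for j in range(cfg.n_compartments)]
    p_member = np.clip(
        np.where(essential_mask,
                 cfg.compartment_rate * cfg.compartment_enrichment,
                 cfg.compartment_rate),
        0.0, 1.0,
    )
    sl_membership: dict[str, set[str]] = {}
    for i in range(n):
        hits = rng.random(cfg.n_compartments) < p_member[i]
        if hits.any():
            sl_membership[ids[i]] = {loc_ids[j] for j in np.nonzero(hits)[0]}
    subcellular = SubcellularAnnotation(localization_ids=loc_ids,
                                        membership=sl_membership)

    orth_rate = np.where(essential_mask,
                         cfg.orthology_mean * cfg.orthology_enrichment,
                         cfg.orthology_mean)
    orthology = OrthologyScores(
        scores={ids[i]: float(rng.poisson(orth_rate[i])) for i in range(n)}
    )

    essentials = EssentialSet(ids={ids[i] for i in np.nonzero(essential_mask)[0]})
    return InputBundle(
        network=network,
        expression=expression,
        domains=domains,
        subcellular=subcellular,
        orthology=orthology,
        essentials=essentials,
        config=pipeline_config or PipelineConfig(random_seed=cfg.seed),
    )


def null_fixture_config(seed: int = 0, **overrides) -> FixtureConfig:
    """A signal-free variant: unit enrichment ratios and no co-phased edges."""
    base = dict(
        essential_attachment_ratio=1.0,
        domain_enrichment=1.0,
        compartment_enrichment=1.0,
        orthology_enrichment=1.0,
        coexpression_edge_fraction=0.0,
        seed=seed,
    )
    base.update(overrides)
    return FixtureConfig(**base)


FIXTURE_FILENAMES = {
    "ppi": "ppi_edges.tsv",
    "domains": "protein_domains.tsv",
    "expression": "expression.tsv",
    "subcellular": "subcellular.tsv",
    "orthology": "orthology.tsv",
    "essentials": "essentials.txt",
}


def write_fixture_files(bundle: InputBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the six input files in the dialects the loaders read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FIXTURE_FILENAMES.items()}

    net = bundle.network
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    with open(paths["ppi"], "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{net.protein_ids[i]}\t{net.protein_ids[j]}\n")

    with open(paths["domains"], "w") as fh:
        pi, dj = np.nonzero(bundle.domains.matrix)
        for i, j in zip(pi, dj):
            fh.write(f"{net.protein_ids[i]}\t{bundle.domains.domain_ids[j]}\n")

    with open(paths["expression"], "w") as fh:
        for pid in net.protein_ids:
            if pid in bundle.expression.profiles:
                vals = "\t".join(f"{v:.6f}" for v in bundle.expression.profiles[pid])
                fh.write(f"{pid}\t{vals}\n")

    with open(paths["subcellular"], "w") as fh:
        for pid in net.protein_ids:
            for loc in sorted(bundle.subcellular.membership.get(pid, ())):
                fh.write(f"{pid}\t{loc}\n")

    with open(paths["orthology"], "w") as fh:
        for pid in net.protein_ids:
            fh.write(f"{pid}\t{bundle.orthology.get(pid):g}\n")

    with open(paths["essentials"], "w") as fh:
        for pid in net.protein_ids:
            if bundle.essentials is not None and pid in bundle.essentials:
                fh.write(f"{pid}\n")

    return paths
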