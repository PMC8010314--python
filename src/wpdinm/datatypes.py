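"""Core containers for the heterogeneous protein-domain ranking pipeline.

Every matrix in the pipeline is indexed against a single frozen ordering of
protein identifiers (first appearance in the PPI edge list) held by
:class:`ProteinNetwork`; :class:`InputBundle` groups the network with the
optional annotation layers (expression time series, domain membership,
subcellular compartments, orthology counts) and the gold-standard essential
set used only for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .config import PipelineConfig
from .errors import DimensionError


@dataclass
class ProteinNetwork:
    """Undirected PPI network: id ordering + binary symmetric adjacency."""

    protein_ids: list[str]
    adjacency: np.ndarray  # O x O, dtype int8, zero diagonal

    @cached_property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.protein_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def edges(self) -> set[frozenset]:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return {
            frozenset((self.protein_ids[i], self.protein_ids[j]))
            for i, j in zip(ii, jj)
        }

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], extra_ids: tuple[str, ...] = ()
    ) -> "ProteinNetwork":
        """Build from undirected pairs; duplicates and self-loops ignored.

        Node index order is first appearance in the edge list.
        """
        ids: list[str] = []
        index: dict[str, int] = {}
        for pair in edges:
            for p in pair:
                if p not in index:
                    index[p] = len(ids)
                    ids.append(p)
        for p in extra_ids:
            if p not in index:
                index[p] = len(ids)
                ids.append(p)
        n = len(ids)
        adj = np.zeros((n, n), dtype=np.int8)
        for a, b in edges:
            if a == b:
                continue
            i, j = index[a], index[b]
            adj[i, j] = 1
            adj[j, i] = 1
        return cls(protein_ids=ids, adjacency=adj)

    def validate(self) -> None:
        a = self.adjacency
        if a.shape != (self.n_proteins, self.n_proteins):
            raise DimensionError("adjacency shape does not match protein count")
        if not np.array_equal(a, a.T):
            raise DimensionError("adjacency is not symmetric")
        if np.diag(a).any():
            raise DimensionError("adjacency diagonal is not zero")


@dataclass
class ExpressionTable:
    """Gene-expression time series, one fixed-length vector per protein."""

    series_length: int
    profiles: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def coverage(self) -> set[str]:
        return set(self.profiles)

    def validate(self) -> None:
        for p, v in self.profiles.items():
            if len(v) != self.series_length:
                raise DimensionError(
                    f"expression series for {p} has length {len(v)}, "
                    f"expected {self.series_length}"
                )

    @classmethod
    def empty(cls, series_length: int = 0) -> "ExpressionTable":
        return cls(series_length=series_length, profiles={})


@dataclass
class DomainAnnotation:
    """Protein-domain membership as a binary O x Q matrix.

    Column order defines the domain index; every retained domain has at
    least one member (empty columns are dropped at load time).
    """

    domain_ids: list[str]
    matrix: np.ndarray  # O x Q, dtype int8

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    @cached_property
    def index(self) -> dict[str, int]:
        return {d: j for j, d in enumerate(self.domain_ids)}

    @classmethod
    def empty(cls, n_proteins: int) -> "DomainAnnotation":
        return cls(domain_ids=[], matrix=np.zeros((n_proteins, 0), dtype=np.int8))


@dataclass
class SubcellularAnnotation:
    """Protein -> compartment membership with per-compartment counts."""

    localization_ids: list[str]
    membership: dict[str, set[str]] = field(default_factory=dict)

    @cached_property
    def counts(self) -> dict[str, int]:
        c = {loc: 0 for loc in self.localization_ids}
        for locs in self.membership.values():
            for loc in locs:
                c[loc] += 1
        return c

    @property
    def n_localizations(self) -> int:
        return len(self.localization_ids)

    @classmethod
    def empty(cls) -> "SubcellularAnnotation":
        return cls(localization_ids=[], membership={})


@dataclass
class OrthologyScores:
    """Per-protein orthology counts; missing proteins implicitly score 0."""

    scores: dict[str, float] = field(default_factory=dict)

    def get(self, protein_id: str) -> float:
        return self.scores.get(protein_id, 0.0)

    @classmethod
    def empty(cls) -> "OrthologyScores":
        return cls(scores={})


@dataclass
class EssentialSet:
    """Gold-standard essential protein identifiers (evaluation only)."""

    ids: set[str] = field(default_factory=set)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.ids

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class InputBundle:
    """All parsed inputs, indexed against one protein ordering."""

    network: ProteinNetwork
    expression: ExpressionTable
    domains: DomainAnnotation
    subcellular: SubcellularAnnotation
    orthology: OrthologyScores
    essentials: EssentialSet | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def protein_ids(self) -> list[str]:
        return self.network.protein_ids
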