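"""Readers and writers for the plain-text input/output dialects.

All inputs are header-less whitespace/tab separated text: a 2-column PPI
edge list, 2-column protein-domain and protein-compartment pair files, a
2-column orthology count table, an expression table (id + M numeric
columns), and a one-id-per-line essential list.  Identifiers are treated
case-sensitively and whitespace-trimmed.  Annotations that reference
proteins absent from the PPI network are dropped with a logged count — all
downstream matrices are built over the PPI protein set.
"""

from __future__ import annotations

import logging
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
from .errors import DimensionError, ParseError, WpdinmError

logger = logging.getLogger(__name__)


def _rows(path: str | Path, n_cols: int) -> list[tuple[str, ...]]:
    """Parse a fixed-column whitespace-delimited file, trimming fields."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{ln}: expected {n_cols} columns, got {len(parts)}"
                )
            out.append(tuple(p.strip() for p in parts))
    return out


def load_edge_list(path: str | Path) -> list[tuple[str, str]]:
    return [(a, b) for a, b in _rows(path, 2)]


def load_network(path: str | Path) -> ProteinNetwork:
    """Load a PPI edge list, collapsing duplicates and dropping self-loops."""
    edges = load_edge_list(path)
    net = ProteinNetwork.from_edges(edges)
    n_self = sum(1 for a, b in edges if a == b)
    if n_self:
        logger.info("dropped %d self-loop(s) from %s", n_self, path)
    return net


def load_expression(path: str | Path) -> ExpressionTable:
    """Load id + M numeric columns; all rows must share the same length M."""
    profiles: dict[str, np.ndarray] = {}
    series_length: int | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected id + values")
            pid, values = parts[0], parts[1:]
            if series_length is None:
                series_length = len(values)
            elif len(values) != series_length:
                raise DimensionError(
                    f"{path}:{ln}: series length {len(values)} != {series_length}"
                )
            try:
                profiles[pid] = np.array([float(v) for v in values])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric value ({exc})") from exc
    return ExpressionTable(series_length=series_length or 0, profiles=profiles)


def load_pairs(path: str | Path) -> list[tuple[str, str]]:
    return [(a, b) for a, b in _rows(path, 2)]


def load_orthology(path: str | Path) -> OrthologyScores:
    scores: dict[str, float] = {}
    for ln, (pid, val) in enumerate(_rows(path, 2), start=1):
        try:
            v = float(val)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric orthology count {val!r}") from exc
        if v < 0:
            raise ParseError(f"{path}: negative orthology count for {pid}")
        scores[pid] = v
    return OrthologyScores(scores=scores)


def load_id_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _restrict_pairs(
    pairs: list[tuple[str, str]], known: set[str], what: str
) -> list[tuple[str, str]]:
    kept = [(p, x) for p, x in pairs if p in known]
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("dropped %d %s annotation(s) for proteins not in the network",
                    dropped, what)
    return kept


def load_input_bundle(
    ppi_path: str | Path,
    domains_path: str | Path | None = None,
    expression_path: str | Path | None = None,
    subcellular_path: str | Path | None = None,
    orthology_path: str | Path | None = None,
    essentials_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> InputBundle:
    """Parse all input files into one consistently indexed bundle.

    The PPI edge list is required; each other file is optional and yields an
    empty structure (the corresponding score contributes 0) when absent.
    """
    config = config or PipelineConfig()
    network = load_network(ppi_path)
    known = set(network.protein_ids)

    if expression_path is not None:
        expression = load_expression(expression_path)
        extra = set(expression.profiles) - known
        if extra:
            logger.info("dropped %d expression profile(s) for unknown proteins",
                        len(extra))
            for p in extra:
                del expression.profiles[p]
        expression.validate()
    else:
        logger.warning("no expression file given; edge weights fall back to topology")
        expression = ExpressionTable.empty()

    if domains_path is not None:
        pairs = _restrict_pairs(load_pairs(domains_path), known, "domain")
        domains = _pairs_to_domains(pairs, network)
    else:
        logger.warning("no domain file given; domain-derived scores will be 0")
        domains = DomainAnnotation.empty(network.n_proteins)

    if subcellular_path is not None:
        pairs = _restrict_pairs(load_pairs(subcellular_path), known, "subcellular")
        membership: dict[str, set[str]] = {}
        loc_ids: list[str] = []
        seen: set[str] = set()
        for pid, loc in pairs:
            membership.setdefault(pid, set()).add(loc)
            if loc not in seen:
                seen.add(loc)
                loc_ids.append(loc)
        subcellular = SubcellularAnnotation(localization_ids=loc_ids,
                                            membership=membership)
    else:
        subcellular = SubcellularAnnotation.empty()

    if orthology_path is not None:
        orthology = load_orthology(orthology_path)
        extra = set(orthology.scores) - known
        for p in extra:
            del orthology.scores[p]
        if extra:
            logger.info("dropped %d orthology score(s) for unknown proteins",
                        len(extra))
    else:
        orthology = OrthologyScores.empty()

    essentials = None
    if essentials_path is not None:
        essentials = EssentialSet(ids=load_id_list(essentials_path))

    return InputBundle(
        network=network,
        expression=expression,
        domains=domains,
        subcellular=subcellular,
        orthology=orthology,
        essentials=essentials,
        config=config,
    )


def _pairs_to_domains(
    pairs: list[tuple[str, str]], network: ProteinNetwork
) -> DomainAnnotation:
    """Binary membership matrix; domains in first-appearance order.

    Domains ending up with zero members cannot occur here (each listed pair
    has a network protein), so no column drop is needed beyond dedup.
    """
    domain_ids: list[str] = []
    dindex: dict[str, int] = {}
    for _, d in pairs:
        if d not in dindex:
            dindex[d] = len(domain_ids)
            domain_ids.append(d)
    mat = np.zeros((network.n_proteins, len(domain_ids)), dtype=np.int8)
    for pid, d in pairs:
        mat[network.index[pid], dindex[d]] = 1
    keep = mat.sum(axis=0) > 0
    if not keep.all():
        dropped = [d for d, k in zip(domain_ids, keep) if not k]
        logger.info("dropped %d domain(s) without annotated proteins", len(dropped))
        domain_ids = [d for d, k in zip(domain_ids, keep) if k]
        mat = mat[:, keep]
    return DomainAnnotation(domain_ids=domain_ids, matrix=mat)


def write_ranking(
    ranking: list[tuple[str, float]],
    path: str | Path,
    essentials: EssentialSet | None = None,
) -> None:
    """Write rank/protein_id/score/is_essential TSV (header included)."""
    if not ranking:
        raise WpdinmError("refusing to write an empty ranking")
    with open(path, "w") as fh:
        fh.write("rank\tprotein_id\tscore\tis_essential\n")
        for rank, (pid, score) in enumerate(ranking, start=1):
            flag = "" if essentials is None else str(int(pid in essentials))
            fh.write(f"{rank}\t{pid}\t{score:.12g}\t{flag}\n")


def read_ranking(path: str | Path) -> list[tuple[str, float]]:
    """Read a ranking TSV written by :func:`write_ranking`."""
    out: list[tuple[str, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("rank\t"):
            raise ParseError(f"{path}: missing ranking header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 columns")
            out.append((parts[1], float(parts[2])))
    return out


def write_edge_list(network: ProteinNetwork, path: str | Path) -> None:
    """Dump the network back as an edge list (index order, upper triangle)."""
    ii, jj = np.nonzero(np.triu(network.adjacency, 1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{network.protein_ids[i]}\t{network.protein_ids[j]}\n")
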