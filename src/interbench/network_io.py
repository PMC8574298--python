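"""Reading, harmonizing and sanitizing interaction networks and gene-set collections.

Interaction networks arrive as two- or three-column tab-separated edge lists
(gene_a, gene_b[, confidence]); gene sets arrive in GMT format, protein
complexes optionally in an extended TSV carrying a bait column.  Everything is
reduced to two in-memory models: :class:`Interactome` (a named, simple,
undirected graph over opaque gene-identifier strings) and
:class:`GeneSetCollection`.

Sanitization is tolerant by design: self-loops, duplicate rows, unmapped
identifiers and edges collapsing onto self-loops after identifier mapping are
dropped and counted through the module logger, never raised.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

VALID_CATEGORIES = ("complex", "pathway", "disease")


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list rows (with the offending line number)."""


def _canonical(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered edge key: endpoints sorted lexicographically."""
    return (u, v) if u <= v else (v, u)


class Interactome:
    """A named simple undirected graph over gene identifiers.

    Wraps a :class:`networkx.Graph`; edge confidences, when present, live in
    the ``confidence`` edge attribute.  Gene identifiers are opaque strings —
    no namespace or species validation is performed.
    """

    def __init__(self, name: str, graph: Optional[nx.Graph] = None):
        self.name = name
        self.graph = graph if graph is not None else nx.Graph()

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def gene_order(self) -> list[str]:
        """Canonical (sorted) gene order used by all matrix-valued results."""
        return sorted(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {_canonical(u, v) for u, v in self.graph.edges}

    def confidence(self, u: str, v: str):
        return self.graph.edges[u, v].get("confidence")

    def has_confidence(self) -> bool:
        """True iff every edge carries a confidence score."""
        return all("confidence" in d for _, _, d in self.graph.edges(data=True))

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def degrees(self) -> list[int]:
        return [d for _, d in self.graph.degree]

    def add_edge(self, u: str, v: str, confidence: Optional[float] = None) -> None:
        """Add a simple edge; on duplicates the maximum confidence wins."""
        if u == v:
            return
        if self.graph.has_edge(u, v):
            if confidence is not None:
                prev = self.graph.edges[u, v].get("confidence")
                if prev is None or confidence > prev:
                    self.graph.edges[u, v]["confidence"] = confidence
        else:
            if confidence is None:
                self.graph.add_edge(u, v)
            else:
                self.graph.add_edge(u, v, confidence=confidence)

    def copy(self, name: Optional[str] = None) -> "Interactome":
        return Interactome(name or self.name, self.graph.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome({self.name!r}, genes={self.n_genes}, edges={self.n_edges})"


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: a protein complex, a pathway or a disease gene pool."""

    id: str
    category: str
    members: frozenset[str]
    bait: Optional[str] = None

    def __post_init__(self):
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")
        if self.bait is not None and self.bait not in self.members:
            raise ValueError(f"bait {self.bait!r} is not a member of {self.id!r}")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene-set ids within a collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def ids(self) -> list[str]:
        return [s.id for s in self.sets]


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def load_edgelist(path, name: str) -> Interactome:
    """Load a TSV edge list into a simple undirected :class:`Interactome`.

    Rows have at least two fields; an optional third numeric field is the
    interaction confidence.  Reversed duplicates collapse onto one edge, and
    when duplicate rows disagree on confidence the highest score is kept as
    representative of the interaction.  Self-loops are dropped.  Lines
    starting with ``#`` are comments.
    """
    net = Interactome(name)
    n_rows = n_selfloops = n_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated files
                fields = line.split()
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected >= 2 fields, got {len(fields)}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            conf = None
            if len(fields) >= 3 and fields[2].strip() != "":
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: non-numeric confidence {fields[2]!r}"
                    ) from exc
            n_rows += 1
            if u == v:
                n_selfloops += 1
                continue
            if net.graph.has_edge(u, v):
                n_dups += 1
            net.add_edge(u, v, conf)
    if n_rows == 0:
        raise EdgeListParseError(f"{path}: no interaction rows found")
    if n_selfloops or n_dups:
        logger.info(
            "%s: dropped %d self-loops, collapsed %d duplicate rows",
            name, n_selfloops, n_dups,
        )
    return net


def write_edgelist(net: Interactome, path) -> None:
    """Write the canonical edge list (sorted endpoints, sorted rows)."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edge_set()):
            conf = net.confidence(u, v)
            if conf is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{conf:g}\n")


def load_mapping(path) -> dict[str, str]:
    """Two-column TSV old-id → new-id (possibly many-to-one)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def map_identifiers(net: Interactome, mapping: Mapping[str, str]) -> Interactome:
    """Translate gene identifiers through a (possibly partial, many-to-one) map.

    Genes absent from the map are dropped.  Edges that collapse onto the same
    translated pair are merged keeping the maximum confidence; edges that
    collapse onto a self-loop are dropped.
    """
    out = Interactome(net.name)
    unmapped = {g for g in net.graph.nodes if g not in mapping}
    n_selfloops = 0
    for u, v, data in net.graph.edges(data=True):
        if u in unmapped or v in unmapped:
            continue
        mu, mv = mapping[u], mapping[v]
        if mu == mv:
            n_selfloops += 1
            continue
        out.add_edge(mu, mv, data.get("confidence"))
    if unmapped:
        logger.info("%s: dropped %d unmapped genes", net.name, len(unmapped))
    if n_selfloops:
        logger.info("%s: dropped %d edges collapsing to self-loops", net.name, n_selfloops)
    return out


def filter_by_confidence(net: Interactome, threshold: float) -> Interactome:
    """Keep edges with confidence >= threshold; isolated genes are removed."""
    missing = [
        (u, v) for u, v, d in net.graph.edges(data=True) if "confidence" not in d
    ]
    if missing:
        raise ValueError(
            f"{net.name}: {len(missing)} edges lack a confidence score "
            f"(first: {missing[0]})"
        )
    g = nx.Graph()
    for u, v, d in net.graph.edges(data=True):
        if d["confidence"] >= threshold:
            g.add_edge(u, v, confidence=d["confidence"])
    return Interactome(net.name, g)


def extract_lcc(net: Interactome) -> Interactome:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member gene so the
    result is deterministic.
    """
    if net.n_genes == 0:
        raise ValueError(f"{net.name}: empty graph has no connected component")
    components = [set(c) for c in nx.connected_components(net.graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    lcc = components[0]
    logger.info(
        "%s: LCC keeps %d/%d genes (%.1f%%)",
        net.name, len(lcc), net.n_genes, 100.0 * len(lcc) / net.n_genes,
    )
    return Interactome(net.name, net.graph.subgraph(lcc).copy())


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, category: str, source: str = "") -> GeneSetCollection:
    """Standard GMT: set-id TAB description TAB member genes."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need >= 3 fields")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                logger.warning("%s: line %d: empty gene set %r skipped", path, lineno, fields[0])
                continue
            sets.append(GeneSet(id=fields[0], category=category, members=members))
    return GeneSetCollection(sets=sets, source=source or str(path))


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.id, s.category, *sorted(s.members)]) + "\n")


def read_complexes_tsv(path, source: str = "") -> GeneSetCollection:
    """Extended complex TSV: id TAB bait-or-'-' TAB comma-separated members."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected id, bait, members")
            bait = fields[1].strip()
            members = frozenset(g.strip() for g in fields[2].split(",") if g.strip())
            sets.append(
                GeneSet(
                    id=fields[0],
                    category="complex",
                    members=members,
                    bait=None if bait in ("-", "") else bait,
                )
            )
    return GeneSetCollection(sets=sets, source=source or str(path))


def expand_complex(cset: GeneSet) -> list[tuple[str, str]]:
    """Expand a complex into binary interactions.

    With a designated bait the spoke model applies (bait to every other
    member); without one, the matrix model (all unordered pairs).
    """
    if cset.category != "complex":
        raise ValueError(f"{cset.id!r} is not a complex")
    if cset.size < 2:
        raise ValueError(f"complex {cset.id!r} needs >= 2 members")
    members = sorted(cset.members)
    if cset.bait is not None:
        return [_canonical(cset.bait, m) for m in members if m != cset.bait]
    return [tuple(p) for p in itertools.combinations(members, 2)]


def filter_genesets(
    coll: GeneSetCollection, min_size: int, max_size: int
) -> GeneSetCollection:
    """Keep sets with min_size <= |members| <= max_size (bounds inclusive)."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    kept = [s for s in coll if min_size <= s.size <= max_size]
    return GeneSetCollection(sets=kept, source=coll.source)
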