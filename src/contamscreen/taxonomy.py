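"""Taxonomy tree, lowest-common-ancestor queries, and three-way read labels.

Every classifier in the pipeline reduces a set of reference taxa to a single
node by LCA and then interprets that node relative to a designated *focal*
clade (the taxon the assembly is supposed to belong to): nodes inside the
focal clade are genuine (``FOCAL``), nodes on the root-path strictly above it
are classified-yet-uninformative (``UNKNOWN``, e.g. a domain-level LCA), and
everything else is foreign (``CONTAMINANT``).  Sequences with no reference
signal at all are ``UNCLASSIFIED``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class TaxonomyError(ValueError):
    """Raised for malformed trees or unknown taxon identifiers."""


class Label(enum.Enum):
    FOCAL = "focal"
    CONTAMINANT = "contaminant"
    UNKNOWN = "unknown"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ReadLabel:
    """Classification outcome for one sequence.

    ``taxon_id`` is ``None`` exactly when ``label`` is ``UNCLASSIFIED``.
    """

    label: Label
    taxon_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.label is Label.UNCLASSIFIED) != (self.taxon_id is None):
            raise ValueError("taxon_id must be absent iff UNCLASSIFIED")


UNCLASSIFIED_READ = ReadLabel(Label.UNCLASSIFIED, None)


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: Optional[str]  # None only for the root
    rank: str = "no-rank"
    name: str = ""


@dataclass
class TaxonomyTree:
    """Rooted labelled tree with a designated focal clade.

    Construction validates the tree invariants: unique ids, exactly one
    root, all parent links resolving, and no cycles.
    """

    nodes: Mapping[str, TaxonNode]
    root_id: str = field(init=False)
    focal_id: str = field(default="")

    def __init__(self, nodes: Iterable[TaxonNode], focal_id: str) -> None:
        node_map: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in node_map:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            node_map[node.taxon_id] = node
        roots = [n.taxon_id for n in node_map.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyError(f"tree must have exactly one root, found {roots!r}")
        self.nodes = node_map
        self.root_id = roots[0]
        self.focal_id = focal_id
        self._depth: dict[str, int] = {}
        self._compute_depths()
        if focal_id not in node_map:
            raise TaxonomyError(f"focal_id {focal_id!r} not in tree")
        self._focal_path = frozenset(self.path_to_root(focal_id))

    def _compute_depths(self) -> None:
        for tid in self.nodes:
            chain = []
            cur: Optional[str] = tid
            seen = set()
            while cur is not None and cur not in self._depth:
                if cur in seen:
                    raise TaxonomyError(f"parent chain of {tid!r} loops at {cur!r}")
                seen.add(cur)
                chain.append(cur)
                parent = self.nodes[cur].parent_id
                if parent is not None and parent not in self.nodes:
                    raise TaxonomyError(f"node {cur!r} has unknown parent {parent!r}")
                cur = parent
            base = 0 if cur is None else self._depth[cur] + 1
            for i, node_id in enumerate(reversed(chain)):
                self._depth[node_id] = base + i

    # -- queries ---------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def depth(self, taxon_id: str) -> int:
        self._require(taxon_id)
        return self._depth[taxon_id]

    def parent(self, taxon_id: str) -> Optional[str]:
        self._require(taxon_id)
        return self.nodes[taxon_id].parent_id

    def rank(self, taxon_id: str) -> str:
        self._require(taxon_id)
        return self.nodes[taxon_id].rank

    def children(self, taxon_id: str) -> list[str]:
        self._require(taxon_id)
        return [n.taxon_id for n in self.nodes.values() if n.parent_id == taxon_id]

    def leaves(self) -> list[str]:
        has_child = {n.parent_id for n in self.nodes.values() if n.parent_id}
        return [tid for tid in self.nodes if tid not in has_child]

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Node ids from ``taxon_id`` up to and including the root."""
        self._require(taxon_id)
        path = []
        cur: Optional[str] = taxon_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True if ``ancestor`` is an ancestor-or-self of ``descendant``."""
        return ancestor in self.path_to_root(descendant)

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        for tid in self.path_to_root(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def _require(self, taxon_id: str) -> None:
        if taxon_id not in self.nodes:
            raise TaxonomyError(f"unknown taxon_id {taxon_id!r}")


def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    """Deepest node that is an ancestor-or-self of every taxon in ``taxa``."""
    taxa = list(taxa)
    if not taxa:
        raise TaxonomyError("lca of empty taxon set")
    common: Optional[set[str]] = None
    for tid in taxa:
        path = set(tree.path_to_root(tid))
        common = path if common is None else common & path
    assert common  # root is always shared
    return max(common, key=tree.depth)


def label_of(tree: TaxonomyTree, taxon_id: Optional[str]) -> ReadLabel:
    """Map a taxon (or no hit) onto the focal/contaminant/unknown trichotomy.

    A strict ancestor of the focal clade carries no information about
    contamination (e.g. a domain-level "Bacteria" assignment) and is
    labelled UNKNOWN; the focal clade and its descendants are FOCAL; any
    other node is CONTAMINANT.
    """
    if taxon_id is None:
        return UNCLASSIFIED_READ
    tree._require(taxon_id)
    if tree.is_ancestor(tree.focal_id, taxon_id):
        return ReadLabel(Label.FOCAL, taxon_id)
    if taxon_id in tree._focal_path:
        return ReadLabel(Label.UNKNOWN, taxon_id)
    return ReadLabel(Label.CONTAMINANT, taxon_id)


# -- serialisation -------------------------------------------------------


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    """Write the tree as 4-column TSV: taxon_id, parent_id, rank, name."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#taxon_id\tparent_id\trank\tname\n")
        fh.write(f"#focal\t{tree.focal_id}\n")
        for node in tree.nodes.values():
            parent = node.parent_id if node.parent_id is not None else ""
            fh.write(f"{node.taxon_id}\t{parent}\t{node.rank}\t{node.name}\n")


def read_taxonomy(path, focal_id: Optional[str] = None) -> TaxonomyTree:
    """Read a 4-column TSV taxonomy; '#focal' comment records the focal clade."""
    nodes: list[TaxonNode] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#focal\t") and focal_id is None:
                    focal_id = line.split("\t", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TaxonomyError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            tid, parent, rank, name = parts
            nodes.append(TaxonNode(tid, parent or None, rank, name))
    if focal_id is None:
        raise TaxonomyError("no focal clade recorded in file or given")
    return TaxonomyTree(nodes, focal_id=focal_id)
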