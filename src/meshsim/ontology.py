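"""Tree-number ontology forest.

MeSH-style ontologies place each concept (*heading*) at one or more
positions in a forest of category trees.  A position is written as a
dot-separated *tree number* such as ``G02.111.222``: the components name
the full path from a category root, so the string alone determines the
node's depth, its parent, and every ancestor.  This module materialises
that forest, joins the category trees under a synthetic *virtual root*
of depth 0 (so every node pair has a least common ancestor and a finite
path length), and computes a structure-based (intrinsic) information
content per node from its depth and child count:

    IC(v) = H(v) * (1 - log(|C(v)| + 1) / log(T_total))

where ``H(v)`` is the node's depth (component count), ``C(v)`` its set
of children, and ``T_total`` the number of real nodes in the forest.
Leaves therefore have ``IC = H``; the virtual root has ``IC = 0``.  The
expression is a ratio of logarithms, so the log base is irrelevant.

Conventions
-----------
* depth = number of tree-number components; a category root has depth 1,
  the virtual root depth 0.  This makes ``WP(v, v) = 1`` well defined.
* Ancestors implied by a tree-number prefix but absent from the input
  are materialised as unnamed nodes and counted in ``T_total`` — a tree
  number guarantees their existence.
* ``C(v)`` counts *direct* children by default; ``children_mode=
  "descendants"`` switches to the full descendant count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union


class OntologyError(ValueError):
    """Base class for ontology construction and lookup failures."""


class MalformedTreeNumberError(OntologyError):
    """Raised for empty tree numbers or empty dot components."""


class UnknownNodeError(OntologyError):
    """Raised when a tree number is not present in the ontology."""


class UnknownHeadingError(OntologyError):
    """Raised when a heading name is not registered."""


@dataclass(frozen=True, order=True)
class TreeNumber:
    """A dot-separated ontology position, e.g. ``G02.111.222``."""

    components: tuple[str, ...]

    @property
    def text(self) -> str:
        return ".".join(self.components)

    @property
    def depth(self) -> int:
        return len(self.components)

    @property
    def parent(self) -> "TreeNumber | None":
        """The prefix of length ``depth - 1``; ``None`` for a category root."""
        if len(self.components) == 1:
            return None
        return TreeNumber(self.components[:-1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def parse_tree_number(text: str) -> TreeNumber:
    """Parse a dot-separated tree number.

    Raises :class:`MalformedTreeNumberError` on an empty string or an
    empty component (``"A..B"``, ``".A"``, ``"A."``).
    """
    if not isinstance(text, str) or not text:
        raise MalformedTreeNumberError("tree number must be a non-empty string")
    components = tuple(text.split("."))
    if any(not c for c in components):
        raise MalformedTreeNumberError(f"empty component in tree number {text!r}")
    return TreeNumber(components)


NodeRef = Union[str, TreeNumber, "OntologyNode"]


@dataclass(eq=False)
class OntologyNode:
    """One position in the forest.

    ``id is None`` marks the virtual root.  Equality is identity: nodes
    are unique per ontology.
    """

    id: TreeNumber | None
    depth: int
    parent: "OntologyNode | None" = None
    children: list["OntologyNode"] = field(default_factory=list, repr=False)

    @property
    def text(self) -> str:
        return "" if self.id is None else self.id.text

    @property
    def is_virtual_root(self) -> bool:
        return self.id is None

    @property
    def n_children(self) -> int:
        return len(self.children)

    def __repr__(self) -> str:
        return f"OntologyNode({self.text or '<root>'}, depth={self.depth})"


@dataclass(frozen=True)
class Heading:
    """A named concept mapped to one or more ontology positions."""

    name: str
    node_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.node_ids:
            raise OntologyError(f"heading {self.name!r} has no tree numbers")

    @property
    def node_number(self) -> int:
        return len(self.node_ids)


class Ontology:
    """Forest of tree-number nodes joined at a virtual root.

    Build with :func:`build_ontology` or incrementally with
    :meth:`add_tree_number` / :meth:`register_heading`.
    """

    def __init__(self) -> None:
        self.virtual_root = OntologyNode(id=None, depth=0)
        self._nodes: dict[str, OntologyNode] = {}
        self.headings: dict[str, Heading] = {}
        self._ic_cache: dict[tuple[str, str], float] = {}
        self._descendant_counts: dict[str, int] | None = None

    # -- construction -------------------------------------------------

    def add_tree_number(self, tn: str | TreeNumber) -> OntologyNode:
        """Insert a node, materialising any missing ancestors."""
        if isinstance(tn, str):
            tn = parse_tree_number(tn)
        node = self._nodes.get(tn.text)
        if node is not None:
            return node
        parent_tn = tn.parent
        parent = self.virtual_root if parent_tn is None else self.add_tree_number(parent_tn)
        node = OntologyNode(id=tn, depth=tn.depth, parent=parent)
        parent.children.append(node)
        self._nodes[tn.text] = node
        self._invalidate_caches()
        return node

    def register_heading(self, name: str, tree_numbers: Iterable[str | TreeNumber]) -> Heading:
        """Register a named heading; its nodes are added if missing.

        A duplicate name with a conflicting node set is an error.
        """
        ids = frozenset(
            (tn if isinstance(tn, TreeNumber) else parse_tree_number(tn)).text
            for tn in tree_numbers
        )
        existing = self.headings.get(name)
        if existing is not None:
            if existing.node_ids != ids:
                raise OntologyError(
                    f"heading {name!r} registered twice with conflicting tree numbers"
                )
            return existing
        for text in ids:
            self.add_tree_number(text)
        heading = Heading(name=name, node_ids=ids)
        self.headings[name] = heading
        return heading

    def _invalidate_caches(self) -> None:
        self._ic_cache.clear()
        self._descendant_counts = None

    # -- lookup -------------------------------------------------------

    @property
    def nodes(self) -> dict[str, OntologyNode]:
        return self._nodes

    @property
    def t_total(self) -> int:
        """Number of real nodes (the virtual root is excluded)."""
        return len(self._nodes)

    @property
    def max_depth(self) -> int:
        """Maximum node depth D over the loaded forest (0 when empty)."""
        if not self._nodes:
            return 0
        return max(node.depth for node in self._nodes.values())

    def node(self, ref: NodeRef) -> OntologyNode:
        if isinstance(ref, OntologyNode):
            return ref
        text = ref.text if isinstance(ref, TreeNumber) else ref
        try:
            return self._nodes[text]
        except KeyError:
            raise UnknownNodeError(f"node {text!r} is not in the ontology") from None

    def heading(self, name: str) -> Heading:
        try:
            return self.headings[name]
        except KeyError:
            raise UnknownHeadingError(f"heading {name!r} is not registered") from None

    # -- structural queries -------------------------------------------

    def lca(self, a: NodeRef, b: NodeRef) -> OntologyNode:
        """Least common ancestor: the longest common component prefix.

        Nodes in different category trees resolve to the virtual root.
        """
        na, nb = self.node(a), self.node(b)
        ca, cb = na.id.components, nb.id.components
        k = 0
        for x, y in zip(ca, cb):
            if x != y:
                break
            k += 1
        if k == 0:
            return self.virtual_root
        return self._nodes[".".join(ca[:k])]

    def path_length(self, a: NodeRef, b: NodeRef) -> int:
        """Edge count of the shortest path through the forest."""
        na, nb = self.node(a), self.node(b)
        anc = self.lca(na, nb)
        return na.depth + nb.depth - 2 * anc.depth

    # -- information content ------------------------------------------

    def _descendants(self, text: str) -> int:
        if self._descendant_counts is None:
            # deepest-first order so child counts exist before parents
            counts: dict[str, int] = {}
            order = sorted(self._nodes, key=lambda t: -self._nodes[t].depth)
            for text_ in order:
                node = self._nodes[text_]
                counts[text_] = sum(1 + counts[c.id.text] for c in node.children)
            self._descendant_counts = counts
        return self._descendant_counts[text]

    def information_content(self, ref: NodeRef, children_mode: str = "direct") -> float:
        """Structure-based IC of a node; 0 for the virtual root.

        ``children_mode`` selects what ``|C(v)|`` counts: ``"direct"``
        children (the default) or all ``"descendants"``.
        """
        node = ref if isinstance(ref, OntologyNode) else self.node(ref)
        if node.is_virtual_root:
            return 0.0
        if children_mode not in ("direct", "descendants"):
            raise ValueError(f"unknown children_mode {children_mode!r}")
        key = (children_mode, node.id.text)
        cached = self._ic_cache.get(key)
        if cached is not None:
            return cached
        if self.t_total < 2:
            raise OntologyError("information content needs at least 2 nodes (log T_total > 0)")
        c = node.n_children if children_mode == "direct" else self._descendants(node.id.text)
        ic = node.depth * (1.0 - math.log(c + 1) / math.log(self.t_total))
        self._ic_cache[key] = ic
        return ic

    def max_information_content(self, children_mode: str = "direct") -> float:
        """Largest IC over the loaded nodes (used to rescale Resnik output)."""
        return max(self.information_content(n, children_mode) for n in self._nodes.values())

    # -- pickling: rebuild from flat records (node graph is cyclic) ----

    def __getstate__(self) -> dict:
        return {
            "tree_numbers": sorted(self._nodes),
            "headings": {name: sorted(h.node_ids) for name, h in self.headings.items()},
        }

    def __setstate__(self, state: dict) -> None:
        self.__init__()
        for text in state["tree_numbers"]:
            self.add_tree_number(text)
        for name, ids in state["headings"].items():
            self.register_heading(name, ids)

    def __contains__(self, ref: str | TreeNumber) -> bool:
        text = ref.text if isinstance(ref, TreeNumber) else ref
        return text in self._nodes

    def __iter__(self) -> Iterator[OntologyNode]:
        return iter(self._nodes.values())

    def __repr__(self) -> str:
        return (
            f"Ontology(T_total={self.t_total}, D={self.max_depth}, "
            f"headings={len(self.headings)})"
        )


def build_ontology(records: Iterable[tuple[str, Sequence[str]]]) -> Ontology:
    """Build an ontology plus heading registry from (name, tree numbers) records."""
    ontology = Ontology()
    for name, tree_numbers in records:
        ontology.register_heading(name, tree_numbers)
    return ontology


# -- file dialects ----------------------------------------------------


def read_mesh_ascii(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read heading records from the MeSH descriptor ASCII format.

    Records are separated by ``*NEWRECORD``; the heading name comes from
    the ``MH = `` field and tree numbers from repeated ``MN = `` lines.
    All other fields are ignored.  Records without both an ``MH`` and at
    least one ``MN`` are skipped (e.g. check tags without tree numbers).
    """
    records: list[tuple[str, list[str]]] = []
    name: str | None = None
    numbers: list[str] = []

    def flush() -> None:
        nonlocal name, numbers
        if name is not None and numbers:
            records.append((name, numbers))
        name, numbers = None, []

    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.strip() == "*NEWRECORD":
                flush()
            elif line.startswith("MH = "):
                name = line[len("MH = "):].strip()
            elif line.startswith("MN = "):
                numbers.append(line[len("MN = "):].strip())
    flush()
    return records


def read_ontology_tsv(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read ``heading<TAB>treeNum1;treeNum2`` records."""
    records: list[tuple[str, list[str]]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            try:
                name, numbers = line.split("\t")
            except ValueError:
                raise OntologyError(f"{path}:{lineno}: expected 2 tab-separated fields") from None
            records.append((name, [t for t in numbers.split(";") if t]))
    return records


def write_ontology_tsv(ontology: Ontology, path: str | Path) -> None:
    """Write the heading registry as ``heading<TAB>treeNum1;treeNum2``."""
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted(ontology.headings):
            heading = ontology.headings[name]
            handle.write(f"{name}\t{';'.join(sorted(heading.node_ids))}\n")
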