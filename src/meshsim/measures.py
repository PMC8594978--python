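"""Semantic similarity measures over ontology nodes and headings.

Six measures, split by the granularity of their arguments:

Node level (aggregated up to headings by average maximum match):

* ``WP``  — Wu–Palmer: ``2 * depth(lca) / (depth(v) + depth(v'))``, in [0, 1].
* ``Res`` — Resnik: ``IC(lca)``; unbounded above (up to the max IC).
* ``Lin`` — ``2 * IC(lca) / (IC(v) + IC(v'))``, in [0, 1].
* ``Sch`` — Schlicker: Lin damped by ``1 - exp(-IC(lca))``, in [0, 1).

Heading level (computed directly from path statistics between the two
headings' node sets):

* ``SP`` — relative path spread: ``(L_max - L_min) / L_max``.
* ``LC`` — Leacock–Chodorow style: ``1 - log(1 + L_min) / log(1 + 2D)``,
  with ``D`` the maximum depth of the loaded ontology.

``L_min`` / ``L_max`` are the shortest / longest path length over all
node pairs drawn from the two headings, including paths through the
virtual root when the nodes sit in different category trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

from .ontology import Heading, NodeRef, Ontology, OntologyError


class MeasureLevelError(OntologyError):
    """A node-level measure was requested for a heading-level name or vice versa."""


class Measure(str, Enum):
    """Measure names, with their argument level."""

    SP = "SP"
    WP = "WP"
    LC = "LC"
    RES = "Res"
    LIN = "Lin"
    SCH = "Sch"

    @classmethod
    def from_name(cls, name: "Measure | str") -> "Measure":
        if isinstance(name, Measure):
            return name
        try:
            return _BY_LOWER_NAME[str(name).lower()]
        except KeyError:
            raise ValueError(
                f"unknown measure {name!r}; choose from {[m.value for m in cls]}"
            ) from None

    @property
    def is_node_level(self) -> bool:
        return self in (Measure.WP, Measure.RES, Measure.LIN, Measure.SCH)

    @property
    def is_heading_level(self) -> bool:
        return not self.is_node_level

    @property
    def bounded(self) -> bool:
        """Whether values are guaranteed to lie in [0, 1] (all but Res)."""
        return self is not Measure.RES


_BY_LOWER_NAME = {m.value.lower(): m for m in Measure}

HeadingRef = Union[str, Heading]


def _heading(ontology: Ontology, ref: HeadingRef) -> Heading:
    return ref if isinstance(ref, Heading) else ontology.heading(ref)


# -- node-level measures ----------------------------------------------


def sim_wp(ontology: Ontology, v: NodeRef, v2: NodeRef) -> float:
    """Wu–Palmer similarity; 0 across category trees, 1 for identical nodes."""
    a, b = ontology.node(v), ontology.node(v2)
    anc = ontology.lca(a, b)
    return 2.0 * anc.depth / (a.depth + b.depth)


def sim_res(ontology: Ontology, v: NodeRef, v2: NodeRef, children_mode: str = "direct") -> float:
    """Resnik similarity: the information content of the LCA."""
    anc = ontology.lca(ontology.node(v), ontology.node(v2))
    return ontology.information_content(anc, children_mode)


def sim_lin(ontology: Ontology, v: NodeRef, v2: NodeRef, children_mode: str = "direct") -> float:
    """Lin similarity; 0 when both nodes carry zero IC (degenerate case)."""
    a, b = ontology.node(v), ontology.node(v2)
    denom = ontology.information_content(a, children_mode) + ontology.information_content(
        b, children_mode
    )
    if denom == 0.0:
        return 0.0
    anc = ontology.lca(a, b)
    return 2.0 * ontology.information_content(anc, children_mode) / denom


def sim_sch(ontology: Ontology, v: NodeRef, v2: NodeRef, children_mode: str = "direct") -> float:
    """Schlicker similarity: Lin scaled by ``1 - exp(-IC(lca))``."""
    a, b = ontology.node(v), ontology.node(v2)
    lin = sim_lin(ontology, a, b, children_mode)
    if lin == 0.0:
        return 0.0
    anc = ontology.lca(a, b)
    return lin * (1.0 - math.exp(-ontology.information_content(anc, children_mode)))


def node_sim(
    ontology: Ontology,
    measure: Measure | str,
    v: NodeRef,
    v2: NodeRef,
    children_mode: str = "direct",
) -> float:
    """Dispatch a node-level measure by name."""
    measure = Measure.from_name(measure)
    if not measure.is_node_level:
        raise MeasureLevelError(f"{measure.value} is heading-level, not node-level")
    if measure is Measure.WP:
        return sim_wp(ontology, v, v2)
    if measure is Measure.RES:
        return sim_res(ontology, v, v2, children_mode)
    if measure is Measure.LIN:
        return sim_lin(ontology, v, v2, children_mode)
    return sim_sch(ontology, v, v2, children_mode)


# -- heading-level measures -------------------------------------------


@dataclass(frozen=True)
class HeadingPathStats:
    """Shortest and longest path length between two headings' node sets."""

    l_min: int
    l_max: int

    def __post_init__(self) -> None:
        if not 0 <= self.l_min <= self.l_max:
            raise ValueError(f"invalid path stats: {self}")


def heading_path_stats(ontology: Ontology, m: HeadingRef, m2: HeadingRef) -> HeadingPathStats:
    """Min/max path length over all node pairs of two headings."""
    ha, hb = _heading(ontology, m), _heading(ontology, m2)
    lengths = [
        ontology.path_length(va, vb) for va in ha.node_ids for vb in hb.node_ids
    ]
    return HeadingPathStats(l_min=min(lengths), l_max=max(lengths))


def sim_sp(ontology: Ontology, m: HeadingRef, m2: HeadingRef) -> float:
    """Relative path spread ``(L_max - L_min) / L_max``.

    When ``L_max = 0`` (two identical single-node headings) the formula
    is 0/0; identical headings are maximally similar, so 1 is returned.
    """
    stats = heading_path_stats(ontology, m, m2)
    if stats.l_max == 0:
        return 1.0
    return (stats.l_max - stats.l_min) / stats.l_max


def sim_lc(ontology: Ontology, m: HeadingRef, m2: HeadingRef) -> float:
    """``1 - log(1 + L_min) / log(1 + 2D)`` with D the loaded max depth."""
    d = ontology.max_depth
    if d < 1:
        raise OntologyError("LC needs an ontology of maximum depth >= 1")
    stats = heading_path_stats(ontology, m, m2)
    return 1.0 - math.log(1 + stats.l_min) / math.log(1 + 2 * d)


def heading_level_sim(
    ontology: Ontology, measure: Measure | str, m: HeadingRef, m2: HeadingRef
) -> float:
    """Dispatch a heading-level measure (SP or LC) by name."""
    measure = Measure.from_name(measure)
    if not measure.is_heading_level:
        raise MeasureLevelError(f"{measure.value} is node-level, not heading-level")
    if measure is Measure.SP:
        return sim_sp(ontology, m, m2)
    return sim_lc(ontology, m, m2)
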