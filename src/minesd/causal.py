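"""Causal-loop diagram analysis: signed digraphs, feedback loops, polarity.

A causal loop diagram is a signed digraph of influences: a ``+`` edge means
an increase in the source raises the target, a ``-`` edge that it lowers it.
A feedback loop (elementary cycle) is *positive* (reinforcing) when it has an
even number of negative edges, *negative* (balancing) when odd.

The built-in mining-area fixture wires the policy loop diagram: GDP funds a
fixed environmental-investment budget, the budget splits into five treatment
investments (air, solid waste, water, vegetation, land reclamation), each
investment moves its environmental indicator, the indicators feed back on
pollution-control cost / mining revenue / GDP on one side and on aggregate
ecological-environment quality on the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "SignedDigraph",
    "FeedbackLoop",
    "classify_polarity",
    "enumerate_loops",
    "figure_fixture",
    "read_edgelist",
    "write_edgelist",
]


@dataclass(frozen=True)
class SignedDigraph:
    """A directed graph whose edges carry a polarity sign (+1 or -1)."""

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, int], ...]

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for u, v, s in self.edges:
            if s not in (1, -1):
                raise ValueError(f"edge ({u!r}, {v!r}) has sign {s!r}; must be +1 or -1")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "SignedDigraph":
        edges = tuple(sorted((str(u), str(v), int(s)) for u, v, s in edges))
        nodes = frozenset(extra_nodes) | {u for u, _, _ in edges} | {v for _, v, _ in edges}
        return cls(nodes=nodes, edges=edges)

    def sign_of(self, u: str, v: str) -> int:
        for a, b, s in self.edges:
            if (a, b) == (u, v):
                return s
        raise KeyError(f"no edge ({u!r}, {v!r})")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, s in self.edges:
            g.add_edge(u, v, sign=s)
        return g


def classify_polarity(loop_signs: Sequence[int]) -> str:
    """``positive`` iff the loop has an even number of negative edges."""
    signs = list(loop_signs)
    if not signs:
        raise ValueError("a feedback loop has at least one edge")
    if any(s not in (1, -1) for s in signs):
        raise ValueError("signs must be +1 or -1")
    negatives = sum(1 for s in signs if s == -1)
    return "positive" if negatives % 2 == 0 else "negative"


@dataclass(frozen=True)
class FeedbackLoop:
    """An elementary cycle in canonical rotation with its edge signs."""

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]

    def __post_init__(self):
        if len(self.nodes) != len(self.edge_signs):
            raise ValueError("one sign per edge of the cycle")

    @property
    def polarity(self) -> str:
        return classify_polarity(self.edge_signs)

    def __str__(self) -> str:
        arrows = "".join(
            f"{n} →{'+' if s == 1 else '-'} "
            for n, s in zip(self.nodes, self.edge_signs)
        )
        return f"({self.polarity}) {arrows}{self.nodes[0]}"


def _canonical(cycle: Sequence[str]) -> tuple[str, ...]:
    """Rotate so the lexicographically smallest node comes first."""
    i = min(range(len(cycle)), key=lambda k: cycle[k])
    return tuple(cycle[i:]) + tuple(cycle[:i])


def enumerate_loops(graph: SignedDigraph) -> list[FeedbackLoop]:
    """Every elementary cycle, once, canonically rotated, lexicographically sorted."""
    g = graph.to_networkx()
    loops = []
    for cycle in nx.simple_cycles(g):
        nodes = _canonical(cycle)
        signs = tuple(
            g.edges[nodes[i], nodes[(i + 1) % len(nodes)]]["sign"]
            for i in range(len(nodes))
        )
        loops.append(FeedbackLoop(nodes=nodes, edge_signs=signs))
    loops.sort(key=lambda lp: lp.nodes)
    return loops


# Display names as they appear in the causal loop diagram.
GDP = "GDP"
ENV_INVESTMENT = "Environmental Investment"
COST = "Cost of pollution control"
REVENUE = "Mining revenue"
ECO_QUALITY = "Ecological environment quality"

# (investment node, indicator node, indicator kind) per subsystem.  A
# "quality" indicator rises with investment, raises eco-quality and lowers
# control cost; a "pollution" index falls with investment, lowers eco-quality
# and raises control cost.
_BRANCHES = (
    ("Investment in air treatment", "Air quality", "quality"),
    ("Investment in solid waste management", "Solid pollution index", "pollution"),
    ("Investment in water pollution control", "Water pollution index", "pollution"),
    ("Vegetation investment", "Vegetation greening rate", "quality"),
    ("Investment in land reclamation", "Land reclamation rate", "quality"),
)


def figure_fixture() -> SignedDigraph:
    """The built-in mining-area causal loop diagram.

    The published loop listings carry a handful of mutually inconsistent edge
    signs (the same edge printed with both polarities in different loops);
    this fixture uses the unique semantically consistent sign table, under
    which the five GDP-revenue loops are reinforcing and the five
    eco-quality-budget loops are balancing.
    """
    edges = [
        (GDP, ENV_INVESTMENT, +1),
        (COST, REVENUE, -1),
        (REVENUE, GDP, +1),
        (ECO_QUALITY, ENV_INVESTMENT, -1),
    ]
    for investment, indicator, kind in _BRANCHES:
        s = +1 if kind == "quality" else -1
        edges += [
            (ENV_INVESTMENT, investment, +1),
            (investment, indicator, s),
            (indicator, COST, -s),
            (indicator, ECO_QUALITY, s),
        ]
    return SignedDigraph.from_edges(edges)


def write_edgelist(graph: SignedDigraph, path) -> None:
    """One edge per line: ``source<TAB>target<TAB>+|-``."""
    lines = [f"{u}\t{v}\t{'+' if s == 1 else '-'}\n" for u, v, s in graph.edges]
    Path(path).write_text("".join(lines))


def read_edgelist(path) -> SignedDigraph:
    edges = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3 or parts[2] not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: expected 'source<TAB>target<TAB>+|-'")
        edges.append((parts[0], parts[1], 1 if parts[2] == "+" else -1))
    return SignedDigraph.from_edges(edges)
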