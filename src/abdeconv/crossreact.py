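"""Cross-reactivity matrix and antibody graph construction.

Testing one immunogen at a time against the whole array yields, for each
antibody j, a column of signals on every spot i. After background
subtraction and positivity gating, the column is normalised to the cognate
signal, giving the cross-reactivity matrix G with G_jj = 1 and
G_ij = (F_i - B) / (F_j - B). The associated antibody graph has a directed
link j -> i of weight G_ij for every positive off-diagonal entry; nodes
with out-going links are type A (their immunogen lights other spots),
nodes without are type B.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .quantify import DEFAULT_MULTIPLIER, AssayProfile, positivity_call

__all__ = [
    "CrossReactivityMatrix",
    "AntibodyGraph",
    "CognateSignalError",
    "build_matrix",
    "prune_antibodies",
    "build_graph",
    "DEFAULT_WEAK_LINK_FLOOR",
]

#: Off-diagonal entries below this, after positivity gating, are zeroed —
#: they are background-ratio noise, not reproducible cross-reactions.
DEFAULT_WEAK_LINK_FLOOR = 0.01


class CognateSignalError(ValueError):
    """An antibody's own immunogen failed the positivity rule.

    Such antibodies cannot anchor a matrix column; prune them first
    (see :func:`prune_antibodies`).
    """

    def __init__(self, failing: list[str]):
        self.failing = list(failing)
        super().__init__(
            "cognate self-signal fails positivity for: "
            + ", ".join(self.failing)
            + "; prune these antibodies before building the matrix"
        )


@dataclass(frozen=True)
class CrossReactivityMatrix:
    """N x N matrix G over ``antibody_order`` with unit diagonal."""

    antibody_order: tuple[str, ...]
    G: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        n = len(self.antibody_order)
        if G.shape != (n, n):
            raise ValueError(f"G shape {G.shape} does not match {n} antibodies")
        if not np.allclose(np.diag(G), 1.0):
            raise ValueError("G must have unit diagonal (G_jj = 1)")
        if (G < 0).any():
            raise ValueError("G entries must be non-negative")
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "antibody_order", tuple(self.antibody_order))

    @property
    def n(self) -> int:
        return len(self.antibody_order)

    def index(self, code: str) -> int:
        return self.antibody_order.index(code)

    def subset(self, codes) -> "CrossReactivityMatrix":
        idx = [self.index(c) for c in codes]
        return CrossReactivityMatrix(tuple(codes), self.G[np.ix_(idx, idx)])


@dataclass(frozen=True)
class AntibodyGraph:
    """Directed weighted graph over antibodies (self-loops omitted)."""

    graph: nx.DiGraph

    @classmethod
    def from_matrix(cls, matrix: CrossReactivityMatrix) -> "AntibodyGraph":
        g = nx.DiGraph()
        order = matrix.antibody_order
        g.add_nodes_from(order)
        G = matrix.G
        for j, src in enumerate(order):
            for i, dst in enumerate(order):
                if i != j and G[i, j] > 0:
                    g.add_edge(src, dst, weight=float(G[i, j]))
        for node in g.nodes:
            g.nodes[node]["node_type"] = "A" if g.out_degree(node) > 0 else "B"
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def node_type(self, code: str) -> str:
        return self.graph.nodes[code]["node_type"]

    def out_neighbors(self, code: str) -> list[tuple[str, float]]:
        """Out-links ``code -> k`` with their weights G_k,code."""
        return [
            (k, self.graph.edges[code, k]["weight"])
            for k in self.graph.successors(code)
        ]


def prune_antibodies(
    panel_assays: dict[str, AssayProfile],
    panel=None,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> list[str]:
    """Antibodies retained for the cross-reactivity matrix.

    An antibody is dropped when its cognate self-signal fails the
    positivity rule in its own single-immunogen assay, or when panel
    metadata flags it as a poor performer (e.g. antibodies that fail in
    sandwich format). Returns the retained codes in assay order.
    """
    flagged = set()
    if panel is not None:
        flagged = {e.code for e in panel.entries if e.poor_performer}
    retained = []
    for code, profile in panel_assays.items():
        if code in flagged:
            continue
        b = profile.background
        if b is None:
            raise ValueError(f"assay for {code!r} has no background estimate")
        f_self = float(profile.data.loc[code, "F"])
        if positivity_call(f_self, b, multiplier):
            retained.append(code)
    if not retained:
        raise ValueError("pruning removed every antibody; no usable panel")
    return retained


def build_matrix(
    panel_assays: dict[str, AssayProfile],
    multiplier: float = DEFAULT_MULTIPLIER,
    weak_link_floor: float = DEFAULT_WEAK_LINK_FLOOR,
    antibody_order=None,
) -> CrossReactivityMatrix:
    """Build G from one single-immunogen assay per antibody.

    Column j comes from the assay of antibody j's cognate immunogen:
    G_ij = (F_i - B) / (F_j - B) on background-subtracted signals, with
    G_ij forced to 0 whenever spot i fails the positivity rule in that
    assay, and G_jj = 1 by construction. Off-diagonal values below
    ``weak_link_floor`` are zeroed.

    Raises
    ------
    CognateSignalError
        If any cognate self-signal fails positivity (candidates for
        pruning are listed, never silently kept).
    """
    order = list(antibody_order) if antibody_order is not None else list(panel_assays)
    missing = [c for c in order if c not in panel_assays]
    if missing:
        raise ValueError(f"no panel assay for: {missing}")

    failing = []
    for code in order:
        prof = panel_assays[code]
        if prof.background is None:
            raise ValueError(f"assay for {code!r} has no background estimate")
        if not positivity_call(prof.data.loc[code, "F"], prof.background, multiplier):
            failing.append(code)
    if failing:
        raise CognateSignalError(failing)

    n = len(order)
    G = np.zeros((n, n))
    for j, code in enumerate(order):
        prof = panel_assays[code]
        b = prof.background
        f = prof.f_vector(order)
        positive = positivity_call(f, b, multiplier)
        denom = f[j] - b
        col = np.where(positive, (f - b) / denom, 0.0)
        col = np.maximum(col, 0.0)
        col[np.abs(col) < weak_link_floor] = 0.0
        col[j] = 1.0
        G[:, j] = col
    return CrossReactivityMatrix(tuple(order), G)


def build_graph(matrix: CrossReactivityMatrix) -> AntibodyGraph:
    """Antibody graph of the matrix: links are positive off-diagonals."""
    return AntibodyGraph.from_matrix(matrix)
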