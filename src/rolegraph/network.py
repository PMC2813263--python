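"""Network data model, edge-list I/O and evidence-to-weight mapping.

Networks are simple undirected weighted graphs: no self-loops, one edge per
unordered node pair, strictly positive weights.  Edges may optionally carry an
evidence category describing the experimental support for the interaction
(yeast two-hybrid, in-vitro, in-vivo, and their combinations), which maps to an
integer weight 1-7 encoding a ranking of belief in the interaction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceCategory",
    "Network",
    "Assignment",
    "parse_evidence",
    "load_network",
    "write_edge_list",
    "largest_component",
    "EVIDENCE_WEIGHTS",
    "HPRD6_INTERACTION_COUNTS",
    "HPRD6_LARGEST_COMPONENT_EDGES",
    "HPRD6_LARGEST_COMPONENT_NODES",
]

# canonical evidence tokens and their accepted spellings
_TOKEN_ALIASES = {
    "y2h": "yeast 2-hybrid",
    "yeast 2-hybrid": "yeast 2-hybrid",
    "yeast two-hybrid": "yeast 2-hybrid",
    "yeast-2-hybrid": "yeast 2-hybrid",
    "yeast2hybrid": "yeast 2-hybrid",
    "in vitro": "in vitro",
    "in-vitro": "in vitro",
    "invitro": "in vitro",
    "in vivo": "in vivo",
    "in-vivo": "in vivo",
    "invivo": "in vivo",
}

# canonical token order used when printing combined labels
_TOKEN_ORDER = ("in vitro", "in vivo", "yeast 2-hybrid")

#: Evidence category -> integer link weight (ranking of belief).
EVIDENCE_WEIGHTS: dict[frozenset, int] = {
    frozenset({"yeast 2-hybrid"}): 1,
    frozenset({"in vitro"}): 2,
    frozenset({"in vitro", "yeast 2-hybrid"}): 3,
    frozenset({"in vivo"}): 4,
    frozenset({"in vivo", "yeast 2-hybrid"}): 5,
    frozenset({"in vitro", "in vivo"}): 6,
    frozenset({"in vitro", "in vivo", "yeast 2-hybrid"}): 7,
}

#: Interaction counts per evidence category in the HPRD release 6 largest
#: connected component, kept as reference metadata for bookkeeping checks.
HPRD6_INTERACTION_COUNTS: dict[str, int] = {
    "yeast 2-hybrid": 6580,
    "in vitro": 7872,
    "in vitro+yeast 2-hybrid": 1298,
    "in vivo": 6721,
    "in vivo+yeast 2-hybrid": 824,
    "in vitro+in vivo": 6877,
    "in vitro+in vivo+yeast 2-hybrid": 2159,
}
HPRD6_LARGEST_COMPONENT_EDGES = 32331
HPRD6_LARGEST_COMPONENT_NODES = 8756

_DELIMITERS = re.compile(r"[;,+|/]")


@dataclass(frozen=True, order=True)
class EvidenceCategory:
    """A canonical combination of evidence tokens with its link weight."""

    weight: int
    label: str
    tokens: frozenset = field(compare=False)

    @staticmethod
    def from_tokens(tokens: Iterable[str]) -> "EvidenceCategory":
        tok = frozenset(tokens)
        try:
            weight = EVIDENCE_WEIGHTS[tok]
        except KeyError:
            raise ValueError(f"unknown evidence combination: {sorted(tok)}") from None
        label = "+".join(t for t in _TOKEN_ORDER if t in tok)
        return EvidenceCategory(weight=weight, label=label, tokens=tok)

    @staticmethod
    def from_weight(weight: int) -> "EvidenceCategory":
        for tok, w in EVIDENCE_WEIGHTS.items():
            if w == int(weight):
                return EvidenceCategory.from_tokens(tok)
        raise ValueError(f"no evidence category has weight {weight!r}")


def parse_evidence(label: str) -> EvidenceCategory:
    """Parse a delimiter-separated evidence label into its canonical category.

    Token order and letter case are irrelevant: ``"in vivo;y2h"`` and
    ``"Y2H + In Vivo"`` denote the same category (weight 5).  Unknown tokens
    raise ``ValueError`` naming the offending token.
    """
    tokens = []
    for raw in _DELIMITERS.split(label):
        part = " ".join(raw.strip().lower().split())
        if not part:
            continue
        try:
            tokens.append(_TOKEN_ALIASES[part])
        except KeyError:
            raise ValueError(f"unknown evidence token: {raw.strip()!r}") from None
    if not tokens:
        raise ValueError(f"empty evidence label: {label!r}")
    return EvidenceCategory.from_tokens(tokens)


class Network:
    """Simple undirected weighted network.

    Node identifiers are opaque strings; internal integer indices are assigned
    in first-seen order.  Edges are stored once per unordered pair with a
    positive weight and an optional :class:`EvidenceCategory`.
    """

    def __init__(self) -> None:
        self.node_names: list[str] = []
        self._index: dict[str, int] = {}
        # (i, j) with i < j -> (weight, category-or-None)
        self._edges: dict[tuple[int, int], tuple[float, Optional[EvidenceCategory]]] = {}
        self._adj: list[set[int]] = []

    # -- construction ------------------------------------------------------
    def add_node(self, name: str) -> int:
        idx = self._index.get(name)
        if idx is None:
            idx = len(self.node_names)
            self._index[name] = idx
            self.node_names.append(name)
            self._adj.append(set())
        return idx

    def add_edge(
        self,
        u: str,
        v: str,
        weight: float = 1.0,
        category: Optional[EvidenceCategory] = None,
    ) -> None:
        """Add (or strengthen) the edge ``{u, v}``.

        Self-loops are rejected.  If the pair already exists, the edge with
        the larger weight wins (strongest evidence subsumes weaker reports).
        """
        if u == v:
            raise ValueError(f"self-loop not allowed: {u!r}")
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight!r}")
        i, j = self.add_node(u), self.add_node(v)
        key = (i, j) if i < j else (j, i)
        old = self._edges.get(key)
        if old is None or weight > old[0]:
            self._edges[key] = (float(weight), category)
        self._adj[i].add(j)
        self._adj[j].add(i)

    # -- basic queries -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_names)

    @property
    def m(self) -> int:
        return len(self._edges)

    @property
    def W(self) -> float:
        """Total edge weight."""
        return float(sum(w for w, _ in self._edges.values()))

    def index(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def has_edge(self, u: str, v: str) -> bool:
        i, j = self._index.get(u), self._index.get(v)
        if i is None or j is None:
            return False
        return ((i, j) if i < j else (j, i)) in self._edges

    def neighbors(self, name: str) -> list[str]:
        return [self.node_names[j] for j in sorted(self._adj[self._index[name]])]

    def degree(self, name: str) -> int:
        return len(self._adj[self._index[name]])

    def edges(self) -> Iterator[tuple[str, str, float, Optional[EvidenceCategory]]]:
        for (i, j), (w, cat) in self._edges.items():
            yield self.node_names[i], self.node_names[j], w, cat

    def iter_edge_indices(self) -> Iterator[tuple[int, int, float]]:
        for (i, j), (w, _) in self._edges.items():
            yield i, j, w

    def edge_weight(self, u: str, v: str) -> float:
        i, j = self._index[u], self._index[v]
        key = (i, j) if i < j else (j, i)
        return self._edges[key][0]

    def categories(self) -> dict[Optional[str], int]:
        """Edge counts per evidence category label (None for uncategorised)."""
        out: dict[Optional[str], int] = {}
        for _, _, _, cat in self.edges():
            key = cat.label if cat is not None else None
            out[key] = out.get(key, 0) + 1
        return out

    # -- array views -------------------------------------------------------
    def csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric adjacency as (indptr, neighbors, weights) arrays."""
        deg = np.zeros(self.n, dtype=np.int64)
        for (i, j), _ in self._edges.items():
            deg[i] += 1
            deg[j] += 1
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        nbr = np.zeros(indptr[-1], dtype=np.int64)
        wts = np.zeros(indptr[-1], dtype=np.float64)
        fill = indptr[:-1].copy()
        for (i, j), (w, _) in self._edges.items():
            nbr[fill[i]] = j
            wts[fill[i]] = w
            fill[i] += 1
            nbr[fill[j]] = i
            wts[fill[j]] = w
            fill[j] += 1
        return indptr, nbr, wts

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weight matrix (small networks only)."""
        A = np.zeros((self.n, self.n))
        for i, j, w in self.iter_edge_indices():
            A[i, j] = A[j, i] = w
        return A

    # -- conversions -------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        for u, v, w, cat in self.edges():
            g.add_edge(u, v, weight=w, category=cat)
        return g

    @staticmethod
    def from_edges(
        edges: Iterable[tuple], nodes: Optional[Sequence[str]] = None
    ) -> "Network":
        """Build a network from (u, v, weight[, category]) tuples."""
        net = Network()
        if nodes is not None:
            for name in nodes:
                net.add_node(name)
        for e in edges:
            u, v, w = e[0], e[1], e[2]
            cat = e[3] if len(e) > 3 else None
            net.add_edge(u, v, w, cat)
        return net

    def subnetwork(self, names: Iterable[str]) -> "Network":
        """Induced subgraph, preserving first-seen node order and attributes."""
        keep = set(names)
        sub = Network()
        for name in self.node_names:
            if name in keep:
                sub.add_node(name)
        for u, v, w, cat in self.edges():
            if u in keep and v in keep:
                sub.add_edge(u, v, w, cat)
        return sub


def load_network(path, weight_mode: str = "evidence") -> Network:
    """Read a tab-separated edge list.

    Columns: ``node_a TAB node_b TAB evidence-or-weight``.  In ``evidence``
    mode the third column is an evidence label (see :func:`parse_evidence`);
    in ``numeric`` mode it is a positive real weight and may be omitted
    (defaulting to 1).  Lines starting with ``#`` are skipped.  Self-loops are
    dropped with a logged count; duplicate pairs keep the strongest evidence
    (highest weight).
    """
    if weight_mode not in ("evidence", "numeric"):
        raise ValueError(f"weight_mode must be 'evidence' or 'numeric', got {weight_mode!r}")
    net = Network()
    n_lines = 0
    n_selfloops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed line: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            try:
                if weight_mode == "evidence":
                    if len(parts) < 3:
                        raise ValueError("missing evidence column")
                    cat = parse_evidence(parts[2])
                    w = float(cat.weight)
                else:
                    cat = None
                    w = float(parts[2]) if len(parts) > 2 and parts[2].strip() else 1.0
                    if w <= 0:
                        raise ValueError(f"non-positive weight {w}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            n_lines += 1
            if u == v:
                n_selfloops += 1
                net.add_node(u)
                continue
            net.add_edge(u, v, w, cat)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_selfloops:
        logger.info("dropped %d self-loop(s) while reading %s", n_selfloops, path)
    return net


def write_edge_list(net: Network, path, weight_mode: str = "auto") -> None:
    """Write the canonical TSV edge list: sorted unordered pairs, canonical
    evidence labels (or numeric weights for uncategorised edges)."""
    rows = []
    for u, v, w, cat in net.edges():
        a, b = (u, v) if u <= v else (v, u)
        if cat is not None and weight_mode != "numeric":
            col = cat.label
        else:
            col = f"{w:g}"
        rows.append((a, b, col))
    rows.sort()
    with open(path, "w") as fh:
        for a, b, col in rows:
            fh.write(f"{a}\t{b}\t{col}\n")


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken towards the component containing the
    lexicographically smallest node identifier, so the result is deterministic.
    An empty network is returned unchanged.
    """
    if net.n == 0:
        return net
    seen = [False] * net.n
    components: list[list[int]] = []
    for start in range(net.n):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        stack = [start]
        while stack:
            i = stack.pop()
            for j in net._adj[i]:
                if not seen[j]:
                    seen[j] = True
                    comp.append(j)
                    stack.append(j)
        components.append(comp)
    # tie rule: among equally sized components prefer the one whose smallest
    # node name is lexicographically least
    size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == size]
    best = min(tied, key=lambda c: min(net.node_names[i] for i in c))
    return net.subnetwork(net.node_names[i] for i in best)


class Assignment:
    """Mapping of every node to one of ``q`` roles.

    Roles are stored 0-based in an integer array aligned with the network's
    node order; unused (empty) roles are legal.  Text output uses 1-based
    role labels.
    """

    def __init__(self, roles: Sequence[int], q: int) -> None:
        roles = np.asarray(roles, dtype=np.int64)
        if roles.ndim != 1:
            raise ValueError("roles must be a 1-d sequence")
        if q < 1:
            raise ValueError("q must be >= 1")
        if roles.size and (roles.min() < 0 or roles.max() >= q):
            raise ValueError(f"role indices must lie in [0, {q})")
        self.roles = roles
        self.q = int(q)

    def __len__(self) -> int:
        return self.roles.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Assignment)
            and self.q == other.q
            and np.array_equal(self.roles, other.roles)
        )

    def counts(self) -> np.ndarray:
        return np.bincount(self.roles, minlength=self.q)

    def relabel(self, perm: Sequence[int]) -> "Assignment":
        """Apply a role permutation: new role of a node = perm[old role]."""
        perm = np.asarray(perm, dtype=np.int64)
        return Assignment(perm[self.roles], self.q)

    @staticmethod
    def from_dict(net: Network, mapping: dict, q: int) -> "Assignment":
        unknown = set(mapping) - set(net.node_names)
        if unknown:
            raise ValueError(f"assignment references unknown nodes: {sorted(unknown)[:5]}")
        missing = set(net.node_names) - set(mapping)
        if missing:
            raise ValueError(f"assignment missing nodes: {sorted(missing)[:5]}")
        roles = [mapping[name] for name in net.node_names]
        return Assignment(roles, q)

    def to_dict(self, net: Network) -> dict:
        return {name: int(r) for name, r in zip(net.node_names, self.roles)}

    def write_tsv(self, net: Network, path) -> None:
        with open(path, "w") as fh:
            for name, r in zip(net.node_names, self.roles):
                fh.write(f"{name}\t{int(r) + 1}\n")

    @staticmethod
    def read_tsv(net: Network, path, q: Optional[int] = None) -> "Assignment":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, role = line.split("\t")[:2]
                mapping[name.strip()] = int(role) - 1
        qq = q if q is not None else (max(mapping.values()) + 1 if mapping else 1)
        return Assignment.from_dict(net, mapping, qq)
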