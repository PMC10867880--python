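"""Food-web data model, file I/O, validation, and basic topology.

The central container is :class:`FoodWeb`: a directed graph whose edges run
consumer → resource ("predator to prey"). Bottom-up analyses (cascades,
bottom-up homophily) traverse these links in reverse; :func:`invert_links`
makes that reversal explicit as a new web.

Group labels follow the five ecological groups of a desert terrestrial
community: birds, mammals, reptiles, invertebrate orders, and plant orders.
Plants are basal — they consume nothing — and bird nodes may additionally
carry a residency label (year-round resident vs seasonally present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "Residency",
    "MetabolicType",
    "SpeciesNode",
    "FoodWeb",
    "Violation",
    "read_node_table",
    "read_edge_list",
    "read_adjacency_matrix",
    "write_edge_list",
    "write_node_table",
    "group_degree_stats",
    "trophic_levels",
    "invert_links",
    "validate_web",
]


class Group(str, Enum):
    """Ecological group of a node."""

    bird = "bird"
    mammal = "mammal"
    reptile = "reptile"
    invertebrate = "invertebrate"
    plant = "plant"


class Residency(str, Enum):
    """Seasonal residency status; meaningful for birds only."""

    resident = "resident"
    nonresident = "nonresident"
    not_applicable = "not_applicable"


class MetabolicType(str, Enum):
    """Metabolic category used by the energetics module."""

    vertebrate_endotherm = "vertebrate_endotherm"
    vertebrate_ectotherm = "vertebrate_ectotherm"
    invertebrate = "invertebrate"
    plant = "plant"


_DEFAULT_METABOLIC: dict[Group, MetabolicType] = {
    Group.bird: MetabolicType.vertebrate_endotherm,
    Group.mammal: MetabolicType.vertebrate_endotherm,
    Group.reptile: MetabolicType.vertebrate_ectotherm,
    Group.invertebrate: MetabolicType.invertebrate,
    Group.plant: MetabolicType.plant,
}


@dataclass(frozen=True)
class SpeciesNode:
    """A node of the food web.

    Parameters
    ----------
    id:
        Unique identifier (any non-empty string).
    group:
        One of the five ecological groups.
    name:
        Human-readable name; defaults to ``id``.
    residency:
        ``resident`` / ``nonresident`` for birds, ``not_applicable`` otherwise.
    metabolic_type:
        Defaults from the group (birds/mammals endotherm, reptiles ectotherm,
        invertebrates invertebrate, plants plant).
    """

    id: str
    group: Group
    name: str = ""
    residency: Residency = Residency.not_applicable
    metabolic_type: MetabolicType | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be a non-empty string")
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "residency", Residency(self.residency))
        if not self.name:
            object.__setattr__(self, "name", self.id)
        if self.metabolic_type is None:
            object.__setattr__(
                self, "metabolic_type", _DEFAULT_METABOLIC[self.group]
            )
        else:
            object.__setattr__(
                self, "metabolic_type", MetabolicType(self.metabolic_type)
            )
        if self.group is Group.plant and self.metabolic_type is not MetabolicType.plant:
            raise ValueError(f"plant node {self.id!r} must have plant metabolic type")
        if self.residency is not Residency.not_applicable and self.group is not Group.bird:
            raise ValueError(
                f"residency labels apply only to birds; node {self.id!r} is "
                f"{self.group.value}"
            )


class FoodWeb:
    """Directed consumer → resource graph with labeled nodes.

    Node insertion order is preserved and defines the canonical index used by
    matrix views, so results are deterministic for a given construction order.
    Self-loops are rejected at construction (readers drop them with a warning
    before building the web). The plant-basality invariant is *reported* by
    :func:`validate_web` rather than enforced here, because inverted webs and
    randomized null webs legitimately violate it.
    """

    def __init__(
        self,
        nodes: Iterable[SpeciesNode],
        edges: Iterable[tuple[str, str]],
    ) -> None:
        self._nodes: dict[str, SpeciesNode] = {}
        for n in nodes:
            if n.id in self._nodes:
                raise ValueError(f"duplicate node id {n.id!r}")
            self._nodes[n.id] = n
        edge_set: set[tuple[str, str]] = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in self._nodes or v not in self._nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) references an undeclared node")
            edge_set.add((u, v))
        self._edges = frozenset(edge_set)
        self._resources: dict[str, set[str]] = {i: set() for i in self._nodes}
        self._consumers: dict[str, set[str]] = {i: set() for i in self._nodes}
        for u, v in self._edges:
            self._resources[u].add(v)
            self._consumers[v].add(u)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> Mapping[str, SpeciesNode]:
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    @property
    def ids(self) -> list[str]:
        return list(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def resources_of(self, node_id: str) -> frozenset[str]:
        """Resources (prey) of ``node_id``: successors along consumption edges."""
        return frozenset(self._resources[node_id])

    def consumers_of(self, node_id: str) -> frozenset[str]:
        """Consumers (predators) of ``node_id``."""
        return frozenset(self._consumers[node_id])

    def basal_ids(self) -> list[str]:
        """Nodes with no resources of their own (topologically basal)."""
        return [i for i in self._nodes if not self._resources[i]]

    def group_of(self, node_id: str) -> Group:
        return self._nodes[node_id].group

    def group_members(self, group: Group | str) -> list[str]:
        g = Group(group)
        return [i for i, n in self._nodes.items() if n.group is g]

    # -- matrix / networkx views ------------------------------------------
    def index(self) -> dict[str, int]:
        """Node id → position in the canonical (insertion) order."""
        return {i: k for k, i in enumerate(self._nodes)}

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean matrix ``A[i, j] = True`` iff node ``i`` consumes node ``j``."""
        idx = self.index()
        a = np.zeros((len(self), len(self)), dtype=bool)
        for u, v in self._edges:
            a[idx[u], idx[v]] = True
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, n in self._nodes.items():
            g.add_node(i, group=n.group.value, residency=n.residency.value)
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"FoodWeb(n_nodes={len(self)}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_node_row(row: pd.Series, rownum: int) -> SpeciesNode:
    try:
        group = Group(str(row["group"]).strip())
    except ValueError:
        raise ValueError(
            f"unknown group label {row['group']!r} in node table row {rownum}"
        ) from None
    residency = row.get("residency", None)
    if residency is None or (isinstance(residency, float) and np.isnan(residency)) or str(
        residency
    ).strip() in ("", "nan"):
        residency = Residency.not_applicable
    else:
        try:
            residency = Residency(str(residency).strip())
        except ValueError:
            raise ValueError(
                f"unknown residency label {row['residency']!r} in node table "
                f"row {rownum}"
            ) from None
    name = str(row["name"]) if "name" in row and not pd.isna(row["name"]) else ""
    return SpeciesNode(
        id=str(row["id"]).strip(), group=group, name=name, residency=residency
    )


def read_node_table(path_or_df) -> list[SpeciesNode]:
    """Read a node metadata table (CSV columns ``id,group[,name,residency]``)."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, dtype=str)
    )
    if "id" not in df.columns or "group" not in df.columns:
        raise ValueError("node table must have columns 'id' and 'group'")
    return [_parse_node_row(row, k + 2) for k, (_, row) in enumerate(df.iterrows())]


def _collapse_edges(
    raw: Sequence[tuple[str, str]],
) -> tuple[list[tuple[str, str]], int, int]:
    """Drop self-loops and duplicates; return (edges, n_dup, n_selfloop)."""
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    n_dup = n_self = 0
    for e in raw:
        if e[0] == e[1]:
            n_self += 1
            continue
        if e in seen:
            n_dup += 1
            continue
        seen.add(e)
        out.append(e)
    return out, n_dup, n_self


def read_edge_list(
    path,
    nodes: Iterable[SpeciesNode] | None = None,
    *,
    node_table=None,
    consumer_col: str = "consumer",
    resource_col: str = "resource",
) -> FoodWeb:
    """Read a consumer → resource edge list (CSV).

    Node metadata must come either from ``nodes`` (parsed
    :class:`SpeciesNode` objects) or from ``node_table`` (path or DataFrame,
    see :func:`read_node_table`). Duplicate rows are collapsed and self-loops
    dropped, each with a logged warning; an edge referencing an undeclared
    node is an error.
    """
    if nodes is None:
        if node_table is None:
            raise ValueError("supply node metadata via `nodes` or `node_table`")
        nodes = read_node_table(node_table)
    nodes = list(nodes)
    df = pd.read_csv(path, dtype=str)
    for col in (consumer_col, resource_col):
        if col not in df.columns:
            raise ValueError(f"edge list is missing column {col!r}")
    raw = [
        (str(u).strip(), str(v).strip())
        for u, v in zip(df[consumer_col], df[resource_col])
    ]
    edges, n_dup, n_self = _collapse_edges(raw)
    if n_dup:
        logger.warning("collapsed %d duplicate edge row(s)", n_dup)
    if n_self:
        logger.warning("dropped %d self-loop edge row(s)", n_self)
    declared = {n.id for n in nodes}
    for u, v in edges:
        if u not in declared:
            raise ValueError(f"edge ({u!r}, {v!r}): consumer {u!r} is not declared")
        if v not in declared:
            raise ValueError(f"edge ({u!r}, {v!r}): resource {v!r} is not declared")
    return FoodWeb(nodes, edges)


def read_adjacency_matrix(
    path,
    nodes: Iterable[SpeciesNode] | None = None,
    *,
    node_table=None,
    orientation: str = "rows_consume_cols",
) -> FoodWeb:
    """Read a 0/1 adjacency matrix (CSV; first row and column are labels).

    ``orientation`` is explicit, never guessed: ``rows_consume_cols`` reads a
    1 at (r, c) as "row label consumes column label"; ``cols_consume_rows``
    is the transpose convention. When node metadata is supplied, a plant
    acquiring resources under the chosen orientation triggers a warning — a
    typical symptom of the wrong orientation.
    """
    if orientation not in ("rows_consume_cols", "cols_consume_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if nodes is None:
        if node_table is None:
            raise ValueError("supply node metadata via `nodes` or `node_table`")
        nodes = read_node_table(node_table)
    nodes = list(nodes)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got {df.shape}")
    if set(df.index) != set(df.columns):
        raise ValueError("adjacency row and column labels do not match")
    vals = df.to_numpy()
    uniq = np.unique(vals)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("adjacency matrix must be binary (0/1)")
    df = df.loc[df.index, df.index]  # align columns to row order
    a = df.to_numpy().astype(bool)
    labels = list(df.index)
    if orientation == "cols_consume_rows":
        a = a.T
    raw = [
        (labels[i], labels[j]) for i, j in zip(*np.nonzero(a))
    ]
    edges, _, n_self = _collapse_edges(raw)
    if n_self:
        logger.warning("dropped %d self-loop(s) from adjacency diagonal", n_self)
    declared = {n.id: n for n in nodes}
    missing = [l for l in labels if l not in declared]
    if missing:
        raise ValueError(f"adjacency labels not in node table: {missing[:5]}")
    web = FoodWeb(nodes, edges)
    for pid in web.group_members(Group.plant):
        if web.resources_of(pid):
            logger.warning(
                "plant node %r has resources under orientation %s — check the "
                "adjacency orientation",
                pid,
                orientation,
            )
            break
    return web


def write_edge_list(web: FoodWeb, path) -> None:
    """Write the consumer → resource edge list as CSV (sorted, deterministic)."""
    df = pd.DataFrame(sorted(web.edges), columns=["consumer", "resource"])
    df.to_csv(path, index=False)


def write_node_table(web: FoodWeb, path) -> None:
    rows = [
        {
            "id": n.id,
            "name": n.name,
            "group": n.group.value,
            "residency": n.residency.value,
        }
        for n in web.nodes.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Topology statistics
# ---------------------------------------------------------------------------


def group_degree_stats(web: FoodWeb) -> pd.DataFrame:
    """Total degree (in + out) summarized by group.

    Returns a DataFrame indexed by group name with columns
    ``n, mean, sd, median``; groups with no nodes are absent (not zero).
    The sum of total degree over all nodes equals ``2 * n_edges``.
    """
    deg = {i: len(web.resources_of(i)) + len(web.consumers_of(i)) for i in web.ids}
    rows = {}
    for g in Group:
        members = web.group_members(g)
        if not members:
            continue
        d = np.array([deg[i] for i in members], dtype=float)
        rows[g.value] = {
            "n": len(members),
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
            "median": float(np.median(d)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


class StrandedConsumerError(ValueError):
    """A consumer has no directed path to any basal node."""

    def __init__(self, stranded: Sequence[str]):
        self.stranded = list(stranded)
        super().__init__(
            "consumer(s) with no directed path to a basal node: "
            + ", ".join(sorted(self.stranded))
        )


def trophic_levels(web: FoodWeb) -> dict[str, float]:
    """Prey-averaged trophic levels.

    Basal nodes (no resources) sit at level 1; every consumer sits one level
    above the mean level of its resources: ``TL(j) = 1 + mean_i TL(i)`` over
    resources ``i`` of ``j``. Solved as a linear system, so consumption
    cycles are permitted as long as every consumer has some directed path
    down to a basal node; a stranded consumer raises
    :class:`StrandedConsumerError` naming the stranded nodes.
    """
    ids = web.ids
    if not ids:
        return {}
    idx = web.index()
    basal = set(web.basal_ids())
    # reachability down to basal along consumer → resource edges
    reach = set(basal)
    frontier = set(basal)
    while frontier:
        nxt = {
            c
            for r in frontier
            for c in web.consumers_of(r)
            if c not in reach
        }
        # a consumer is reachable as soon as *one* resource is (any path works)
        reach |= nxt
        frontier = nxt
    stranded = [i for i in ids if i not in reach]
    if stranded:
        raise StrandedConsumerError(stranded)
    n = len(ids)
    m = np.eye(n)
    for j in ids:
        res = web.resources_of(j)
        if not res:
            continue
        w = 1.0 / len(res)
        for r in res:
            m[idx[j], idx[r]] -= w
    tl = np.linalg.solve(m, np.ones(n))
    return {i: float(tl[idx[i]]) for i in ids}


def invert_links(web: FoodWeb) -> FoodWeb:
    """Reverse every edge (u, v) → (v, u); node set unchanged.

    The inverted web reads resource → consumer and is the bottom-up view used
    for homophily. Applying the inversion twice returns the original web.
    """
    return FoodWeb(web.nodes.values(), [(v, u) for u, v in web.edges])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_web`."""

    kind: str  # self_loop | plant_consumes | duplicate_edge | undeclared_endpoint
    subject: tuple[str, ...]

    def __str__(self) -> str:
        return f"{self.kind}: {', '.join(self.subject)}"


def validate_web(
    web: FoodWeb | None = None,
    *,
    nodes: Iterable[SpeciesNode] | None = None,
    edges: Iterable[tuple[str, str]] | None = None,
) -> list[Violation]:
    """Report invariant violations; an empty list means the web is valid.

    Accepts either a constructed :class:`FoodWeb` (whose constructor already
    rejects self-loops and undeclared endpoints, so only ``plant_consumes``
    can fire) or raw ``nodes``/``edges`` lists, for pre-construction checks.
    """
    out: list[Violation] = []
    if web is not None:
        node_map = dict(web.nodes)
        edge_list: list[tuple[str, str]] = list(web.edges)
    else:
        node_map = {n.id: n for n in (nodes or [])}
        edge_list = list(edges or [])
    seen: set[tuple[str, str]] = set()
    for u, v in edge_list:
        if u == v:
            out.append(Violation("self_loop", (u,)))
            continue
        if u not in node_map or v not in node_map:
            out.append(Violation("undeclared_endpoint", (u, v)))
            continue
        if (u, v) in seen:
            out.append(Violation("duplicate_edge", (u, v)))
            continue
        seen.add((u, v))
        if node_map[u].group is Group.plant:
            out.append(Violation("plant_consumes", (u, v)))
    return out
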